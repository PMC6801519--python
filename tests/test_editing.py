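"""Replicate-aware C→U editing calling, binning and mismatch signatures."""

import numpy as np
import pandas as pd
import pytest

from mitoatlas.editing import (
    EditingSite,
    PILEUP_COLUMNS,
    PileupTable,
    bin_efficiencies,
    call_editing_sites,
    detect_mismatch_signatures,
    read_pileup,
)
from mitoatlas.genome_model import GeneFeature, MitoGenome, Molecule
from mitoatlas.simulate import generate_genome, simulate_pileups

from conftest import codes_to_seq


def _pileup(library, rows):
    return PileupTable(library, pd.DataFrame(rows, columns=PILEUP_COLUMNS))


def _simple_genome():
    #            123456789
    seq = "AACGTACGTTACGTACGTTA" * 5
    return MitoGenome([Molecule("m", seq)])


def _site_rows(pos, ref, counts_by_lib):
    """counts_by_lib: list of (A, C, G, T) per library."""
    return [
        [("m", pos, ref, *c)] for c in counts_by_lib
    ]


class TestReadPileup:
    def test_well_formed_file(self, tmp_path):
        p = tmp_path / "p.tsv"
        rows = [f"m\t{i}\tC\t0\t90\t0\t10" for i in range(1, 11)]
        p.write_text("\t".join(PILEUP_COLUMNS) + "\n" + "\n".join(rows) + "\n")
        table = read_pileup(p)
        assert len(table.data) == 10
        assert (table.depth() == 100).all()

    def test_negative_count_errors(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("\t".join(PILEUP_COLUMNS) + "\nm\t1\tC\t0\t-1\t0\t0\n")
        with pytest.raises(ValueError, match="negative"):
            read_pileup(p)

    def test_ref_mismatch_vs_genome_names_position(self, tmp_path):
        genome = _simple_genome()
        p = tmp_path / "p.tsv"
        p.write_text(
            "\t".join(PILEUP_COLUMNS)
            + "\nm\t3\tC\t0\t50\t0\t0\n"   # genome has C at 3: fine
            + "m\t5\tG\t0\t0\t50\t0\n"     # genome has T at 5: mismatch
        )
        with pytest.raises(ValueError, match="m:5"):
            read_pileup(p, genome=genome)


class TestCallingRules:
    def _call(self, counts_by_lib, pos=3, ref="C", strand="+", **kw):
        genome = _simple_genome()
        feats = [GeneFeature("m", "cds", [(1, 100)], strand, "g1")]
        pileups = [
            _pileup(f"lib{i + 1}", rows)
            for i, rows in enumerate(_site_rows(pos, ref, counts_by_lib))
        ]
        return call_editing_sites(pileups, genome, feats, **kw)

    def test_high_efficiency_site_called_and_binned(self):
        # three libraries at ~96% edited
        sites = self._call([(0, 4, 0, 96), (0, 4, 0, 96), (0, 5, 0, 95)])
        assert len(sites) == 1
        s = sites[0]
        assert s.strand == "+"
        assert s.supporting_libraries == 3
        assert abs(s.pooled_efficiency - 0.957) < 0.01
        assert s.efficiency_bin == "high"

    def test_single_supporting_library_not_called(self):
        # fractions (0.12, 0.08, 0.09): only one library reaches 10%
        sites = self._call([(0, 88, 0, 12), (0, 92, 0, 8), (0, 91, 0, 9)])
        assert sites == []

    def test_two_of_three_rule(self):
        sites = self._call([(0, 80, 0, 20), (0, 85, 0, 15), (0, 95, 0, 5)])
        assert len(sites) == 1
        assert sites[0].supporting_libraries == 2

    def test_minus_strand_gene_uses_g_to_a(self):
        # genomic G at 4, gene on minus strand: edited base is A
        sites = self._call([(30, 0, 70, 0)] * 3, pos=4, ref="G", strand="-")
        assert len(sites) == 1
        assert sites[0].strand == "-"
        assert abs(sites[0].pooled_efficiency - 0.30) < 1e-9

    def test_depth_threshold_applies_per_library(self):
        # high fraction but depth below 10 in two libraries
        sites = self._call([(0, 1, 0, 4), (0, 1, 0, 4), (0, 20, 0, 80)])
        assert sites == []

    def test_unannotated_position_marked_ambiguous(self):
        genome = _simple_genome()
        pileups = [_pileup(f"l{i}", [("m", 3, "C", 0, 50, 0, 50)])
                   for i in range(3)]
        sites = call_editing_sites(pileups, genome, features=[])
        assert len(sites) == 1
        assert sites[0].strand == "ambiguous"

    def test_pooled_efficiency_within_library_range(self):
        sites = self._call([(0, 60, 0, 40), (0, 40, 0, 60), (0, 50, 0, 50)])
        s = sites[0]
        lo, hi = min(s.per_library_fraction), max(s.per_library_fraction)
        assert lo <= s.pooled_efficiency <= hi

    def test_monotonicity_in_thresholds(self):
        counts = [(0, 70, 0, 30), (0, 75, 0, 25), (0, 90, 0, 10)]
        base = self._call(counts)
        assert len(base) == 1
        assert self._call(counts, min_frac=0.35) == []
        assert self._call(counts, min_libs=3, min_frac=0.10) != []
        assert self._call(counts, min_depth=1000) == []


class TestStrandSymmetry:
    def test_mirrored_genome_gives_mirrored_calls(self):
        genome, truth = generate_genome(seed=5, n_editing_sites=20)
        pileups = simulate_pileups(genome, truth, depth_mean=60, seed=5)
        feats = truth.genes + truth.trnas
        sites = call_editing_sites(pileups, genome, feats)
        assert sites

        # mirror: reverse-complement genome, flip strands and coordinates,
        # and swap the pileup count columns A<->T, C<->G
        from mitoatlas.genome_model import reverse_complement

        mirrored_mols = [
            Molecule(m.name, reverse_complement(m.sequence), m.topology)
            for m in genome
        ]
        mg = MitoGenome(mirrored_mols)
        L = {m.name: len(m) for m in genome}

        def flip_feat(f):
            ivs = [(L[f.molecule] - e + 1, L[f.molecule] - s + 1)
                   for s, e in f.intervals]
            return GeneFeature(f.molecule, f.kind, ivs,
                               "-" if f.strand == "+" else "+", f.gene_id)

        mfeats = [flip_feat(f) for f in feats]
        mpileups = []
        for pt in pileups:
            df = pt.data.copy()
            df["position"] = df["molecule"].map(L) - df["position"] + 1
            df["ref"] = df["ref"].map(dict(zip("ACGT", "TGCA")))
            df = df.rename(columns={
                "count_A": "count_T", "count_T": "count_A",
                "count_C": "count_G", "count_G": "count_C",
            })[PILEUP_COLUMNS]
            mpileups.append(PileupTable(pt.library, df))
        msites = call_editing_sites(mpileups, mg, mfeats)
        orig = {(s.molecule, L[s.molecule] - s.position + 1,
                 round(s.pooled_efficiency, 9)) for s in sites}
        mirr = {(s.molecule, s.position, round(s.pooled_efficiency, 9))
                for s in msites}
        assert orig == mirr


class TestBinEfficiencies:
    def test_printed_counts_give_printed_percentages(self):
        sites = (
            [EditingSite("m", i, "+", [1.0], [100], 0.97, 3)
             for i in range(510)]
            + [EditingSite("m", 1000 + i, "+", [0.1], [100], 0.10, 3)
               for i in range(149)]
            + [EditingSite("m", 3000 + i, "+", [0.5], [100], 0.50, 3)
               for i in range(799 - 510 - 149)]
        )
        bins = bin_efficiencies(sites)
        assert bins["n_sites"] == 799
        assert (bins["n_high"], bins["n_low"]) == (510, 149)
        assert bins["pct_high"] == 64
        # 149/799 = 18.65%: nearest-integer rounding gives 19, one point
        # from the usual printed summary of 18%
        assert abs(bins["pct_low"] - 18) <= 1

    def test_all_fully_edited(self):
        sites = [EditingSite("m", i, "+", [1.0], [50], 1.0, 3)
                 for i in range(10)]
        bins = bin_efficiencies(sites)
        assert (bins["pct_high"], bins["pct_low"]) == (100, 0)

    def test_uniform_efficiencies_match_bin_measure(self):
        rng = np.random.default_rng(60)
        effs = rng.uniform(0, 1, 10_000)
        sites = [EditingSite("m", i, "+", [e], [100], float(e), 3)
                 for i, e in enumerate(effs)]
        bins = bin_efficiencies(sites)
        # bins have uniform measure 0.05 and 0.25; 3 s.e. tolerance
        se_high = 100 * np.sqrt(0.05 * 0.95 / 10_000)
        se_low = 100 * np.sqrt(0.25 * 0.75 / 10_000)
        assert abs(bins["pct_high"] - 5) <= 3 * se_high + 0.5
        assert abs(bins["pct_low"] - 25) <= 3 * se_low + 0.5

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            bin_efficiencies([])


class TestMismatchSignatures:
    def test_m1a_style_signature_flagged(self):
        genome = MitoGenome([Molecule("m", "AAAA" + "C" * 16)])
        pileups = [
            _pileup(f"l{i}", [("m", 2, "A", 150, 0, 0, 183)])
            for i in range(3)
        ]
        sigs = detect_mismatch_signatures(pileups, genome)
        assert len(sigs) == 1
        assert abs(sigs[0].pooled_fraction - 0.55) < 0.01
        assert sigs[0].label == "putative m1A"

    def test_pure_reference_not_flagged(self):
        genome = MitoGenome([Molecule("m", "AAAA" + "C" * 16)])
        pileups = [_pileup("l1", [("m", 2, "A", 300, 0, 0, 0)])]
        assert detect_mismatch_signatures(pileups, genome) == []

    def test_editing_type_mismatch_excluded(self):
        genome = MitoGenome([Molecule("m", "AACA" + "C" * 16)])
        pileups = [_pileup("l1", [("m", 3, "C", 0, 70, 0, 30)])]
        # C with 30% T is an editing candidate, never a signature
        sigs = detect_mismatch_signatures(
            pileups, genome, ref_base="C", mismatch_base="T")
        assert sigs == []


class TestSimulatedRecovery:
    def test_recovery_on_simulated_pileups(self):
        genome, truth = generate_genome(seed=6, n_editing_sites=50)
        pileups = simulate_pileups(
            genome, truth, depth_mean=100, error_rate=0.005, seed=6)
        sites = call_editing_sites(
            pileups, genome, truth.genes + truth.trnas)
        truth_map = {(s.molecule, s.position): s.efficiency
                     for s in truth.editing_sites}
        called = {(s.molecule, s.position) for s in sites}
        assert called <= set(truth_map), "no false positives"
        strong = {k for k, e in truth_map.items() if e >= 0.15}
        assert strong <= called, "all strong sites recovered"

    def test_clean_null_has_perfect_specificity(self):
        genome, truth = generate_genome(seed=7, n_editing_sites=10)
        for s in truth.editing_sites:
            s.efficiency = 0.0
        pileups = simulate_pileups(
            genome, truth, depth_mean=80, error_rate=0.0, seed=7)
        sites = call_editing_sites(pileups, genome, truth.genes)
        assert sites == []
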