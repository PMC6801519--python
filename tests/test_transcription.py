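"""Coverage segmentation, promoter scanning, stem-loops, t-elements."""

import numpy as np
import pytest

from mitoatlas.genome_model import GeneFeature, Interval, MitoGenome, Molecule
from mitoatlas.simulate import generate_genome, simulate_coverage
from mitoatlas.transcription import (
    CoverageTrack,
    TranscriptionUnit,
    associate_t_elements,
    classify_five_prime_ends,
    find_stem_loops,
    scan_promoters,
    segment_coverage,
)

from conftest import codes_to_seq
from _oracles import hairpin_oracle, merge_double_stem_loops, revcomp


class TestSegmentation:
    def test_all_zero_coverage_gives_no_units(self):
        track = CoverageTrack("m", "+", np.zeros(5000))
        assert segment_coverage(track) == []

    def test_single_unit_boundaries_within_half_window(self):
        depth = np.full(10_000, 2.0)
        depth[3000:4500] = 500.0
        units = segment_coverage(CoverageTrack("m", "+", depth))
        assert len(units) == 1
        u = units[0]
        assert abs(u.interval.start - 3001) <= 26
        assert abs(u.interval.end - 4500) <= 26

    def test_generated_units_all_recovered_with_correct_strand(self):
        genome, truth = generate_genome(seed=2)
        tracks = simulate_coverage(genome, truth, background_depth=2.0, seed=2)
        units = []
        for track in tracks.values():
            units.extend(segment_coverage(track))
        assert len(units) == len(truth.units)
        for u in units:
            matches = [
                t for t in truth.units
                if t.molecule == u.molecule and t.strand == u.strand
                and abs(t.interval.start - u.interval.start) <= 26
                and abs(t.interval.end - u.interval.end) <= 26
            ]
            assert len(matches) == 1

    def test_merge_gap_and_min_length(self):
        depth = np.full(5000, 1.0)
        depth[1000:1200] = 100.0
        depth[1250:1400] = 100.0   # gap 50 < merge_gap: merged
        depth[3000:3080] = 100.0   # 80 < min_unit_length: dropped
        units = segment_coverage(CoverageTrack("m", "+", depth))
        assert len(units) == 1
        assert units[0].interval.start < 1250 < units[0].interval.end

    def test_units_disjoint_and_sorted(self):
        rng = np.random.default_rng(4)
        depth = np.full(20_000, 2.0)
        for s in (1000, 5000, 9000, 13000):
            depth[s : s + 1500] = rng.uniform(50, 500)
        units = segment_coverage(CoverageTrack("m", "+", depth))
        assert len(units) == 4
        for a, b in zip(units, units[1:]):
            assert a.interval.end < b.interval.start

    def test_raising_threshold_never_adds_covered_bases(self):
        rng = np.random.default_rng(5)
        depth = rng.poisson(3.0, 10_000).astype(float)
        depth[2000:3500] += 80
        depth[6000:6800] += 20
        def covered(mult):
            units = segment_coverage(
                CoverageTrack("m", "+", depth), background_mult=mult)
            return sum(u.interval.end - u.interval.start + 1 for u in units)
        c = [covered(m) for m in (2, 5, 10, 20)]
        assert all(a >= b for a, b in zip(c, c[1:]))


class TestPromoterScan:
    def _unit(self, start, end, strand="+"):
        return TranscriptionUnit("m", strand, Interval(start, end), 100.0)

    def test_planted_motif_found_at_offset(self):
        rng = np.random.default_rng(6)
        seq = list(codes_to_seq(rng.integers(0, 4, 2000)))
        # CGTA ending 31 nt before a unit starting at 1001 -> offset 30
        seq[966:970] = list("CGTA")
        genome = MitoGenome([Molecule("m", "".join(seq))])
        hits = scan_promoters(genome, [self._unit(1001, 1500)])
        cgta = [h for h in hits if h.motif == "CGTA" and h.position == 967]
        assert cgta and cgta[0].offset == 30

    def test_all_t_window_has_no_hits(self):
        genome = MitoGenome([Molecule("m", "T" * 500)])
        assert scan_promoters(genome, [self._unit(201, 400)]) == []

    def test_hits_sorted_closest_first(self):
        seq = list("T" * 500)
        seq[186:193] = list("TATATAA")  # ends at 193: offset 12 from 206
        seq[121:125] = list("CGTA")     # ends at 125: offset 80
        genome = MitoGenome([Molecule("m", "".join(seq))])
        hits = scan_promoters(genome, [self._unit(206, 400)])
        assert hits[0].motif == "TATATAA"
        assert hits[0].offset == 12
        assert hits[0].offset <= hits[-1].offset

    def test_minus_strand_motif(self):
        rng = np.random.default_rng(7)
        seq = list(codes_to_seq(rng.integers(0, 4, 1000)))
        # unit on minus strand ending at 400: upstream is 401..500
        seq[430:434] = list(revcomp("CGTA"))
        genome = MitoGenome([Molecule("m", "".join(seq))])
        hits = scan_promoters(genome, [self._unit(101, 400, "-")])
        cgta = [h for h in hits if h.motif == "CGTA"]
        assert cgta
        from mitoatlas.genome_model import subsequence
        h = cgta[0]
        text = subsequence(genome["m"],
                           Interval(h.position, h.position + 3), "-")
        assert text == "CGTA"

    def test_every_hit_literally_present(self):
        genome, truth = generate_genome(seed=8)
        tracks = simulate_coverage(genome, truth, seed=8)
        units = []
        for track in tracks.values():
            units.extend(segment_coverage(track))
        from mitoatlas.genome_model import subsequence
        hits = scan_promoters(genome, units)
        assert hits
        for h in hits:
            iv = Interval(h.position, h.position + len(h.motif) - 1)
            assert subsequence(genome[h.molecule], iv, h.strand) == h.motif

    def test_window_truncated_at_linear_edge(self):
        genome = MitoGenome([Molecule("m", "T" * 300)])
        hits = scan_promoters(genome, [self._unit(50, 200)])
        assert hits == []  # no motifs, but no crash; flag covered below
        seq = list("T" * 300)
        seq[10:14] = list("CGTA")
        genome = MitoGenome([Molecule("m", "".join(seq))])
        hits = scan_promoters(genome, [self._unit(50, 200)])
        assert hits and hits[0].truncated_window


class TestStemLoops:
    def _hairpin(self, stem, loop_seq, rng):
        # loop edges chosen not to pair, so the planted stem is maximal
        arm = codes_to_seq(rng.integers(0, 4, stem))
        return arm + loop_seq + revcomp(arm)

    def test_planted_perfect_hairpin(self):
        rng = np.random.default_rng(9)
        hp = self._hairpin(12, "TTCTTT", rng)
        seq = "A" * 30 + hp + "A" * 20
        genome = MitoGenome([Molecule("m", seq)])
        sls = find_stem_loops(genome, "m", Interval(1, len(seq)),
                              max_mismatch=0)
        assert len(sls) == 1
        assert sls[0].stem_length == 12
        assert sls[0].loop_length == 6
        assert sls[0].mismatches == 0
        assert sls[0].kind == "single"

    def test_two_hairpins_merge_into_double(self):
        rng = np.random.default_rng(10)
        hp1 = self._hairpin(10, "TTCT", rng)
        hp2 = self._hairpin(9, "TCTGT", rng)
        seq = "A" * 20 + hp1 + "A" * 8 + hp2 + "A" * 20
        genome = MitoGenome([Molecule("m", seq)])
        sls = find_stem_loops(genome, "m", Interval(1, len(seq)),
                              max_mismatch=0, search_window=len(seq))
        doubles = [s for s in sls if s.kind == "double"]
        assert len(doubles) == 1
        assert doubles[0].stem_length == 10

    @pytest.mark.parametrize("seed", range(12))
    def test_equals_exhaustive_oracle_on_random_windows(self, seed):
        rng = np.random.default_rng(2000 + seed)
        n = int(rng.integers(60, 121))
        seq = codes_to_seq(rng.integers(0, 4, n))
        genome = MitoGenome([Molecule("m", seq)])
        got = find_stem_loops(genome, "m", Interval(1, n),
                              search_window=n)
        expected = merge_double_stem_loops(hairpin_oracle(seq))
        got_rows = sorted(
            (s.interval.start - 1, s.interval.end - 1, s.stem_length,
             s.mismatches, s.kind) for s in got
        )
        exp_rows = sorted(
            (s, e, stem, mism, kind) for s, e, stem, loop, mism, kind
            in expected
        )
        assert got_rows == exp_rows


class TestTElements:
    def _setup(self, trna_iv, unit_iv, trna_strand="+", unit_strand="+"):
        trna = GeneFeature("m", "tRNA", [trna_iv], trna_strand, "t1")
        unit = TranscriptionUnit("m", unit_strand, Interval(*unit_iv), 50.0)
        associate_t_elements([unit], [trna])
        return unit

    def test_trna_upstream_of_unit_start_marks_five_prime(self):
        unit = self._setup((100, 172), (178, 600))
        assert unit.five_prime_feature == "t_element"

    def test_trna_downstream_of_unit_end_marks_three_prime(self):
        unit = self._setup((615, 687), (200, 600))
        assert unit.three_prime_feature == "t_element"

    def test_opposite_strand_trna_ignored(self):
        unit = self._setup((100, 172), (178, 600), trna_strand="-")
        assert unit.five_prime_feature == "none"

    def test_distant_trna_ignored(self):
        unit = self._setup((100, 172), (250, 600))
        assert unit.five_prime_feature == "none"

    def test_minus_strand_geometry(self):
        # minus-strand unit: 5' end is the interval end
        unit = self._setup((610, 682), (200, 600), trna_strand="-",
                           unit_strand="-")
        assert unit.five_prime_feature == "t_element"

    def test_promoter_vs_processing_dichotomy(self):
        seq = list("T" * 800)
        seq[187:194] = list("TATATAA")
        genome = MitoGenome([Molecule("m", "".join(seq))])
        with_promoter = TranscriptionUnit("m", "+", Interval(206, 400), 50.0)
        without = TranscriptionUnit("m", "+", Interval(600, 750), 50.0)
        hits = scan_promoters(genome, [with_promoter, without])
        classify_five_prime_ends([with_promoter, without], hits)
        assert with_promoter.five_prime_feature == "promoter"
        assert without.five_prime_feature == "processing"
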