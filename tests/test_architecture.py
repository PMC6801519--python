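"""Recombination isoform enumeration and in-silico PCR."""

from collections import Counter

import numpy as np
import pytest

from mitoatlas.architecture import (
    _canonical_sequence,
    configuration_key,
    enumerate_isoforms,
    in_silico_pcr,
)
from mitoatlas.genome_model import (
    Interval,
    MitoGenome,
    Molecule,
    reverse_complement,
)
from mitoatlas.repeat_finder import RepeatPair, find_repeats

from conftest import codes_to_seq


def _circle_with_direct_repeat(seed=7, L=10_000, a=1000, b=6000, r=100):
    rng = np.random.default_rng(seed)
    s = rng.integers(0, 4, L)
    s[b : b + r] = s[a : a + r]
    genome = MitoGenome([Molecule("c", codes_to_seq(s), "circular")])
    pair = RepeatPair("c", Interval(a + 1, a + r), "c", Interval(b + 1, b + r),
                      "direct", r, 1.0)
    return genome, pair


class TestExcision:
    def test_direct_repeat_on_circle_gives_two_circles(self):
        genome, pair = _circle_with_direct_repeat()
        configs = enumerate_isoforms(genome, [pair])
        assert len(configs) == 1
        products = configs[0].molecules
        assert sorted(len(m) for m in products) == [5000, 5000]
        assert all(m.topology == "circular" for m in products)

    def test_excision_conserves_total_length(self):
        genome, pair = _circle_with_direct_repeat(a=2000, b=5500)
        (config,) = enumerate_isoforms(genome, [pair])
        assert config.total_length == genome.total_length

    def test_each_product_carries_one_repeat_copy(self):
        genome, pair = _circle_with_direct_repeat()
        (config,) = enumerate_isoforms(genome, [pair])
        repeat_text = genome["c"].sequence[1000:1100]
        for m in config.molecules:
            doubled = m.sequence + m.sequence  # circular product
            starts = [
                i for i in range(len(m.sequence))
                if doubled[i : i + len(repeat_text)] == repeat_text
            ]
            assert len(starts) == 1

    def test_direct_repeat_on_linear_gives_circle_plus_fragments(self):
        rng = np.random.default_rng(8)
        s = rng.integers(0, 4, 10_000)
        s[6000:6100] = s[1000:1100]
        genome = MitoGenome([Molecule("l", codes_to_seq(s), "linear")])
        pair = RepeatPair("l", Interval(1001, 1100), "l", Interval(6001, 6100),
                          "direct", 100, 1.0)
        (config,) = enumerate_isoforms(genome, [pair])
        circles = [m for m in config.molecules if m.topology == "circular"]
        fragments = [m for m in config.molecules if m.discarded]
        assert len(circles) == 1
        assert len(circles[0]) == 5000
        assert len(fragments) == 2  # both terminal remnants retained
        assert config.total_length == genome.total_length

    def test_overlapping_copies_skipped_with_warning(self):
        rng = np.random.default_rng(9)
        s = rng.integers(0, 4, 8000)
        genome = MitoGenome([Molecule("c", codes_to_seq(s), "circular")])
        pair = RepeatPair("c", Interval(1001, 1300), "c", Interval(1200, 1499),
                          "direct", 300, 1.0)
        with pytest.warns(UserWarning, match="overlap"):
            configs = enumerate_isoforms(genome, [pair])
        assert configs == []


class TestInversion:
    def test_inverted_repeat_preserves_length_and_pair_composition(self):
        rng = np.random.default_rng(10)
        s = rng.integers(0, 4, 10_000)
        s[6000:6100] = (3 - s[1000:1100])[::-1]
        genome = MitoGenome([Molecule("c", codes_to_seq(s), "circular")])
        pair = RepeatPair("c", Interval(1001, 1100), "c", Interval(6001, 6100),
                          "inverted", 100, 1.0)
        (config,) = enumerate_isoforms(genome, [pair])
        (product,) = config.molecules
        assert len(product) == 10_000
        before = Counter(genome["c"].sequence)
        after = Counter(product.sequence)
        # double-stranded base-pair content is conserved under inversion
        assert before["A"] + before["T"] == after["A"] + after["T"]
        assert before["G"] + before["C"] == after["G"] + after["C"]

    def test_inner_segment_is_reverse_complemented(self):
        rng = np.random.default_rng(21)
        s = rng.integers(0, 4, 10_000)
        s[6000:6100] = (3 - s[1000:1100])[::-1]
        seq = codes_to_seq(s)
        genome = MitoGenome([Molecule("c", seq, "circular")])
        pair = RepeatPair("c", Interval(1001, 1100), "c", Interval(6001, 6100),
                          "inverted", 100, 1.0)
        (config,) = enumerate_isoforms(genome, [pair])
        product = config.molecules[0].sequence
        assert product[:1000] == seq[:1000]
        assert product[1000:6100] == reverse_complement(seq[1000:6100])
        assert product[6100:] == seq[6100:]


class TestFusionRoundTrip:
    def test_excise_then_fuse_recovers_parent_up_to_rotation(self):
        genome, pair = _circle_with_direct_repeat(seed=30)
        (excised,) = enumerate_isoforms(genome, [pair])
        two_circles = MitoGenome([
            Molecule(m.name, m.sequence, "circular") for m in excised.molecules
        ])
        # the repeat survives as one copy per product, found de novo
        found = find_repeats(two_circles)
        cross = [p for p in found if p.molecule_a != p.molecule_b]
        assert cross, "recombining repeat should be re-detected across circles"
        fused_configs = enumerate_isoforms(two_circles, [cross[0]])
        fused = [m for c in fused_configs for m in c.molecules
                 if len(m) == genome.total_length]
        assert fused
        assert _canonical_sequence(fused[0].sequence, "circular") == \
               _canonical_sequence(genome["c"].sequence, "circular")

    def test_dedup_by_canonical_key(self):
        genome, pair = _circle_with_direct_repeat(seed=31)
        c1 = enumerate_isoforms(genome, [pair])
        c2 = enumerate_isoforms(genome, [pair, pair])  # same event twice
        assert len(c1) == len(c2) == 1
        assert configuration_key(c1[0]) == configuration_key(c2[0])


class TestGuards:
    def test_max_events_guard(self):
        genome, pair = _circle_with_direct_repeat()
        with pytest.raises(ValueError, match="max_events"):
            enumerate_isoforms(genome, [pair], max_events=4)

    def test_unknown_molecule_in_repeat_errors(self):
        genome, _ = _circle_with_direct_repeat()
        bad = RepeatPair("zz", Interval(1, 100), "c", Interval(200, 299),
                         "direct", 100, 1.0)
        with pytest.raises(ValueError, match="unknown molecule"):
            enumerate_isoforms(genome, [bad])


class TestInSilicoPcr:
    def _toy(self):
        rng = np.random.default_rng(40)
        s = codes_to_seq(rng.integers(0, 4, 6000))
        return s

    def test_junction_amplicon_only_in_recombined_configuration(self):
        s = self._toy()
        genome = MitoGenome([Molecule("l", s, "linear")])
        # excision product joins 1000.. and ..4000 around a 100 bp repeat
        rng = np.random.default_rng(41)
        codes = np.frombuffer(s.encode(), np.uint8)
        seq = list(s)
        seq[4000:4100] = seq[1000:1100]
        s2 = "".join(seq)
        genome2 = MitoGenome([Molecule("l", s2, "linear")])
        pair = RepeatPair("l", Interval(1001, 1100), "l", Interval(4001, 4100),
                          "direct", 100, 1.0)
        (config,) = enumerate_isoforms(genome2, [pair])
        circle = next(m for m in config.molecules if m.topology == "circular")
        # primers flanking the excision junction (the circle's origin):
        # the product must wrap, so it exists only in the recombined circle
        fwd = circle.sequence[2800:2820]
        rev_site = circle.sequence[100:120]
        rev = reverse_complement(rev_site)
        amps_parent = in_silico_pcr(genome2, [("j1", fwd, rev)])
        amps_product = in_silico_pcr(config, [("j1", fwd, rev)])
        junction_amp = [a for a in amps_product if a.molecule == circle.name]
        expected = len(circle.sequence) - 2800 + 120  # direct string oracle
        assert junction_amp and junction_amp[0].length == expected
        assert amps_parent == []

    def test_divergent_primers_give_no_amplicon(self):
        s = self._toy()
        genome = MitoGenome([Molecule("l", s, "linear")])
        fwd = s[3000:3020]
        other_plus = s[3500:3520]  # both sit on the plus strand
        amps = in_silico_pcr(genome, [("d1", fwd, other_plus)])
        # the reverse primer as given anneals on the plus strand only:
        # its reverse complement never occurs, so no convergent layout
        assert all(a.length != 520 for a in amps)

    def test_amplicon_across_circular_origin(self):
        s = self._toy()[:1000]
        genome = MitoGenome([Molecule("c", s, "circular")])
        fwd = s[970:990]  # plus-strand site near the end
        rev_site = s[10:30]  # downstream across the origin
        rev = reverse_complement(rev_site)
        amps = in_silico_pcr(genome, [("o1", fwd, rev)])
        assert len(amps) == 1
        a = amps[0]
        assert a.spans_origin
        # oracle: product built by direct string construction
        expected = (s + s)[970 : 1000 + 30]
        assert a.length == len(expected) == 60

    def test_short_primer_rejected(self):
        genome = MitoGenome([Molecule("c", self._toy(), "circular")])
        with pytest.raises(ValueError, match="shorter"):
            in_silico_pcr(genome, [("p", "ACGTACGTACGT", "ACGTACGTACGTACGT")])

    def test_non_acgt_primer_rejected(self):
        genome = MitoGenome([Molecule("c", self._toy(), "circular")])
        with pytest.raises(ValueError, match="non-ACGT"):
            in_silico_pcr(genome, [("p", "ACGTACGTACGTACGN", "ACGTACGTACGTACGT")])
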