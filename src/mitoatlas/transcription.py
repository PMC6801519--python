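"""Coverage segmentation into transcription units and end-feature calls.

Strand-split RNA-seq coverage is median-smoothed and thresholded at a
multiple of the genome-wide median depth to delimit transcription
units.  Unit 5' ends are scanned for the core promoter motifs found
upstream of plant mitochondrial transcription starts (CRTA, R = A/G,
and TATATAA); unit ends near tRNA genes are annotated as
RNase P/Z-style processing signals (t-elements); 3' ends are scanned
for single or double stem-loop structures (inverted-repeat hairpins).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.ndimage import median_filter

from mitoatlas.genome_model import (
    GeneFeature,
    Interval,
    MitoGenome,
    Molecule,
    reverse_complement,
    subsequence,
)


@dataclass
class CoverageTrack:
    """Per-position read depth for one molecule and strand."""

    molecule: str
    strand: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if (self.depth < 0).any():
            raise ValueError("negative depth in coverage track")


@dataclass
class TranscriptionUnit:
    molecule: str
    strand: str
    interval: Interval
    mean_depth: float
    gene_ids: list[str] = field(default_factory=list)
    five_prime_feature: str = "none"   # promoter | t_element | processing | none
    three_prime_feature: str = "none"  # stem_loop | double_stem_loop | t_element | none

    @property
    def five_prime_end(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def three_prime_end(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start


@dataclass(frozen=True)
class PromoterHit:
    molecule: str
    strand: str
    motif: str
    offset: int  # nt upstream of the unit 5' end (0 = immediately adjacent)
    position: int  # 1-based genomic start of the motif match
    unit_five_prime: int = 0  # 5' end of the unit this hit belongs to
    truncated_window: bool = False


@dataclass(frozen=True)
class StemLoop:
    interval: Interval  # full hairpin extent (both arms + loop)
    stem_length: int
    loop_length: int
    mismatches: int
    kind: str  # single | double


def segment_coverage(
    track: CoverageTrack,
    background_mult: float = 5.0,
    min_unit_length: int = 150,
    smooth_window: int = 51,
    merge_gap: int = 100,
    features: Sequence[GeneFeature] = (),
) -> list[TranscriptionUnit]:
    """Segment a coverage track into transcription units.

    Depth is median-filtered over ``smooth_window`` positions and
    thresholded at ``background_mult`` times the track-wide median depth
    (the median is floored at 1 so fully quiescent genomes still get a
    positive threshold).  Above-threshold runs separated by less than
    ``merge_gap`` positions are merged; runs shorter than
    ``min_unit_length`` are dropped.
    """
    depth = track.depth
    if not depth.any():
        return []
    smoothed = median_filter(depth, size=smooth_window, mode="nearest")
    threshold = background_mult * max(float(np.median(depth)), 1.0)
    above = smoothed > threshold
    runs = _runs(above)
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    units = []
    for s, e in merged:
        if e - s + 1 < min_unit_length:
            continue
        iv = Interval(s + 1, e + 1)
        genes = sorted(
            f.gene_id for f in features
            if f.molecule == track.molecule
            and f.strand == track.strand
            and f.start >= iv.start and f.end <= iv.end
        )
        units.append(TranscriptionUnit(
            molecule=track.molecule,
            strand=track.strand,
            interval=iv,
            mean_depth=float(depth[s : e + 1].mean()),
            gene_ids=genes,
        ))
    return units


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """0-based inclusive (start, end) runs of True."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(diff == 1)[0] + 1)
    ends = list(np.nonzero(diff == -1)[0])
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask) - 1)
    return list(zip(starts, ends))


PROMOTER_MOTIFS = ("CATA", "CGTA", "TATATAA")  # CRTA expansions + TATA-like


def scan_promoters(
    genome: MitoGenome,
    units: Sequence[TranscriptionUnit],
    upstream_window: int = 100,
) -> list[PromoterHit]:
    """Scan for core promoter motifs upstream of unit 5' ends.

    Searches the unit strand within ``upstream_window`` nt upstream of
    each 5' end; hits are reported closest-first (smallest offset).  The
    offset is the distance from the motif's 3'-most base to the unit 5'
    end minus one, so a motif ending immediately before the unit has
    offset 0.  At linear molecule edges the window is truncated and the
    hit flagged.
    """
    hits: list[PromoterHit] = []
    for unit in units:
        mol = genome[unit.molecule]
        L = len(mol)
        five = unit.five_prime_end
        truncated = False
        if unit.strand == "+":
            lo = five - upstream_window
            if lo < 1:
                if mol.topology == "linear":
                    lo, truncated = 1, True
            hi = five - 1
            if hi < lo and not (mol.topology == "circular" and lo < 1):
                continue
            if mol.topology == "circular" and lo < 1:
                iv = Interval((lo - 1) % L + 1, hi, wrap=True)
            else:
                iv = Interval(lo, hi)
            window_seq = subsequence(mol, iv, "+")
        else:
            lo = five + 1
            hi = five + upstream_window
            if hi > L:
                if mol.topology == "linear":
                    hi, truncated = L, True
            if hi < lo:
                continue
            if mol.topology == "circular" and hi > L:
                iv = Interval(lo, hi - L, wrap=True)
            else:
                iv = Interval(lo, hi)
            window_seq = subsequence(mol, iv, "-")
        # window_seq reads 5'->3' toward the unit start on the unit strand
        w = len(window_seq)
        unit_hits = []
        for motif in PROMOTER_MOTIFS:
            start = 0
            while True:
                p = window_seq.find(motif, start)
                if p < 0:
                    break
                offset = w - (p + len(motif))
                if unit.strand == "+":
                    genomic = five - upstream_window + p
                    if mol.topology == "circular":
                        genomic = (genomic - 1) % L + 1
                    elif truncated:
                        genomic = lo + p
                else:
                    genomic = five + (w - p) - len(motif) + 1 if truncated else (
                        five + upstream_window - p - len(motif) + 1)
                    if mol.topology == "circular":
                        genomic = (genomic - 1) % L + 1
                unit_hits.append(PromoterHit(
                    molecule=unit.molecule,
                    strand=unit.strand,
                    motif=motif,
                    offset=offset,
                    position=genomic,
                    unit_five_prime=five,
                    truncated_window=truncated,
                ))
                start = p + 1
        unit_hits.sort(key=lambda h: (h.offset, h.motif))
        hits.extend(unit_hits)
    return hits


def _hairpins_in_window(
    seq: str,
    min_stem: int,
    max_loop: int,
    min_loop: int,
    max_mismatch: int,
) -> list[tuple[int, int, int, int]]:
    """Maximal hairpins in ``seq``: (start0, stem, loop, mismatches).

    A hairpin at ``start0`` with arm length ``s`` and loop ``l`` spans
    ``2 s + l`` positions; the left arm must reverse-complement-match the
    right arm with at most ``max_mismatch`` mismatches.  Only hairpins
    whose arms cannot be extended outward (keeping the mismatch budget)
    are reported, which suppresses the nested sub-hairpins of every
    perfect stem.
    """
    n = len(seq)

    def arm_mismatches(loop_start: int, loop_len: int, stem: int) -> int | None:
        """Mismatch count of the stem, or None if invalid.

        Validity requires the arms to fit in the sequence, the innermost
        and outermost pairs to match (no terminal mismatches), and at
        most ``max_mismatch`` mismatched pairs overall.
        """
        if loop_start - stem < 0 or loop_start + loop_len + stem > n:
            return None
        mism = 0
        for t in range(stem):
            a = seq[loop_start - 1 - t]
            b = seq[loop_start + loop_len + t]
            paired = _COMP.get(a) == b
            if not paired:
                if t == 0 or t == stem - 1:
                    return None  # terminal mismatch: not part of the stem
                mism += 1
        return mism if mism <= max_mismatch else None

    found = []
    for loop_start in range(n):
        for loop in range(min_loop, max_loop + 1):
            max_stem = min(loop_start, n - loop_start - loop)
            if max_stem < min_stem:
                continue
            best = None
            mism = 0
            first_matches = False
            for t in range(max_stem):
                a = seq[loop_start - 1 - t]
                b = seq[loop_start + loop + t]
                paired = _COMP.get(a) == b
                if t == 0:
                    first_matches = paired
                if not paired:
                    mism += 1
                    if mism > max_mismatch:
                        break  # mismatches only accumulate outward
                stem = t + 1
                if stem >= min_stem and first_matches and paired:
                    best = (stem, mism)
            if best is None:
                continue
            # loop-minimal: a shrinkable loop means this hairpin is the
            # loop-enlarged shadow of a longer-stemmed one
            if loop - 2 >= min_loop:
                if arm_mismatches(loop_start + 1, loop - 2, best[0] + 1) is not None:
                    continue
            stem, mism = best
            found.append((loop_start - stem, stem, loop, mism))
    return sorted(set(found))


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def find_stem_loops(
    genome: MitoGenome,
    molecule: str,
    region: Interval,
    strand: str = "+",
    min_stem: int = 8,
    max_loop: int = 20,
    min_loop: int = 3,
    max_mismatch: int = 1,
    search_window: int = 80,
) -> list[StemLoop]:
    """Find stem-loops (hairpins) near a region's 3' end.

    Enumerates inverted-repeat hairpins within ``search_window`` nt of
    the 3' end of ``region`` on the given strand.  Two hairpins whose
    spans are separated by at most 10 nt merge into one double
    stem-loop.  Sorted by stem length descending.
    """
    mol = genome[molecule]
    L = len(mol)
    if strand == "+":
        hi = min(region.end, L)
        lo = max(1, hi - search_window + 1)
    else:
        lo = max(region.start, 1)
        hi = min(L, lo + search_window - 1)
    window_seq = mol.sequence[lo - 1 : hi]
    raw = _hairpins_in_window(window_seq, min_stem, max_loop, min_loop, max_mismatch)
    hairpins = []
    for start0, stem, loop, mism in raw:
        g_start = lo + start0
        g_end = g_start + 2 * stem + loop - 1
        hairpins.append(StemLoop(
            interval=Interval(g_start, g_end),
            stem_length=stem,
            loop_length=loop,
            mismatches=mism,
            kind="single",
        ))
    hairpins.sort(key=lambda h: h.interval.start)
    merged: list[StemLoop] = []
    for hp in hairpins:
        if merged and hp.interval.start - merged[-1].interval.end - 1 <= 10 \
                and hp.interval.start > merged[-1].interval.end:
            prev = merged.pop()
            merged.append(StemLoop(
                interval=Interval(prev.interval.start, hp.interval.end),
                stem_length=max(prev.stem_length, hp.stem_length),
                loop_length=prev.loop_length,
                mismatches=prev.mismatches + hp.mismatches,
                kind="double",
            ))
        else:
            merged.append(hp)
    merged.sort(key=lambda h: (-h.stem_length, h.interval.start))
    return merged


def associate_t_elements(
    units: Sequence[TranscriptionUnit],
    trna_features: Sequence[GeneFeature],
    max_dist: int = 20,
) -> None:
    """Label unit ends processed at flanking tRNA genes (in place).

    A unit 5' end at most ``max_dist`` nt downstream of a same-strand
    tRNA 3' end is an RNase Z-style t-element 5' end; a unit 3' end at
    most ``max_dist`` nt upstream of a same-strand tRNA 5' end is an
    RNase P-style t-element 3' end.
    """
    for unit in units:
        for trna in trna_features:
            if trna.kind != "tRNA" or trna.molecule != unit.molecule:
                continue
            if trna.strand != unit.strand:
                continue
            if unit.strand == "+":
                trna5, trna3 = trna.start, trna.end
                d5 = unit.five_prime_end - trna3
                d3 = trna5 - unit.three_prime_end
            else:
                trna5, trna3 = trna.end, trna.start
                d5 = trna3 - unit.five_prime_end
                d3 = unit.three_prime_end - trna5
            if 0 < d5 <= max_dist:
                unit.five_prime_feature = "t_element"
            if 0 < d3 <= max_dist:
                unit.three_prime_feature = "t_element"


def classify_five_prime_ends(
    units: Sequence[TranscriptionUnit],
    promoter_hits: Sequence[PromoterHit],
) -> None:
    """Mark each unannotated unit 5' end as promoter or processing site.

    A 5' end with any promoter motif hit in its own upstream window is
    promoter-driven; remaining ends (not already t-elements) are
    processing sites.
    """
    for unit in units:
        if unit.five_prime_feature == "t_element":
            continue
        has_hit = any(
            h.molecule == unit.molecule and h.strand == unit.strand
            and h.unit_five_prime == unit.five_prime_end
            for h in promoter_hits
        )
        unit.five_prime_feature = "promoter" if has_hit else "processing"
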