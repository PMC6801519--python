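"""Syntenic block detection between two mitochondrial genomes.

Blocks are regions conserved in sequence and order between two genomes,
kept when the aligned region is at least ``min_length`` bp at
``min_identity`` (defaults 5 kb, 95%, the usual organelle comparative
thresholds).  Detection is anchor-and-chain: exact ``seed_k``-mer
matches are chained co-linearly (same or reverse orientation) when the
gaps between consecutive anchors are at most ``chain_gap`` on both
genomes; the chained span is scored by a gap-free columnar comparison
in which inter-anchor bases beyond the shorter side count as
mismatches.  Block length is the query-genome span.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from mitoatlas.genome_model import (
    Interval,
    MitoGenome,
    reverse_complement,
)
from mitoatlas.repeat_finder import _encode, _kmer_codes, _seed_pairs, _N_CODE


@dataclass(frozen=True)
class SyntenyBlock:
    molecule_a: str
    interval_a: Interval
    molecule_b: str
    interval_b: Interval
    orientation: str  # same | reverse
    length: int  # query (genome A) span
    identity: float

    def as_row(self) -> tuple:
        return (
            self.molecule_a, self.interval_a.start, self.interval_a.end,
            self.molecule_b, self.interval_b.start, self.interval_b.end,
            self.orientation, self.length, round(self.identity, 4),
        )


def _merge_anchors(anchors: list[tuple[int, int]], k: int) -> list[tuple[int, int, int]]:
    """Merge overlapping/adjacent same-diagonal anchors into runs.

    Input (i, j) seed starts sorted by i; output (i_start, j_start, length).
    """
    runs: list[list[int]] = []
    for i, j in anchors:
        if runs and runs[-1][2] == j - i and i <= runs[-1][0] + runs[-1][3]:
            runs[-1][3] = max(runs[-1][3], i - runs[-1][0] + k)
        else:
            runs.append([i, j, j - i, k])
    return [(i, j, ln) for i, j, _, ln in runs]


def _chain_runs(
    runs: list[tuple[int, int, int]], chain_gap: int, seed_k: int
) -> list[list[tuple[int, int, int]]]:
    """Greedy co-linear chaining of anchor runs sorted by query position.

    A run joins a chain when it advances it on both genomes, the gaps on
    both sides are at most ``chain_gap`` (small overlaps up to a seed
    length are indel artefacts and allowed), and the diagonal drift
    between the gaps is bounded by ``chain_gap``.
    """
    chains: list[list[tuple[int, int, int]]] = []
    for run in runs:
        i, j, ln = run
        placed = False
        for chain in chains:
            pi, pj, pln = chain[-1]
            gap_a = i - (pi + pln)
            gap_b = j - (pj + pln)
            if (
                -(seed_k - 1) <= gap_a <= chain_gap
                and -(seed_k - 1) <= gap_b <= chain_gap
                and abs(gap_a - gap_b) <= chain_gap
                and i + ln > pi + pln
                and j + ln > pj + pln
            ):
                chain.append(run)
                placed = True
                break
        if not placed:
            chains.append([run])
    return chains


def _score_chain(
    chain: list[tuple[int, int, int]],
    enc_a: np.ndarray,
    enc_b: np.ndarray,
) -> tuple[int, int, int, int, float]:
    """(a0, a1, b0, b1, identity) for a chain, 0-based inclusive ends."""
    a0, b0 = chain[0][0], chain[0][1]
    a1 = chain[-1][0] + chain[-1][2] - 1
    b1 = chain[-1][1] + chain[-1][2] - 1
    matches = 0
    columns = 0
    prev_a_end, prev_b_end = a0, b0
    for i, j, ln in chain:
        # inter-anchor region: columnar compare the overlap, surplus = mismatch
        ga, gb = i - prev_a_end, j - prev_b_end
        if ga > 0 or gb > 0:
            m = min(max(ga, 0), max(gb, 0))
            if m > 0:
                seg_a = enc_a[prev_a_end : prev_a_end + m]
                seg_b = enc_b[prev_b_end : prev_b_end + m]
                matches += int(((seg_a == seg_b) & (seg_a != _N_CODE)).sum())
            columns += max(ga, gb, 0)
        start_i = max(i, prev_a_end)
        trim = start_i - i
        if ln - trim > 0:
            matches += ln - trim
            columns += ln - trim
        prev_a_end, prev_b_end = i + ln, j + ln
    identity = matches / columns if columns else 0.0
    return a0, a1, b0, b1, identity


def find_synteny_blocks(
    genome_a: MitoGenome,
    genome_b: MitoGenome,
    min_length: int = 5000,
    min_identity: float = 0.95,
    seed_k: int = 15,
    chain_gap: int = 500,
) -> list[SyntenyBlock]:
    """Detect syntenic blocks between two genomes.

    Overlapping chains on the query are resolved greedily by length, then
    identity, then leftmost coordinate.  Output sorted by length
    descending.
    """
    if seed_k < 11:
        raise ValueError("seed_k < 11: spurious anchors")
    if not genome_a.molecules or not genome_b.molecules:
        raise ValueError("both genomes must be non-empty")

    candidates: list[SyntenyBlock] = []
    for mol_a in genome_a:
        enc_a = _encode(mol_a.sequence)
        codes_a = _kmer_codes(enc_a, seed_k)
        for mol_b in genome_b:
            for orientation in ("same", "reverse"):
                seq_b = (
                    mol_b.sequence if orientation == "same"
                    else reverse_complement(mol_b.sequence)
                )
                enc_b = _encode(seq_b)
                codes_b = _kmer_codes(enc_b, seed_k)
                ia, jb = _seed_pairs(codes_a, codes_b)
                if len(ia) == 0:
                    continue
                order = np.lexsort((jb, ia))
                anchors = list(zip(ia[order].tolist(), jb[order].tolist()))
                # group by diagonal for run merging, then chain across diagonals
                by_diag: dict[int, list[tuple[int, int]]] = {}
                for i, j in anchors:
                    by_diag.setdefault(j - i, []).append((i, j))
                runs: list[tuple[int, int, int]] = []
                for d in by_diag:
                    runs.extend(_merge_anchors(sorted(by_diag[d]), seed_k))
                runs.sort()
                for chain in _chain_runs(runs, chain_gap, seed_k):
                    a0, a1, b0, b1, ident = _score_chain(chain, enc_a, enc_b)
                    span = a1 - a0 + 1
                    if span < min_length or ident < min_identity:
                        continue
                    if orientation == "same":
                        iv_b = Interval(b0 + 1, b1 + 1)
                    else:
                        L = len(mol_b)
                        iv_b = Interval(L - b1, L - b0)
                    candidates.append(SyntenyBlock(
                        molecule_a=mol_a.name,
                        interval_a=Interval(a0 + 1, a1 + 1),
                        molecule_b=mol_b.name,
                        interval_b=iv_b,
                        orientation=orientation,
                        length=span,
                        identity=ident,
                    ))
    # greedy overlap resolution on the query genome
    candidates.sort(key=lambda b: (
        -b.length, -b.identity, b.molecule_a, b.interval_a.start,
        b.molecule_b, b.interval_b.start, b.orientation,
    ))
    kept: list[SyntenyBlock] = []
    for block in candidates:
        clash = any(
            k.molecule_a == block.molecule_a
            and k.molecule_b == block.molecule_b
            and k.orientation == block.orientation
            and _overlap_frac(k.interval_a, block.interval_a) > 0.5
            and _overlap_frac(k.interval_b, block.interval_b) > 0.5
            for k in kept
        )
        if not clash:
            kept.append(block)
    return kept


def _overlap_frac(a: Interval, b: Interval) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    if inter <= 0:
        return 0.0
    return inter / min(a.end - a.start + 1, b.end - b.start + 1)


SYNTENY_TABLE_COLUMNS = [
    "molecule_a", "start_a", "end_a", "molecule_b", "start_b", "end_b",
    "orientation", "length", "identity",
]


def blocks_to_table(blocks: Sequence[SyntenyBlock]):
    import pandas as pd

    return pd.DataFrame([b.as_row() for b in blocks], columns=SYNTENY_TABLE_COLUMNS)
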