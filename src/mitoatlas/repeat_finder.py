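"""Direct/inverted repeat detection by windowed self-comparison.

The detector reproduces the classic dot-plot definition: a sliding window
of ``window`` bp along every diagonal of every molecule-vs-molecule
comparison (both orientations), a window "hit" wherever at least
``ceil(window * min_identity)`` positions match, co-diagonal hits chained
when their windows are separated by at most ``max_gap`` bp, and the
chained span kept when it is at least ``min_length`` bp at
``min_identity`` overall.

For speed, candidate diagonals/offsets are located by exact k-mer
seeding.  The seed length is derived from the window parameters so that
seeding is lossless: a window with at most ``m`` mismatches must contain
an exact run of ``ceil((window - m) / (m + 1))`` matching bases, so every
qualifying window is guaranteed to contain a seed.  The output is
therefore identical to the exhaustive all-diagonal scan.

Circular molecules are scanned on their doubled sequence and hit
coordinates folded back, so repeats spanning the origin are found.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from mitoatlas.genome_model import Interval, MitoGenome, Molecule

Orientation = Literal["direct", "inverted"]

# identity thresholds are compared in exact integer arithmetic at this scale
_IDENT_SCALE = 10**6


def _ident_num(min_identity: float) -> int:
    return round(min_identity * _IDENT_SCALE)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_N_CODE = 4


@dataclass(frozen=True)
class RepeatPair:
    """Two repeated genomic intervals with orientation and identity."""

    molecule_a: str
    interval_a: Interval
    molecule_b: str
    interval_b: Interval
    orientation: Orientation
    length: int
    identity: float

    def as_row(self) -> tuple:
        return (
            self.molecule_a,
            self.interval_a.start,
            self.interval_a.end,
            self.molecule_b,
            self.interval_b.start,
            self.interval_b.end,
            self.orientation,
            self.length,
            round(self.identity, 4),
        )


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, _N_CODE, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        table[ord(base)] = code
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _revcomp_codes(arr: np.ndarray) -> np.ndarray:
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    return comp[arr][::-1]


def seed_length(window: int, min_identity: float) -> int:
    """Smallest guaranteed exact-run length inside a qualifying window."""
    p = _ident_num(min_identity)
    need = -((-p * window) // _IDENT_SCALE)
    mismatches = window - need
    return max(4, math.ceil((window - mismatches) / (mismatches + 1)))


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Base-4 rolling codes; windows containing N are coded -1."""
    n = len(arr)
    if n < k:
        return np.empty(0, dtype=np.int64)
    vals = arr.astype(np.int64)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(vals, k)
    codes = windows @ weights
    has_n = (windows == _N_CODE).any(axis=1)
    codes[has_n] = -1
    return codes


def _seed_pairs(codes_a: np.ndarray, codes_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All (i, j) with codes_a[i] == codes_b[j] != -1, via sort-join."""
    order = np.argsort(codes_b, kind="stable")
    sorted_b = codes_b[order]
    left = np.searchsorted(sorted_b, codes_a, side="left")
    right = np.searchsorted(sorted_b, codes_a, side="right")
    counts = right - left
    counts[codes_a < 0] = 0
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    ia = np.repeat(np.arange(len(codes_a)), counts)
    starts = np.repeat(np.cumsum(counts) - counts, counts)
    within = np.arange(total) - starts
    jb = order[np.repeat(left, counts) + within]
    return ia, jb


def _window_hits(
    enc_a: np.ndarray,
    enc_b: np.ndarray,
    ia: np.ndarray,
    jb: np.ndarray,
    window: int,
    need: int,
    k: int,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Qualifying window starts (and match counts) per diagonal.

    Only windows overlapping a seed are evaluated; seeding is lossless so
    these are exactly the qualifying windows of the full scan.
    """
    nA, nB = len(enc_a), len(enc_b)
    if len(ia) == 0:
        return {}
    d = jb - ia
    # dedupe seeds, then prefilter: any qualifying window containing a
    # seed lies inside the seed's (2*window - k)-wide super-window, whose
    # total match count must then itself reach the window threshold
    key = (d + nB) * np.int64(nA + 1) + ia
    _, uniq = np.unique(key, return_index=True)
    ia, d = ia[uniq], d[uniq]
    sup = ia[:, None] + np.arange(-(window - k), window, dtype=np.int64)[None, :]
    lo = np.maximum(0, -d)[:, None]
    hi = np.minimum(nA, nB - d)[:, None]
    valid = (sup >= lo) & (sup < hi)
    sa = enc_a[np.clip(sup, 0, nA - 1)]
    sb = enc_b[np.clip(sup + d[:, None], 0, nB - 1)]
    sup_matches = (valid & (sa == sb) & (sa != _N_CODE)).sum(axis=1)
    keep = sup_matches >= need
    ia, d = ia[keep], d[keep]
    if len(ia) == 0:
        return {}
    offsets = np.arange(-(window - k), 1, dtype=np.int64)
    cand_i = (ia[:, None] + offsets[None, :]).ravel()
    cand_d = np.repeat(d, len(offsets))
    lo = np.maximum(0, -cand_d)
    hi = np.minimum(nA, nB - cand_d) - window
    valid = (cand_i >= lo) & (cand_i <= hi)
    cand_i, cand_d = cand_i[valid], cand_d[valid]
    if len(cand_i) == 0:
        return {}
    key = (cand_d + nB) * np.int64(nA + 1) + cand_i
    _, uniq_idx = np.unique(key, return_index=True)
    cand_i, cand_d = cand_i[uniq_idx], cand_d[uniq_idx]
    t = np.arange(window, dtype=np.int64)
    rows_a = enc_a[cand_i[:, None] + t[None, :]]
    rows_b = enc_b[(cand_i + cand_d)[:, None] + t[None, :]]
    match = (rows_a == rows_b) & (rows_a != _N_CODE)
    counts = match.sum(axis=1)
    ok = counts >= need
    hits: dict[int, tuple[list, list]] = {}
    for i, dd, c in zip(cand_i[ok], cand_d[ok], counts[ok]):
        hits.setdefault(int(dd), ([], []))
        hits[int(dd)][0].append(int(i))
        hits[int(dd)][1].append(int(c))
    out = {}
    for dd, (starts, cs) in hits.items():
        order = np.argsort(starts)
        out[dd] = (np.asarray(starts)[order], np.asarray(cs)[order])
    return out


def _span_matches(enc_a, enc_b, i0, i1, d) -> int:
    a = enc_a[i0 : i1 + 1]
    b = enc_b[i0 + d : i1 + 1 + d]
    return int(((a == b) & (a != _N_CODE)).sum())


def _refine_span(
    enc_a, enc_b, d: int, i0: int, i1: int, min_identity: float
) -> tuple[int, int, int]:
    """Trim a chained span to its maximum-scoring subsegment.

    Matches score ``1 - t`` and mismatches ``-t`` with ``t`` the identity
    threshold, so any non-negative-scoring segment has identity >= t and
    the optimum ends on matches; random flank picked up by boundary
    windows is shed.  Ties broken toward the longer, then leftmost span.
    """
    a = enc_a[i0 : i1 + 1]
    b = enc_b[i0 + d : i1 + 1 + d]
    match = ((a == b) & (a != _N_CODE)).astype(np.int64)
    q = _IDENT_SCALE
    p = _ident_num(min_identity)
    # integer per-position scores: q*match - p; prefix-minimum scan yields
    # the best (score, length, leftmost) subsegment exactly
    score = q * match - p
    prefix = np.concatenate([[0], np.cumsum(score)])
    best = (np.iinfo(np.int64).min, -1, 0, -1)  # score, length, -start, end
    min_p, min_idx = 0, 0
    for j in range(1, len(prefix)):
        sc = int(prefix[j] - min_p)
        cand = (sc, j - min_idx, -min_idx, j - 1)
        if cand[:3] > best[:3]:
            best = cand
        if prefix[j] < min_p:
            min_p, min_idx = int(prefix[j]), j
    _, _, neg_start, end = best
    s = -neg_start
    matches = int(match[s : end + 1].sum())
    return i0 + s, i0 + end, matches


def _evaluate_chain(
    enc_a,
    enc_b,
    d: int,
    starts: np.ndarray,
    wsums: np.ndarray,
    window: int,
    min_identity: float,
    min_length: int,
    out: list,
) -> None:
    """Emit the chained span if it passes, else split at the weakest window."""
    if len(starts) == 0:
        return
    i0, i1 = int(starts[0]), int(starts[-1]) + window - 1
    span_len = i1 - i0 + 1
    matches = _span_matches(enc_a, enc_b, i0, i1, d)
    if _IDENT_SCALE * matches >= _ident_num(min_identity) * span_len:
        r0, r1, r_matches = _refine_span(enc_a, enc_b, d, i0, i1, min_identity)
        r_len = r1 - r0 + 1
        if r_len >= min_length:
            out.append((r0, r1, d, r_matches / r_len))
        return
    if len(starts) == 1:
        return
    weakest = int(np.argmin(wsums))
    _evaluate_chain(enc_a, enc_b, d, starts[:weakest], wsums[:weakest],
                   window, min_identity, min_length, out)
    _evaluate_chain(enc_a, enc_b, d, starts[weakest + 1 :], wsums[weakest + 1 :],
                   window, min_identity, min_length, out)


def _fold(pos0: int, L: int, circular: bool) -> int:
    """Map a 0-based doubled-sequence position to a 1-based molecule position."""
    return (pos0 % L) + 1 if circular else pos0 + 1


def _fold_interval(i0: int, i1: int, L: int, circular: bool) -> Interval:
    s = _fold(i0, L, circular)
    e = _fold(i1, L, circular)
    wrap = circular and e < s
    return Interval(s, e, wrap=wrap)


def find_repeats(
    genome: MitoGenome,
    window: int = 30,
    min_identity: float = 0.90,
    min_length: int = 100,
    max_gap: int = 30,
) -> list[RepeatPair]:
    """Find direct and inverted repeat pairs within and between molecules.

    Defaults match the dot-plot settings used for organelle repeat
    surveys: 30 bp window at 90% score, keeping repeats over 100 bp.
    Output is sorted by length descending, deterministically.
    """
    if window < 8:
        raise ValueError("window < 8: seed too weak")
    if not (0.0 < min_identity <= 1.0):
        raise ValueError("min_identity must be in (0, 1]")
    p = _ident_num(min_identity)
    need = -((-p * window) // _IDENT_SCALE)  # ceil(p*window/q), exact
    k = min(seed_length(window, min_identity), window)

    mols = list(genome)
    enc = {}
    for m in mols:
        e = _encode(m.sequence)
        enc[m.name] = np.concatenate([e, e]) if m.topology == "circular" else e

    raw: dict[tuple, RepeatPair] = {}
    for ai in range(len(mols)):
        for bi in range(ai, len(mols)):
            A, B = mols[ai], mols[bi]
            LA, LB = len(A), len(B)
            ea = enc[A.name]
            for orientation in ("direct", "inverted"):
                eb = enc[B.name] if orientation == "direct" else _revcomp_codes(enc[B.name])
                nB = len(eb)
                ia, jb = _seed_pairs(_kmer_codes(ea, k), _kmer_codes(eb, k))
                if A.name == B.name and orientation == "direct":
                    d = jb - ia
                    if A.topology == "circular":
                        keep = (d % LA) != 0
                    else:
                        keep = d != 0
                    ia, jb = ia[keep], jb[keep]
                hits = _window_hits(ea, eb, ia, jb, window, need, k)
                spans: list[tuple] = []
                for dd in sorted(hits):
                    starts, wsums = hits[dd]
                    breaks = np.where(np.diff(starts) > window + max_gap)[0] + 1
                    for grp_s, grp_w in zip(
                        np.split(starts, breaks), np.split(wsums, breaks)
                    ):
                        _evaluate_chain(ea, eb, dd, grp_s, grp_w, window,
                                        min_identity, min_length, spans)
                for i0, i1, dd, ident in spans:
                    span_len = i1 - i0 + 1
                    if span_len > min(LA, LB):
                        continue  # longer than a molecule: doubled-sequence artifact
                    j0, j1 = i0 + dd, i1 + dd
                    if orientation == "inverted":
                        j0, j1 = nB - 1 - j1, nB - 1 - j0
                    iv_a = _fold_interval(i0, i1, LA, A.topology == "circular")
                    iv_b = _fold_interval(j0, j1, LB, B.topology == "circular")
                    key_a = (A.name, iv_a.start, iv_a.end, iv_a.wrap)
                    key_b = (B.name, iv_b.start, iv_b.end, iv_b.wrap)
                    if key_a == key_b:
                        continue  # identical interval (self palindrome/diagonal)
                    if key_b < key_a:
                        key_a, key_b = key_b, key_a
                        iv_a, iv_b = iv_b, iv_a
                        name_a, name_b = B.name, A.name
                    else:
                        name_a, name_b = A.name, B.name
                    dedup = (key_a, key_b, orientation)
                    pair = RepeatPair(
                        molecule_a=name_a,
                        interval_a=iv_a,
                        molecule_b=name_b,
                        interval_b=iv_b,
                        orientation=orientation,
                        length=span_len,
                        identity=ident,
                    )
                    if dedup not in raw or raw[dedup].identity < ident:
                        raw[dedup] = pair
    lengths = {m.name: len(m) for m in mols}
    topo = {m.name: m.topology for m in mols}
    filtered = _drop_contained(list(raw.values()), lengths, topo)
    pairs = sorted(
        filtered,
        key=lambda p: (
            -p.length,
            -p.identity,
            p.molecule_a,
            p.interval_a.start,
            p.molecule_b,
            p.interval_b.start,
            p.orientation,
        ),
    )
    return pairs


def _iv_pos(iv: Interval) -> tuple[int, int]:
    """(0-based start, length-agnostic) helper for modular containment."""
    return iv.start - 1, iv.end - 1


def _contained_same_alignment(
    p: RepeatPair, q: RepeatPair, lengths: dict, topo: dict
) -> bool:
    """True if p is the same alignment as q restricted to a sub-span.

    Containment is checked circularly where the molecule is circular, and
    the relative offsets on both sides must agree so only redundant
    sub-hits of one alignment are dropped, never genuinely distinct
    shorter repeats.
    """
    if p.orientation != q.orientation:
        return False

    def mod_len(mol: str) -> int:
        return lengths[mol]

    def contains(mol: str, inner: Interval, outer: Interval) -> int | None:
        L = mod_len(mol)
        circ = topo[mol] == "circular"
        i0 = inner.start - 1
        o0 = outer.start - 1
        inner_len = inner.length(L)
        outer_len = outer.length(L)
        off = (i0 - o0) % L if circ else i0 - o0
        if off < 0 or off + inner_len > outer_len:
            return None
        return off

    for (pa_mol, pa, pb_mol, pb) in (
        (p.molecule_a, p.interval_a, p.molecule_b, p.interval_b),
        (p.molecule_b, p.interval_b, p.molecule_a, p.interval_a),
    ):
        if pa_mol != q.molecule_a or pb_mol != q.molecule_b:
            continue
        off_a = contains(pa_mol, pa, q.interval_a)
        off_b = contains(pb_mol, pb, q.interval_b)
        if off_a is None or off_b is None:
            continue
        if p.orientation == "direct":
            if off_a == off_b:
                return True
        else:
            La, Lb = mod_len(pa_mol), mod_len(pb_mol)
            # inverted: position x in a maps to the mirrored position in b
            qa_len = q.interval_a.length(La)
            pa_len = pa.length(La)
            if off_a == qa_len - off_b - pa_len:
                return True
    return False


def _drop_contained(
    pairs: list[RepeatPair], lengths: dict, topo: dict
) -> list[RepeatPair]:
    pairs = sorted(pairs, key=lambda p: -p.length)
    kept: list[RepeatPair] = []
    for p in pairs:
        if any(_contained_same_alignment(p, q, lengths, topo) for q in kept):
            continue
        kept.append(p)
    return kept


REPEAT_TABLE_COLUMNS = [
    "molecule_a", "start_a", "end_a",
    "molecule_b", "start_b", "end_b",
    "orientation", "length", "identity",
]


def repeats_to_table(pairs: Iterable[RepeatPair]):
    """Repeat pairs as a pandas DataFrame with the standard columns."""
    import pandas as pd

    return pd.DataFrame([p.as_row() for p in pairs], columns=REPEAT_TABLE_COLUMNS)
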