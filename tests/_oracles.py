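"""Independent reference implementations used as test oracles.

These are deliberately naive re-implementations of the declarative
definitions (full dot-plot scan, exhaustive hairpin enumeration) and
share no code with the package's fast paths.
"""

from __future__ import annotations

import numpy as np

Q = 10**6  # identity threshold scale (exact integer comparisons)


def _p(min_identity: float) -> int:
    return round(min_identity * Q)


_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# full dot-plot repeat scan (linear molecules only)


def _best_subsegment(match: list[int], min_identity: float):
    """Brute-force max-(score, length, leftmost) subsegment."""
    p = _p(min_identity)
    n = len(match)
    cum = [0]
    for m in match:
        cum.append(cum[-1] + m)
    best = None
    for s in range(n):
        for e in range(s, n):
            length = e - s + 1
            matches = cum[e + 1] - cum[s]
            score = Q * matches - p * length
            cand = (score, length, -s)
            if best is None or cand > best[0]:
                best = (cand, s, e, matches)
    _, s, e, matches = best
    return s, e, matches


def _chains(ok_starts: list[int], window: int, max_gap: int):
    groups = []
    for s in ok_starts:
        if groups and s - groups[-1][-1] <= window + max_gap:
            groups[-1].append(s)
        else:
            groups.append([s])
    return groups


def _evaluate(group, wsums, diag, window, min_identity, min_length, out):
    if not group:
        return
    p = _p(min_identity)
    i0, i1 = group[0], group[-1] + window - 1
    span = diag[i0 : i1 + 1]
    matches = sum(span)
    if Q * matches >= p * len(span):
        s, e, m = _best_subsegment(list(span), min_identity)
        if e - s + 1 >= min_length:
            out.append((i0 + s, i0 + e, m / (e - s + 1)))
        return
    if len(group) == 1:
        return
    weakest = min(range(len(group)), key=lambda t: wsums[t])
    _evaluate(group[:weakest], wsums[:weakest], diag, window, min_identity,
              min_length, out)
    _evaluate(group[weakest + 1:], wsums[weakest + 1:], diag, window,
              min_identity, min_length, out)


def dotplot_repeats(genome, window=30, min_identity=0.90, min_length=100,
                    max_gap=30):
    """Exhaustive windowed dot-plot repeat scan over all diagonals.

    Supports linear molecules only.  Returns canonical row tuples
    (mol_a, start_a, end_a, mol_b, start_b, end_b, orientation, length,
    identity rounded to 4 dp) sorted as the detector sorts.
    """
    p = _p(min_identity)
    need = -((-p * window) // Q)
    mols = list(genome)
    assert all(m.topology == "linear" for m in mols)
    raw = {}
    for ai in range(len(mols)):
        for bi in range(ai, len(mols)):
            A, B = mols[ai], mols[bi]
            arr_a = np.frombuffer(A.sequence.encode(), dtype=np.uint8)
            ncode = ord("N")
            for orientation in ("direct", "inverted"):
                bseq = B.sequence if orientation == "direct" else revcomp(B.sequence)
                arr_b = np.frombuffer(bseq.encode(), dtype=np.uint8)
                nA, nB = len(arr_a), len(arr_b)
                eq = (arr_a[:, None] == arr_b[None, :]) & \
                     (arr_a[:, None] != ncode)
                for d in range(-(nA - 1), nB):
                    if A.name == B.name and orientation == "direct" and d == 0:
                        continue
                    diag = np.diagonal(eq, offset=d).astype(int)
                    if len(diag) < window:
                        continue
                    sums = np.convolve(diag, np.ones(window, dtype=int), "valid")
                    ok = [int(i) for i in np.nonzero(sums >= need)[0]]
                    spans = []
                    for group in _chains(ok, window, max_gap):
                        _evaluate(group, [int(sums[g]) for g in group], diag,
                                  window, min_identity, min_length, spans)
                    for s, e, ident in spans:
                        # offset along the diagonal -> sequence coordinates
                        ia = s + max(0, -d)
                        ja = ia + d
                        ib = e + max(0, -d)
                        jbb = ib + d
                        if orientation == "inverted":
                            ja, jbb = nB - 1 - jbb, nB - 1 - ja
                        key_a = (A.name, ia + 1, ib + 1)
                        key_b = (B.name, ja + 1, jbb + 1)
                        if key_a == key_b:
                            continue
                        if key_b < key_a:
                            key_a, key_b = key_b, key_a
                        row = key_a + key_b + (orientation, ib - ia + 1, ident)
                        dk = (key_a, key_b, orientation)
                        if dk not in raw or raw[dk][-1] < ident:
                            raw[dk] = row
    rows = _drop_contained_rows(list(raw.values()))
    rows.sort(key=lambda r: (-r[7], -r[8], r[0], r[1], r[3], r[4], r[6]))
    return [r[:8] + (round(r[8], 4),) for r in rows]


def _drop_contained_rows(rows):
    """Drop sub-hits that are the same alignment restricted to a sub-span."""
    def contained(p, q):
        if p[6] != q[6]:
            return False
        for (pa, pb) in (((p[0], p[1], p[2]), (p[3], p[4], p[5])),
                         ((p[3], p[4], p[5]), (p[0], p[1], p[2]))):
            if pa[0] != q[0] or pb[0] != q[3]:
                continue
            off_a = pa[1] - q[1]
            if off_a < 0 or pa[2] > q[2]:
                continue
            off_b = pb[1] - q[4]
            if off_b < 0 or pb[2] > q[5]:
                continue
            if p[6] == "direct":
                if off_a == off_b:
                    return True
            else:
                qa_len = q[2] - q[1] + 1
                pa_len = pa[2] - pa[1] + 1
                if off_a == qa_len - off_b - pa_len:
                    return True
        return False

    rows = sorted(rows, key=lambda r: -r[7])
    kept = []
    for r in rows:
        if not any(contained(r, q) for q in kept):
            kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# exhaustive hairpin enumeration


def hairpin_oracle(seq: str, min_stem=8, max_loop=20, min_loop=3,
                   max_mismatch=1):
    """All maximal, loop-minimal hairpins by exhaustive enumeration.

    Returns (start0, stem, loop, mismatches) tuples, sorted.
    """
    n = len(seq)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def mism_or_none(loop_start, loop, stem):
        if loop_start - stem < 0 or loop_start + loop + stem > n:
            return None
        mism = 0
        for t in range(stem):
            a = seq[loop_start - 1 - t]
            b = seq[loop_start + loop + t]
            paired = comp.get(a) == b
            if not paired:
                if t == 0 or t == stem - 1:
                    return None
                mism += 1
        return mism if mism <= max_mismatch else None

    out = set()
    for loop_start in range(n):
        for loop in range(min_loop, max_loop + 1):
            valid = [
                (stem, mism_or_none(loop_start, loop, stem))
                for stem in range(min_stem, n)
            ]
            valid = [(s, m) for s, m in valid if m is not None]
            if not valid:
                continue
            stem, mism = max(valid)
            if loop - 2 >= min_loop and \
                    mism_or_none(loop_start + 1, loop - 2, stem + 1) is not None:
                continue
            out.add((loop_start - stem, stem, loop, mism))
    return sorted(out)


def merge_double_stem_loops(hairpins):
    """(start0, stem, loop, mism) -> merged spans with single/double kinds."""
    spans = sorted(
        (s, s + 2 * stem + loop - 1, stem, loop, mism)
        for s, stem, loop, mism in hairpins
    )
    merged = []
    for s, e, stem, loop, mism in spans:
        if merged and s > merged[-1][1] and s - merged[-1][1] - 1 <= 10:
            ps, pe, pstem, ploop, pmism, _ = merged.pop()
            merged.append((ps, e, max(pstem, stem), ploop, pmism + mism,
                           "double"))
        else:
            merged.append((s, e, stem, loop, mism, "single"))
    return merged
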