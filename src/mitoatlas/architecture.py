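"""Recombination isoform enumeration and in-silico PCR.

Homologous recombination between repeated sequences reshapes plant
mitochondrial genomes.  A single crossover between two copies of a
repeat has a small set of outcomes:

* direct pair on one circle — excision into two smaller circles;
* direct pair on one linear molecule — an excised circle plus the
  terminal fragments (kept in the record, flagged discarded);
* inverted pair on one molecule — inversion of the enclosed segment;
* pair across two circles — fusion into one larger circle.

Each product carries exactly one full repeat copy per junction.  The
crossover is placed at the first base of the repeat by default; with
non-identical copies the junction sequence then follows the copy that
opens the product.  The alternative convention (crossover at the repeat
end) is selectable and recorded in provenance.

``in_silico_pcr`` verifies configurations the way bench PCR across
recombination junctions does: convergent primer sites within a product
size bound, origin-spanning on circular molecules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from mitoatlas.genome_model import (
    Interval,
    MitoGenome,
    Molecule,
    reverse_complement,
    subsequence,
)
from mitoatlas.repeat_finder import RepeatPair


@dataclass
class ProductMolecule:
    """One molecule of a configuration, with its derivation segments."""

    name: str
    sequence: str
    topology: str
    segments: list[str] = field(default_factory=list)
    discarded: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class IsoformConfiguration:
    """A genome configuration reachable by recombination events."""

    config_id: str
    molecules: list[ProductMolecule]
    provenance: list[str] = field(default_factory=list)
    n_events: int = 0

    @property
    def total_length(self) -> int:
        return sum(len(m) for m in self.molecules)

    def retained_molecules(self) -> list[ProductMolecule]:
        return [m for m in self.molecules if not m.discarded]


@dataclass(frozen=True)
class Amplicon:
    configuration_id: str
    primer_pair_id: str
    molecule: str
    start: int
    end: int
    length: int
    spans_origin: bool


def _least_rotation(s: str) -> str:
    """Booth's algorithm: lexicographically least rotation of ``s``."""
    s2 = s + s
    n = len(s2)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = s2[j]
        i = f[j - k - 1]
        while i != -1 and sj != s2[k + i + 1]:
            if sj < s2[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s2[k + i + 1]:
            if sj < s2[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return s2[k : k + len(s)]


def _canonical_sequence(seq: str, topology: str) -> str:
    rc = reverse_complement(seq)
    if topology == "circular":
        return min(_least_rotation(seq), _least_rotation(rc))
    return min(seq, rc)


def configuration_key(config: IsoformConfiguration) -> tuple:
    """Dedup key: sorted multiset of (topology, length, canonical hash)."""
    import hashlib

    parts = []
    for m in config.molecules:
        canon = _canonical_sequence(m.sequence, m.topology)
        h = hashlib.sha1(canon.encode()).hexdigest()
        parts.append((m.topology, len(m), h, m.discarded))
    return tuple(sorted(parts))


@dataclass(frozen=True)
class _Copy:
    mol_idx: int
    start0: int  # 0-based
    length: int
    reversed_reading: bool  # True if the locus reads as the reverse complement


def _copies_from_pair(
    config: IsoformConfiguration, pair: RepeatPair
) -> tuple[_Copy, _Copy] | None:
    """Locate the two repeat copies inside a configuration's molecules."""
    names = [m.name for m in config.molecules]
    if pair.molecule_a in names and pair.molecule_b in names:
        ia = names.index(pair.molecule_a)
        ib = names.index(pair.molecule_b)
        a = _Copy(ia, pair.interval_a.start - 1,
                  pair.interval_a.length(len(config.molecules[ia].sequence)), False)
        b = _Copy(ib, pair.interval_b.start - 1,
                  pair.interval_b.length(len(config.molecules[ib].sequence)),
                  pair.orientation == "inverted")
        return a, b
    return None


def _locate_copies_by_sequence(
    config: IsoformConfiguration, seq_a: str, seq_b: str
) -> tuple[_Copy, _Copy] | None:
    """Find the two copies by literal search (used after the first event)."""
    found: list[_Copy] = []
    queries = []
    for q, rev in ((seq_a, False), (seq_b, False)):
        if q not in [x[0] for x in queries]:
            queries.append((q, rev))
    for mi, mol in enumerate(config.molecules):
        for q, _ in queries:
            for text, rev in ((q, False), (reverse_complement(q), True)):
                start = 0
                while True:
                    p = mol.sequence.find(text, start)
                    if p < 0:
                        break
                    c = _Copy(mi, p, len(text), rev)
                    if c not in found:
                        found.append(c)
                    start = p + 1
    # collapse duplicates at identical loci
    loci = {(c.mol_idx, c.start0, c.length) for c in found}
    if len(loci) != 2:
        return None
    uniq = sorted({(c.mol_idx, c.start0, c.length): c for c in found}.values(),
                  key=lambda c: (c.mol_idx, c.start0))
    return uniq[0], uniq[1]


def _overlap(a: _Copy, b: _Copy) -> bool:
    if a.mol_idx != b.mol_idx:
        return False
    return not (a.start0 + a.length <= b.start0 or b.start0 + b.length <= a.start0)


def _apply_event(
    config: IsoformConfiguration,
    a: _Copy,
    b: _Copy,
    event_label: str,
    crossover: str,
) -> IsoformConfiguration | None:
    mols = config.molecules
    if _overlap(a, b):
        warnings.warn(f"{event_label}: repeat copies overlap; event skipped")
        return None
    same_reading = a.reversed_reading == b.reversed_reading
    new_mols: list[ProductMolecule] = [
        m for i, m in enumerate(mols) if i not in (a.mol_idx, b.mol_idx)
    ]
    note = f"{event_label} crossover={crossover}"

    if a.mol_idx == b.mol_idx:
        parent = mols[a.mol_idx]
        s = parent.sequence
        left, right = (a, b) if a.start0 < b.start0 else (b, a)
        if same_reading:
            # excision via a direct-equivalent pair
            if crossover == "start":
                ca, cb = left.start0, right.start0
            else:
                ca, cb = left.start0 + left.length, right.start0 + right.length
            inner = s[ca:cb]
            if parent.topology == "circular":
                outer = s[cb:] + s[:ca]
                new_mols.append(ProductMolecule(
                    f"{parent.name}.x1", inner, "circular",
                    [f"{parent.name}:{ca + 1}-{cb}"]))
                new_mols.append(ProductMolecule(
                    f"{parent.name}.x2", outer, "circular",
                    [f"{parent.name}:{cb + 1}-{ca} (wrap)"]))
            else:
                new_mols.append(ProductMolecule(
                    f"{parent.name}.circle", inner, "circular",
                    [f"{parent.name}:{ca + 1}-{cb}"]))
                if ca > 0:
                    new_mols.append(ProductMolecule(
                        f"{parent.name}.frag5", s[:ca], "linear",
                        [f"{parent.name}:1-{ca}"], discarded=True))
                if cb < len(s):
                    new_mols.append(ProductMolecule(
                        f"{parent.name}.frag3", s[cb:], "linear",
                        [f"{parent.name}:{cb + 1}-{len(s)}"], discarded=True))
        else:
            # inversion via an inverted-equivalent pair
            if crossover == "start":
                i0, i1 = left.start0, right.start0 + right.length
            else:
                i0, i1 = left.start0 + left.length, right.start0
            inverted = s[:i0] + reverse_complement(s[i0:i1]) + s[i1:]
            new_mols.append(ProductMolecule(
                f"{parent.name}.inv", inverted, parent.topology,
                [f"{parent.name}: inverted {i0 + 1}-{i1}"]))
    else:
        m1, m2 = mols[a.mol_idx], mols[b.mol_idx]
        if m1.topology != "circular" or m2.topology != "circular":
            warnings.warn(
                f"{event_label}: cross-molecule event requires two circular "
                "molecules; event skipped"
            )
            return None
        s1, s2 = m1.sequence, m2.sequence
        if not same_reading:
            s2 = reverse_complement(s2)
            b = _Copy(b.mol_idx, len(s2) - (b.start0 + b.length), b.length,
                      a.reversed_reading)
        if crossover == "start":
            p1, p2 = a.start0, b.start0
        else:
            p1, p2 = a.start0 + a.length, b.start0 + b.length
        fused = s1[p1:] + s1[:p1] + s2[p2:] + s2[:p2]
        new_mols.append(ProductMolecule(
            f"{m1.name}+{m2.name}", fused, "circular",
            [f"{m1.name} rotated to {p1 + 1}", f"{m2.name} rotated to {p2 + 1}"]))

    return IsoformConfiguration(
        config_id="",
        molecules=new_mols,
        provenance=config.provenance + [note],
        n_events=config.n_events + 1,
    )


def enumerate_isoforms(
    genome: MitoGenome,
    repeats: Sequence[RepeatPair],
    max_events: int = 1,
    crossover: str = "start",
) -> list[IsoformConfiguration]:
    """Enumerate configurations reachable by up to ``max_events`` crossovers.

    Breadth-first over single-crossover events, deduplicated by the
    multiset of (topology, length, rotation/reflection-canonical sequence)
    of the product molecules.
    """
    if max_events > 3:
        raise ValueError("max_events > 3: combinatorial guard")
    if crossover not in ("start", "end"):
        raise ValueError("crossover must be 'start' or 'end'")
    for pair in repeats:
        for name in (pair.molecule_a, pair.molecule_b):
            if name not in genome:
                raise ValueError(f"repeat refers to unknown molecule {name!r}")

    root = IsoformConfiguration(
        config_id="parent",
        molecules=[
            ProductMolecule(m.name, m.sequence, m.topology) for m in genome
        ],
    )
    seen = {configuration_key(root)}
    results: list[IsoformConfiguration] = []
    frontier = [root]
    counter = 0
    for depth in range(1, max_events + 1):
        next_frontier = []
        for config in frontier:
            for ri, pair in enumerate(repeats):
                if depth == 1:
                    copies = _copies_from_pair(config, pair)
                else:
                    mol_a = genome[pair.molecule_a]
                    mol_b = genome[pair.molecule_b]
                    seq_a = subsequence(mol_a, pair.interval_a)
                    seq_b = subsequence(mol_b, pair.interval_b)
                    copies = _locate_copies_by_sequence(config, seq_a, seq_b)
                if copies is None:
                    continue
                label = (
                    f"event {depth}: repeat {ri} "
                    f"({pair.molecule_a}:{pair.interval_a.start}-"
                    f"{pair.interval_a.end} x {pair.molecule_b}:"
                    f"{pair.interval_b.start}-{pair.interval_b.end} "
                    f"{pair.orientation})"
                )
                product = _apply_event(config, *copies, label, crossover)
                if product is None:
                    continue
                key = configuration_key(product)
                if key in seen:
                    continue
                seen.add(key)
                counter += 1
                product.config_id = f"config_{counter:03d}"
                results.append(product)
                next_frontier.append(product)
        frontier = next_frontier
    return results


# ---------------------------------------------------------------------------
# in-silico PCR


def _primer_sites(seq_enc: np.ndarray, primer_enc: np.ndarray, max_mismatch: int) -> np.ndarray:
    """0-based start positions where the primer matches with <= max_mismatch."""
    n, k = len(seq_enc), len(primer_enc)
    if n < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(seq_enc, k)
    mism = (windows != primer_enc[None, :]).sum(axis=1)
    return np.nonzero(mism <= max_mismatch)[0]


def _enc(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def in_silico_pcr(
    target: MitoGenome | IsoformConfiguration,
    primers: Sequence[tuple[str, str, str]],
    max_product: int = 20000,
    max_mismatch: int = 0,
) -> list[Amplicon]:
    """Predict PCR products of convergent primer pairs on a genome or isoform.

    ``primers`` rows are (pair_id, forward_sequence, reverse_sequence), both
    written 5'→3'.  An amplicon runs from the 5' base of the plus-strand
    primer site to the 5' base of the minus-strand primer site inclusive,
    so its length is at least the sum of the primer lengths.  Circular
    molecules are additionally checked across the origin.
    """
    if isinstance(target, MitoGenome):
        config_id = "genome"
        molecules = [(m.name, m.sequence, m.topology) for m in target]
    else:
        config_id = target.config_id
        molecules = [
            (m.name, m.sequence, m.topology) for m in target.retained_molecules()
        ]

    for pid, fwd, rev in primers:
        for seq in (fwd, rev):
            if len(seq) < 15:
                raise ValueError(f"primer in pair {pid!r} shorter than 15 nt")
            if set(seq.upper()) - set("ACGT"):
                raise ValueError(f"primer in pair {pid!r} has non-ACGT base")

    amplicons: list[Amplicon] = []
    for mol_name, seq, topology in molecules:
        L = len(seq)
        circular = topology == "circular"
        search_seq = seq + seq if circular else seq
        enc_seq = _enc(search_seq)
        for pid, fwd, rev in primers:
            fwd, rev = fwd.upper(), rev.upper()
            plus_sites: list[tuple[int, int]] = []   # (start0, primer_len)
            minus_sites: list[tuple[int, int]] = []
            for primer in (fwd, rev):
                for s in _primer_sites(enc_seq, _enc(primer), max_mismatch):
                    if s < L:
                        plus_sites.append((int(s), len(primer)))
                for s in _primer_sites(enc_seq, _enc(reverse_complement(primer)),
                                       max_mismatch):
                    minus_sites.append((int(s), len(primer)))
            seen: set[tuple] = set()
            minus_sites.sort()
            for ps, plen in plus_sites:
                for ms, mlen in minus_sites:
                    m_end = ms + mlen - 1
                    if m_end <= ps + plen - 1:
                        continue  # not downstream: divergent or overlapping
                    if ms < ps + plen:
                        continue
                    length = m_end - ps + 1
                    if length > max_product or length > L:
                        continue
                    if not circular and m_end >= L:
                        continue
                    start1 = ps + 1
                    end1 = (m_end % L) + 1 if circular else m_end + 1
                    spans = circular and m_end >= L
                    key = (pid, start1, end1)
                    if key in seen:
                        continue
                    seen.add(key)
                    amplicons.append(Amplicon(
                        configuration_id=config_id,
                        primer_pair_id=pid,
                        molecule=mol_name,
                        start=start1,
                        end=end1,
                        length=length,
                        spans_origin=spans,
                    ))
    amplicons.sort(key=lambda a: (a.molecule, a.primer_pair_id, a.start, a.length))
    return amplicons
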