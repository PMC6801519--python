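"""Synthetic mitogenomes, pileups and coverage with complete truth tables.

The generator emulates the structure of a multichromosomal plant
mitochondrial dataset: several molecules (circular and linear) of i.i.d.
uniform background sequence; planted direct/inverted repeat pairs copied
to a target identity by drawing the exact mutation count; protein-coding
genes with valid start/stop codons and stop-free interiors; tRNA genes
(some plastid-like); C→U editing sites with assigned true efficiencies;
strand-specific transcription units with promoter motifs, 3' stem-loops
and flanking tRNAs acting as t-elements; and intron stem maps.

Randomness: a single integer master seed is fanned out to per-component
substreams by fixed labels, so each artefact can be regenerated
independently and everything is byte-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from mitoatlas.genome_model import (
    GeneFeature,
    Interval,
    MitoGenome,
    Molecule,
    reverse_complement,
)
from mitoatlas.repeat_finder import RepeatPair
from mitoatlas.editing import PILEUP_COLUMNS, PileupTable
from mitoatlas.consequence import IntronStemMap
from mitoatlas.transcription import CoverageTrack

_BASES = np.array(list("ACGT"))

# substream labels (fixed: part of the reproducibility contract)
_STREAMS = {
    "background": 1, "repeats": 2, "genes": 3, "trnas": 4,
    "editing": 5, "units": 6, "promoters": 7, "stemloops": 8,
    "introns": 9, "pileups": 10, "coverage": 11,
}


def _rng(seed: int, label: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[label], extra])


@dataclass
class TruthUnit:
    molecule: str
    strand: str
    interval: Interval
    depth_multiplier: float


@dataclass
class TruthEditingSite:
    molecule: str
    position: int
    strand: str
    efficiency: float


@dataclass
class TruthTable:
    repeats: list[RepeatPair] = field(default_factory=list)
    genes: list[GeneFeature] = field(default_factory=list)
    trnas: list[GeneFeature] = field(default_factory=list)
    editing_sites: list[TruthEditingSite] = field(default_factory=list)
    units: list[TruthUnit] = field(default_factory=list)
    promoters: list[tuple] = field(default_factory=list)  # (mol, strand, motif, pos, offset)
    stem_loops: list[tuple] = field(default_factory=list)  # (mol, start, end, stem, loop)
    stem_maps: list[IntronStemMap] = field(default_factory=list)

    def verify(self, genome: MitoGenome) -> None:
        """Check every truth record against the emitted genome string."""
        for pair in self.repeats:
            a = _interval_text(genome, pair.molecule_a, pair.interval_a)
            b = _interval_text(genome, pair.molecule_b, pair.interval_b)
            if pair.orientation == "inverted":
                b = reverse_complement(b)
            mism = sum(1 for x, y in zip(a, b) if x != y)
            ident = 1 - mism / len(a)
            if abs(ident - pair.identity) > 1e-9:
                raise AssertionError("planted repeat identity inconsistent")
        for gene in self.genes:
            from mitoatlas.genome_model import spliced_sequence
            cds = spliced_sequence(gene, genome)
            if cds[:3] != "ATG" or cds[-3:] not in ("TAA", "TAG", "TGA"):
                raise AssertionError("planted gene lacks start/stop")
        for mol, strand, motif, pos, _off in self.promoters:
            text = _interval_text(genome, mol, Interval(pos, pos + len(motif) - 1))
            if strand == "-":
                text = reverse_complement(text)
            if text != motif:
                raise AssertionError("planted promoter motif inconsistent")
        for site in self.editing_sites:
            base = genome[site.molecule].sequence[site.position - 1]
            expect = "C" if site.strand == "+" else "G"
            if base != expect:
                raise AssertionError("planted editing site base inconsistent")


def _interval_text(genome: MitoGenome, mol: str, iv: Interval) -> str:
    from mitoatlas.genome_model import subsequence

    return subsequence(genome[mol], iv)


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n)


def _mutate_to_identity(
    rng: np.random.Generator, codes: np.ndarray, identity: float
) -> tuple[np.ndarray, float]:
    """Mutate an exact copy to a target identity; mutation count is drawn
    exactly, so the realised identity differs from the target by < 1/len."""
    n = len(codes)
    n_mut = int(round(n * (1.0 - identity)))
    out = codes.copy()
    if n_mut:
        pos = rng.choice(n, size=n_mut, replace=False)
        out[pos] = (out[pos] + rng.integers(1, 4, size=n_mut)) % 4
    return out, 1.0 - n_mut / n


class PlacementError(RuntimeError):
    pass


def _place(
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    mol_len: int,
    length: int,
    margin: int = 10,
    tries: int = 200,
) -> int:
    """Non-overlapping 0-based placement for a feature of ``length``."""
    for _ in range(tries):
        start = int(rng.integers(margin, mol_len - length - margin))
        if all(start + length + margin <= s or start >= e + margin
               for s, e in occupied):
            occupied.append((start, start + length))
            return start
    raise PlacementError(
        f"could not place feature of length {length} after {tries} tries"
    )


_STOP_CODES = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA, TAG, TGA as base codes


def _gene_codes(rng: np.random.Generator, n_codons: int) -> np.ndarray:
    """ATG + stop-free interior + stop, as base codes."""
    codes = [0, 3, 2]  # ATG
    for _ in range(n_codons - 2):
        while True:
            codon = tuple(rng.integers(0, 4, size=3))
            if codon not in _STOP_CODES:
                break
        codes.extend(codon)
    stop = [(3, 0, 0), (3, 0, 2), (3, 2, 0)][int(rng.integers(0, 3))]
    codes.extend(stop)
    return np.array(codes)


_AA_CHOICES = ["F", "P", "S", "Y", "C", "M", "W", "D", "E", "G", "K", "N",
               "Q", "H", "I", "L"]


def generate_genome(
    n_molecules: int = 3,
    lengths: Sequence[int] = (50_000, 20_000, 10_000),
    topologies: Sequence[str] = ("linear", "circular", "circular"),
    n_repeats: int = 5,
    repeat_len_range: tuple[int, int] = (120, 2000),
    repeat_identity_range: tuple[float, float] = (0.90, 1.0),
    n_genes: int = 10,
    n_trna: int = 6,
    n_editing_sites: int = 60,
    editing_efficiency_range: tuple[float, float] = (0.05, 1.0),
    n_units: int | None = None,
    unit_depth_range: tuple[float, float] = (5.0, 50.0),
    promoter_fraction: float = 0.5,
    stemloop_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[MitoGenome, TruthTable]:
    """Generate a multichromosomal genome plus its complete truth table.

    Defaults model a down-scaled multipartite organelle genome: a large
    linear molecule and two circles, intermediate-size repeats at
    90–100% identity, protein genes inside strand-specific transcription
    units, and editing sites with efficiencies spanning the full range
    so both high- and low-efficiency bins are populated.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    if len(lengths) != n_molecules or len(topologies) != n_molecules:
        raise ValueError("lengths/topologies must match n_molecules")
    if any(l < 5000 for l in lengths):
        raise ValueError("molecule lengths must be >= 5 kb")

    truth = TruthTable()
    rng_bg = _rng(seed, "background")
    seqs = {f"mol_{i + 1}": _random_seq(rng_bg, L)
            for i, L in enumerate(lengths)}
    names = list(seqs)
    occupied = {name: [] for name in names}
    weights = np.asarray(lengths, dtype=float) / sum(lengths)

    def pick_molecule(rng) -> str:
        return names[int(rng.choice(n_molecules, p=weights))]

    def place_anywhere(rng, length, margin=10, attempts=20):
        """Length-weighted molecule choice with cross-molecule retries."""
        for _ in range(attempts):
            mol = pick_molecule(rng)
            try:
                return mol, _place(rng, occupied[mol], len(seqs[mol]), length,
                                   margin=margin)
            except PlacementError:
                continue
        raise PlacementError(
            f"could not place feature of length {length} on any molecule")

    # --- repeats: copy + mutate, possibly across molecules -----------------
    rng_rep = _rng(seed, "repeats")
    for _ in range(n_repeats):
        length = int(rng_rep.integers(repeat_len_range[0], repeat_len_range[1] + 1))
        identity = float(rng_rep.uniform(*repeat_identity_range))
        orientation = "direct" if rng_rep.random() < 0.5 else "inverted"
        src_mol, s0 = place_anywhere(rng_rep, length)
        dst_mol, d0 = place_anywhere(rng_rep, length)
        copy, realised = _mutate_to_identity(
            rng_rep, seqs[src_mol][s0 : s0 + length], identity
        )
        if orientation == "inverted":
            copy = (3 - copy)[::-1]
        seqs[dst_mol][d0 : d0 + length] = copy
        key_a = (src_mol, s0)
        key_b = (dst_mol, d0)
        if key_b < key_a:
            iv_a, iv_b = Interval(d0 + 1, d0 + length), Interval(s0 + 1, s0 + length)
            mol_a, mol_b = dst_mol, src_mol
        else:
            iv_a, iv_b = Interval(s0 + 1, s0 + length), Interval(d0 + 1, d0 + length)
            mol_a, mol_b = src_mol, dst_mol
        truth.repeats.append(RepeatPair(
            molecule_a=mol_a, interval_a=iv_a,
            molecule_b=mol_b, interval_b=iv_b,
            orientation=orientation, length=length, identity=realised,
        ))

    # --- genes -------------------------------------------------------------
    rng_gene = _rng(seed, "genes")
    for gi in range(n_genes):
        n_codons = int(rng_gene.integers(100, 300))
        length = 3 * n_codons
        strand = "+" if rng_gene.random() < 0.5 else "-"
        mol, start0 = place_anywhere(rng_gene, length, margin=600)
        codes = _gene_codes(rng_gene, n_codons)
        if strand == "-":
            codes = (3 - codes)[::-1]
        seqs[mol][start0 : start0 + length] = codes
        truth.genes.append(GeneFeature(
            molecule=mol, kind="cds",
            intervals=[(start0 + 1, start0 + length)],
            strand=strand, gene_id=f"gene{gi + 1:02d}",
        ))

    # --- tRNAs -------------------------------------------------------------
    rng_trna = _rng(seed, "trnas")
    for ti in range(n_trna):
        length = int(rng_trna.integers(71, 90))
        strand = "+" if rng_trna.random() < 0.5 else "-"
        mol, start0 = place_anywhere(rng_trna, length, margin=30)
        truth.trnas.append(GeneFeature(
            molecule=mol, kind="tRNA",
            intervals=[(start0 + 1, start0 + length)],
            strand=strand, gene_id=f"trna{ti + 1:02d}",
            plastid_like=bool(rng_trna.random() < 0.4),
        ))

    # --- transcription units over genes ------------------------------------
    rng_unit = _rng(seed, "units")
    for gene in truth.genes:
        pad5 = int(rng_unit.integers(60, 120))
        pad3 = int(rng_unit.integers(60, 120))
        if gene.strand == "+":
            s, e = gene.start - pad5, gene.end + pad3
        else:
            s, e = gene.start - pad3, gene.end + pad5
        s = max(1, s)
        e = min(len(seqs[gene.molecule]), e)
        truth.units.append(TruthUnit(
            molecule=gene.molecule, strand=gene.strand,
            interval=Interval(s, e),
            depth_multiplier=float(rng_unit.uniform(*unit_depth_range)),
        ))

    # --- promoter motifs upstream of some unit 5' ends ----------------------
    rng_prom = _rng(seed, "promoters")
    motifs = ("CGTA", "CATA", "TATATAA")
    for unit in truth.units:
        if rng_prom.random() >= promoter_fraction:
            continue
        motif = motifs[int(rng_prom.integers(0, len(motifs)))]
        offset = int(rng_prom.integers(5, 60))
        L = len(seqs[unit.molecule])
        if unit.strand == "+":
            five = unit.interval.start
            m_start = five - offset - len(motif)
            if m_start < 1:
                continue
            codes = np.array([_BASES.tolist().index(b) for b in motif])
            seqs[unit.molecule][m_start - 1 : m_start - 1 + len(motif)] = codes
            truth.promoters.append(
                (unit.molecule, "+", motif, m_start, offset))
        else:
            five = unit.interval.end
            m_start = five + offset + 1
            if m_start + len(motif) - 1 > L:
                continue
            rc = reverse_complement(motif)
            codes = np.array([_BASES.tolist().index(b) for b in rc])
            seqs[unit.molecule][m_start - 1 : m_start - 1 + len(motif)] = codes
            truth.promoters.append(
                (unit.molecule, "-", motif, m_start, offset))

    # --- stem-loops at some unit 3' ends ------------------------------------
    rng_sl = _rng(seed, "stemloops")
    for unit in truth.units:
        if rng_sl.random() >= stemloop_fraction:
            continue
        stem = int(rng_sl.integers(10, 15))
        loop = int(rng_sl.integers(4, 8))
        total = 2 * stem + loop
        three = unit.interval.end if unit.strand == "+" else unit.interval.start
        if unit.strand == "+":
            h_start = three - total - 5
        else:
            h_start = three + 5
        if h_start < 1 or h_start + total - 1 > len(seqs[unit.molecule]):
            continue
        arm = _random_seq(rng_sl, stem)
        loop_seq = _random_seq(rng_sl, loop)
        hairpin = np.concatenate([arm, loop_seq, (3 - arm)[::-1]])
        seqs[unit.molecule][h_start - 1 : h_start - 1 + total] = hairpin
        truth.stem_loops.append(
            (unit.molecule, h_start, h_start + total - 1, stem, loop))

    # --- editing sites inside genes (transcript-strand C) --------------------
    rng_edit = _rng(seed, "editing")
    eligible: list[tuple[str, int, str]] = []
    for gene in truth.genes:
        seq = seqs[gene.molecule]
        want = 1 if gene.strand == "+" else 2  # C on + genes, G on - genes
        s, e = gene.start, gene.end
        # avoid start/stop codons so gene structure stays intact
        inner = np.arange(s + 3, e - 3)
        cand = inner[seq[inner - 1] == want]
        for p in cand:
            eligible.append((gene.molecule, int(p), gene.strand))
    if n_editing_sites > len(eligible):
        warnings.warn("fewer eligible C positions than requested editing sites")
        n_editing_sites = len(eligible)
    idx = rng_edit.choice(len(eligible), size=n_editing_sites, replace=False)
    for i in sorted(idx):
        mol, pos, strand = eligible[i]
        truth.editing_sites.append(TruthEditingSite(
            molecule=mol, position=pos, strand=strand,
            efficiency=float(rng_edit.uniform(*editing_efficiency_range)),
        ))

    # --- intron stem maps (synthetic stems V/VI analogues) -------------------
    rng_int = _rng(seed, "introns")
    for gene in truth.genes[: min(3, len(truth.genes))]:
        s, e = gene.start, gene.end
        mid = (s + e) // 2
        pairs = []
        for t in range(4):
            pairs.append((mid + t, mid + 20 - t))
        truth.stem_maps.append(IntronStemMap(
            intron_id=f"{gene.gene_id}.intron1", pairs=pairs,
            interval=Interval(s, e),
        ))

    molecules = [
        Molecule(name=name, sequence="".join(_BASES[seqs[name]]),
                 topology=topologies[i])
        for i, name in enumerate(names)
    ]
    genome = MitoGenome(molecules)
    truth.verify(genome)
    return genome, truth


def simulate_pileups(
    genome: MitoGenome,
    truth: TruthTable,
    depth_mean: float = 100.0,
    error_rate: float = 0.005,
    n_libraries: int = 3,
    library_efficiency_jitter: float = 0.02,
    seed: int = 0,
) -> list[PileupTable]:
    """Simulate replicate per-base pileups over the transcribed positions.

    Depth per site is Poisson with mean ``depth_mean`` times the local
    transcription-unit multiplier; at editing sites the edited-base count
    is Binomial(depth, efficiency ± a per-library jitter, clipped to
    [0, 1]); every other read substitutes uniformly at ``error_rate``.
    """
    if not truth.editing_sites:
        raise ValueError("truth table has no editing sites")
    if depth_mean < 1:
        raise ValueError("depth_mean must be >= 1")
    base_idx = {b: i for i, b in enumerate("ACGT")}
    edit_target = {"C": "T", "G": "A"}
    site_map = {(s.molecule, s.position): s for s in truth.editing_sites}

    # positions covered by any transcription unit
    covered: dict[str, np.ndarray] = {}
    mult: dict[str, np.ndarray] = {}
    for mol in genome:
        mask = np.zeros(len(mol), dtype=bool)
        mvals = np.ones(len(mol), dtype=float)
        for unit in truth.units:
            if unit.molecule != mol.name:
                continue
            sl = slice(unit.interval.start - 1, unit.interval.end)
            mask[sl] = True
            mvals[sl] = np.maximum(mvals[sl], unit.depth_multiplier)
        covered[mol.name] = np.nonzero(mask)[0]
        mult[mol.name] = mvals

    tables = []
    for li in range(n_libraries):
        rng = _rng(seed, "pileups", li)
        jitter = float(rng.uniform(-library_efficiency_jitter,
                                   library_efficiency_jitter))
        frames = []
        for mol in genome:
            pos0 = covered[mol.name]
            if len(pos0) == 0:
                continue
            n = len(pos0)
            depths = rng.poisson(depth_mean * mult[mol.name][pos0]).astype(np.int64)
            seq_codes = np.frombuffer(mol.sequence.encode(), dtype=np.uint8)
            lut = np.zeros(256, dtype=np.int64)
            for b, i in base_idx.items():
                lut[ord(b)] = i
            ref_idx = lut[seq_codes[pos0]]
            # editing: binomial edited-read counts at the planted sites
            n_edit = np.zeros(n, dtype=np.int64)
            edit_idx = ref_idx.copy()
            is_site = np.zeros(n, dtype=bool)
            for t, p0 in enumerate(pos0):
                site = site_map.get((mol.name, int(p0) + 1))
                if site is not None and mol.sequence[p0] in edit_target:
                    eff = min(1.0, max(0.0, site.efficiency + jitter))
                    n_edit[t] = rng.binomial(depths[t], eff)
                    edit_idx[t] = base_idx[edit_target[mol.sequence[p0]]]
                    is_site[t] = True
            n_plain = depths - n_edit
            # uniform substitution error on non-edited reads, split over
            # the three alternative bases by a binomial chain
            if error_rate > 0:
                n_err = rng.binomial(n_plain, error_rate)
                e1 = rng.binomial(n_err, 1.0 / 3.0)
                e2 = rng.binomial(n_err - e1, 0.5)
                e3 = n_err - e1 - e2
            else:
                n_err = e1 = e2 = e3 = np.zeros(n, dtype=np.int64)
            counts = np.zeros((n, 4), dtype=np.int64)
            idx = np.arange(n)
            np.add.at(counts, (idx, edit_idx), n_edit)
            np.add.at(counts, (idx, ref_idx), n_plain - n_err)
            np.add.at(counts, (idx, (ref_idx + 1) % 4), e1)
            np.add.at(counts, (idx, (ref_idx + 2) % 4), e2)
            np.add.at(counts, (idx, (ref_idx + 3) % 4), e3)
            frames.append(pd.DataFrame({
                "molecule": mol.name,
                "position": pos0 + 1,
                "ref": [mol.sequence[p] for p in pos0],
                "count_A": counts[:, 0],
                "count_C": counts[:, 1],
                "count_G": counts[:, 2],
                "count_T": counts[:, 3],
            }))
        df = pd.concat(frames, ignore_index=True)[PILEUP_COLUMNS]
        tables.append(PileupTable(f"lib{li + 1}", df))
    return tables


def simulate_coverage(
    genome: MitoGenome,
    truth: TruthTable,
    background_depth: float = 2.0,
    boundary_noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[tuple[str, str], CoverageTrack]:
    """Strand-split coverage tracks with (optionally jittered) unit bounds.

    Unit depth is ``background_depth × depth_multiplier`` over the unit
    extent; boundaries are shifted by rounded Gaussian noise of the given
    standard deviation.  Returns a dict keyed by (molecule, strand).
    """
    rng = _rng(seed, "coverage")
    tracks: dict[tuple[str, str], CoverageTrack] = {}
    for mol in genome:
        for strand in "+-":
            depth = np.full(len(mol), background_depth, dtype=float)
            tracks[(mol.name, strand)] = CoverageTrack(mol.name, strand, depth)
    for unit in truth.units:
        track = tracks[(unit.molecule, unit.strand)]
        s, e = unit.interval.start, unit.interval.end
        if boundary_noise_sd > 0:
            s += int(round(rng.normal(0, boundary_noise_sd)))
            e += int(round(rng.normal(0, boundary_noise_sd)))
        L = len(track.depth)
        s = max(1, min(L, s))
        e = max(s, min(L, e))
        unit_depth = max(
            background_depth, 1.0
        ) * unit.depth_multiplier
        track.depth[s - 1 : e] = np.maximum(track.depth[s - 1 : e], unit_depth)
    return tracks


def write_pileup(table: PileupTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def write_coverage(tracks: dict, path_prefix) -> list[str]:
    """Write one 3-column TSV (molecule, position, depth) per strand."""
    paths = []
    for strand, tag in (("+", "plus"), ("-", "minus")):
        rows = []
        for (mol, s), track in sorted(tracks.items()):
            if s != strand:
                continue
            for i, d in enumerate(track.depth):
                rows.append((mol, i + 1, d))
        path = f"{path_prefix}.{tag}.tsv"
        pd.DataFrame(rows, columns=["molecule", "position", "depth"]).to_csv(
            path, sep="\t", index=False
        )
        paths.append(path)
    return paths
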