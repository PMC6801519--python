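"""Core data model: molecules, genomes, features, circular coordinates.

Coordinates are 1-based inclusive at every public interface, matching the
convention of organelle genome annotation tables.  Circular molecules may
carry origin-spanning (wrapping) intervals; a wrapping interval ``(s, e)``
on a molecule of length ``L`` covers positions ``s..L`` followed by
``1..e``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

Topology = Literal["circular", "linear"]
Strand = Literal["+", "-"]

_DNA_ALPHABET = set("ACGTN")

FEATURE_KINDS = ("cds", "exon", "tRNA", "rRNA", "orf", "pseudogene")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Interval:
    """1-based inclusive interval; ``wrap`` marks origin-spanning spans."""

    start: int
    end: int
    wrap: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(f"interval positions must be >= 1: {self}")
        if not self.wrap and self.end < self.start:
            raise ValueError(f"non-wrap interval with end < start: {self}")

    def length(self, molecule_length: int | None = None) -> int:
        if not self.wrap:
            return self.end - self.start + 1
        if molecule_length is None:
            raise ValueError("wrap interval length requires molecule length")
        return molecule_length - self.start + 1 + self.end


@dataclass
class Molecule:
    """A single mitochondrial DNA molecule with declared topology."""

    name: str
    sequence: str
    topology: Topology = "linear"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValueError(f"molecule {self.name!r} is empty")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"molecule {self.name!r} contains non-DNA characters: {sorted(bad)}"
            )
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MitoGenome:
    """Ordered collection of uniquely named molecules."""

    molecules: list[Molecule] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [m.name for m in self.molecules]
        if len(names) != len(set(names)):
            raise ValueError("duplicate molecule names in genome")

    @property
    def total_length(self) -> int:
        return sum(len(m) for m in self.molecules)

    def __getitem__(self, name: str) -> Molecule:
        for m in self.molecules:
            if m.name == name:
                return m
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(m.name == name for m in self.molecules)

    def __iter__(self):
        return iter(self.molecules)


@dataclass
class GeneFeature:
    """A gene-level feature; multi-exon genes carry several intervals.

    ``intervals`` are in genomic order (ascending start), regardless of
    strand; transcript order is derived from the strand when splicing.
    """

    molecule: str
    kind: str
    intervals: list[tuple[int, int]]
    strand: Strand
    gene_id: str
    plastid_like: bool = False
    wrap: bool = False

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -: {self.strand!r}")
        if not self.intervals:
            raise ValueError(f"feature {self.gene_id!r} has no intervals")
        ivs = sorted(self.intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"feature {self.gene_id!r} has overlapping intervals"
                )
        self.intervals = ivs

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    def contains(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.intervals)

    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)


# ---------------------------------------------------------------------------
# I/O


def read_genome(
    path: str | Path,
    topology_map: Mapping[str, Topology] | None = None,
) -> MitoGenome:
    """Read a multi-record FASTA into a :class:`MitoGenome`.

    ``topology_map`` maps record names to ``circular``/``linear``; records
    absent from the map default to linear.  Sequences are uppercased and
    must be DNA over {A, C, G, T, N}.
    """
    topology_map = dict(topology_map or {})
    molecules: list[Molecule] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate FASTA record name {record.id!r}")
        seen.add(record.id)
        seq = str(record.seq).upper()
        if "U" in seq:
            raise ValueError(
                f"record {record.id!r} contains U: RNA sequences not accepted"
            )
        molecules.append(
            Molecule(
                name=record.id,
                sequence=seq,
                topology=topology_map.get(record.id, "linear"),
            )
        )
    if not molecules:
        raise ValueError(f"no FASTA records found in {path}")
    return MitoGenome(molecules)


def write_genome(genome: MitoGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for mol in genome:
            fh.write(f">{mol.name}\n")
            for i in range(0, len(mol.sequence), 70):
                fh.write(mol.sequence[i : i + 70] + "\n")


_GFF_KIND_MAP = {
    "cds": "cds",
    "mrna": "cds",
    "gene": "cds",
    "exon": "exon",
    "trna": "tRNA",
    "rrna": "rRNA",
    "orf": "orf",
    "pseudogene": "pseudogene",
}


def read_annotation(
    path: str | Path,
    genome: MitoGenome | None = None,
) -> list[GeneFeature]:
    """Read gene features from GFF3, joining multi-exon genes by gene_id.

    Feature types map onto the model kinds (CDS/gene/mRNA → cds, tRNA,
    rRNA, ORF, pseudogene, exon).  When a genome is supplied coordinates
    are validated against molecule lengths and seqids against molecule
    names.
    """
    import gffutils

    text = Path(path).read_text()
    if not text.strip() or all(
        line.startswith("#") or not line.strip() for line in text.splitlines()
    ):
        return []
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    # group rows by (seqid, gene_id, type-kind, strand)
    groups: dict[tuple, dict] = {}
    order: list[tuple] = []
    for f in db.all_features():
        kind = _GFF_KIND_MAP.get(f.featuretype.lower())
        if kind is None:
            continue
        gene_id = (
            f.attributes.get("gene_id", [None])[0]
            or f.attributes.get("ID", [None])[0]
            or f.id
        )
        plastid = f.attributes.get("plastid_like", ["false"])[0].lower() == "true"
        if genome is not None:
            if f.seqid not in genome:
                raise ValueError(f"unknown seqid {f.seqid!r} in annotation")
            L = len(genome[f.seqid])
            if f.start < 1 or f.end > L:
                raise ValueError(
                    f"feature {gene_id!r} coordinates ({f.start}, {f.end}) "
                    f"outside molecule {f.seqid!r} (length {L})"
                )
        key = (f.seqid, gene_id, kind, f.strand)
        if key not in groups:
            groups[key] = {"intervals": [], "plastid": plastid}
            order.append(key)
        groups[key]["intervals"].append((f.start, f.end))
        groups[key]["plastid"] = groups[key]["plastid"] or plastid
    features = []
    for key in order:
        seqid, gene_id, kind, strand = key
        features.append(
            GeneFeature(
                molecule=seqid,
                kind=kind,
                intervals=groups[key]["intervals"],
                strand=strand,
                gene_id=gene_id,
                plastid_like=groups[key]["plastid"],
            )
        )
    return features


def write_annotation(features: Sequence[GeneFeature], path: str | Path) -> None:
    """Write features as GFF3 (one row per interval, joined by gene_id)."""
    kind_out = {"cds": "CDS", "exon": "exon", "tRNA": "tRNA", "rRNA": "rRNA",
                "orf": "orf", "pseudogene": "pseudogene"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            attrs = f"gene_id={feat.gene_id}"
            if feat.plastid_like:
                attrs += ";plastid_like=true"
            for s, e in feat.intervals:
                fh.write(
                    "\t".join(
                        [
                            feat.molecule,
                            "mitoatlas",
                            kind_out[feat.kind],
                            str(s),
                            str(e),
                            ".",
                            feat.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Coordinate arithmetic


def subsequence(molecule: Molecule, iv: Interval, strand: Strand = "+") -> str:
    """Extract the sequence of ``iv``; strand ``-`` reverse-complements.

    Wrapping intervals are only valid on circular molecules.
    """
    L = len(molecule)
    if iv.end > L or iv.start > L:
        raise ValueError(f"interval {iv} outside molecule of length {L}")
    if iv.wrap:
        if molecule.topology != "circular":
            raise ValueError(
                f"wrap interval on linear molecule {molecule.name!r}"
            )
        text = molecule.sequence[iv.start - 1 :] + molecule.sequence[: iv.end]
    else:
        text = molecule.sequence[iv.start - 1 : iv.end]
    if strand == "-":
        text = reverse_complement(text)
    return text


def spliced_sequence(feature: GeneFeature, genome: MitoGenome) -> str:
    """Splice a multi-interval feature into its transcript-orientation mRNA."""
    mol = genome[feature.molecule]
    parts = [subsequence(mol, Interval(s, e)) for s, e in feature.intervals]
    text = "".join(parts)
    if feature.strand == "-":
        text = reverse_complement(text)
    return text


_NONCANONICAL_STARTS = ("GTG", "ACG")


def translate(
    cds_text: str,
    allow_noncanonical_start: bool = False,
) -> tuple[str, dict]:
    """Translate a CDS with the standard genetic code.

    Returns ``(protein, meta)`` where meta records the start codon, the
    codon index (1-based) of the first in-frame stop if any, and whether a
    partial trailing codon was dropped.  With ``allow_noncanonical_start``
    a leading GTG or ACG is read as methionine (plant mitochondria use the
    universal code; non-AUG initiation is an initiation-level exception,
    not a code change).
    """
    cds_text = cds_text.upper()
    if len(cds_text) < 3:
        raise ValueError("CDS shorter than one codon")
    trailing = len(cds_text) % 3
    if trailing:
        warnings.warn(
            f"dropping partial trailing codon of {trailing} nt", stacklevel=2
        )
        cds_text = cds_text[: len(cds_text) - trailing]
    full = str(Seq(cds_text).translate())
    start_codon = cds_text[:3]
    meta = {
        "start_codon": start_codon,
        "noncanonical_start": False,
        "first_stop_codon_index": None,
        "n_codons_translated": len(full),
        "trailing_nt_dropped": trailing,
    }
    if allow_noncanonical_start and start_codon in _NONCANONICAL_STARTS:
        full = "M" + full[1:]
        meta["noncanonical_start"] = True
    if "*" in full:
        meta["first_stop_codon_index"] = full.index("*") + 1
        protein = full[: full.index("*")]
    else:
        protein = full
    return protein, meta
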