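"""Genomic context and coding consequences of editing sites.

C→U editing can create initiation codons (ACG→AUG), create premature
stop codons that shorten the genomic ORF, restore conserved amino acids,
or repair base-pairing in group II intron stems V/VI.  Because plant
mitochondrial genes can overlap in different frames, a single edit is
evaluated both in the frame of its own gene and in the frames of any
overlapping annotated ORFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio.Seq import Seq

from mitoatlas.genome_model import (
    GeneFeature,
    Interval,
    MitoGenome,
    reverse_complement,
    spliced_sequence,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}

REGION_PRECEDENCE = ["cds", "tRNA", "rRNA", "intron", "utr5", "utr3", "intergenic"]


@dataclass
class FrameEffect:
    gene_id: str
    codon_index: int  # 1-based along the spliced CDS
    codon_position: int  # 1..3
    ref_codon: str
    edited_codon: str
    ref_aa: str
    edited_aa: str
    event: str  # missense | silent | start_gain | stop_gain | other


@dataclass
class Consequence:
    molecule: str
    position: int
    region_class: str
    primary: FrameEffect | None = None
    overlapping: list[FrameEffect] = field(default_factory=list)
    codons_shortened: int | None = None
    indeterminate: bool = False

    @property
    def event(self) -> str:
        return self.primary.event if self.primary else "other"


@dataclass
class IntronStemMap:
    """Positions meant to base-pair in stems V/VI of a group II intron."""

    intron_id: str
    pairs: list[tuple[int, int]]
    interval: Interval | None = None

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if i in seen or j in seen or i == j:
                raise ValueError(f"stem map {self.intron_id!r} pairs not disjoint")
            seen.update((i, j))
        if self.interval is not None:
            for i, j in self.pairs:
                for p in (i, j):
                    if not (self.interval.start <= p <= self.interval.end):
                        raise ValueError(
                            f"stem map position {p} outside intron interval"
                        )


def classify_site_region(
    molecule: str,
    position: int,
    features: Sequence[GeneFeature],
    transcription_units: Sequence = (),
    introns: Sequence[tuple[str, str, Interval]] = (),
) -> str:
    """Region class of a position, with precedence cds > tRNA > rRNA >
    intron > UTR > intergenic.

    UTRs require transcription units: a position inside a unit but
    outside every gene interval is a 5' or 3' UTR relative to the unit's
    genes.  Without units such positions classify as intergenic.
    ``introns`` rows are (intron_id, molecule, interval).
    """
    kinds = set()
    for feat in features:
        if feat.molecule == molecule and feat.contains(position):
            kinds.add("cds" if feat.kind in ("cds", "orf") else feat.kind)
        elif (
            feat.molecule == molecule
            and len(feat.intervals) > 1
            and feat.start <= position <= feat.end
        ):
            kinds.add("intron")  # between exons of a multi-exon gene
    for _, mol, iv in introns:
        if mol == molecule and iv.start <= position <= iv.end:
            kinds.add("intron")
    for cls in ("cds", "tRNA", "rRNA", "intron"):
        if cls in kinds:
            return cls
    for unit in transcription_units:
        if unit.molecule != molecule:
            continue
        if not (unit.interval.start <= position <= unit.interval.end):
            continue
        genes = [
            f for f in features
            if f.molecule == molecule
            and f.start >= unit.interval.start
            and f.end <= unit.interval.end
        ]
        if not genes:
            continue
        gmin = min(f.start for f in genes)
        gmax = max(f.end for f in genes)
        if position < gmin:
            return "utr5" if unit.strand == "+" else "utr3"
        if position > gmax:
            return "utr3" if unit.strand == "+" else "utr5"
    return "intergenic"


def _transcript_offset(feature: GeneFeature, position: int) -> int | None:
    """0-based offset of a genomic position along the spliced transcript."""
    if not feature.contains(position):
        return None
    offset = 0
    for s, e in feature.intervals:
        if s <= position <= e:
            offset += position - s
            break
        offset += e - s + 1
    if feature.strand == "-":
        offset = feature.spliced_length() - 1 - offset
    return offset


def _frame_effect(
    feature: GeneFeature, position: int, genome: MitoGenome
) -> FrameEffect | None:
    """Effect of editing the C at ``position`` in ``feature``'s frame."""
    offset = _transcript_offset(feature, position)
    if offset is None:
        return None
    cds = spliced_sequence(feature, genome)
    if cds[offset] != "C":
        return None  # the transcript base here is not an editable C
    codon_index = offset // 3
    codon_pos = offset % 3
    codon_start = codon_index * 3
    ref_codon = cds[codon_start : codon_start + 3]
    if len(ref_codon) < 3:
        return None
    edited_codon = (
        ref_codon[:codon_pos] + "T" + ref_codon[codon_pos + 1 :]
    )
    ref_aa = str(Seq(ref_codon).translate())
    edited_aa = str(Seq(edited_codon).translate())
    if edited_codon in STOP_CODONS:
        event = "stop_gain"
    elif codon_index == 0 and ref_codon == "ACG" and edited_codon == "ATG":
        event = "start_gain"
    elif ref_aa == edited_aa:
        event = "silent"
    elif ref_aa != edited_aa:
        event = "missense"
    else:
        event = "other"
    return FrameEffect(
        gene_id=feature.gene_id,
        codon_index=codon_index + 1,
        codon_position=codon_pos + 1,
        ref_codon=ref_codon,
        edited_codon=edited_codon,
        ref_aa=ref_aa,
        edited_aa=edited_aa,
        event=event,
    )


def codon_consequence(
    molecule: str,
    position: int,
    cds: GeneFeature,
    genome: MitoGenome,
    all_features: Sequence[GeneFeature] = (),
) -> Consequence:
    """Coding consequence of an edit inside ``cds``, plus overlapping frames.

    Overlapping annotated CDS/ORF features containing the same position
    are evaluated in their own frames, capturing cases where one edit is
    missense in one gene and creates a stop in an overlapping gene.
    """
    if not cds.contains(position):
        raise ValueError(
            f"position {position} not inside feature {cds.gene_id!r}"
        )
    primary = _frame_effect(cds, position, genome)
    overlapping = []
    for feat in all_features:
        if feat.gene_id == cds.gene_id:
            continue
        if feat.kind not in ("cds", "orf"):
            continue
        if feat.molecule == molecule and feat.contains(position):
            eff = _frame_effect(feat, position, genome)
            if eff is not None:
                overlapping.append(eff)
    return Consequence(
        molecule=molecule,
        position=position,
        region_class="cds",
        primary=primary,
        overlapping=overlapping,
        indeterminate=primary is None,
    )


def orf_shortening(
    cds: GeneFeature,
    molecule: str,
    position: int,
    genome: MitoGenome,
) -> int:
    """Codons removed when an edit creates a premature stop in ``cds``.

    Returns the distance (in codons) between the annotated genomic stop
    codon and the editing-created stop codon; 0 when the edit falls in
    the annotated stop codon itself.
    """
    effect = _frame_effect(cds, position, genome)
    if effect is None or effect.event != "stop_gain":
        raise ValueError("site does not create a stop codon in this frame")
    cds_seq = spliced_sequence(cds, genome)
    n_codons = len(cds_seq) // 3
    genomic_stop_index = None
    for ci in range(effect.codon_index - 1, n_codons):
        codon = cds_seq[ci * 3 : ci * 3 + 3]
        if len(codon) == 3 and codon in STOP_CODONS:
            genomic_stop_index = ci + 1
            break
    if genomic_stop_index is None:
        raise ValueError(
            f"no genomic stop codon downstream of edit in {cds.gene_id!r}"
        )
    return genomic_stop_index - effect.codon_index


_PAIRING = {
    ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),  # Watson-Crick
    ("G", "T"), ("T", "G"),  # GU wobble (DNA alphabet for the RNA pair)
}


def pairing_table() -> dict[tuple[str, str], bool]:
    """The full 4×4 table of accepted base pairs (WC + GU wobble)."""
    bases = "ACGT"
    return {(x, y): (x, y) in _PAIRING for x in bases for y in bases}


def intron_pairing_effect(
    molecule: str,
    position: int,
    stem_map: IntronStemMap,
    genome: MitoGenome,
    strand: str = "+",
) -> tuple[str, bool]:
    """Effect of a C→U edit on a mapped intron stem pair.

    Returns ``(effect, mapped)`` with effect in {improves, disrupts,
    neutral}: improves when the edit converts a non-pairing combination
    into A-U or G-U; disrupts the reverse; neutral otherwise (including
    unmapped positions, where mapped is False).
    """
    partner = None
    for i, j in stem_map.pairs:
        if position == i:
            partner = j
            break
        if position == j:
            partner = i
            break
    if partner is None:
        return "neutral", False
    seq = genome[molecule].sequence
    base = seq[position - 1]
    other = seq[partner - 1]
    if strand == "-":
        base = reverse_complement(base)
        other = reverse_complement(other)
    if base != "C":
        return "neutral", True
    before = (base, other) in _PAIRING
    after = ("T", other) in _PAIRING
    if after and not before:
        return "improves", True
    if before and not after:
        return "disrupts", True
    return "neutral", True


def annotate_sites(
    sites,
    features: Sequence[GeneFeature],
    genome: MitoGenome,
    transcription_units: Sequence = (),
    introns: Sequence[tuple[str, str, Interval]] = (),
) -> None:
    """Fill region_class and consequence on called editing sites in place."""
    for site in sites:
        site.region_class = classify_site_region(
            site.molecule, site.position, features,
            transcription_units=transcription_units, introns=introns,
        )
        if site.region_class != "cds":
            continue
        host = next(
            (f for f in features
             if f.molecule == site.molecule
             and f.kind in ("cds", "orf")
             and f.contains(site.position)),
            None,
        )
        if host is None:
            continue
        cons = codon_consequence(
            site.molecule, site.position, host, genome, all_features=features
        )
        parts = []
        if cons.primary is not None:
            parts.append(f"{cons.primary.gene_id}:{cons.primary.event}")
        for eff in cons.overlapping:
            parts.append(f"{eff.gene_id}:{eff.event}")
        site.consequence = ";".join(parts) if parts else "indeterminate"
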