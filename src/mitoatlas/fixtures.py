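"""Packaged annotation of the potato (Solanum tuberosum) mitogenome.

The package ships the published gene and tRNA coordinate tables of the
potato mitochondrial genome as GFF3, transcribed onto three molecules:
``molecule_1`` (312,491 bp, linear), ``molecule_2`` (112,797 bp,
circular) and ``molecule_3`` (49,229 bp, circular).  Duplicated genes
carry ``_1``/``_2`` suffixes so each feature keeps a unique gene_id;
plastid-derived tRNA genes are tagged ``plastid_like=true``.

Only coordinates are packaged, not sequence; operations that need the
DNA accept any genome with matching molecule names and lengths.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from mitoatlas.genome_model import GeneFeature, MitoGenome, read_annotation

POTATO_MOLECULE_LENGTHS = {
    "molecule_1": 312_491,
    "molecule_2": 112_797,
    "molecule_3": 49_229,
}

POTATO_TOPOLOGIES = {
    "molecule_1": "linear",
    "molecule_2": "circular",
    "molecule_3": "circular",
}


def _data_path(name: str) -> Path:
    return Path(resources.files("mitoatlas") / "data" / name)


def potato_gene_annotation(genome: MitoGenome | None = None) -> list[GeneFeature]:
    """Protein-coding genes, orfs, rRNAs and the rps14 pseudogene."""
    return read_annotation(_data_path("potato_mt_genes.gff3"), genome)


def potato_trna_annotation(genome: MitoGenome | None = None) -> list[GeneFeature]:
    """The 23 tRNA genes, plastid-like copies tagged."""
    return read_annotation(_data_path("potato_mt_trnas.gff3"), genome)


def trna_amino_acid_counts(features: list[GeneFeature]) -> dict:
    """Distinct amino-acid identities among tRNA genes.

    Reported both raw and with the plastid-like copies known to lack
    expression excluded, since published summaries differ on whether
    pseudogene tRNAs count toward the amino-acid tally.
    """
    def aa(feat: GeneFeature) -> str:
        stem = feat.gene_id.split("-")[0]
        return stem.removeprefix("trn").rstrip("fe") or stem

    all_aas = {aa(f) for f in features}
    expressed = {aa(f) for f in features if not f.plastid_like}
    return {
        "n_trna_genes": len(features),
        "n_amino_acids_raw": len(all_aas),
        "n_amino_acids_excluding_plastid_like": len(expressed),
    }
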