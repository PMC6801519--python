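"""Stage orchestration: config validation, stage running, TSV reports.

Every stage writes a plain TSV with a documented header so it can be
re-run and inspected in isolation; the summary collects the headline
counts (repeats, isoforms, units, promoter hits, editing sites and
their efficiency bins, region classes, synteny blocks).  The run is
fail-fast: inputs are validated before any computation starts, and the
first stage error stops the run leaving earlier outputs intact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import mitoatlas
from mitoatlas import editing as ed
from mitoatlas import repeat_finder as rf
from mitoatlas import synteny as syn
from mitoatlas import transcription as tr
from mitoatlas.architecture import enumerate_isoforms, in_silico_pcr
from mitoatlas.consequence import annotate_sites
from mitoatlas.genome_model import Interval, MitoGenome, read_annotation, read_genome

logger = logging.getLogger("mitoatlas")

_PARAM_BLOCKS = {
    "repeats": {"window": 30, "min_identity": 0.90, "min_length": 100,
                "max_gap": 30},
    "isoforms": {"max_events": 1, "crossover": "start"},
    "pcr": {"max_product": 20000, "max_mismatch": 0},
    "units": {"background_mult": 5.0, "min_unit_length": 150,
              "smooth_window": 51, "merge_gap": 100},
    "promoters": {"upstream_window": 100},
    "stemloops": {"min_stem": 8, "max_loop": 20, "min_loop": 3,
                  "max_mismatch": 1, "search_window": 80},
    "t_elements": {"max_dist": 20},
    "edits": {"min_frac": 0.10, "min_libs": 2, "min_depth": 10},
    "synteny": {"min_length": 5000, "min_identity": 0.95, "seed_k": 15,
                "chain_gap": 500},
}

_INPUT_KEYS = {
    "genome_fasta", "topology", "annotation_gff3", "trna_gff3",
    "pileups", "coverage_plus", "coverage_minus", "primers_tsv",
    "second_genome_fasta", "second_topology",
}


@dataclass
class PipelineConfig:
    inputs: dict
    params: dict = field(default_factory=dict)
    output_dir: str = "mitoatlas_out"
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.inputs) - _INPUT_KEYS
        if unknown:
            raise ValueError(f"unknown input keys: {sorted(unknown)}")
        unknown_blocks = set(self.params) - set(_PARAM_BLOCKS)
        if unknown_blocks:
            raise ValueError(f"unknown parameter blocks: {sorted(unknown_blocks)}")
        for block, values in self.params.items():
            unknown_params = set(values) - set(_PARAM_BLOCKS[block])
            if unknown_params:
                raise ValueError(
                    f"unknown keys in {block!r}: {sorted(unknown_params)}"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {"inputs", "params", "output_dir", "seed"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            inputs=raw.get("inputs", {}),
            params=raw.get("params", {}),
            output_dir=raw.get("output_dir", "mitoatlas_out"),
            seed=raw.get("seed", 0),
        )

    def block(self, name: str) -> dict:
        merged = dict(_PARAM_BLOCKS[name])
        merged.update(self.params.get(name, {}))
        return merged


def _load_topology(path: str | None) -> dict:
    if not path:
        return {}
    p = Path(path)
    if p.suffix in (".yaml", ".yml"):
        return yaml.safe_load(p.read_text()) or {}
    out = {}
    for line in p.read_text().splitlines():
        if line.strip() and not line.startswith("#"):
            name, topo = line.split("\t")[:2]
            out[name] = topo.strip()
    return out


def _read_coverage_tsv(path: str, strand: str, genome: MitoGenome) -> dict:
    import numpy as np

    df = pd.read_csv(path, sep="\t")
    tracks = {}
    for mol in genome:
        depth = np.zeros(len(mol), dtype=float)
        sub = df[df["molecule"] == mol.name]
        if len(sub):
            depth[sub["position"].to_numpy() - 1] = sub["depth"].to_numpy()
        tracks[(mol.name, strand)] = tr.CoverageTrack(mol.name, strand, depth)
    return tracks


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns the summary dict."""
    inputs = config.inputs
    required = ["genome_fasta"]
    for key in required:
        if key not in inputs:
            raise ValueError(f"missing required input {key!r}")
    # fail fast: every referenced path must exist before any stage runs
    for key, value in inputs.items():
        paths = value if isinstance(value, list) else [value]
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"input {key!r}: {p} does not exist")

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("mitoatlas %s seed=%s", mitoatlas.__version__, config.seed)
    for block in _PARAM_BLOCKS:
        logger.info("params %s: %s", block, config.block(block))

    summary: dict = {}
    try:
        genome = read_genome(
            inputs["genome_fasta"], _load_topology(inputs.get("topology"))
        )
        summary["total_genome_length"] = genome.total_length
        summary["n_molecules"] = len(genome.molecules)

        features = []
        if inputs.get("annotation_gff3"):
            features = read_annotation(inputs["annotation_gff3"], genome)
        if inputs.get("trna_gff3"):
            features += read_annotation(inputs["trna_gff3"], genome)

        repeats = rf.find_repeats(genome, **config.block("repeats"))
        rf.repeats_to_table(repeats).to_csv(
            outdir / "repeats.tsv", sep="\t", index=False)
        summary["n_repeat_pairs"] = len(repeats)
        logger.info("repeats: %d pairs", len(repeats))

        isoforms = enumerate_isoforms(genome, repeats, **config.block("isoforms"))
        iso_rows = [
            (c.config_id, "; ".join(c.provenance), len(c.molecules),
             ",".join(str(len(m)) for m in c.molecules))
            for c in isoforms
        ]
        pd.DataFrame(iso_rows, columns=[
            "config_id", "event", "molecule_count", "lengths",
        ]).to_csv(outdir / "isoforms.tsv", sep="\t", index=False)
        summary["n_isoform_configurations"] = len(isoforms)

        if inputs.get("primers_tsv"):
            primers = [
                tuple(r) for r in pd.read_csv(
                    inputs["primers_tsv"], sep="\t"
                )[["id", "fwd", "rev"]].itertuples(index=False)
            ]
            amplicons = in_silico_pcr(genome, primers, **config.block("pcr"))
            pd.DataFrame(
                [(a.configuration_id, a.primer_pair_id, a.molecule, a.start,
                  a.end, a.length, a.spans_origin) for a in amplicons],
                columns=["configuration", "primer_pair", "molecule", "start",
                         "end", "length", "spans_origin"],
            ).to_csv(outdir / "amplicons.tsv", sep="\t", index=False)
            summary["n_amplicons"] = len(amplicons)

        units = []
        if inputs.get("coverage_plus") and inputs.get("coverage_minus"):
            tracks = {}
            tracks.update(_read_coverage_tsv(inputs["coverage_plus"], "+", genome))
            tracks.update(_read_coverage_tsv(inputs["coverage_minus"], "-", genome))
            for track in tracks.values():
                units.extend(tr.segment_coverage(
                    track, features=features, **config.block("units")))
            hits = tr.scan_promoters(genome, units, **config.block("promoters"))
            trnas = [f for f in features if f.kind == "tRNA"]
            tr.associate_t_elements(units, trnas, **config.block("t_elements"))
            tr.classify_five_prime_ends(units, hits)
            stem_rows = []
            for unit in units:
                sls = tr.find_stem_loops(
                    genome, unit.molecule, unit.interval, unit.strand,
                    **config.block("stemloops"))
                if sls:
                    best = sls[0]
                    unit.three_prime_feature = (
                        "double_stem_loop" if best.kind == "double" else "stem_loop"
                    ) if unit.three_prime_feature == "none" else unit.three_prime_feature
                    for sl in sls:
                        stem_rows.append((
                            unit.molecule, unit.strand, sl.interval.start,
                            sl.interval.end, sl.stem_length, sl.loop_length,
                            sl.mismatches, sl.kind))
            pd.DataFrame(
                [(u.molecule, u.strand, u.interval.start, u.interval.end,
                  round(u.mean_depth, 2), ",".join(u.gene_ids),
                  u.five_prime_feature, u.three_prime_feature) for u in units],
                columns=["molecule", "strand", "start", "end", "mean_depth",
                         "genes", "five_prime_feature", "three_prime_feature"],
            ).to_csv(outdir / "units.tsv", sep="\t", index=False)
            pd.DataFrame(
                [(h.molecule, h.strand, h.motif, h.offset, h.position)
                 for h in hits],
                columns=["molecule", "strand", "motif", "offset", "position"],
            ).to_csv(outdir / "promoters.tsv", sep="\t", index=False)
            pd.DataFrame(stem_rows, columns=[
                "molecule", "strand", "start", "end", "stem", "loop",
                "mismatches", "kind",
            ]).to_csv(outdir / "stemloops.tsv", sep="\t", index=False)
            summary["n_transcription_units"] = len(units)
            summary["n_promoter_hits"] = len(hits)

        if inputs.get("pileups"):
            pileups = [
                ed.read_pileup(p, genome=genome) for p in inputs["pileups"]
            ]
            sites = ed.call_editing_sites(
                pileups, genome, features, **config.block("edits"))
            annotate_sites(sites, features, genome, transcription_units=units)
            ed.sites_to_table(sites).to_csv(
                outdir / "editing_sites.tsv", sep="\t", index=False)
            summary["n_editing_sites"] = len(sites)
            if sites:
                bins = ed.bin_efficiencies(sites)
                summary["editing_bins"] = bins
                region_counts: dict = {}
                for s in sites:
                    region_counts[s.region_class] = (
                        region_counts.get(s.region_class, 0) + 1)
                summary["editing_region_classes"] = region_counts

        if inputs.get("second_genome_fasta"):
            genome_b = read_genome(
                inputs["second_genome_fasta"],
                _load_topology(inputs.get("second_topology")),
            )
            blocks = syn.find_synteny_blocks(
                genome, genome_b, **config.block("synteny"))
            syn.blocks_to_table(blocks).to_csv(
                outdir / "synteny.tsv", sep="\t", index=False)
            summary["n_synteny_blocks"] = len(blocks)

        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
        logger.info("summary: %s", summary)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return summary
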