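"""C→U RNA-editing detection from replicate RNA-seq pileups.

Plant mitochondrial transcripts undergo cytidine deamination (C→U).
Against the genomic reference this appears in unstranded RNA-seq pileups
as C-to-T mismatches for plus-strand transcripts and G-to-A mismatches
for minus-strand transcripts.  The caller applies a replicate-aware
rule: a site is reported when the edited fraction reaches ``min_frac``
at sufficient depth in at least ``min_libs`` of the replicate libraries.
Efficiency (the fraction of transcripts edited) is quantified per
library and pooled over libraries.

A separate scan flags non-editing mismatch signatures such as the
A-to-T mis-incorporation opposite 1-methyladenosine (m¹A) during cDNA
synthesis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from mitoatlas.genome_model import GeneFeature, MitoGenome

PILEUP_COLUMNS = [
    "molecule", "position", "ref", "count_A", "count_C", "count_G", "count_T",
]

_COUNT_COLS = ["count_A", "count_C", "count_G", "count_T"]


@dataclass
class PileupTable:
    """Per-base A/C/G/T counts for one sequencing library."""

    library: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PILEUP_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"pileup missing columns: {missing}")
        if (self.data[_COUNT_COLS].to_numpy() < 0).any():
            raise ValueError("negative count in pileup")
        dup = self.data.duplicated(subset=["molecule", "position"])
        if dup.any():
            raise ValueError("duplicate (molecule, position) rows in pileup")

    def depth(self) -> pd.Series:
        return self.data[_COUNT_COLS].sum(axis=1)


def read_pileup(
    path: str | Path,
    library: str | None = None,
    genome: MitoGenome | None = None,
) -> PileupTable:
    """Read a tab-separated pileup table (header line required).

    When a genome is supplied, the ref column is validated against it and
    mismatching positions are reported in the error.
    """
    df = pd.read_csv(path, sep="\t")
    table = PileupTable(library or Path(path).stem, df)
    if genome is not None:
        bad = []
        for mol_name, sub in df.groupby("molecule"):
            seq = genome[mol_name].sequence
            pos = sub["position"].to_numpy()
            ref = sub["ref"].to_numpy()
            genomic = np.frombuffer(seq.encode(), dtype=np.uint8)[pos - 1]
            mism = genomic != np.frombuffer(
                "".join(ref).encode(), dtype=np.uint8
            )
            for p in pos[mism]:
                bad.append(f"{mol_name}:{p}")
        if bad:
            raise ValueError(
                "pileup ref base disagrees with genome at: " + ", ".join(bad)
            )
    return table


@dataclass
class EditingSite:
    molecule: str
    position: int
    strand: str  # '+', '-', or 'ambiguous'
    per_library_fraction: list[float]
    per_library_depth: list[int]
    pooled_efficiency: float
    supporting_libraries: int
    efficiency_bin: str = ""
    region_class: str = ""
    consequence: str = ""
    conflicting: bool = False

    def __post_init__(self) -> None:
        if not self.efficiency_bin:
            self.efficiency_bin = efficiency_bin(self.pooled_efficiency)


def efficiency_bin(eff: float) -> str:
    """Bin an efficiency: 'high' above 0.95, 'low' below 0.25, else 'mid'."""
    if eff > 0.95:
        return "high"
    if eff < 0.25:
        return "low"
    return "mid"


@dataclass(frozen=True)
class MismatchSignature:
    molecule: str
    position: int
    ref_base: str
    mismatch_base: str
    pooled_fraction: float
    depth: int
    label: str


_EDIT_BASE = {"+": ("C", "count_C", "count_T"), "-": ("G", "count_G", "count_A")}


def _strand_of_position(
    molecule: str, position: int, features: Sequence[GeneFeature]
) -> str | None:
    """Strand of the annotated feature overlapping a position, if any."""
    for feat in features:
        if feat.molecule == molecule and feat.contains(position):
            return feat.strand
    return None


_BASE_TO_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _site_stats(
    rows: list[tuple[int, int, int, int]],
    strand: str,
    min_frac: float,
    min_depth: int,
) -> tuple[list[float], list[int], float, int]:
    """Per-library edited fractions/depths plus pooled efficiency/support.

    ``rows`` are per-library (A, C, G, T) count tuples.
    """
    ref_base, _, edit_col = _EDIT_BASE[strand]
    ref_idx = _BASE_TO_IDX[ref_base]
    edit_idx = _BASE_TO_IDX[edit_col[-1]]
    fracs, depths = [], []
    pooled_edit = pooled_ref = 0
    support = 0
    for counts in rows:
        edited = counts[edit_idx]
        refc = counts[ref_idx]
        depth = sum(counts)
        denom = edited + refc
        frac = edited / denom if denom else 0.0
        fracs.append(frac)
        depths.append(depth)
        pooled_edit += edited
        pooled_ref += refc
        if depth >= min_depth and frac >= min_frac:
            support += 1
    pooled = pooled_edit / (pooled_edit + pooled_ref) if (pooled_edit + pooled_ref) else 0.0
    return fracs, depths, pooled, support


def call_editing_sites(
    pileups: Sequence[PileupTable],
    genome: MitoGenome,
    features: Sequence[GeneFeature],
    min_frac: float = 0.10,
    min_libs: int = 2,
    min_depth: int = 10,
) -> list[EditingSite]:
    """Call C→U editing sites across replicate libraries.

    The edited base is T at genomic C for plus-strand transcripts and A at
    genomic G for minus-strand transcripts; transcript orientation comes
    from the overlapping annotation.  Unannotated positions are evaluated
    in both orientations and reported as ambiguous with the stronger one.
    A library supports a site when its own edited fraction is at least
    ``min_frac`` at depth ``min_depth``; a site is called with support
    from at least ``min_libs`` libraries.
    """
    if len(pileups) < min_libs:
        raise ValueError(
            f"need at least min_libs={min_libs} pileup tables, got {len(pileups)}"
        )
    merged: dict[tuple[str, int], dict[int, tuple]] = {}
    for li, pt in enumerate(pileups):
        cols = pt.data[["molecule", "position", *_COUNT_COLS]]
        for mol, pos, a, c, g, t in cols.itertuples(index=False, name=None):
            merged.setdefault((mol, int(pos)), {})[li] = (
                int(a), int(c), int(g), int(t))

    any_depth = False
    sites: list[EditingSite] = []
    n_libs = len(pileups)
    zero = (0, 0, 0, 0)
    for (mol, pos) in sorted(merged):
        lib_rows = merged[(mol, pos)]
        rows = [lib_rows.get(li, zero) for li in range(n_libs)]
        ref = genome[mol].sequence[pos - 1]
        if any(sum(r) >= min_depth for r in rows):
            any_depth = True
        strand = _strand_of_position(mol, pos, features)
        candidates = []
        if strand is not None:
            expect_ref = _EDIT_BASE[strand][0]
            if ref == expect_ref:
                candidates.append((strand, False))
        else:
            for s in ("+", "-"):
                if ref == _EDIT_BASE[s][0]:
                    candidates.append((s, True))
        results = []
        for s, ambiguous in candidates:
            fracs, depths, pooled, support = _site_stats(
                rows, s, min_frac, min_depth
            )
            if support >= min_libs:
                results.append((s, ambiguous, fracs, depths, pooled, support))
        if not results:
            continue
        conflicting = len(results) > 1
        results.sort(key=lambda r: -r[4])
        s, ambiguous, fracs, depths, pooled, support = results[0]
        sites.append(EditingSite(
            molecule=mol,
            position=pos,
            strand="ambiguous" if ambiguous else s,
            per_library_fraction=fracs,
            per_library_depth=depths,
            pooled_efficiency=pooled,
            supporting_libraries=support,
            conflicting=conflicting,
        ))
    if not any_depth:
        warnings.warn("no position reaches min_depth in any library")
    return sites


def bin_efficiencies(sites: Sequence[EditingSite]) -> dict:
    """Summarise pooled efficiencies into high (>0.95) / mid / low (<0.25).

    Percentages are rounded to the nearest integer.
    """
    if not sites:
        raise ValueError("no editing sites to bin")
    n = len(sites)
    high = sum(1 for s in sites if s.pooled_efficiency > 0.95)
    low = sum(1 for s in sites if s.pooled_efficiency < 0.25)
    mid = n - high - low
    return {
        "n_sites": n,
        "n_high": high,
        "n_mid": mid,
        "n_low": low,
        "pct_high": round(100.0 * high / n),
        "pct_mid": round(100.0 * mid / n),
        "pct_low": round(100.0 * low / n),
    }


def detect_mismatch_signatures(
    pileups: Sequence[PileupTable],
    genome: MitoGenome,
    ref_base: str = "A",
    mismatch_base: str = "T",
    min_frac: float = 0.20,
    min_depth: int = 50,
    called_sites: Sequence[EditingSite] = (),
    label: str = "putative m1A",
) -> list[MismatchSignature]:
    """Flag high-frequency non-editing mismatches (e.g., m¹A signatures).

    Pools all libraries; reports genomic ``ref_base`` positions where the
    ``mismatch_base`` fraction reaches ``min_frac`` at pooled depth
    ``min_depth``.  Editing-type mismatches (T at genomic C, A at genomic
    G) and positions already called as editing are excluded.
    """
    if (ref_base, mismatch_base) in (("C", "T"), ("G", "A")):
        return []  # editing-type mismatches belong to the editing caller
    called = {(s.molecule, s.position) for s in called_sites}
    pooled: dict[tuple[str, int], np.ndarray] = {}
    for pt in pileups:
        cols = pt.data[["molecule", "position", *_COUNT_COLS]]
        for mol, pos, a, c, g, t in cols.itertuples(index=False, name=None):
            key = (mol, int(pos))
            counts = np.array([a, c, g, t], dtype=np.int64)
            pooled[key] = pooled.get(key, np.zeros(4, dtype=np.int64)) + counts
    base_idx = {b: i for i, b in enumerate("ACGT")}
    out: list[MismatchSignature] = []
    for (mol, pos) in sorted(pooled):
        if (mol, pos) in called:
            continue
        ref = genome[mol].sequence[pos - 1]
        if ref != ref_base:
            continue
        counts = pooled[(mol, pos)]
        depth = int(counts.sum())
        if depth < min_depth:
            continue
        frac = counts[base_idx[mismatch_base]] / depth
        if frac >= min_frac:
            out.append(MismatchSignature(
                molecule=mol,
                position=pos,
                ref_base=ref_base,
                mismatch_base=mismatch_base,
                pooled_fraction=float(frac),
                depth=depth,
                label=label,
            ))
    return out


EDITING_TABLE_COLUMNS = [
    "molecule", "position", "strand", "pooled_efficiency",
    "supporting_libraries", "efficiency_bin", "region_class", "consequence",
]


def sites_to_table(sites: Sequence[EditingSite]) -> pd.DataFrame:
    rows = []
    for s in sites:
        row = {
            "molecule": s.molecule,
            "position": s.position,
            "strand": s.strand,
            "pooled_efficiency": round(s.pooled_efficiency, 4),
            "supporting_libraries": s.supporting_libraries,
            "efficiency_bin": s.efficiency_bin,
            "region_class": s.region_class,
            "consequence": s.consequence,
        }
        for i, f in enumerate(s.per_library_fraction):
            row[f"frac_lib{i + 1}"] = round(f, 4)
        rows.append(row)
    return pd.DataFrame(rows)
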