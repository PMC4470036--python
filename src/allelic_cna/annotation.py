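"""Probe annotation: synthetic array manifests and coordinate helpers.

An annotation is a DataFrame with columns ``probe_id, chrom, pos, arm,
cytoband`` sorted by (chromosome, position), positions strictly increasing
within a chromosome, 0-based. The packaged synthetic manifest is a desk-scale
stand-in for a 1M-probe genotyping array: equally spaced probes over the 22
autosomes (+X), arm boundary at a fixed fraction of each chromosome.
"""
from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .model import CHROM_ORDER, CHROMOSOMES

#: approximate human chromosome sizes in Mb, used only to shape the synthetic
#: manifest (the pipeline itself never assumes a genome build)
APPROX_CHROM_MB: dict[str, float] = {
    "1": 249, "2": 243, "3": 198, "4": 191, "5": 181, "6": 171, "7": 159,
    "8": 146, "9": 141, "10": 136, "11": 135, "12": 134, "13": 115,
    "14": 107, "15": 102, "16": 90, "17": 83, "18": 80, "19": 59,
    "20": 63, "21": 48, "22": 51, "X": 155, "Y": 57,
}


def make_annotation(
    n_probes: int = 20_000,
    chrom_sizes_mb: Optional[Mapping[str, float]] = None,
    arm_fraction: float = 0.4,
    include_x: bool = True,
    include_y: bool = False,
    prefix: str = "p",
) -> pd.DataFrame:
    """Build a synthetic probe manifest.

    ``n_probes`` are distributed over the chromosomes proportionally to their
    sizes and spaced equally within each chromosome; the p/q boundary sits at
    ``arm_fraction`` of the chromosome length. Cytobands are coarse synthetic
    labels (one band per arm decile).
    """
    if chrom_sizes_mb is None:
        chroms = [c for c in CHROMOSOMES if c.isdigit()]
        if include_x:
            chroms.append("X")
        if include_y:
            chroms.append("Y")
        chrom_sizes_mb = {c: APPROX_CHROM_MB[c] for c in chroms}
    sizes = {c: float(mb) * 1e6 for c, mb in chrom_sizes_mb.items()}
    bad = [c for c in sizes if c not in CHROM_ORDER]
    if bad:
        raise ValueError(f"unknown chromosomes in size table: {bad}")
    order = sorted(sizes, key=CHROM_ORDER.get)
    total = sum(sizes.values())
    counts = {c: max(2, int(round(n_probes * sizes[c] / total))) for c in order}

    rows = []
    i = 0
    for c in order:
        n = counts[c]
        length = sizes[c]
        spacing = length / n
        pos = (np.arange(n) * spacing + spacing / 2).astype(np.int64)
        boundary = arm_fraction * length
        for p in pos:
            arm = "p" if p < boundary else "q"
            if arm == "p":
                decile = int(10 * p / boundary) if boundary > 0 else 0
            else:
                decile = int(10 * (p - boundary) / (length - boundary))
            rows.append((f"{prefix}{i:06d}", c, int(p), arm,
                         f"{c}{arm}{min(decile, 9) + 1}"))
            i += 1
    ann = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "arm", "cytoband"])
    return ann


def sort_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    key = ann["chrom"].map(CHROM_ORDER)
    if key.isna().any():
        bad = ann.loc[key.isna(), "chrom"].unique()
        raise ValueError(f"unknown chromosome labels: {list(bad)}")
    out = ann.assign(_k=key).sort_values(["_k", "pos"], kind="mergesort")
    out = out.drop(columns="_k").reset_index(drop=True)
    for c, grp in out.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
            raise ValueError(f"positions not strictly increasing on chromosome {c}")
    return out


def chrom_slices(ann: pd.DataFrame) -> dict[str, slice]:
    """Global probe-index range per chromosome (annotation must be sorted)."""
    out: dict[str, slice] = {}
    start = 0
    for c, grp in ann.groupby("chrom", sort=False):
        out[c] = slice(start, start + len(grp))
        start += len(grp)
    return out


def arm_index_ranges(ann: pd.DataFrame) -> dict[tuple[str, str], slice]:
    """Global probe-index range per (chromosome, arm)."""
    out: dict[tuple[str, str], slice] = {}
    sl = chrom_slices(ann)
    for c, s in sl.items():
        arms = ann["arm"].to_numpy()[s]
        n_p = int((arms == "p").sum())
        out[(c, "p")] = slice(s.start, s.start + n_p)
        out[(c, "q")] = slice(s.start + n_p, s.stop)
    return out


def chrom_extent_bp(ann: pd.DataFrame) -> dict[str, int]:
    """Approximate chromosome extent: last probe position + median spacing."""
    out = {}
    for c, grp in ann.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        spacing = int(np.median(np.diff(pos))) if len(pos) > 1 else 1
        out[c] = int(pos[-1] + spacing)
    return out
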