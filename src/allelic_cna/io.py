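"""Readers and writers for the pipeline's plain-text formats.

Probe matrices and annotation are tab-separated; genomic intervals go out as
BED (0-based half-open, "chr"-prefixed labels, attributes from column 4).
Internally chromosome labels carry no prefix.
"""
from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .annotation import sort_annotation
from .model import GENOTYPES, SIGNAL_COLUMNS, normalize_chrom

log = logging.getLogger("allelic_cna")

_TRIPLET = ("logR", "baf", "genotype")


def read_annotation(path, one_based: bool = False) -> pd.DataFrame:
    """Read a probe annotation TSV (probe_id, chrom, pos, arm, cytoband).

    ``one_based=True`` converts 1-based input positions to the internal
    0-based convention at read time.
    """
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str, "probe_id": str})
    missing = {"probe_id", "chrom", "pos", "arm", "cytoband"} - set(ann.columns)
    if missing:
        raise ValueError(f"annotation is missing columns: {sorted(missing)}")
    ann["chrom"] = ann["chrom"].map(normalize_chrom)
    if one_based:
        ann["pos"] = ann["pos"] - 1
    dup = ann["probe_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate probe id in annotation: "
                         f"{ann.loc[dup, 'probe_id'].iloc[0]!r}")
    return sort_annotation(ann)


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def write_probe_matrix(signals: dict[str, pd.DataFrame], annotation: pd.DataFrame,
                       path) -> None:
    """Write per-sample LogR/BAF/genotype triplets keyed to annotation order."""
    out = annotation[["probe_id"]].copy()
    for sample, df in signals.items():
        aligned = df.set_index("probe_id").reindex(out["probe_id"])
        for f in _TRIPLET:
            out[f"{sample}.{f}"] = aligned[f].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_probe_matrix(path, annotation: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Read a probe-signal matrix and align it to the annotation.

    Returns one DataFrame (``probe_id, logR, baf, genotype``) per sample, in
    annotation order. Probes absent from the annotation are dropped (counted
    in the log); BAF outside [0, 1] and non-finite LogR are flagged missing
    (NaN), never silently zeroed.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    if "probe_id" not in raw.columns:
        raise ValueError("probe matrix must have a 'probe_id' column")
    dup = raw["probe_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate probe id: {raw.loc[dup, 'probe_id'].iloc[0]!r}")

    samples: dict[str, set[str]] = {}
    for col in raw.columns:
        if col == "probe_id":
            continue
        if "." not in col:
            raise ValueError(f"unrecognized column {col!r}; expected "
                             "'<sample>.logR|baf|genotype'")
        sample, f = col.rsplit(".", 1)
        samples.setdefault(sample, set()).add(f)
    for sample, fields in samples.items():
        if fields != set(_TRIPLET):
            raise ValueError(
                f"sample {sample!r} has incomplete column triplet: "
                f"has {sorted(fields)}, needs {sorted(_TRIPLET)}")

    known = raw["probe_id"].isin(set(annotation["probe_id"]))
    n_dropped = int((~known).sum())
    if n_dropped:
        log.info("dropped %d probes absent from annotation", n_dropped)
    raw = raw[known]
    order = annotation["probe_id"]
    indexed = raw.set_index("probe_id").reindex(order)

    out: dict[str, pd.DataFrame] = {}
    for sample in samples:
        logR = pd.to_numeric(indexed[f"{sample}.logR"], errors="coerce").to_numpy(float)
        baf = pd.to_numeric(indexed[f"{sample}.baf"], errors="coerce").to_numpy(float)
        gt = indexed[f"{sample}.genotype"].astype(object).to_numpy()
        logR[~np.isfinite(logR)] = np.nan
        bad_baf = ~np.isfinite(baf) | (baf < 0) | (baf > 1)
        if (n_bad := int(bad_baf.sum()) - int(pd.isna(indexed[f"{sample}.baf"]).sum())) > 0:
            log.info("sample %s: %d BAF values outside [0,1] flagged missing",
                     sample, n_bad)
        baf[bad_baf] = np.nan
        gt = np.where(pd.isna(gt) | ~np.isin(gt, GENOTYPES), "NC", gt)
        out[sample] = pd.DataFrame({
            "probe_id": order.to_numpy(), "logR": logR, "baf": baf, "genotype": gt,
        })
    return out


def write_regions(regions: pd.DataFrame, path, header_comment: Optional[str] = None) -> None:
    """Write genomic intervals as BED: chrom, start, end, then attributes.

    Intervals must carry ``chrom, start, end`` (0-based half-open); remaining
    columns are serialized from column 4 on. Output is sorted by (chromosome,
    start, end) for determinism.
    """
    required = ["chrom", "start", "end"]
    missing = [c for c in required if c not in regions.columns]
    if missing:
        raise ValueError(f"regions are missing columns: {missing}")
    bad = regions["end"] <= regions["start"]
    if bad.any():
        r = regions[bad].iloc[0]
        raise ValueError(f"interval end <= start: {r['chrom']}:{r['start']}-{r['end']}")
    attrs = [c for c in regions.columns if c not in required]
    from .model import CHROM_ORDER
    out = regions.copy()
    out["chrom"] = out["chrom"].map(normalize_chrom)
    out = out.assign(_k=out["chrom"].map(CHROM_ORDER))
    out = out.sort_values(["_k", "start", "end"], kind="mergesort").drop(columns="_k")
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# columns: chrom\tstart\tend" +
                 ("\t" + "\t".join(attrs) if attrs else "") + "\n")
        for _, r in out.iterrows():
            fields = [f"chr{r['chrom']}", str(int(r["start"])), str(int(r["end"]))]
            for c in attrs:
                v = r[c]
                fields.append(repr(float(v)) if isinstance(v, float) else str(v))
            fh.write("\t".join(fields) + "\n")


def read_regions(path) -> pd.DataFrame:
    """Read a BED file written by :func:`write_regions` (lossless round-trip)."""
    attrs: list[str] = []
    rows: list[list] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                if line.startswith("# columns:"):
                    cols = line[len("# columns:"):].strip().split("\t")
                    attrs = cols[3:]
                continue
            if not line:
                continue
            rows.append(line.split("\t"))
    parsed = []
    for fields in rows:
        chrom = normalize_chrom(fields[0])
        rec = [chrom, int(fields[1]), int(fields[2])]
        for val in fields[3:]:
            try:
                rec.append(int(val))
            except ValueError:
                try:
                    rec.append(float(val))
                except ValueError:
                    rec.append(val)
        parsed.append(rec)
    columns = ["chrom", "start", "end"] + attrs
    if not parsed:
        return pd.DataFrame(columns=columns)
    width = max(len(r) for r in parsed)
    if len(columns) < width:
        columns += [f"attr{i}" for i in range(len(columns), width)]
    return pd.DataFrame(parsed, columns=columns[:width])


def read_expression(path) -> pd.DataFrame:
    """Read a normalized expression matrix (rows: genes/probes, cols: samples)."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if mat.index.duplicated().any():
        raise ValueError("duplicate row identifiers in expression matrix")
    return mat
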