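"""Raw intensity to LogR, BAF genotype calling, and sex handling.

LogR is ``log2(R / mean_R)`` against a reference pool of control samples.
Raw R intensities are first normalized by multiplicative median scaling so
the sample's autosomal median matches the pool's; this is a deliberately
simple, documented normalization — downstream stages depend only on LogR
being centred at 0 for two copies.
"""
from __future__ import annotations

import logging
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .model import SampleSex

log = logging.getLogger("allelic_cna")

#: arbitrary intensity unit of the synthetic reference pools
POOL_UNIT = 1000.0
#: background intensity of an absent chromosome (reads ~3 log2 units down)
_BACKGROUND = POOL_UNIT * 2 ** -4


def make_reference_pool(annotation: pd.DataFrame, sex: str = "mixed",
                        unit: float = POOL_UNIT) -> pd.DataFrame:
    """Synthetic reference pool: expected mean R per probe for a control
    population of the given sex composition (male, female or mixed 50/50).

    Autosomes sit at the diploid unit; X at the sex's X dosage; Y at the
    male one-copy level, background for females, and their average for the
    mixed pool.
    """
    chrom = annotation["chrom"].to_numpy()
    mean_R = np.full(len(annotation), unit)
    x_level = {"female": unit, "male": unit / 2, "mixed": 0.75 * unit}
    y_level = {"female": _BACKGROUND * unit / POOL_UNIT,
               "male": unit / 2,
               "mixed": (unit / 2 + _BACKGROUND * unit / POOL_UNIT) / 2}
    if sex not in x_level:
        raise ValueError(f"pool sex must be male/female/mixed, got {sex!r}")
    mean_R[chrom == "X"] = x_level[sex]
    mean_R[chrom == "Y"] = y_level[sex]
    return pd.DataFrame({
        "probe_id": annotation["probe_id"].to_numpy(),
        "mean_R": mean_R,
        "sex": sex,
    })


def _aligned_pool(pool: pd.DataFrame, annotation: pd.DataFrame) -> np.ndarray:
    m = pool.set_index("probe_id")["mean_R"].reindex(annotation["probe_id"])
    if m.isna().any():
        missing = annotation["probe_id"][m.isna().to_numpy()].iloc[0]
        raise ValueError(f"reference pool does not cover probe {missing!r}")
    return m.to_numpy(float)


def normalize_R(R: np.ndarray, pool: pd.DataFrame,
                annotation: pd.DataFrame) -> np.ndarray:
    """Multiplicative median scaling: after scaling, the sample median of
    autosomal R equals the pool's median autosomal mean_R. Missing probes
    stay missing."""
    R = np.asarray(R, float)
    autosomal = annotation["chrom"].str.isdigit().to_numpy()
    finite = np.isfinite(R)
    if not finite.any():
        raise ValueError("all probes missing: cannot normalize")
    sel = autosomal & finite
    if not sel.any():
        sel = finite
    sample_med = np.median(R[sel])
    pool_R = _aligned_pool(pool, annotation)
    pool_med = np.median(pool_R[autosomal] if autosomal.any() else pool_R)
    if sample_med <= 0:
        raise ValueError("non-positive sample median intensity")
    return R * (pool_med / sample_med)


def compute_logR(R: np.ndarray, pool: pd.DataFrame,
                 annotation: pd.DataFrame) -> np.ndarray:
    """log2(R / mean_R); probes with missing R or mean_R <= 0 become NaN."""
    R = np.asarray(R, float)
    pool_R = _aligned_pool(pool, annotation)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.isfinite(R) & (pool_R > 0) & (R > 0),
                       np.log2(R / np.where(pool_R > 0, pool_R, 1.0)), np.nan)
    return out


def call_genotypes(baf: np.ndarray, hom_window: float = 0.05,
                   het_window: float = 0.15) -> np.ndarray:
    """Threshold genotype caller on BAF.

    AA for baf <= hom_window, BB for baf >= 1 - hom_window, AB for
    |baf - 0.5| <= het_window, NC otherwise (including missing BAF).
    """
    if not 0 < hom_window < het_window < 0.5:
        raise ValueError("require 0 < hom_window < het_window < 0.5")
    baf = np.asarray(baf, float)
    out = np.full(baf.shape, "NC", dtype=object)
    with np.errstate(invalid="ignore"):
        out[baf <= hom_window] = "AA"
        out[baf >= 1 - hom_window] = "BB"
        out[np.abs(baf - 0.5) <= het_window] = "AB"
        out[~np.isfinite(baf)] = "NC"
    return out


def infer_sex_and_select_pool(
    R: np.ndarray,
    annotation: pd.DataFrame,
    pools: Mapping[str, pd.DataFrame],
    y_threshold: float = -1.0,
    metadata_sex: Optional[str] = None,
    sample: str = "sample",
) -> tuple[SampleSex, np.ndarray]:
    """Infer sex from Y-probe LogR and compute LogR with matched pools.

    Y presence (mean Y-probe LogR against the mixed pool above
    ``y_threshold``) is taken as reliable evidence of male origin and wins
    over conflicting metadata. Autosomes (and Y) are referenced against the
    mixed pool; the X chromosome against the sex-matched pool, and skipped
    (NaN, with a warning) when sex cannot be determined.
    """
    chrom = annotation["chrom"].to_numpy()
    mixed = pools["mixed"]
    Rn = normalize_R(np.asarray(R, float), mixed, annotation)
    logR = compute_logR(Rn, mixed, annotation)

    y_mask = chrom == "Y"
    y_evidence = float(np.nan)
    if y_mask.any():
        y_evidence = float(np.nanmean(logR[y_mask]))
        sex = "male" if y_evidence > y_threshold else "female"
        if metadata_sex and metadata_sex != "unknown" and metadata_sex != sex:
            log.warning("sample %s: metadata sex %r conflicts with Y evidence "
                        "(mean Y logR %.2f); Y evidence wins",
                        sample, metadata_sex, y_evidence)
    elif metadata_sex in ("male", "female"):
        sex = metadata_sex
    else:
        sex = "unknown"
        log.warning("sample %s: no Y probes and no metadata sex; "
                    "X-chromosome analysis skipped", sample)

    x_mask = chrom == "X"
    if x_mask.any():
        if sex in ("male", "female"):
            logR_x = compute_logR(Rn, pools[sex], annotation)
            logR[x_mask] = logR_x[x_mask]
        else:
            logR[x_mask] = np.nan
    return SampleSex(sample=sample, sex=sex, y_evidence=y_evidence), logR
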