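"""Genomic-instability metrics, association tests, and curated-table counts.

Instability per sample is measured three ways: megabases of genome altered
(gained + lost, from segment extents), fraction of probes altered, and the
number of altered segments. Cohorts are split into lower/middle/upper
tertiles per metric. Group comparisons use the two-sided Wilcoxon rank-sum
test (exact for small samples) and 2x2 chi-square without continuity
correction by default.
"""
from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .curated import CuratedLineTable, resolve

log = logging.getLogger("allelic_cna")

PROFILE_COLUMNS = ["sample", "mb_gained", "mb_lost", "mb_altered",
                   "frac_probes_altered", "n_altered_segments"]


def instability_metrics(segments: pd.DataFrame, n_probes: int,
                        sample: Optional[str] = None) -> pd.Series:
    """Instability profile of one sample from its called segments."""
    if sample is not None:
        segments = segments[segments["sample"] == sample]
    elif segments["sample"].nunique() > 1:
        raise ValueError("segments contain multiple samples; pass sample=")
    bp = (segments["end_bp"] - segments["start_bp"]).to_numpy(float)
    call = segments["call"].to_numpy()
    npb = segments["n_probes"].to_numpy()
    gained = bp[call >= 1].sum() / 1e6
    lost = bp[call <= -1].sum() / 1e6
    altered_probes = int(npb[call != 0].sum())
    return pd.Series({
        "sample": sample if sample is not None else
        (segments["sample"].iloc[0] if len(segments) else ""),
        "mb_gained": gained,
        "mb_lost": lost,
        "mb_altered": gained + lost,
        "frac_probes_altered": altered_probes / n_probes,
        "n_altered_segments": int((call != 0).sum()),
    })


def cohort_instability(segments: pd.DataFrame, n_probes: int) -> pd.DataFrame:
    """Per-sample instability profiles with tertile classes per metric."""
    profiles = pd.DataFrame(
        [instability_metrics(segments, n_probes, sample=s)
         for s in sorted(segments["sample"].unique())])
    if len(profiles) >= 3:
        for metric in ("mb_altered", "frac_probes_altered", "n_altered_segments"):
            profiles[f"{metric}_tertile"] = tertile_classify(
                profiles[metric].to_numpy(float))
    return profiles.reset_index(drop=True)


def tertile_classify(values: np.ndarray) -> np.ndarray:
    """Lower/middle/upper tertile labels; boundary ties go to the lower
    class (deterministic, order-invariant)."""
    values = np.asarray(values, float)
    if len(values) < 3:
        raise ValueError("tertile classification needs >= 3 samples")
    q1, q2 = np.quantile(values, [1 / 3, 2 / 3])
    if q1 == q2:
        warnings.warn("degenerate tertile boundaries (tied values); "
                      "ties assigned to the lower class")
    out = np.full(len(values), "high", dtype=object)
    out[values <= q2] = "intermediate"
    out[values <= q1] = "low"
    return out


def group_association(values: np.ndarray, groups: np.ndarray
                      ) -> tuple[float, tuple[float, float], tuple[float, float]]:
    """Two-sided Wilcoxon rank-sum comparison of a metric between two groups.

    Exact null distribution for combined n <= 20 (without ties), normal
    approximation with continuity correction otherwise. Returns
    (p, (mean_a, mean_b), (sd_a, sd_b)).
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {list(labels)}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(values)) < len(values)
    method = "exact" if (len(a) + len(b) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return (float(res.pvalue),
            (float(a.mean()), float(b.mean())),
            (float(a.std(ddof=1)) if len(a) > 1 else 0.0,
             float(b.std(ddof=1)) if len(b) > 1 else 0.0))


def frequency_chi2(mutants_a: int, n_a: int, mutants_b: int, n_b: int,
                   yates: bool = False) -> tuple[float, float]:
    """2x2 chi-square comparing mutation frequencies between two cohorts.

    No continuity correction by default (``yates=True`` enables it).
    Degenerate margins (no mutants or all mutants in both) give (0, 1) with
    a warning.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("cohort sizes must be positive")
    table = np.array([[mutants_a, n_a - mutants_a],
                      [mutants_b, n_b - mutants_b]], dtype=float)
    if (table < 0).any():
        raise ValueError("mutant counts exceed cohort sizes")
    if (table.sum(axis=0) == 0).any():
        warnings.warn("zero margin in 2x2 table; chi-square undefined, "
                      "returning statistic 0")
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(stat), float(p)


_DISCORDANCE_TYPES = ("gain/loss", "gain/no-change", "loss/no-change")


def replicate_concordance(calls_a: np.ndarray, calls_b: np.ndarray
                          ) -> tuple[float, dict[str, float]]:
    """Absolute call concordance between replicates plus a discordance
    breakdown (fractions of all probes) by type; +2 counts as gain."""
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.shape != b.shape:
        raise ValueError("replicate call vectors must align probe-for-probe")
    n = len(a)
    same = a == b
    rate = float(same.mean())
    ga, gb = a >= 1, b >= 1
    la, lb = a <= -1, b <= -1
    breakdown = {}
    disc = ~same
    gl = disc & ((ga & lb) | (la & gb))
    gn = disc & ~gl & (ga | gb)
    ln = disc & ~gl & ~gn & (la | lb)
    for name, mask in zip(_DISCORDANCE_TYPES, (gl, gn, ln)):
        if mask.any():
            breakdown[name] = float(mask.mean())
    return rate, breakdown


def count_dual_mutants(table: CuratedLineTable, gene_a: str, gene_b: str,
                       policy: str = "any_source") -> int:
    """Lines carrying a point mutation in both genes under the policy.

    Fusions and amplifications are not point mutations. Under
    ``own_data_precedence`` a gene's own-assay entries override external
    sources when present.
    """
    count = 0
    for line in table.lines:
        mutant = []
        for gene in (gene_a, gene_b):
            entries = resolve(table.mutation_status(line, gene), policy)
            mutant.append(any(e.is_point_mutation for e in entries))
        count += all(mutant)
    return count


def count_gene_loss(table: CuratedLineTable, gene: str, status: str,
                    policy: str = "own_data_precedence") -> int:
    """Lines whose resolved copy-number status for the gene equals ``status``
    (LOH or HD) under the source-resolution policy."""
    if status not in ("LOH", "HD"):
        raise ValueError("status must be 'LOH' or 'HD'")
    count = 0
    for line in table.lines:
        entries = resolve(table.cn_status(line, gene), policy)
        count += any(e.status == status for e in entries)
    return count
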