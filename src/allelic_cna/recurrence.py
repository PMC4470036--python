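"""Cohort-level recurrence: alteration frequencies, permutation-tested
minimal common regions (MCRs), recurrent amplifications, and arm tables.

The MCR null assumes the alterations found are randomly located in the
genome: each permutation relocates every sample's altered segments to
uniformly random positions (probe-count sizes preserved, within-sample
overlaps resolved by rejection), and per-probe p-values compare the observed
recurrence against the permuted one, followed by Benjamini-Hochberg FDR
control. Consecutive probes below the adjusted-p cutoff join into an MCR.

Because genome-wide uniform relocation gives every probe the same marginal
null, the default p-value estimator pools the permuted frequencies across
probes, which extends the attainable resolution from 1/(n_perm+1) to
1/(n_perm * n_probes + 1); the strict per-probe estimator is available as
``p_mode="per_probe"``.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .annotation import chrom_slices
from .segment import calls_by_probe

log = logging.getLogger("allelic_cna")

MCR_COLUMNS = ["chrom", "start_bp", "end_bp", "direction", "n_probes",
               "frequency", "p_adjusted"]


def _direction_mask(calls: np.ndarray, direction: str) -> np.ndarray:
    if direction == "gain":
        return calls >= 1  # amplification counts as gain
    if direction == "loss":
        return calls <= -1
    raise ValueError(f"direction must be 'gain' or 'loss', got {direction!r}")


def probe_frequency(calls: np.ndarray, direction: str) -> np.ndarray:
    """Fraction of samples altered in the given direction, per probe."""
    mask = _direction_mask(np.asarray(calls), direction)
    return mask.mean(axis=1)


def _probe_end(annotation: pd.DataFrame) -> np.ndarray:
    pos = annotation["pos"].to_numpy()
    out = np.empty(len(pos), dtype=np.int64)
    for sl in chrom_slices(annotation).values():
        n = sl.stop - sl.start
        spacing = int(np.median(np.diff(pos[sl]))) if n > 1 else 1
        out[sl.start:sl.stop - 1] = pos[sl.start + 1:sl.stop]
        out[sl.stop - 1] = pos[sl.stop - 1] + spacing
    return out


def mcr_permutation_test(
    segments: pd.DataFrame,
    annotation: pd.DataFrame,
    direction: str,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    null_scope: str = "genome",
    p_mode: str = "pooled",
) -> pd.DataFrame:
    """Permutation-tested minimal common regions for one direction.

    Returns a region table (MCR_COLUMNS); ``frequency`` is the peak probe
    frequency within the region and ``p_adjusted`` the minimum BH-adjusted
    p over its probes.
    """
    if n_perm < 100:
        log.warning("n_perm=%d gives coarse p-value resolution", n_perm)
    rng = np.random.default_rng(seed)
    n_probes = len(annotation)
    sls = chrom_slices(annotation)
    chrom_bounds = [(sl.start, sl.stop) for sl in sls.values()]

    mat, samples = calls_by_probe(segments, n_probes)
    n_samples = len(samples)
    altered = _direction_mask(mat, direction)
    obs_count = altered.sum(axis=1).astype(np.int64)
    if obs_count.sum() == 0:
        return pd.DataFrame(columns=MCR_COLUMNS)

    # per-sample altered runs as (chromosome index, length in probes)
    runs: list[list[tuple[int, int]]] = []
    sub = segments[_direction_mask(segments["call"].to_numpy(), direction)]
    chrom_of = {c: i for i, c in enumerate(sls)}
    for s in samples:
        mine = sub[sub["sample"] == s]
        runs.append([(chrom_of[r["chrom"]], r["end_index"] - r["start_index"])
                     for _, r in mine.iterrows()])

    # valid placements per run length
    lengths = {l for rs in runs for (_, l) in rs}
    valid: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for l in lengths:
        counts = np.array([max(0, b - a - l + 1) for a, b in chrom_bounds])
        valid[l] = (counts, counts.cumsum())

    exceed = np.zeros(n_probes, dtype=np.int64)
    pool_hist = np.zeros(n_samples + 1, dtype=np.int64)
    diff = np.empty(n_probes + 1, dtype=np.int64)
    for _ in range(n_perm):
        diff[:] = 0
        for sample_runs in runs:
            placed: list[tuple[int, int]] = []
            for ci, l in sample_runs:
                counts, cum = valid[l]
                for _try in range(200):
                    if null_scope == "genome":
                        total = cum[-1]
                        u = int(rng.integers(total))
                        c_idx = int(np.searchsorted(cum, u, side="right"))
                        offset = u - (cum[c_idx - 1] if c_idx else 0)
                        start = chrom_bounds[c_idx][0] + offset
                    else:
                        a, b = chrom_bounds[ci]
                        start = int(rng.integers(a, max(a + 1, b - l + 1)))
                    end = start + l
                    if all(end <= p0 or p1 <= start for p0, p1 in placed):
                        break
                placed.append((start, end))
                diff[start] += 1
                diff[end] -= 1
        counts_vec = np.cumsum(diff[:-1])
        exceed += counts_vec >= obs_count
        pool_hist += np.bincount(counts_vec, minlength=n_samples + 1)

    if p_mode == "per_probe":
        p = (1 + exceed) / (n_perm + 1)
    elif p_mode == "pooled":
        tail = pool_hist[::-1].cumsum()[::-1]  # tail[c] = #{pooled >= c}
        obs_clip = np.minimum(obs_count, n_samples)
        p = (1 + tail[obs_clip]) / (1 + n_perm * n_probes)
        p = np.minimum(p, 1.0)
    else:
        raise ValueError(f"unknown p_mode {p_mode!r}")

    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    freq = obs_count / n_samples
    sig = p_adj < alpha

    pend = _probe_end(annotation)
    pos = annotation["pos"].to_numpy()
    rows = []
    for chrom, sl in sls.items():
        mask = sig[sl.start:sl.stop]
        for lo, hi in _bool_runs(mask):
            a, b = sl.start + lo, sl.start + hi
            rows.append((chrom, int(pos[a]), int(pend[b - 1]), direction,
                         b - a, float(freq[a:b].max()),
                         float(p_adj[a:b].min())))
    return pd.DataFrame(rows, columns=MCR_COLUMNS)


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    return list(zip(np.flatnonzero(d == 1).tolist(),
                    np.flatnonzero(d == -1).tolist()))


def recurrent_amplifications(
    segments: pd.DataFrame,
    annotation: pd.DataFrame,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Maximal probe runs amplified (call +2) in >= min_samples samples."""
    mat, samples = calls_by_probe(segments, len(annotation))
    amp_count = (mat == 2).sum(axis=1)
    hot = amp_count >= min_samples
    pos = annotation["pos"].to_numpy()
    pend = _probe_end(annotation)
    rows = []
    for chrom, sl in chrom_slices(annotation).items():
        for lo, hi in _bool_runs(hot[sl.start:sl.stop]):
            a, b = sl.start + lo, sl.start + hi
            in_region = (mat[a:b] == 2).any(axis=0)
            carriers = [s for s, flag in zip(samples, in_region) if flag]
            rows.append((chrom, int(pos[a]), int(pend[b - 1]), b - a,
                         int(amp_count[a:b].max()), ",".join(carriers)))
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp",
                                       "n_probes", "max_samples", "samples"])


def arm_alteration_table(segments_with_scope: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome counts of whole-chromosome and arm gains/losses.

    Each sample contributes at most once per (chromosome, scope, direction);
    a whole-chromosome event never double-counts as two arm events. Requires
    segments labelled by :func:`allelic_cna.segment.classify_scope` and an
    ``arm`` column naming the covered arm for whole_arm segments.
    """
    seg = segments_with_scope
    cols = ["whole_gain", "whole_loss", "p_gain", "p_loss", "q_gain", "q_loss"]
    table: dict[str, dict[str, set]] = {}
    for _, r in seg.iterrows():
        if r["call"] == 0 or r["scope"] == "focal":
            continue
        direction = "gain" if r["call"] >= 1 else "loss"
        chrom = r["chrom"]
        slot = (f"whole_{direction}" if r["scope"] == "whole_chromosome"
                else f"{r.get('arm', '?')}_{direction}")
        if slot not in cols:
            continue
        table.setdefault(chrom, {c: set() for c in cols})[slot].add(r["sample"])
    rows = {c: [len(v[col]) for col in cols] for c, v in table.items()}
    out = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    out.index.name = "chrom"
    return out.fillna(0).astype(int)
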