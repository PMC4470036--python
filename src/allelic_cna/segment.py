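"""Change-point segmentation of LogR series and categorical calling.

Segmentation follows circular binary segmentation (CBS): within each
segment the candidate change is the arc [i, j) maximizing the standardized
mean-difference statistic between the arc and its (circular) complement;
the candidate is accepted when its within-segment permutation p-value is
below alpha, and the algorithm recurses on the resulting pieces. An
interior arc contributes both edges as breakpoints (the double split); an
edge-anchored arc is a single split.

For speed, the arc scan runs over a geometric grid of arc widths, after
which the winning arc's edges are refined by exact coordinate ascent; the
permutation null uses the same grid statistic as the observed value.
Permutations are drawn in blocks with early termination in both directions
(reject once significance is unattainable; accept once no permutation has
reached the observed statistic in the first 200), which leaves the decision
deterministic for a given seed.

Calls follow the study convention: -1 loss (hemi- or homozygous), 0 neutral,
+1 gain, +2 amplification (>= 5 copies, i.e. mean LogR >= log2(5/2)).
"""
from __future__ import annotations

import logging
import math
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import arm_index_ranges, chrom_slices
from .model import RunConfig, SEGMENT_COLUMNS

log = logging.getLogger("allelic_cna")

#: geometric growth factor of the arc-width grid
_WIDTH_FACTOR = 1.5
#: permutations drawn per early-stopping block
_PERM_BLOCK = 32
#: clean permutations before an early accept
_EARLY_ACCEPT = 200


def _arc_widths(n: int, min_probes: int) -> list[int]:
    """Geometric grid of arc widths in [min_probes, n//2]."""
    widths = []
    w = min_probes
    while w <= n // 2:
        widths.append(w)
        w = max(w + 1, int(w * _WIDTH_FACTOR))
    return widths or []


def _arc_stat_coeffs(n: int, w: int) -> tuple[float, float, float]:
    """stat = |a * arc_sum + b| / se is affine in the arc sum."""
    inv = 1.0 / w + 1.0 / (n - w)
    se = math.sqrt(inv)
    return inv, se


def _best_arc(x: np.ndarray, min_probes: int) -> tuple[int, int, float]:
    """Best arc [i, j) on the width grid, then exact edge refinement.

    Returns (i, j, grid_stat); the significance decision uses the grid
    statistic (matching the permutation null), the refined edges only fix
    the breakpoint locations.
    """
    n = len(x)
    cums = np.concatenate([[0.0], np.cumsum(x)])
    total = cums[-1]
    best = (0, n, 0.0)
    for w in _arc_widths(n, min_probes):
        inv, se = _arc_stat_coeffs(n, w)
        arc = cums[w:] - cums[:-w]
        stats = np.abs(arc * inv - total / (n - w)) / se
        k = int(np.argmax(stats))
        if stats[k] > best[2]:
            best = (k, k + w, float(stats[k]))
    i, j, grid_stat = best
    if grid_stat <= 0:
        return best
    i, j = _refine_arc(x, cums, i, j, min_probes)
    return i, j, grid_stat


def _exact_arc_stat(cums: np.ndarray, total: float, n: int,
                    i: np.ndarray, j: np.ndarray) -> np.ndarray:
    w = j - i
    arc = cums[j] - cums[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / w + 1.0 / (n - w)
        return np.abs(arc * inv - total / (n - w)) / np.sqrt(inv)


def _refine_arc(x: np.ndarray, cums: np.ndarray, i: int, j: int,
                min_probes: int, max_rounds: int = 4) -> tuple[int, int]:
    """Coordinate ascent on the exact arc statistic to localize the edges.

    Edges stay flush with the segment border or >= min_probes away from it,
    the arc keeps >= min_probes probes, and the complement stays non-empty.
    """
    n = len(x)
    total = float(cums[-1])
    pos = np.arange(n + 1)
    for _ in range(max_rounds):
        i0, j0 = i, j
        cand = pos[((pos == 0) | (pos >= min_probes))
                   & (j - pos >= min_probes) & (j - pos <= n - 1)]
        if len(cand):
            stats = _exact_arc_stat(cums, total, n, cand,
                                    np.full(len(cand), j))
            i = int(cand[np.argmax(stats)])
        cand = pos[((pos == n) | (pos <= n - min_probes))
                   & (pos - i >= min_probes) & (pos - i <= n - 1)]
        if len(cand):
            stats = _exact_arc_stat(cums, total, n, np.full(len(cand), i),
                                    cand)
            j = int(cand[np.argmax(stats)])
        if (i, j) == (i0, j0):
            break
    return i, j


def _perm_max_stats(x: np.ndarray, b: int, widths: list[int],
                    rng: np.random.Generator) -> np.ndarray:
    """Max grid-arc statistic for b random permutations of x.

    Uses the affine form of the statistic in the arc sum: per width only
    the running max/min of the arc sums are needed.
    """
    n = len(x)
    perm = rng.permuted(np.broadcast_to(x, (b, n)), axis=1)
    cums = np.concatenate([np.zeros((b, 1)), np.cumsum(perm, axis=1)], axis=1)
    total = cums[:, -1]
    out = np.zeros(b)
    for w in widths:
        inv, se = _arc_stat_coeffs(n, w)
        arc = cums[:, w:] - cums[:, :-w]
        hi = arc.max(axis=1)
        lo = arc.min(axis=1)
        shift = total / (n - w)
        stat = np.maximum(np.abs(hi * inv - shift),
                          np.abs(lo * inv - shift)) / se
        np.maximum(out, stat, out=out)
    return out


def _split_significant(x: np.ndarray, t_obs: float, alpha: float,
                       n_perm: int, min_probes: int,
                       rng: np.random.Generator) -> bool:
    """Adaptive permutation test: p = (1 + #exceed) / (#perms + 1).

    Stops early once p >= alpha is guaranteed, or accepts once
    _EARLY_ACCEPT permutations have passed without a single exceedance.
    """
    k_stop = math.ceil(alpha * (n_perm + 1))  # forces p >= alpha
    widths = _arc_widths(len(x), min_probes)
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(_PERM_BLOCK, n_perm - done)
        stats = _perm_max_stats(x, b, widths, rng)
        exceed += int((stats >= t_obs).sum())
        done += b
        if exceed >= k_stop:
            return False
        if exceed == 0 and done >= _EARLY_ACCEPT:
            return True
    return (1 + exceed) / (n_perm + 1) < alpha


def segment_logR(
    x: np.ndarray,
    alpha: float = 0.01,
    min_probes: int = 5,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[int]:
    """Segment one chromosome's LogR series; returns sorted breakpoints.

    A breakpoint b means segments split as [..., b) / [b, ...). Missing
    values are dropped internally with index bookkeeping: breakpoints are
    reported in the original index space (at the first finite probe of the
    right-hand segment). A series shorter than 2*min_probes yields no
    breakpoints (with a warning).
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    x = np.asarray(x, float)
    finite_idx = np.flatnonzero(np.isfinite(x))
    xs = x[finite_idx]
    if len(xs) < 2 * min_probes:
        log.warning("series of %d finite probes is shorter than 2*min_probes;"
                    " returning a single segment", len(xs))
        return []

    breakpoints: list[int] = []
    stack = [(0, len(xs))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2 * min_probes:
            continue
        seg = xs[lo:hi]
        i, j, t_obs = _best_arc(seg, min_probes)
        if t_obs <= 1e-12:  # constant segment
            continue
        if _split_significant(seg, t_obs, alpha, n_perm, min_probes, rng):
            cuts = [k for k in (i, j) if 0 < k < hi - lo]
            if not cuts:
                continue
            breakpoints.extend(lo + k for k in cuts)
            bounds = [lo] + [lo + k for k in cuts] + [hi]
            for a, b in zip(bounds, bounds[1:]):
                stack.append((a, b))
    return sorted(int(finite_idx[b]) for b in breakpoints)


def merge_short_segments(x: np.ndarray, breakpoints: list[int],
                         min_probes: int) -> list[int]:
    """Merge segments shorter than min_probes into the more similar
    neighbour (ties toward the left neighbour)."""
    bps = sorted(breakpoints)
    changed = True
    while changed:
        changed = False
        bounds = [0] + bps + [len(x)]
        for i in range(len(bounds) - 1):
            lo, hi = bounds[i], bounds[i + 1]
            if hi - lo >= min_probes or len(bounds) <= 2:
                continue
            seg_mean = np.nanmean(x[lo:hi])
            first, last = i == 0, i == len(bounds) - 2
            d_left = (abs(seg_mean - np.nanmean(x[bounds[i - 1]:lo]))
                      if not first else np.inf)
            d_right = (abs(seg_mean - np.nanmean(x[hi:bounds[i + 2]]))
                       if not last else np.inf)
            bps.remove(hi if first or (d_right < d_left and not last) else lo)
            changed = True
            break
    return bps


def segment_sample(
    signals: pd.DataFrame,
    annotation: pd.DataFrame,
    config: Optional[RunConfig] = None,
    *,
    sample: str = "sample",
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Segment and call every chromosome of one sample.

    Returns the segment table (SEGMENT_COLUMNS); indices are global probe
    indices into the annotation, half-open, tiling each chromosome.
    """
    cfg = config or RunConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    logR = signals["logR"].to_numpy(float)
    pos = annotation["pos"].to_numpy()
    rows = []
    for chrom, sl in chrom_slices(annotation).items():
        x = logR[sl]
        n = sl.stop - sl.start
        spacing = int(np.median(np.diff(pos[sl]))) if n > 1 else 1
        probe_end = np.empty(n, dtype=np.int64)
        probe_end[:-1] = pos[sl.start + 1:sl.stop]
        probe_end[-1] = pos[sl.stop - 1] + spacing
        bps = segment_logR(x, cfg.cbs_alpha, cfg.cbs_min_probes,
                           cfg.cbs_n_perm, rng=rng)
        bounds = [0] + bps + [n]
        for lo, hi in zip(bounds, bounds[1:]):
            seg = x[lo:hi]
            mean = float(np.nanmean(seg)) if np.isfinite(seg).any() else np.nan
            rows.append((sample, chrom, sl.start + lo, sl.start + hi,
                         int(pos[sl.start + lo]), int(probe_end[hi - 1]),
                         hi - lo, mean, 0))
    segs = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return call_segments(segs, cfg.loss_threshold, cfg.gain_threshold,
                         cfg.amp_threshold)


def call_segments(segments: pd.DataFrame, loss_t: float = -0.3,
                  gain_t: float = 0.3,
                  amp_t: float = math.log2(5 / 2)) -> pd.DataFrame:
    """Categorical calls from segment mean LogR by documented thresholds."""
    if not loss_t < 0 < gain_t < amp_t:
        raise ValueError("require loss_t < 0 < gain_t < amp_t")
    m = segments["mean_logR"].to_numpy(float)
    call = np.zeros(len(segments), dtype=int)
    call[m <= loss_t] = -1
    call[m >= gain_t] = 1
    call[m >= amp_t] = 2
    out = segments.copy()
    out["call"] = call
    return out


def segment_cohort(cohort: dict[str, pd.DataFrame], annotation: pd.DataFrame,
                   config: Optional[RunConfig] = None,
                   seed: Optional[int] = None) -> pd.DataFrame:
    """Segment every sample of a cohort (per-sample seeds spawned from one)."""
    cfg = config or RunConfig()
    base = cfg.seed if seed is None else seed
    frames = []
    for i, (name, sig) in enumerate(sorted(cohort.items())):
        frames.append(segment_sample(sig, annotation, cfg, sample=name,
                                     seed=base + 7919 * (i + 1)))
    return pd.concat(frames, ignore_index=True)


def classify_scope(segments: pd.DataFrame, annotation: pd.DataFrame,
                   arm_fraction: float = 0.9) -> pd.DataFrame:
    """Label each segment whole_chromosome / whole_arm / focal.

    A segment is a whole-arm alteration when it covers >= arm_fraction of
    that arm's probes (and less of the other), whole-chromosome when both
    arms are covered; everything else is focal.
    """
    if "arm" not in annotation.columns or annotation["arm"].isna().all():
        log.warning("annotation has no arm information; all segments focal")
        return segments.assign(scope="focal")
    arms = arm_index_ranges(annotation)
    scopes = []
    arm_covered = []
    for _, r in segments.iterrows():
        cov = {}
        for arm in ("p", "q"):
            sl = arms.get((r["chrom"], arm))
            n_arm = (sl.stop - sl.start) if sl else 0
            if n_arm == 0:
                cov[arm] = 1.0  # absent arm is vacuously covered
                continue
            ov = max(0, min(r["end_index"], sl.stop) - max(r["start_index"], sl.start))
            cov[arm] = ov / n_arm
        full = [a for a in ("p", "q") if cov[a] >= arm_fraction]
        if len(full) == 2:
            scopes.append("whole_chromosome")
            arm_covered.append("pq")
        elif len(full) == 1:
            scopes.append("whole_arm")
            arm_covered.append(full[0])
        else:
            scopes.append("focal")
            arm_covered.append("")
    return segments.assign(scope=scopes, arm=arm_covered)


def calls_by_probe(segments: pd.DataFrame, n_probes: int,
                   samples: Optional[list[str]] = None
                   ) -> tuple[np.ndarray, list[str]]:
    """Expand segment calls into a (probe x sample) call matrix."""
    if samples is None:
        samples = sorted(segments["sample"].unique())
    mat = np.zeros((n_probes, len(samples)), dtype=np.int8)
    col = {s: j for j, s in enumerate(samples)}
    for _, r in segments.iterrows():
        if r["call"] != 0 and r["sample"] in col:
            mat[r["start_index"]:r["end_index"], col[r["sample"]]] = r["call"]
    return mat, samples
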