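"""End-to-end recovery studies on synthetic cohorts with planted truth.

Each study generates data with the simulator at its documented defaults,
runs the relevant pipeline stage, and measures recovery against the planted
truth. Problem sizes are desk-scale (see docs/methods.md): the synthetic
manifests keep the probe-per-event geometry of a 1M-probe array while
staying small enough to run interactively.
"""
from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import make_annotation
from .model import CNEvent, EventPlan, NoiseModel, RunConfig
from .allelic import detect_upd
from .instability import frequency_chi2, group_association
from .recurrence import mcr_permutation_test
from .segment import segment_cohort, segment_logR, segment_sample
from .simulate import (make_demo_centroids, simulate_cohort, simulate_expression,
                       simulate_sample)
from .expression import classify_by_centroids


def breakpoint_recovery(n_runs: int = 50, n_per_side: int = 200,
                        delta: float = 1.0, sd: float = 0.15,
                        tolerance: int = 2, seed: int = 0) -> dict:
    """Fraction of step-signal runs whose breakpoint lands within
    +/- tolerance probes of the true change-point."""
    rng = np.random.default_rng(seed)
    truth = n_per_side
    hits = 0
    for _ in range(n_runs):
        x = np.concatenate([rng.normal(0.0, sd, n_per_side),
                            rng.normal(delta, sd, n_per_side)])
        bps = segment_logR(x, rng=rng)
        if any(abs(b - truth) <= tolerance for b in bps):
            hits += 1
    return {"rate": hits / n_runs, "n": n_runs}


#: analytic call for planted total copies
EXPECTED_CALL = {0: -1, 1: -1, 2: 0, 3: 1, 6: 2}


def call_correctness(seed: int = 0) -> dict:
    """Zero-noise pipeline identity: planted copies {0,1,2,3,6} must come
    back with calls {-1,-1,0,+1,+2} and exact boundaries."""
    ann = make_annotation(n_probes=2500,
                         chrom_sizes_mb={str(c): 50 for c in range(1, 6)})
    noise = NoiseModel(logR_sd=0.0, baf_sd=0.0, probe_dropout_rate=0.0)
    events = [CNEvent(str(c), 10_000_000, 20_000_000, copies,
                      min(1, copies // 2))
              for c, copies in zip(range(1, 5), (0, 1, 3, 6))]
    plan = EventPlan("zero_noise", tuple(events))
    sig, truth = simulate_sample(plan, ann, noise, seed=seed)
    segs = segment_sample(sig, ann, RunConfig(), sample="zero_noise", seed=seed)

    chrom = ann["chrom"].to_numpy()
    pos = ann["pos"].to_numpy()
    n_correct = 0
    boundaries_exact = True
    checks = list(truth.itertuples())
    for ev in checks:
        probes = np.flatnonzero((chrom == ev.chrom) & (pos >= ev.start)
                                & (pos < ev.end))
        match = segs[(segs["chrom"] == ev.chrom)
                     & (segs["start_index"] == probes[0])
                     & (segs["end_index"] == probes[-1] + 1)]
        if len(match) == 1 and match["call"].iloc[0] == EXPECTED_CALL[ev.total_copies]:
            n_correct += 1
        else:
            boundaries_exact = False
    # the untouched chromosome must be one neutral segment
    ch5 = segs[segs["chrom"] == "5"]
    neutral_ok = len(ch5) == 1 and ch5["call"].iloc[0] == 0
    return {"n_events": len(checks), "n_correct": n_correct,
            "boundaries_exact": boundaries_exact and n_correct == len(checks),
            "neutral_chromosome_ok": bool(neutral_ok)}


def _upd_annotation() -> pd.DataFrame:
    # ten 45-Mb chromosomes at ~25 kb spacing: a 2 Mb event is ~80 probes,
    # matching the probe-per-event geometry of a 1M-probe array
    return make_annotation(n_probes=18_000,
                          chrom_sizes_mb={str(c): 45 for c in range(1, 11)})


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0])) if ov else 0.0


def upd_recovery(seed: int = 0, n_samples: int = 20,
                 events_per_sample: int = 3, min_overlap: float = 0.5) -> dict:
    """Sensitivity/precision of UPD detection on planted copy-neutral LOH.

    Plants ``n_samples * events_per_sample`` events across whole-chromosome,
    whole-arm and focal scopes (2-50 Mb) at default noise.
    """
    ann = _upd_annotation()
    rng = np.random.default_rng(seed)
    cfg = RunConfig()
    chrom_mb = 45
    arm_split = int(0.4 * chrom_mb * 1e6)
    scopes = ["whole_chromosome", "whole_arm", "focal"]

    n_true = 0
    n_detected = 0
    n_true_matched = 0
    n_det_matched = 0
    for i in range(n_samples):
        chroms = rng.choice(np.arange(1, 11), size=events_per_sample,
                            replace=False)
        events = []
        for j, c in enumerate(chroms):
            scope = scopes[(i + j) % 3]
            if scope == "whole_chromosome":
                start, end = 0, chrom_mb * 10**6
            elif scope == "whole_arm":
                start, end = ((0, arm_split) if rng.integers(2)
                              else (arm_split, chrom_mb * 10**6))
            else:
                size = int(rng.uniform(2e6, 12e6))
                lo, hi = (0, arm_split) if rng.integers(2) else (arm_split,
                                                                 chrom_mb * 10**6)
                start = int(rng.integers(lo, hi - size))
                end = start + size
            events.append(CNEvent(str(c), start, end, 2, 0, scope))
        plan = EventPlan(f"U{i:03d}", tuple(events))
        sig, truth = simulate_sample(plan, ann, NoiseModel(), rng=rng)
        found = detect_upd(sig, ann, cfg, sample=plan.sample)

        truth_iv = [(r.chrom, (r.start, r.end)) for r in truth.itertuples()]
        det_iv = [(r.chrom, (r.start_bp, r.end_bp)) for r in found.itertuples()]
        n_true += len(truth_iv)
        n_detected += len(det_iv)
        for c, iv in truth_iv:
            if any(dc == c and _reciprocal_overlap(iv, div) >= min_overlap
                   for dc, div in det_iv):
                n_true_matched += 1
        for dc, div in det_iv:
            if any(c == dc and _reciprocal_overlap(iv, div) >= min_overlap
                   for c, iv in truth_iv):
                n_det_matched += 1
    return {
        "n_true": n_true,
        "n_detected": n_detected,
        "sensitivity": n_true_matched / n_true if n_true else float("nan"),
        "precision": n_det_matched / n_detected if n_detected else float("nan"),
    }


def upd_null(seed: int = 0, n_samples: int = 20) -> dict:
    """UPD events reported on an all-diploid cohort (specificity)."""
    ann = _upd_annotation()
    rng = np.random.default_rng(seed)
    cfg = RunConfig()
    total = 0
    for i in range(n_samples):
        sig, _ = simulate_sample(EventPlan(f"N{i:03d}"), ann, NoiseModel(),
                                 rng=rng)
        total += len(detect_upd(sig, ann, cfg, sample=f"N{i:03d}"))
    return {"n_events": total, "n_samples": n_samples}


def _mcr_annotation() -> pd.DataFrame:
    return make_annotation(n_probes=20_000, include_x=False)


def mcr_null_calibration(seed: int = 0, n_replicates: int = 20,
                         n_samples: int = 20, background_rate: float = 5.0,
                         n_perm: int = 500) -> dict:
    """Mean fraction of probes inside significant MCRs on null cohorts
    (random background alterations only)."""
    ann = _mcr_annotation()
    cfg = RunConfig(mcr_n_perm=n_perm)
    fractions = []
    for rep in range(n_replicates):
        s = seed + 1000 * (rep + 1)
        cohort, _ = simulate_cohort(n_samples, ann,
                                    background_rate=background_rate,
                                    seed=s)
        segs = segment_cohort(cohort, ann, cfg, seed=s)
        covered = np.zeros(len(ann), dtype=bool)
        for direction in ("gain", "loss"):
            mcrs = mcr_permutation_test(segs, ann, direction, n_perm=n_perm,
                                        alpha=cfg.mcr_alpha, seed=s,
                                        p_mode=cfg.mcr_p_mode)
            for r in mcrs.itertuples():
                sl = (ann["chrom"].to_numpy() == r.chrom) \
                    & (ann["pos"].to_numpy() >= r.start_bp) \
                    & (ann["pos"].to_numpy() < r.end_bp)
                covered |= sl
        fractions.append(covered.mean())
    return {"probe_fraction": float(np.mean(fractions)),
            "n_replicates": n_replicates}


#: fixed location of the shared lesion in the power study (chr8, 5 Mb)
_POWER_EVENT = CNEvent("8", 100_000_000, 105_000_000, 3, 1)


def mcr_power(seed: int = 0, n_replicates: int = 20, n_samples: int = 20,
              penetrance: float = 0.6, background_rate: float = 5.0,
              n_perm: int = 500) -> dict:
    """Fraction of replicate cohorts in which a gain-MCR overlaps a shared
    5 Mb gain planted at the given penetrance."""
    ann = _mcr_annotation()
    cfg = RunConfig(mcr_n_perm=n_perm)
    hits = 0
    for rep in range(n_replicates):
        s = seed + 1000 * (rep + 1)
        cohort, _ = simulate_cohort(n_samples, ann,
                                    shared_events=[_POWER_EVENT],
                                    penetrance=penetrance,
                                    background_rate=background_rate,
                                    seed=s)
        segs = segment_cohort(cohort, ann, cfg, seed=s)
        mcrs = mcr_permutation_test(segs, ann, "gain", n_perm=n_perm,
                                    alpha=cfg.mcr_alpha, seed=s,
                                    p_mode=cfg.mcr_p_mode)
        overlapping = mcrs[(mcrs["chrom"] == _POWER_EVENT.chrom)
                           & (mcrs["start_bp"] < _POWER_EVENT.end)
                           & (mcrs["end_bp"] > _POWER_EVENT.start)]
        hits += int(len(overlapping) > 0)
    return {"power": hits / n_replicates, "n_replicates": n_replicates}


def ranksum_exact_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p by full enumeration of rank assignments.

    Independent oracle for the exact path of group_association: enumerates
    all C(n1+n2, n1) assignments of the pooled ranks (assumes no ties).
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    obs = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for combo in combinations(range(len(pooled)), n1):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / total


def ranksum_oracle_check(seed: int = 0, n_cases: int = 20,
                         max_group: int = 8) -> dict:
    """Max |exact rank-sum p - enumeration p| over random tie-free cases."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        n1 = int(rng.integers(2, max_group + 1))
        n2 = int(rng.integers(2, max_group + 1))
        vals = rng.permutation(np.arange(1, n1 + n2 + 1)).astype(float)
        a, b = vals[:n1], vals[n1:]
        p_impl, _, _ = group_association(
            np.concatenate([a, b]),
            np.array(["a"] * n1 + ["b"] * n2))
        p_oracle = ranksum_exact_oracle(a, b)
        worst = max(worst, abs(p_impl - p_oracle))
    return {"max_abs_diff": worst, "n_cases": n_cases}


def chi2_hand_formula(table: np.ndarray) -> float:
    """Chi-square statistic from the textbook formula sum (O-E)^2 / E."""
    table = np.asarray(table, float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def chi2_oracle_check(seed: int = 0, n_cases: int = 50) -> dict:
    """Max |implementation chi2 - hand formula| over random 2x2 tables."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        n_a, n_b = rng.integers(5, 200, size=2)
        m_a = int(rng.integers(1, n_a))
        m_b = int(rng.integers(1, n_b))
        stat, _ = frequency_chi2(m_a, int(n_a), m_b, int(n_b))
        oracle = chi2_hand_formula([[m_a, n_a - m_a], [m_b, n_b - m_b]])
        worst = max(worst, abs(stat - oracle))
    return {"max_abs_diff": worst, "n_cases": n_cases}


def classifier_recovery(seed: int = 0, n_samples: int = 200,
                        noise_fraction: float = 0.25) -> dict:
    """Nearest-centroid assignment recovery on simulated expression.

    At sd=0 samples equal their centroids (correlation 1, perfect
    assignment); the noisy run uses sd = noise_fraction * centroid spread.
    """
    centroids = make_demo_centroids(seed=seed)
    classes = list(centroids.columns)
    assignment = {f"E{i:03d}": classes[i % len(classes)]
                  for i in range(n_samples)}
    spread = float(centroids.to_numpy().std())

    out = {}
    for label, sd in (("sd0", 0.0), ("noisy", noise_fraction * spread)):
        expr = simulate_expression(centroids, assignment, sd, seed=seed + 1)
        res = classify_by_centroids(expr, centroids).set_index("sample")
        correct = np.mean([res.at[s, "assigned"] == cls
                           for s, cls in assignment.items()])
        out[f"accuracy_{label}"] = float(correct)
        if sd == 0:
            out["min_self_correlation_sd0"] = float(min(
                res.at[s, cls] for s, cls in assignment.items()))
    out["n_samples"] = n_samples
    return out
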