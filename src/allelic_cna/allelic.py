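"""Probe-level allelic state, gene status, and uniparental disomy (UPD).

LOH at a probe: a homozygous genotype call with BAF at 0/1 and a decline in
the containing segment's LogR. Homozygous deletion (HD): a no-call genotype
with "abnormal" BAF (far from all of 0, 0.5, 1 — no allele present, the
signal is noise) and a strong LogR decline.

UPD is copy-neutral (or amplified) LOH: runs of probes with absent
heterozygosity whose rolling-mean LogR stays around 0. Detection is
seed-and-extend: windows with heterozygous-call fraction <= het_max and
rolling LogR above the deletion band seed a run, which is then extended
outward over individually LOH-consistent probes; runs shorter than a
minimum size are discarded. Events are classified into six categories
(whole chromosome, whole arm, focal, focal with segmental duplication,
UPD with segmental amplification, near-whole chromosome with focal
deletion).
"""
from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import arm_index_ranges, chrom_slices
from .model import RunConfig, UPD_CATEGORIES

log = logging.getLogger("allelic_cna")

UPD_COLUMNS = ["sample", "chrom", "start_bp", "end_bp", "start_index",
               "end_index", "n_probes", "mean_logR"]


def _segment_mean_by_probe(segments: pd.DataFrame, n_probes: int) -> np.ndarray:
    out = np.full(n_probes, np.nan)
    for _, r in segments.iterrows():
        out[r["start_index"]:r["end_index"]] = r["mean_logR"]
    return out


def call_allelic_state(
    signals: pd.DataFrame,
    segments: pd.DataFrame,
    annotation: pd.DataFrame,
    config: Optional[RunConfig] = None,
) -> np.ndarray:
    """Per-probe allelic state in {normal, LOH, HD} (annotation order)."""
    cfg = config or RunConfig()
    gt = signals["genotype"].to_numpy()
    baf = signals["baf"].to_numpy(float)
    seg_mean = _segment_mean_by_probe(segments, len(annotation))

    with np.errstate(invalid="ignore"):
        hom_baf = np.fmin(baf, 1 - baf) <= cfg.baf_hom_tol
        abnormal = np.fmin(np.fmin(np.abs(baf), np.abs(baf - 0.5)),
                           np.abs(baf - 1)) > cfg.baf_abnormal_dist
    loh = (np.isin(gt, ("AA", "BB")) & hom_baf
           & (seg_mean <= -cfg.loh_logR_decline))
    hd = (gt == "NC") & abnormal & (seg_mean <= cfg.hd_logR)

    state = np.full(len(annotation), "normal", dtype=object)
    state[loh] = "LOH"
    state[hd] = "HD"
    return state


def _rolling(values: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling mean ignoring NaN, normalized by valid counts."""
    v = np.nan_to_num(values, nan=0.0)
    ok = np.isfinite(values).astype(float)
    kernel = np.ones(window)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(ok, kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def detect_upd(
    signals: pd.DataFrame,
    annotation: pd.DataFrame,
    config: Optional[RunConfig] = None,
    *,
    sample: str = "sample",
) -> pd.DataFrame:
    """Detect copy-neutral (or amplified) LOH runs — candidate UPD events.

    Works on informative probes (genotype called): a probe seeds a run when
    the heterozygous-call fraction in its ``upd_window``-probe window is
    <= ``upd_het_max`` and the window's rolling-mean LogR is above
    ``-upd_logR_zero_tol`` (around 0, or above for amplified UPD). Seed runs
    are extended over consecutive non-heterozygous probes whose rolling LogR
    stays above the band, then filtered to >= ``upd_min_size_mb``.
    """
    cfg = config or RunConfig()
    gt = signals["genotype"].to_numpy()
    logR = signals["logR"].to_numpy(float)
    pos = annotation["pos"].to_numpy()

    events = []
    for chrom, sl in chrom_slices(annotation).items():
        g = gt[sl]
        inf_local = np.flatnonzero(g != "NC")
        if len(inf_local) == 0:
            continue
        n_inf = len(inf_local)
        w = cfg.upd_window
        if w > n_inf:
            log.warning("UPD window %d exceeds %d informative probes on "
                        "chromosome %s; clamped", w, n_inf, chrom)
            w = n_inf
        het = (g[inf_local] == "AB").astype(float)
        lr = logR[sl][inf_local]
        het_frac = _rolling(het, w)
        roll_lr = _rolling(lr, w)
        ok_lr = roll_lr >= -cfg.upd_logR_zero_tol
        seed = (het_frac <= cfg.upd_het_max) & ok_lr
        extendable = (het == 0) & ok_lr

        for lo, hi in _runs(seed):
            while lo > 0 and extendable[lo - 1]:
                lo -= 1
            while hi < n_inf and extendable[hi]:
                hi += 1
            events.append((chrom, sl, inf_local, lo, hi, lr))

    rows = []
    # merge overlapping extended runs per chromosome, then measure/filter
    by_chrom: dict[str, list] = {}
    for ev in events:
        by_chrom.setdefault(ev[0], []).append(ev)
    for chrom, evs in by_chrom.items():
        sl, inf_local, lr = evs[0][1], evs[0][2], evs[0][5]
        spans = sorted((lo, hi) for _, _, _, lo, hi, _ in evs)
        fused: list[list[int]] = []
        for lo, hi in spans:
            if fused and lo <= fused[-1][1]:
                fused[-1][1] = max(fused[-1][1], hi)
            else:
                fused.append([lo, hi])
        for lo, hi in fused:
            gi = inf_local[lo:hi] + sl.start  # global probe indices
            start_bp = int(pos[gi[0]])
            end_bp = int(pos[gi[-1]]) + 1
            if (end_bp - start_bp) < cfg.upd_min_size_mb * 1e6:
                continue
            mean_lr = float(np.nanmean(lr[lo:hi]))
            if not mean_lr >= -cfg.upd_logR_zero_tol:
                continue
            rows.append((sample, chrom, start_bp, end_bp, int(gi[0]),
                         int(gi[-1]) + 1, hi - lo, mean_lr))
    return pd.DataFrame(rows, columns=UPD_COLUMNS)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [lo, hi) runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def classify_upd(
    events: pd.DataFrame,
    segments: pd.DataFrame,
    annotation: pd.DataFrame,
    config: Optional[RunConfig] = None,
) -> pd.DataFrame:
    """Assign each UPD event one of the six categories.

    Order of precedence: whole chromosome (1) when both arms are covered and
    no deletion overlaps the run; whole arm (2); amplified UPD (5) when the
    run overlaps a +2 segment; focal with duplication (4) when focal over a
    +1 segment; near-whole chromosome with a combined focal deletion (6);
    focal (3) otherwise.
    """
    cfg = config or RunConfig()
    arms = arm_index_ranges(annotation)
    sls = chrom_slices(annotation)
    cats = []
    for _, ev in events.iterrows():
        chrom = ev["chrom"]
        lo, hi = ev["start_index"], ev["end_index"]
        segs = segments[segments["chrom"] == chrom]
        over = segs[(segs["start_index"] < hi) & (segs["end_index"] > lo)]
        cov = {}
        for arm in ("p", "q"):
            sl = arms.get((chrom, arm))
            n_arm = (sl.stop - sl.start) if sl else 0
            cov[arm] = (max(0, min(hi, sl.stop) - max(lo, sl.start)) / n_arm
                        if n_arm else 1.0)
        csl = sls[chrom]
        chrom_cov = (hi - lo) / (csl.stop - csl.start)
        has_del_in_run = (over["call"] == -1).any()
        full_arms = sum(cov[a] >= cfg.arm_fraction for a in ("p", "q"))
        # a deletion segment inside or adjacent to the run; adjacency allows
        # one detection window of slack because rolling statistics trim the
        # run boundary by up to half a window next to a deletion
        w = cfg.upd_window
        adj = segs[(segs["call"] == -1) & (segs["start_index"] <= hi + w)
                   & (segs["end_index"] >= lo - w)]
        if full_arms == 2 and not has_del_in_run:
            cats.append(1)
        elif full_arms == 1 and chrom_cov < cfg.upd_near_whole:
            cats.append(2)
        elif (over["call"] == 2).any():
            cats.append(5)
        elif full_arms == 0 and (over["call"] == 1).any():
            cats.append(4)
        elif chrom_cov >= cfg.upd_near_whole and len(adj):
            cats.append(6)
        else:
            cats.append(3)
    out = events.copy()
    out["category"] = cats
    out["category_label"] = [UPD_CATEGORIES[c] for c in cats]
    return out


def gene_status(
    gene_probes: Mapping[str, Sequence[str]],
    allelic_states: np.ndarray,
    segments: pd.DataFrame,
    annotation: pd.DataFrame,
    min_probe_support: int = 2,
) -> pd.DataFrame:
    """Aggregate probe-level states and segment calls into gene status.

    HD wins with >= min_probe_support HD probes, then LOH likewise; else the
    majority segment call over the gene's probes maps to
    amplification/gain/loss/neutral.
    """
    index_of = {p: i for i, p in enumerate(annotation["probe_id"])}
    call_by_probe = np.zeros(len(annotation), dtype=int)
    for _, r in segments.iterrows():
        call_by_probe[r["start_index"]:r["end_index"]] = r["call"]
    rows = []
    for gene, probes in gene_probes.items():
        idx = [index_of[p] for p in probes if p in index_of]
        if not idx:
            log.warning("gene %s has no probes in the annotation; "
                        "status missing", gene)
            rows.append((gene, None, 0))
            continue
        states = allelic_states[idx]
        n_hd = int((states == "HD").sum())
        n_loh = int((states == "LOH").sum())
        if n_hd >= min_probe_support:
            rows.append((gene, "HD", n_hd))
        elif n_loh >= min_probe_support:
            rows.append((gene, "LOH", n_loh))
        else:
            calls = call_by_probe[idx]
            vals, counts = np.unique(calls, return_counts=True)
            major = int(vals[np.argmax(counts)])
            label = {2: "amplification", 1: "gain", -1: "loss",
                     0: "neutral"}[major]
            rows.append((gene, label, int(counts.max())))
    return pd.DataFrame(rows, columns=["gene", "status", "n_probes_support"])


def upd_summary(events: pd.DataFrame,
                samples: Sequence[str]) -> tuple[pd.DataFrame, float]:
    """Per-sample UPD counts and genome size, plus the cohort median count."""
    rows = []
    for s in samples:
        ev = events[events["sample"] == s] if len(events) else events
        n = len(ev)
        bp = int((ev["end_bp"] - ev["start_bp"]).sum()) if n else 0
        rows.append((s, n, bp))
    out = pd.DataFrame(rows, columns=["sample", "n_events", "bp_in_upd"])
    median = float(np.median(out["n_events"])) if len(out) else 0.0
    return out, median
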