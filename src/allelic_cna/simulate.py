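"""Synthetic allele-specific SNP-array cohorts with planted truth.

The generator emulates Illumina-style per-probe signals: LogR ratio (log2 of
sample vs reference intensity, 0 for two copies), B-allele frequency (BAF;
b/c for b of c copies carrying the B allele) and a genotype call derived from
the noisy BAF the way array software would call it. Events are planted as
(total copies, minor-allele copies) intervals: total=2/minor=0 is
copy-neutral LOH (UPD), total=0 a homozygous deletion whose BAF is uniform
noise and whose LogR saturates around -3 rather than diverging.

Every entry point requires an explicit seed; identical seeds give identical
output.
"""
from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import chrom_extent_bp, chrom_slices, arm_index_ranges
from .model import CNEvent, EventPlan, NoiseModel
from .preprocess import call_genotypes

log = logging.getLogger("allelic_cna")

#: LogR level a zero-copy (homozygously deleted) probe saturates at
HD_LOGR_LEVEL = -3.0

TRUTH_COLUMNS = ["sample", "chrom", "start", "end",
                 "total_copies", "minor_copies", "scope"]


def _rng(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("a seed is required: simulations must be reproducible")
    return np.random.default_rng(seed)


def simulate_sample(
    plan: EventPlan,
    annotation: pd.DataFrame,
    noise: NoiseModel = NoiseModel(),
    *,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    sex: str = "female",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one sample's probe signals given a plan of planted events.

    Returns ``(signals, truth)``: signals with columns ``probe_id, logR, baf,
    genotype`` in annotation order, truth with one row per planted event.
    LogR is expressed relative to the sex-appropriate baseline copy number of
    each chromosome (2 for autosomes; X/Y per ``sex``).
    """
    if rng is None:
        rng = _rng(seed)
    chrom = annotation["chrom"].to_numpy()
    pos = annotation["pos"].to_numpy()
    n = len(annotation)
    extents = chrom_extent_bp(annotation)

    baseline = np.full(n, 2, dtype=np.int64)
    if sex == "male":
        baseline[chrom == "X"] = 1
        baseline[chrom == "Y"] = 1
    else:
        baseline[chrom == "Y"] = 0

    # haplotype copy numbers; events rewrite them over their interval
    hapA = np.where(baseline >= 2, 1, np.where(baseline == 1, 1, 0))
    hapB_hap = baseline - hapA  # second haplotype present only at baseline 2
    hap = np.stack([hapA, hapB_hap])  # (2, n)

    for ev in plan.events:
        if ev.chrom not in extents:
            raise ValueError(f"event on unannotated chromosome {ev.chrom!r}")
        if ev.start < 0 or ev.end > extents[ev.chrom]:
            raise ValueError(
                f"event {ev.chrom}:{ev.start}-{ev.end} outside chromosome "
                f"extent {extents[ev.chrom]}")
        mask = (chrom == ev.chrom) & (pos >= ev.start) & (pos < ev.end)
        keep = int(rng.integers(2))  # which parental haplotype is retained/major
        hap[keep, mask] = ev.total_copies - ev.minor_copies
        hap[1 - keep, mask] = ev.minor_copies

    total = hap.sum(axis=0)

    # true genotype at baseline: heterozygous with the stated fraction where
    # two haplotypes exist; hemizygous/absent loci cannot be heterozygous
    is_het = rng.random(n) < noise.heterozygous_fraction
    is_het &= baseline == 2
    b_on_hap = rng.integers(2, size=n)           # phase of the B allele if het
    hom_b = rng.integers(2, size=n).astype(bool)  # BB vs AA if homozygous

    b_copies = np.where(
        is_het, hap[(b_on_hap, np.arange(n))], np.where(hom_b, total, 0))

    with np.errstate(divide="ignore", invalid="ignore"):
        exp_baf = np.where(total > 0, b_copies / np.maximum(total, 1), np.nan)
        denom = np.where(baseline > 0, baseline, 2)  # female Y: reads deleted anyway
        exp_logR = np.where(total > 0, np.log2(np.maximum(total, 1) / denom),
                            HD_LOGR_LEVEL)

    logR = exp_logR + (rng.normal(0.0, noise.logR_sd, n) if noise.logR_sd > 0 else 0.0)
    baf = np.where(
        total > 0,
        np.clip(exp_baf + (rng.normal(0.0, noise.baf_sd, n) if noise.baf_sd > 0 else 0.0),
                0.0, 1.0),
        rng.random(n),
    )
    genotype = call_genotypes(baf)

    if noise.probe_dropout_rate > 0:
        drop = rng.random(n) < noise.probe_dropout_rate
        logR = np.where(drop, np.nan, logR)
        baf = np.where(drop, np.nan, baf)
        genotype = np.where(drop, "NC", genotype)

    signals = pd.DataFrame({
        "probe_id": annotation["probe_id"].to_numpy(),
        "logR": logR, "baf": baf, "genotype": genotype,
    })
    truth = pd.DataFrame(
        [(plan.sample, ev.chrom, ev.start, ev.end, ev.total_copies,
          ev.minor_copies, ev.scope_hint) for ev in plan.events],
        columns=TRUTH_COLUMNS,
    )
    return signals, truth


def simulate_cohort(
    n_samples: int,
    annotation: pd.DataFrame,
    *,
    shared_events: Sequence[CNEvent] = (),
    penetrance: float = 1.0,
    background_rate: float = 0.0,
    background_copies: Sequence[int] = (1, 3),
    noise: NoiseModel = NoiseModel(),
    seed: Optional[int] = None,
    sample_prefix: str = "S",
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate a cohort with an optional shared event and random background.

    The shared events are planted in ``round(penetrance * n_samples)`` samples
    (chosen at random); background events, ``Poisson(background_rate)`` per
    sample, are placed uniformly with sizes log-uniform between 1 Mb and the
    containing arm, never overlapping the shared events.
    """
    if n_samples < 2:
        raise ValueError("a cohort needs n_samples >= 2")
    if shared_events and not 0 < penetrance <= 1:
        raise ValueError("penetrance must be in (0, 1]")
    rng = _rng(seed)
    samples = [f"{sample_prefix}{i:03d}" for i in range(n_samples)]
    n_carriers = int(round(penetrance * n_samples)) if shared_events else 0
    carriers = set(rng.choice(n_samples, size=n_carriers, replace=False).tolist())

    arms = arm_index_ranges(annotation)
    pos = annotation["pos"].to_numpy()
    chrom_arr = annotation["chrom"].to_numpy()
    extents = chrom_extent_bp(annotation)
    arm_bp: list[tuple[str, int, int]] = []
    for (c, a), sl in arms.items():
        if sl.stop > sl.start:
            lo = int(pos[sl.start])
            hi = int(pos[sl.stop - 1]) + 1
            arm_bp.append((c, lo, hi))
    weights = np.array([hi - lo for _, lo, hi in arm_bp], dtype=float)
    weights /= weights.sum()

    cohort: dict[str, pd.DataFrame] = {}
    truths: list[pd.DataFrame] = []
    for i, name in enumerate(samples):
        events: list[CNEvent] = list(shared_events) if i in carriers else []
        n_bg = rng.poisson(background_rate) if background_rate > 0 else 0
        for _ in range(n_bg):
            ev = _place_background(rng, arm_bp, weights, events,
                                   background_copies, extents)
            if ev is not None:
                events.append(ev)
        plan = EventPlan(name, tuple(events))
        sig, truth = simulate_sample(plan, annotation, noise, rng=rng)
        truth["sample"] = name
        cohort[name] = sig
        truths.append(truth)
    truth_all = (pd.concat(truths, ignore_index=True)
                 if truths else pd.DataFrame(columns=TRUTH_COLUMNS))
    return cohort, truth_all


def _place_background(rng, arm_bp, weights, existing, copies_choices, extents,
                      max_tries: int = 100) -> Optional[CNEvent]:
    for _ in range(max_tries):
        k = rng.choice(len(arm_bp), p=weights)
        c, lo, hi = arm_bp[k]
        arm_len = hi - lo
        if arm_len <= 1_000_000:
            continue
        size = int(np.exp(rng.uniform(np.log(1e6), np.log(arm_len))))
        start = int(rng.integers(lo, hi - size + 1))
        end = min(start + size, extents[c])
        if any(e.chrom == c and start < e.end and e.start < end for e in existing):
            continue
        total = int(rng.choice(list(copies_choices)))
        minor = 0 if total <= 1 else 1
        return CNEvent(c, start, end, total, minor)
    log.warning("could not place a background event without overlap; skipped")
    return None


def simulate_expression(
    centroids: pd.DataFrame,
    assignment: Mapping[str, str],
    sd: float,
    *,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Draw a gene x sample expression matrix: class centroid + N(0, sd)."""
    rng = _rng(seed)
    if centroids.shape[1] < 2 or centroids.shape[0] < 10:
        raise ValueError("centroid matrix needs >= 2 classes and >= 10 genes")
    classes = list(centroids.columns)
    for a in range(len(classes)):
        for b in range(a + 1, len(classes)):
            if np.allclose(centroids.iloc[:, a], centroids.iloc[:, b]):
                warnings.warn(
                    f"centroids {classes[a]!r} and {classes[b]!r} are "
                    "identical; classification between them is a tie")
    unknown = set(assignment.values()) - set(classes)
    if unknown:
        raise ValueError(f"assignment references unknown classes: {sorted(unknown)}")
    cols = {}
    for sample, cls in assignment.items():
        base = centroids[cls].to_numpy(float)
        cols[sample] = base + (rng.normal(0.0, sd, len(base)) if sd > 0 else 0.0)
    return pd.DataFrame(cols, index=centroids.index)


def make_demo_centroids(
    n_genes: int = 200,
    classes: Sequence[str] = ("urobasal_a", "genomically_unstable",
                              "urobasal_b", "scc_like"),
    *,
    seed: Optional[int] = None,
    spread: float = 1.0,
) -> pd.DataFrame:
    """Synthetic expression centroids (stand-ins for published signature
    centroids, which are not redistributable with this package)."""
    rng = _rng(seed)
    mat = rng.normal(0.0, spread, size=(n_genes, len(classes)))
    genes = [f"G{i:04d}" for i in range(n_genes)]
    return pd.DataFrame(mat, index=genes, columns=list(classes))
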