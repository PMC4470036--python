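"""Domain types and run configuration.

Tabular objects (probe annotation, probe signals, segments, events) are plain
pandas DataFrames with documented column schemas; small structured values are
dataclasses. Coordinates are 0-based half-open throughout; chromosome labels
are "1".."22", "X", "Y" without a "chr" prefix.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

#: canonical chromosome ordering used for sorting and indexing
CHROMOSOMES = [str(c) for c in range(1, 23)] + ["X", "Y"]
CHROM_ORDER = {c: i for i, c in enumerate(CHROMOSOMES)}

#: genotype codes; NC = no call
GENOTYPES = ("AA", "AB", "BB", "NC")

#: categorical copy-number calls
CALL_LOSS, CALL_NEUTRAL, CALL_GAIN, CALL_AMP = -1, 0, 1, 2

#: UPD event categories
UPD_CATEGORIES = {
    1: "whole_chromosome",
    2: "whole_arm",
    3: "focal",
    4: "focal_with_segmental_duplication",
    5: "upd_with_segmental_amplification",
    6: "near_whole_chromosome_with_focal_deletion",
}

ANNOTATION_COLUMNS = ["probe_id", "chrom", "pos", "arm", "cytoband"]
SIGNAL_COLUMNS = ["probe_id", "logR", "baf", "genotype"]
SEGMENT_COLUMNS = [
    "sample", "chrom", "start_index", "end_index", "start_bp", "end_bp",
    "n_probes", "mean_logR", "call",
]


def normalize_chrom(label: str) -> str:
    """Strip any "chr" prefix and validate against the canonical label set."""
    c = str(label)
    if c.lower().startswith("chr"):
        c = c[3:]
    if c == "23":
        c = "X"
    if c not in CHROM_ORDER:
        raise ValueError(f"unknown chromosome label: {label!r}")
    return c


@dataclass(frozen=True)
class NoiseModel:
    """Array noise model for the simulator.

    logR_sd      per-probe LogR standard deviation (log2 units)
    baf_sd       per-probe BAF standard deviation around the allelic mean
    probe_dropout_rate  fraction of probes with missing measurements
    heterozygous_fraction  population heterozygosity per SNP
    """
    logR_sd: float = 0.15
    baf_sd: float = 0.03
    probe_dropout_rate: float = 0.005
    heterozygous_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.logR_sd < 0 or self.baf_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0 <= self.probe_dropout_rate < 1:
            raise ValueError("probe_dropout_rate must be in [0, 1)")
        if not 0 < self.heterozygous_fraction < 1:
            raise ValueError("heterozygous_fraction must be in (0, 1)")


@dataclass(frozen=True)
class CNEvent:
    """A planted copy-number / allelic event on one chromosome.

    total_copies is the total copy number over the interval;
    minor_copies the copy number of the less-represented parental allele
    (minor <= total/2). total=2, minor=0 encodes copy-neutral LOH (UPD);
    total=0 a homozygous deletion.
    """
    chrom: str
    start: int
    end: int
    total_copies: int
    minor_copies: int = 0
    scope_hint: str = "focal"  # whole_chromosome | whole_arm | focal

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"event end <= start: {self}")
        if self.total_copies < 0 or self.minor_copies < 0:
            raise ValueError("copy numbers must be >= 0")
        if self.total_copies == 0 and self.minor_copies != 0:
            raise ValueError("homozygous deletion (total=0) requires minor=0")
        if self.minor_copies * 2 > self.total_copies:
            raise ValueError("minor allele copies must be <= total/2")


@dataclass(frozen=True)
class EventPlan:
    """All events planted in one simulated sample."""
    sample: str
    events: tuple[CNEvent, ...] = ()

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[CNEvent]] = {}
        for ev in self.events:
            by_chrom.setdefault(ev.chrom, []).append(ev)
        for chrom, evs in by_chrom.items():
            evs = sorted(evs, key=lambda e: e.start)
            for a, b in zip(evs, evs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping events on chromosome {chrom} in sample "
                        f"{self.sample}: {a} / {b}"
                    )


@dataclass(frozen=True)
class SampleSex:
    sample: str
    sex: str  # male | female | unknown
    y_evidence: float  # mean Y-probe logR against the mixed pool


@dataclass
class RunConfig:
    """All tunable analysis parameters, with the package defaults.

    Every threshold is config-exposed; the seed is recorded in output headers.
    The genome build is a label only — no stage assumes a build.
    """
    seed: int = 0
    genome_build: str = "unspecified"

    # genotype calling from BAF
    hom_window: float = 0.05
    het_window: float = 0.15

    # sex inference
    y_presence_threshold: float = -1.0

    # segmentation (CBS)
    cbs_alpha: float = 0.01
    cbs_min_probes: int = 5
    cbs_n_perm: int = 1000

    # categorical calling
    loss_threshold: float = -0.3
    gain_threshold: float = 0.3
    amp_threshold: float = 1.3219280948873623  # log2(5/2): >=5 copies

    # scope classification
    arm_fraction: float = 0.9

    # allelic state / UPD
    baf_hom_tol: float = 0.05
    loh_logR_decline: float = 0.1
    hd_logR: float = -1.0
    baf_abnormal_dist: float = 0.1
    upd_window: int = 50
    upd_het_max: float = 0.02
    upd_logR_zero_tol: float = 0.15
    upd_min_size_mb: float = 2.0
    upd_near_whole: float = 0.8

    # recurrence
    mcr_n_perm: int = 500
    mcr_alpha: float = 0.05
    mcr_null_scope: str = "genome"  # genome | chromosome
    mcr_p_mode: str = "pooled"      # pooled | per_probe
    amp_min_samples: int = 3

    # gene-level status
    min_probe_support: int = 2

    # statistics
    chi2_yates: bool = False

    def validate(self) -> "RunConfig":
        if not 0 < self.hom_window < self.het_window:
            raise ValueError("require 0 < hom_window < het_window")
        if self.het_window >= 0.5:
            raise ValueError("het_window must be < 0.5 (windows must not overlap)")
        if not self.loss_threshold < 0 < self.gain_threshold < self.amp_threshold:
            raise ValueError("require loss_t < 0 < gain_t < amp_t")
        if not 0 < self.cbs_alpha < 1 or not 0 < self.mcr_alpha < 1:
            raise ValueError("significance levels must be in (0, 1)")
        if not 0 < self.arm_fraction <= 1:
            raise ValueError("arm_fraction must be in (0, 1]")
        if self.mcr_null_scope not in ("genome", "chromosome"):
            raise ValueError("mcr_null_scope must be 'genome' or 'chromosome'")
        if self.mcr_p_mode not in ("pooled", "per_probe"):
            raise ValueError("mcr_p_mode must be 'pooled' or 'per_probe'")
        return self

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw).validate()
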