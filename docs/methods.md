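# Methods

This note documents the models and procedures implemented in `allelic_cna`,
the parameters that matter, and the choices made where the design was open.

## Signal model and simulator

The package analyzes allele-specific SNP-array signals. Each probe carries a
**LogR ratio** — log2 of the sample's intensity over a reference pool's mean,
so two copies read ~0, c copies read ~log2(c/2) — and a **B-allele frequency
(BAF)**: with b of c copies carrying the B allele, BAF clusters at b/c
(0/0.5/1 for diploid AA/AB/BB). Genotypes are called from BAF with threshold
windows (AA for BAF ≤ `hom_window` = 0.05, BB symmetric, AB for
|BAF − 0.5| ≤ `het_window` = 0.15, NC otherwise).

The simulator (`allelic_cna.simulate`) plants events as intervals with a
(total copies, minor-allele copies) pair on a per-probe haplotype model:

- each SNP is heterozygous with probability `heterozygous_fraction`
  (default 0.3, a typical array heterozygosity);
- an event rewrites the two haplotype copy numbers to
  (total − minor, minor), with the retained/amplified haplotype chosen at
  random per event, so heterozygous loci inside copy-neutral LOH
  (total = 2, minor = 0) collapse coherently to BAF 0/1;
- LogR noise is Gaussian (`logR_sd` = 0.15), BAF noise Gaussian clipped to
  [0, 1] (`baf_sd` = 0.03), and a small dropout rate (0.005) marks probes
  missing;
- homozygous deletions (total = 0) emit BAF uniform on [0, 1] — with no
  allele present the signal is noise — and LogR around −3 rather than −∞,
  because arrays saturate;
- genotypes are called from the noisy BAF, as array software would.

With the default windows and `baf_sd` = 0.03, a homozygous probe misses its
window with one-tailed probability ~4.8%, giving an overall no-call rate of
~3%; this is the analytically correct behaviour of the stated defaults and
the property tests assert it as such.

The synthetic probe manifests are desk-scale: the default is 20,000 equally
spaced probes over the 22 autosomes (+X on request) with sizes proportional
to the human chromosomes and the p/q boundary at 40% of each chromosome.
What the simulator does **not** emulate: real probe spacing heterogeneity,
GC waves, tumor subclonality and stromal contamination (cell lines are
near-pure, which is also why threshold calling is adequate), linkage
structure of genotypes, and batch effects. Passing the recovery studies
therefore demonstrates correctness of the algorithms under the stated noise
model, not performance on raw array data.

## Preprocessing

Raw R intensities are normalized by **multiplicative median scaling**: the
sample is rescaled so its autosomal median matches the reference pool's
median autosomal mean intensity. This deliberately simple normalization is
clearly labelled; downstream stages depend only on LogR being centred at 0
for two copies. LogR = log2(R / mean_R) against the pool; probes with
missing R or non-positive pool means are flagged missing.

Sex handling: presence of a Y chromosome is treated as reliable evidence of
male origin — the mean Y-probe LogR against the mixed pool above
`y_presence_threshold` (default −1.0) calls a male, and this evidence wins
over conflicting metadata (logged). A male's one-copy Y reads ~+0.9 against
the mixed pool (whose Y level averages the male one-copy level with female
background) while an absent Y reads ~−2, so the default threshold separates
the two by many noise standard deviations. X-chromosome LogR is computed
against the sex-matched pool; without Y probes or metadata the X is skipped
with a warning.

## Segmentation and calling

Segmentation is circular binary segmentation: within a segment the
candidate change is the arc [i, j) maximizing
|mean_arc − mean_complement| / √(1/w + 1/(n−w)); the common noise scale
cancels against the permutation null. The candidate is accepted when its
permutation p-value (values shuffled within the segment) is below
`cbs_alpha` (default 0.01, `cbs_n_perm` = 1000, `cbs_min_probes` = 5);
an interior arc contributes both edges (double split), an edge-anchored arc
one, and the algorithm recurses.

Numerical choices:

- the arc scan runs over a geometric width grid (factor 1.5) for speed; the
  winning arc's edges are then refined by exact coordinate ascent, so
  breakpoint locations are exact while the significance decision uses the
  same grid statistic for observed and permuted data;
- the permutation test stops early in both directions: reject as soon as
  the exceedance count forces p ≥ alpha, accept once 200 permutations have
  passed without one exceedance (an adaptive sequential test; the decision
  is deterministic given the seed);
- ties in the arc argmax resolve to the leftmost position; short-segment
  merging (when invoked) joins a fragment to the more similar neighbour,
  ties toward the left;
- missing values are dropped with index bookkeeping and breakpoints are
  reported in the original probe index space.

Calls are thresholds on segment mean LogR: loss ≤ −0.3, gain ≥ 0.3,
amplification ≥ log2(5/2) ≈ 1.32 (amplification defined as ≥5 copies), else
neutral. The ±0.3 defaults are conventional for near-pure cell-line
material, where discrete copy levels are separable; no ploidy correction is
applied. Alterations are classed whole-chromosome / whole-arm / focal by
arm probe coverage at `arm_fraction` = 0.9.

On null series the split test controls false breakpoints tightly; the
frozen regression bound in the test suite is ≤1 breakpoint on a
10,000-probe pure-noise series.

## Allelic states and UPD

Probe-level states: **LOH** requires a homozygous call with
min(BAF, 1−BAF) ≤ 0.05 and the containing segment's mean LogR ≤ −0.1 (the
"decline" quantified; config-exposed); **HD** requires a no-call genotype,
BAF further than 0.1 from all of {0, 0.5, 1} ("abnormal"), and segment mean
LogR ≤ −1.0.

UPD — copy-neutral or amplified LOH — is detected per chromosome on
informative (called) probes by seed-and-extend: a probe seeds a run when
its `upd_window` (50-probe) window has heterozygous-call fraction ≤ 0.02
and rolling-mean LogR ≥ −`upd_logR_zero_tol` (0.15; "around 0, or above"
admits amplified UPD while excluding hemizygous loss at −1). Seeds are
extended over consecutive non-heterozygous probes while the rolling LogR
stays above the band, overlapping runs merge, and runs shorter than
`upd_min_size_mb` (2 Mb) are discarded — 2 Mb matching the smallest focal
UPD scale the method is designed to report. Every emitted event satisfies
mean LogR ≥ −tolerance by construction. With a 30% het rate, a false seed
needs ≥49 consecutive non-het probes (probability ~10⁻⁸ per locus) and must
then survive the size filter, which makes the detector's null rate
effectively zero at default settings.

Events are classified into six categories by arm coverage
(`arm_fraction` = 0.9) and the copy-number segments they touch:
(1) whole chromosome, (2) whole arm, (3) focal, (4) focal over a +1
duplication, (5) over a +2 amplification, (6) near-whole chromosome
(coverage ≥ `upd_near_whole` = 0.8) with a focal deletion inside or
adjacent to the run. Two interpretation choices are documented here because
the category definitions alone do not order themselves: +1 overlap maps to
category 4 and +2 to category 5; and a one-arm-covering run is only
category 2 when it covers < 80% of the chromosome, otherwise the
category-6 test (which a flanking deletion would otherwise never reach)
applies first. Adjacency for category 6 allows one detection window of
slack, since rolling statistics trim a run's boundary by up to half a
window next to a deletion. UPD runs are not required to align with segment
boundaries.

Gene status aggregates probes: HD with ≥ `min_probe_support` (2) HD probes,
then LOH likewise, else the majority segment call over the gene's probes.

## Recurrence (MCRs)

Per-probe alteration frequency counts samples with a matching call
(amplification counts as gain). The minimal-common-region null assumes
alterations are randomly located in the genome: each permutation relocates
every sample's altered segments to uniform random positions (probe-count
sizes preserved; within-sample overlaps resolved by rejection; genome-wide
by default, per-chromosome via `mcr_null_scope`). Per-probe p-values are
compared against this null, Benjamini–Hochberg adjusted across probes (the
standard FDR choice, stated explicitly), and maximal runs of consecutive
probes with adjusted p < `mcr_alpha` (0.05) become MCRs, reported with
their peak frequency and minimum adjusted p.

Because uniform genome-wide relocation gives every probe the same marginal
null distribution, the default p-value estimator **pools** permuted
frequencies across probes: p = (1 + #{pooled values ≥ observed}) /
(1 + n_perm × n_probes). Pooling extends the resolution from 1/(n_perm+1)
to ~1/(n_perm × n_probes), which is what allows BH-significant regions at
desk-scale permutation counts (n_perm = 500 on a 20,000-probe manifest);
the strict per-probe estimator, whose floor 1/(n_perm+1) cannot pass BH
correction across 20,000 probes at any realistic n_perm, is available as
`mcr_p_mode="per_probe"`. The +1 pseudo-count keeps p-values positive, as
usual for permutation tests.

Recurrent amplifications are maximal probe runs with ≥ `amp_min_samples`
(3) samples at call +2. The arm-alteration table counts each sample at most
once per (chromosome, scope, direction); a whole-chromosome event never
double-counts as two arms.

## Instability statistics

Three per-sample metrics: Mb altered (gained + lost, from segment bp
extents of non-neutral calls), fraction of probes altered, and the number
of altered segments. Cohorts split at the 1/3 and 2/3 empirical quantiles
into tertiles; boundary ties go to the lower class (deterministic; the
choice is otherwise arbitrary).

Group comparisons use the two-sided Wilcoxon **rank-sum** test (two
independent groups — the variant appropriate for mutant vs wild-type lines),
exact for combined n ≤ 20 without ties, normal approximation with
continuity correction otherwise; the exact path is verified against full
enumeration of rank assignments. Frequency comparisons use the 2×2
chi-square **without** continuity correction by default (Yates optional),
verified against the hand formula Σ(O−E)²/E.

The packaged curated cell-line table preserves conflicting multi-source
entries verbatim; resolution is a parameter of the counting operations
(`any_source`, or `own_data_precedence` where the study's own assay
overrides external reports). Fusions and amplification entries are never
counted as point mutations.

## Expression and subtyping

Probe matrices collapse to genes by the maximum over a gene's probes.
Nearest-centroid classification computes Pearson correlation between each
sample and each subtype centroid over the gene intersection (≥10 shared
genes enforced; correlation is invariant to affine transforms of a
sample's vector, which the tests assert); assignment is the argmax,
confidence the margin over the runner-up, ties flagged rather than broken.
Sample ordering for display uses agglomerative hierarchical clustering of
the per-class correlation vectors with Euclidean distance and complete
linkage (documented defaults, config-switchable; samples are pre-sorted by
name so equal merges are deterministic). The packaged centroids are
synthetic stand-ins (published signature centroids are not
redistributable); any gene × class table can be supplied.

Copy-number/expression integration compares altered vs unaltered samples
per gene: fold change of means (log-scale input exponentiated on request)
and the rank-sum p as above.

## Study conditions of the recovery suite

The test suite and `scripts/acceptance.py` run these studies end to end:

- **Breakpoint recovery**: 50 step signals (200+200 probes, step 1.0,
  sd 0.15); fraction of runs with the breakpoint within ±2 probes.
- **Zero-noise call identity**: planted copies {0, 1, 2, 3, 6} on a
  2,500-probe manifest must return calls {−1, −1, 0, +1, +2} with exact
  boundaries.
- **UPD recovery**: 20 samples × 3 planted copy-neutral-LOH events
  (whole-chromosome / whole-arm / focal, 2–50 Mb) on a manifest of ten
  45-Mb chromosomes at 25 kb spacing — chosen so a 2 Mb event spans ~80
  probes, the same order as on a 1M-probe array; sensitivity and precision
  at reciprocal overlap 0.5, plus a 20-sample diploid null.
- **MCR calibration**: 20 null cohorts (Poisson(5) background events per
  sample, sizes log-uniform 1 Mb–arm) for the fraction of probes inside
  significant MCRs; 20 cohorts with a 5 Mb gain at 60% penetrance for
  power; n_perm = 500 on the 20,000-probe autosomal manifest.
- **Statistics oracles**: exact rank-sum vs enumeration (group sizes ≤ 8);
  chi-square vs the hand formula.
- **Classifier recovery**: 200 samples from 4 synthetic centroids at sd 0
  and at sd = 25% of the centroid spread.

## Known limitations

- Threshold calling has no probabilistic uncertainty; borderline segments
  flip with noise rather than carrying a posterior.
- The segmentation arc scan is grid-approximate between refinements; an
  event whose statistic falls between grid widths loses a small fraction of
  power relative to the exhaustive O(n²) scan.
- UPD detection requires events long enough to contain one clean detection
  window (~50 informative probes); shorter events are invisible by design.
- The MCR null relocates segments independently per sample and ignores
  probe-density heterogeneity (uniform manifests make this exact in the
  studies here; on real manifests relocation is uniform in probe space).
- The curated-table counting operations implement two source-resolution
  policies; other curation rules require reprocessing the fixture.
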