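# Methods

## The break model and its filters

A segmented copy-number profile represents each chromosome of a sample
as ordered, non-overlapping segments `(start, end, num_probes,
segment_mean)` with 1-based inclusive coordinates and `segment_mean` on
the log2-ratio scale. Every boundary between two adjacent segments of
the same chromosome is a *candidate* chromosomal break; boundaries are
never formed across chromosomes. Each candidate carries two statistics:

* **SAS** (smallest adjacent segment size) = `min(left.num_probes,
  right.num_probes)`, in probes. Interpreting SAS as the *smaller* of
  the two flanks is the package's convention: a break is only as
  trustworthy as its least-supported side.
* **BrS** (break size) = `|right.segment_mean − left.segment_mean|`, in
  log2-ratio units on the data's native scale.

A candidate is *removed* when `SAS < 20` **or** `BrS < 0.135` — i.e.
retention requires both statistics to reach their thresholds, so
minimal copy-number wobbles and tiny segments with large steps (typical
artifact and repeat-region signatures) are both excluded. Comparisons
are strict-below for removal: a break with BrS exactly 0.135 is
retained. Independently, any boundary whose position is observed in
*any* sample of a matched normal panel is removed as likely germline or
platform-specific; panel matching is exact-coordinate by default with
an optional ±bp tolerance, because real pipelines re-segment normals on
the same probe grid. No SAS/BrS filtering is applied to the normals
themselves — anything a normal shows is grounds for removal. The
filter order (normal → SAS → BrS) only affects the recorded removal
*reason*, never the retained set.

**TBL** is the number of retained breaks. From SV call sets, TBL is
instead computed as breakpoints of copy-number-changing records (DEL,
DUP): two per event by default, because an unbalanced event creates two
genomic breaks and this matches the segment-based count when both
boundaries are visible; a one-per-event convention is provided for call
sets that report single breakends. **FGA** divides the length in
segments with `|segment_mean| ≥ 0.2` by the profiled length (or a
supplied genome length). **TMB** counts non-silent small variants,
optionally per Mb of footprint. Burden corrections in the association
screen operate on raw counts, never per-Mb rates.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume,
not real genomes — no GC bias, purity/ploidy, subclonality, or
realistic coordinates. Probes sit on a regular grid (default 5
chromosomes × 2000 probes × 50 kb spacing), so probe counts and bp
lengths are mutually computable. Break sites are drawn from slots
spaced 40 probes apart, guaranteeing that distinct events cannot erode
each other's flanks below the 20-probe filter; each somatic event
occupies two slots (a DEL/DUP interval with a step of at least 0.2 in
and out), artifacts occupy one slot (either a sub-0.135 step or a
5-probe segment with a large step), and germline sites are cohort-level
slots replayed into the normal panel. This construction makes the
planted somatic count *exactly* recoverable by the break caller — which
is what the recovery tests assert — at the price of regular spacing and
bounded per-sample break capacity (a config error, not silent
truncation, when exceeded).

Defaults are chosen to resemble a mid-size pan-cancer type: 120
samples/type (400 in the impact-score studies, see below), Poisson
break counts with mean 30, a 15% multiplicative break-rate increment
per stage step, a 12% MSI fraction with a 10× SNV excess and a 0.5×
break rate, negative-binomial expression (1000 genes, lognormal base
means around 100, dispersion 0.1, library sizes lognormal σ=0.2), a
20% DE fraction with |log2FC| in [0.5, 2] between the high-burden
quartile and everyone else, exponential survival at baseline hazard
1/1000 per day with a true high-group hazard ratio of 2 and 30%
independent censoring. Optional bimodality (off by default) mixes a
high-rate mode into the break-count distribution, mirroring cancer
types with two distinct SV-burden populations. One global seed feeds
named substreams (segments, decoys, mutations, expression, clinical),
so changing decoy generation cannot perturb the planted signal; a fixed
seed reproduces the cohort byte-identically. A self-audit after every
simulation re-checks that each planted break is a compliant boundary,
each artifact violates a filter, and each germline site is present in
the panel.

What passing tests on these cohorts shows: that the estimators and
tests recover what the model plants at the stated sizes. What it does
not show: robustness to segmentation errors, probe-density variation,
batch effects, correlated genes, or informative censoring — none of
which the generator produces.

## Differential expression contract

The impact score needs a two-group DE engine; the engine is a
*contract* (`de_func`), so any implementation returning per-gene
`log2_fc`, `p`, `p_adj` can be substituted. The reference
implementation is a vectorized negative-binomial Wald test: library
sizes by median-of-ratios against a geometric-mean reference (depth
ratios when too few all-positive genes exist); genes below a mean
normalized count of 1 are excluded before testing; per-gene dispersion
by method of moments, pooled within groups, then shrunk (weight 0.75)
toward an `a0 + a1/μ` least-squares trend and clamped to [1e-8, 10];
the Wald statistic uses the delta-method variance of the log mean
difference with a prior count of 0.5 per group mean, referred to a t
distribution with `n1 + n0 − 2` degrees of freedom; Benjamini-Hochberg
across tested genes. At the working arm size of 10 vs 10 this test is
approximately calibrated (pooled null p within [0.02, 0.09] tail mass
at the 5% level in the suite's calibration run) and detects a
two-fold change at dispersion 0.1 essentially always.

## Impact (proportion) score and its reference distribution

Per cancer type, samples are ranked descending (ties broken by sample
id for reproducibility) and the first/last `n//4` labelled HIGH/LOW.
Types with fewer than 10 HIGH samples are ineligible. Ten subsamples
of 10 HIGH vs 10 LOW (a single subsample when the arms hold exactly
10) are DE-scored; the proportion score of a run is the fraction of
tested genes with `p_adj < 0.05` (the threshold and whether it applies
to adjusted or raw p are config). The reference distribution draws
10+10 samples from *all* samples of the type — including INTERMEDIATE,
since it represents random partitions of the dataset — and the
observed scores are compared to it with a two-sided Mann-Whitney test
(exact when tie-free and small enough, tie-corrected normal otherwise).

Two properties of this design deserve explicit statement. First, under
a null cohort the default adjusted-p criterion yields a score that is
exactly zero in almost every run, so the Mann-Whitney p degenerates to
1 — the test is then conservative but useless for calibration studies;
the raw-p score variant has a non-degenerate null and is what the
calibration suite exercises. Second, the ten observed subsamples share
samples (overlap is explicitly allowed), so their scores are positively
correlated, which the Mann-Whitney independence assumption ignores. In
small cohorts (arms of ~30) this visibly inflates the tails of the
null p distribution; with arms of ~100 (cohorts of ~400, the regime
the calibration suite simulates) the overlap is small and the null p
is uniform. Impact p-values from small cohorts should therefore be
read as indicative rather than exactly calibrated — a limitation of
the subsampling design itself.

## Enrichment

Subsample DE results are averaged (gene-universe intersection) and
genes ranked by `sgn(mean fc) · −log10(mean p_adj)`; a mean adjusted p
of 0 is clamped to the smallest positive float, `sgn(0) = 0`, and ties
break by gene name. Preranked GSEA uses the weighted KS running sum
(hit increments `|score|^weight / Σ|score|^weight`, default weight 1,
miss decrements `1/(N − Nh)`), the signed maximal deviation as ES, and
a gene-permutation null (random same-size sets), which is the only
coherent null for a preranked list. NES divides ES by the mean
|permuted ES| of matching sign; the p-value is the matching-sign
permutation frequency with the +1 correction; BH across sets; sets are
size-filtered to [5, 500] by overlap and dropped when they cover
nothing or everything.

## Association screen

Alteration features are gene×{SNV, SV} flags and arm×{gain, loss}
calls (length-weighted arm mean vs ±0.2). Both breakpoints of an SV
record are mapped into gene intervals. Silent SNVs are excluded; MSI
samples are excluded by default; features need ≥10 altered and ≥10
wild-type samples. Before testing, the sample's own in-gene burden is
subtracted from the matching genome-wide measure (SNVs from TMB, SV
breakpoints from TBL, floored at zero); FGA is never corrected, and a
zero burden reproduces the uncorrected test exactly. The effect size
is `log2((median_altered + c)/(median_wt + c))` with pseudocount 1 for
count measures and 1e-3 for FGA — medians because the measures are
heavily skewed; the fold-change estimator is a package decision, as is
BH (per measure × alteration-kind screen) as the default adjustment
with the Bonferroni `α/m` floor available for power planning (α=0.05,
m=20000 gives 2.5e-06).

## Survival

The dichotomization threshold maximizes Youden's J over all midpoints
between adjacent distinct measure values, with "measure ≥ threshold
predicts the endpoint's event" as the orientation and ties broken
toward the lower threshold; the event indicator used is the analyzed
endpoint's own flag (recurrence for DFS, death for OS), computed per
cancer type. Kaplan-Meier estimation and the log-rank test come from
lifelines; the multivariate Cox model (Efron ties) adjusts for age,
sex, and stage entered as ordinal numeric I→1 … IV→4 (small per-stage
counts make categorical coding fragile; constant covariates are
dropped with a log message). DFS cohorts default to stage I–III, MSS,
untreated; a treated-only mode selects the therapy subset instead. A
constant group indicator raises an error; non-convergence or a
monotone likelihood (standard error above 50 on the log scale, i.e. an
infinite confidence interval) is reported as a non-estimable fit, the
"–" entry of a results table.

## Problem sizes and numerical choices

The test and acceptance studies run at deliberately scaled sizes chosen
as the package's own defaults: 200–1000 simulated profiles for the
break-caller oracles, 200 replicates for calibration/power studies,
100-permutation references in replicated runs (1000 in single
analyses), 1000-gene transcriptomes, and Cox recovery at n=1000 with
~70% events. Exact Mann-Whitney distributions are used up to products
of arm sizes of 20000 without ties. All randomness flows through
numpy Generators seeded explicitly; fixed seeds make every simulation
and permutation reproducible.
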