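# Methods

This note records the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that a user reproducing or
extending the analyses needs to know.

## Coordinates and the genetic map

All coordinates are 1-based inclusive (VCF convention); intervals are
closed on both ends, and the IBD overlap rule is the inclusive one
(segment end ≥ interval start and segment start ≤ interval end). Genetic
positions come from a linear map at 1 cM/Mb unless an explicit cM column
is supplied; the map source is recorded on the `MarkerMap`. Missing
genotypes are rejected at load time: every sharing statistic in the
package (tracts, EHH, IBD overlap) is undefined under missingness, and the
simulator emits complete data, so tolerating holes would only hide input
problems.

## Firth-penalized logistic regression

The risk-model estimator maximizes ℓ*(β) = ℓ(β) + ½ log det I(β) by
modified-score Newton iterations: the score is augmented with the
hat-diagonal correction h_i(½ − p_i), steps are halved whenever the
penalized likelihood would decrease, and convergence is declared when the
largest modified-score component falls below 1e-6 (at most 50 iterations).
Grouped (count-weighted) data fit identically to expanded individual-level
data, which is how the published genotype-count table is analyzed.

Inference follows the profile penalized likelihood: per-term p-values are
penalized LRTs with the term fixed at zero (the penalty always evaluated
on the full design), and 95% CI endpoints are found by bisection
(tolerance 1e-6 on β) on 2(ℓ*max − ℓ*profile) = χ²₁;0.95. Wald intervals
are reported alongside because the convention used for the original
analyses is not documented; the two differ visibly in the separated
dosage-2 cell. The penalized estimator is biased toward zero relative to
the MLE in sparse tables — visible in the worked example (β 1.88 vs 1.95)
— which is the bias–variance trade the penalty buys.

## Stratified and multiple-testing utilities

CMH and Breslow–Day come from statsmodels' stratified 2×2 machinery
(1-df CMH without continuity correction; Breslow–Day without the Tarone
adjustment). The allelic 2×2 test adds a 0.5 continuity value to every
cell only when some cell is zero, and flags that it did so. λ_GC is
median(χ²)/0.4549 with χ² obtained from two-sided p-values through the
1-df quantile transform; BH adjustment is the standard step-up.

## EM haplotypes and the score test

The EM assumes Hardy–Weinberg proportions in the E-step and runs from a
uniform start until the log-likelihood gain drops below tolerance; the
log-likelihood is non-decreasing by construction and with fully
phase-unambiguous data the fixed point equals direct counting. The score
test contrasts posterior-expected haplotype counts e_ih between cases and
controls: conditional on genotypes these are fixed covariates, so under
the null U = Σ(y_i − ȳ)e_i has variance ȳ(1−ȳ)·Σ(e_i−ē)(e_i−ē)', and the
global statistic uses a generalized inverse with df = rank (one less than
the number of haplotypes, from the sum-to-2 constraint). Haplotypes below
a frequency floor can either be skipped (default) or pooled into one rare
column; the dosage model always pools below 0.05 and drops columns that
end up constant. Per-dog dosages in the dosage model use the
maximum-posterior diplotype by default (posterior-weighted dosages are
available behind `weighting="posterior"`); hard calls were chosen as the
default because residual phase uncertainty mainly widens, not shifts, the
estimates, and hard calls make the dosage matrix reproducible integers.

## Sharing statistics

The shared tract between two haplotypes runs from the farthest *matching*
marker on the left of the focal position to the farthest matching marker
on the right. This marker-supported convention is conservative; a
mismatch-midpoint alternative sits behind a flag since the boundary
convention is genuinely arbitrary at array marker density. Tracts that
reach the region edge are kept at their truncated length and flagged
censored; per-haplotype medians are also reported with censored pairs
dropped, because either treatment of censoring is defensible and they can
differ materially near region borders.

EHH is computed unpolarized by successive group refinement outward from
the focal marker: EHH(x) = Σ_g C(n_g,2)/C(n,2) over groups identical on
[focal..x], evaluated at marker positions, linear between. iES integrates
EHH over physical distance (Mb; with the linear map this equals cM up to
scale), truncating each side at the interpolated crossing below a cutoff
(default 0.05, configurable — the value used by the original scan software
is not printed anywhere authoritative). When EHH is still above the cutoff
at a region border the integral is flagged and, by default, discarded —
the convention of locus-centered selection scans. For the replicated
simulation contrasts in the acceptance suite the integral is instead kept
(both classes treated identically), because there the quantity of interest
is the iES *ratio* and discarding would void replicates on a technicality
of the simulated region width.

Half-decay positions are the first interpolated crossings of EHH below
0.5 on each side; a side that never crosses is reported as censored rather
than extrapolated.

## IBD summaries and founder dating

IBD segments are consumed, never detected: detection belongs to external
haplotype-IBD tools, and the simulator supplies truth segments for
testing. Within a class, each pair's sharing over the focal interval is
summarized by the maximum cM length among its overlapping segments; the
proportion of sharing pairs is over all n(n−1)/2 pairs, and the median of
per-pair maxima feeds the dating heuristic g ≈ 50/L. That heuristic is a
rough clock: under a star genealogy with the ancestor g generations back,
pair members are separated by 2g meioses and the two-sided segment around
a locus has median ≈ 1.68·100/(2g) cM, so the heuristic reads ≈ 0.6g — an
underestimate well inside its intended order-of-magnitude use, and the
reason the simulator-recovery test asserts agreement within a factor of
two (on the median across seeded replicates; single replicates with few
carrier pairs are dominated by close relatives and are noisier).

KING-robust kinship is computed exactly from the published moment formula
over markers non-missing in both individuals, after filtering to
MAF ≥ 0.05 and missing rate ≤ 0.05 (LD pruning, when wanted, is an
upstream marker-list decision). Negative values are retained — they are
informative for between-population pairs. The Wilcoxon carrier contrast
reports the Mann–Whitney U of the carrier–carrier group (orientation
documented because the statistic is orientation-dependent), exact for tiny
categories and normal-with-tie-correction otherwise.

## Modifier survival analysis

The analysis population is carriers (dosage ≥ 1); gonadectomized dogs
without a recorded gonadectomy age cannot be classified and are dropped
with a log entry. Exposure is gonadectomy before seizure onset *and*
before the landmark age (5 years primary, 2 years sensitivity) for cases,
before the landmark for controls. The counting-process table gives each
dog intervals partitioning [0, endpoint] (onset for cases, last follow-up
for controls; no left truncation — all dogs enter at birth), with at most
one 0→1 exposure switch at the gonadectomy age; a switch exactly at the
endpoint would create a zero-length interval and instead yields a single
unexposed interval, logged.

The Cox fit uses lifelines' start–stop partial likelihood with Efron
ties. Cluster-robust (by dog) standard errors are computed in-package as
the usual sandwich over dog-summed score residuals (Breslow convention for
the sandwich, the standard approximation even when the point estimates use
Efron weights), because the upstream time-varying fitter does not provide
them. Constant covariates (e.g. nobody gonadectomized) are dropped rather
than fitted. A monotone partial likelihood — for instance every event
occurring in the exposed state — is flagged and stabilized with a light
ridge so that the output is finite but visibly marked unreliable.

The proportional-hazards check is a per-term 1-df score test of the
association between Schoenfeld residuals (computed at event times over the
start–stop risk sets) and a transform of event time (rank by default),
scaled by the summed risk-set information — the same construction as the
standard scaled-Schoenfeld diagnostic. Quantiles in onset summaries use
linear interpolation (the numpy default), stated because the upstream
convention is not documented.

## The synthetic cohort generator

The generator is a diploid Wright–Fisher model with non-overlapping
generations, two lineages ("ShowPet", effective size 500; "Working", 200 —
placeholders to vary, not estimates) exchanging migrants at rate 0.01, and
per-meiosis crossovers Poisson with rate (1 cM/Mb × span)/100, positions
uniform. Ancestry is tracked exactly as founder-mosaic tracts; marker
alleles are painted on at the end from founder haplotypes whose alt-allele
frequencies are Beta(0.8, 0.8) draws, and the true IBD output is the
pairwise overlap of same-founder tracts (min 0.5 cM), in the 8-column
dialect of common haplotype-IBD tools.

One founder chromosome carries the risk allele. Its expansion is a
single-generation popular-sire burst (carrier parents weighted 81:1 in
generation zero, 1.05:1 afterwards), chosen to reproduce two features of
the study system at g = 11: roughly 19 carrier chromosomes among the
sampled ShowPet haplotypes, and a star-shaped carrier genealogy — the
signature of demographic amplification, in which nearly every carrier pair
is separated by the full 2g meioses. A steady per-generation advantage was
considered and rejected: it keeps the carrier pool tiny for many
generations, so sampled carrier pairs are dominated by recent siblings,
shared tracts come out far longer than a recently-expanded-but-widespread
haplotype would show, and the dating heuristic reads a handful of
generations. Runs in which the risk allele is lost by drift are retried
with a derived seed (bounded at 25 attempts, recorded), keeping outputs
deterministic per seed.

The simulated region is chr3:71–107 Mb with the focal marker at the
study's lead position (88,803,651) and 1,200 uniformly placed markers.
The region is wider than the real association interval so that EHH decays
below the integration cutoff before the borders; marker density (~30 kb)
is array-like.

Phenotypes: P(case) = logistic(−1.55 + 1.9·dosage) — matching the observed
pattern that risk homozygotes are essentially always affected while ~18%
of non-carriers are cases of other etiology. Case onset ages follow a
Weibull hazard (shape 2, scale 4 years) multiplied by exp(log 3 · male)
and a time-varying exp(log 2.7 · exposed(t)) switching at the gonadectomy
age when it precedes the 5-year landmark; gonadectomy assignment is
independent of genotype by default so that modifier effects are
recoverable without confounding (a confounded design can be built by
editing the emitted table). Controls are seizure-free dogs followed to at
least 7.5 years. A separate pure survival generator
(`simulate_survival_cohort`) omits the case/control ascertainment layer;
it exists because marginal hazard ratios are only exactly the configured
values when there is no ascertainment filter, which is what the Cox
calibration studies need.

What the generator does **not** emulate: array ascertainment and
genotyping error, LD structure beyond what drift builds in 11 generations,
mutation, realistic dog pedigrees (litters, popular sires beyond the
founder burst), lineage-specific allele-frequency divergence, or
confounding between gonadectomy and genotype. Passing the simulation-based
tests therefore demonstrates that the estimators recover what they claim
from data satisfying their assumptions — not that those assumptions hold
in any particular real cohort.

## Problem sizes in the test and acceptance runs

The replicated studies use 100 seeded replicates of the default cohort
(170 dogs, 1,200 markers) for the founder-expansion properties; 100
replicates at n = 500 (logistic) and n = 300 (Cox) for CI coverage; 1,000
null label redraws on fixed genotypes for the score-test type-I check
(exact under the null, since status is independent of genotype); and
2,000+ descent tracts against the independent meiosis oracle. These sizes
keep every Monte-Carlo standard error well below the asserted margins.

## Known limitations

- The Firth profile CIs assume a unimodal penalized likelihood; with
  pathological designs the bisection bracket can hit its expansion bound
  and report an infinite endpoint (flaggable, not silent).
- The score test treats EM frequencies as known when forming expected
  counts; with very small samples this understates variance slightly. The
  type-I simulation bounds the effect at the study scale.
- The sandwich variance for the time-varying Cox model uses the Breslow
  tie convention even though point estimates use Efron; with heavy ties at
  event ages this is an approximation.
- g ≈ 50/L is a heuristic with ~2× bias depending on genealogy shape; it
  is reported raw and rounded, never with an interval.
- KING-robust assumes diploid biallelic dosages; the estimator is
  undefined (NaN, reported) for pairs without jointly observed
  heterozygous markers.
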