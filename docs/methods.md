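# Methods

This note documents the models behind `mmvdbiome`, the parameters that
matter, the numerical conventions, and what the synthetic cohort does
and does not emulate. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The synthetic cohort

The generator (`mmvdbiome.simulate`) is the package's test substrate: it
emulates a staged canine MMVD cohort with the statistical structure the
downstream analyses assume. Every output is a pure function of
`(CohortConfig, seed)`; each operation draws from its own RNG stream
spawned as `SeedSequence([seed, stream])`, so tables can be regenerated
independently and `B` can be extended reproducibly.

**Stages and metadata.** Group sizes default to 17/23/27/25 for stages
A/B1/B2/CD. Ages are truncated normal (floor 1 year) with stage means
8.9/10.3/10.2/11.5 years and SD 2.0 years. The means and the SD are
taken from the cohort description table, whose entries are means ±
standard errors; SE×√n puts the within-group SD near 2 years, and that
dispersion is what makes age-balanced subsamples findable at all — with
a much tighter SD, the age ANOVA is so powerful that essentially no
12-per-group subsample passes the balance filter. Body weight is
truncated normal around 10.4/9.2/8.1/7.8 kg (SD 3), body-condition
score is clipped normal (5.4 ± 0.8 on the 1–9 scale), sex is Bernoulli
1/2. The age gradient is the planted confound; weight, BCS and sex
carry no planted group signal.

**Community composition.** Each cohort draws a shared baseline
log-abundance profile (Normal, SD 2) over `n_otus` (default 300) OTUs.
Nine marker roles (E. coli-, Turicibacter-, Fusobacterium-,
Faecalibacterium-, C. hiranonis-, Erysipelotrichaceae-, Megamonas-,
Streptococcus-, Blautia-like) receive per-stage log2 shifts whose
directions mirror the study's findings (E. coli and Streptococcus up
with disease, the commensals and the bile-acid converter down); the
role→OTU map is recorded in `truth` and mirrored in the taxonomy
lineages. A sample's composition is the softmax of baseline+shift
perturbed by a Dirichlet draw with total concentration set by the
stage's evenness parameter (250/150/90/50 for A→CD): lower concentration
produces sparser, less even communities, which is how the diversity
gradient (highest in stage A) arises mechanistically rather than being
painted onto an index. Depths are log-normal around 15,000 reads;
counts are multinomial.

**qPCR panel.** Seven taxon targets are affine maps of the matched
OTU's log10 relative abundance (floored at 1e−6) plus Gaussian noise
(SD 0.3); total bacteria is stage-independent Normal(10, 0.2). The
C. hiranonis target is re-centered per stage (6.0/5.5/4.8/4.0) so the
cohort straddles the conversion threshold.

**Bile acids.** The total pool is log-normal (median 20, σ 0.5). The
converted fraction is logistic, `f = 1/(1+exp(−s(x−τ)))` with τ = 4.5
and steepness s = 8 in the C. hiranonis log10 abundance — a smooth
stand-in for the near-step behavior seen in the data that keeps
threshold estimation a well-posed problem. Primary mass splits CA:CDCA
60:40 and secondary mass DCA:LCA:UDCA 70:25:5, each jittered by a
Dirichlet draw; the five concentrations sum exactly to the pool, which
the tests assert. The generator does not attempt to reproduce the
study's anomalous positive UDCA–DI correlation, which a pure converter
model cannot produce.

**Metabolites and SCFAs.** Acylcarnitine-family columns load with
coefficient `assoc_beta` (default 0.3) on the standardized log10
proportion of the Megamonas-like OTU plus a stage trend; TMAO rises
with stage and loads negatively on the Erysipelotrichaceae-like OTU;
ten pure-noise metabolites exercise the FDR control. The metabolite
noise SD defaults to 0.5, chosen so the planted partial correlations
land in the |r| ≈ 0.2–0.5 range that serum-metabolite screens report as
significant; with much larger noise the default cohort would plant
associations too weak for its own screen to see. SCFAs are log-normal
with no stage effect, matching the study design in which fecal SCFAs
showed no group difference.

**What the generator does not emulate:** read-level artifacts (errors,
chimeras), real taxonomies or phylogenies (trees are random
bifurcations with exponential branch lengths, mean 0.1), diet/breed/
medication structure, compositional correlations between marker taxa
beyond the shared softmax, and echo variables. Passing tests therefore
demonstrate that the statistical machinery is correct and calibrated on
data with this structure — not that the biological conclusions transfer
to any particular real cohort.

## Diversity

Rarefaction is a single seeded multivariate-hypergeometric draw to
exactly 7,000 reads (no averaging over repeated rarefactions); samples
below depth are dropped and reported, never rescaled. Faith's PD uses
the root-inclusive convention (the branch path from the root to each
observed tip counts, even for a single observed tip); the suite checks
it exactly against a brute-force path-union oracle. Bray-Curtis assigns
distance 0 to a pair of all-zero samples. PCoA discards eigenvalues
below 1e−10 (no Lingoes/Cailliez correction), reports proportions of
the positive-eigenvalue sum, and fixes each axis's sign by making its
largest-magnitude loading positive. PERMANOVA uses the add-one
permutation estimator `p = (1 + #{F* ≥ F}) / (1 + n_perm)` with a
default of 9,999 permutations at desk scale (the study used 1,000,000;
the count is a parameter); samples are canonicalized to sorted ids so
the p value is invariant to input order, and a zero within-group sum of
squares is tie-ranked as an infinite statistic. Pairwise stage
comparisons report raw p with BH as an option, since the study does not
state a pairwise correction. Degenerate ANOVA inputs (all values equal)
are defined as F = 0, p = 1.

## Differential abundance

The chain is TSS → square root → prevalence filter → Kruskal–Wallis →
BH → Dunn. The prevalence filter drops a feature only when it is zero
in more than half the samples of *every* group. K-W uses the chi-square
approximation at all n (the study's group sizes are ≥ 17); exact
enumeration appears only in test oracles. Dunn's z tests are
tie-corrected and BH-adjusted within feature across the six stage pairs
(a pooled-across-features mode is available; the study does not state
the family). Default q thresholds: 0.10 for taxa, 0.20 for the relaxed
OTU screen.

## Dysbiosis index

The published DI formula for this qPCR panel is proprietary, so the
package uses a documented surrogate with the published sign convention
and category cut-points: per-target scaling by a pooled reference SD
(floored at 1e−3), then `DI = ln(d_N/d_D)` for Euclidean distances to a
normal and a dysbiotic centroid, each floored at 1e−6, clipped to ±10.
In the synthetic pipeline the reference is fit on stage A (normal) vs
stage CD (dysbiotic). The scorer sits behind a small interface
(`DIReference` + `compute_di`) so an exact published formula can be
dropped in; no numeric agreement with the proprietary index is claimed
anywhere.

## Bile-acid summaries and threshold estimation

Percentages are taken on the five unconjugated bile acids; conjugated
species pass through I/O but never enter percentages or the ratio. The
1°/2° ratio floors its denominator at `0.001 × pool` (itself floored at
1e−9), expressing "the ratio explodes when secondary ≈ 0" without
infinities; a zero pool marks all derived quantities NaN. The threshold
estimator fits a two-mean step function by exhaustive search over
midpoints of consecutive sorted unique abundances, minimizing RSS with
ties broken to the smallest candidate; it is exactly equivariant under
shifts of the abundance axis and never fits worse than the constant
model.

## Age-matched bootstrap

Each of B iterations samples k = 12 dogs per stage without replacement
(sampling over sorted ids, so results do not depend on row order),
computes ANOVA p for age, weight and BCS and a chi-square p for
sex×stage (no continuity correction; any zero expected cell gives
p = 1), and retains the iteration when p_age > 0.05 — age only, matching
the study's stated criterion; the other covariates are tracked but do
not gate. Outcome ANOVA p is computed for retained iterations, and the
summary reports the retained count, the significant fraction, and the
median/IQR of retained p values.

Two properties of this procedure, established analytically and borne
out by the calibration tests, are worth knowing. First, within a single
fixed cohort the subsample p values are dependent and concentrate
around the cohort-level p, so uniformity under the null holds
marginally over fresh cohorts, which is how the calibration test pools
them. Second, retention truncates the age F statistic at its critical
value while independent outcome noise re-diffuses mass across that
boundary, so with a genuine age-driven outcome the retained significant
fraction sits slightly above the nominal α rather than exactly at it;
the deconfounding test therefore requires the matched rate to collapse
below α + 0.075 while the unmatched rate stays at least 3× nominal and
3× the matched rate. The direct-effect simulation plants a progressive
diversity deficit (−0.5/−1.0/−1.5 SD for B1/B2/CD), the pattern the
study observed; a deficit confined to one group at −1 SD has analytic
one-way-ANOVA power ≈ 0.71 at these sizes and cannot demonstrate ≥ 80%
retained power.

## Microbe–metabolite associations

Features are OTU proportions filtered at ≥ 0.01% relative abundance in
≥ 10% of samples (both boundaries inclusive). Zeros are replaced per
feature by half its smallest non-zero proportion before log10. Age,
body weight and stage enter as fixed covariates — the upstream tool's
"random effects" wording cannot apply to continuous covariates, and a
fixed-effect linear model is the faithful executable reading. Constant
covariates are absorbed by the intercept; genuinely rank-deficient
designs are skipped with a warning. The reported r is the signed
partial correlation of the feature term, `sign(β)·√(t²/(t²+df))`, and
significance is the joint rule q ≤ 0.05 and |r| ≥ 0.2 with BH across
all (feature, metabolite) pairs. All metabolites are fit per feature in
one multi-response least squares, which keeps the 500-replicate null
calibration cheap.

## Problem sizes and numerical conventions

The test suite runs the full default cohort (92 samples × 300 OTUs,
depth 7,000), 500-replicate null calibrations for each test family,
12-cohort × 150-iteration bootstrap studies for the deconfounding
checks, 100-seed threshold recovery, and 20-cohort effect-size
recovery; the whole suite completes in well under five minutes on one
CPU. Permutation defaults (9,999 for PERMANOVA, 999 for the adonis-style
covariate test) are parameters, not limits. Recovery of the planted
association coefficient is judged on the model's own regressor scale
(coefficient × SD of the pseudocount-log10 regressor), since the
generator's zero-handling (1e−6 floor) and the model's (half-minimum
pseudocount) differ at zero counts by construction.
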