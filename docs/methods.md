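# Methods

This note documents the statistical models, the synthetic-data generator,
and the numerical and design choices behind `evprot`.

## Data model

Intensities live in an `AbundanceTable` (proteins × samples, NaN = missing,
`scale ∈ {raw, log10}`). Non-detections are represented as missing, never
zero: label-free LC/MS non-quantification is left-censoring, and log10 of 0
is undefined. Raw values are strictly positive where observed. Sample
metadata carries cohort (control / SALS), fluid (serum / CSF), week,
treatment arm, measurement batch, and a drug-exposure flag with the trial's
timing invariants enforced (drug-arm samples exposed after week 0; placebo
samples exposed strictly after week 24, the open-label switch; controls
never exposed, one draw recorded as week 0).

## Bridge-sample batch correction

A small number of samples (three by design) are measured in both batches.
Per protein, the correction factor is the arithmetic mean of the
batch-2/batch-1 ratios over bridge pairs, and every batch-2 measurement is
divided by it. With a multiplicative batch effect every bridge ratio equals
the batch factor, so the estimator is exact in the noise-free limit (tested
to 1e-10 relative error). Pairs with a missing member are dropped from the
mean rather than imputed; the minimum number of usable pairs is configurable
(default 1, set to 3 to require complete bridges). Correction precedes the
log10 transform and is computed per fluid.

## Differential abundance

Classical equal-variance (pooled) Student's *t* — the textbook reading of
"Student's t test", not Welch — on log10 intensities, controls vs drug-naive
patients. By default one sample per patient (week 0) enters the contrast, to
avoid pseudo-replication from longitudinal draws; a switch allows pooling
all naive samples. Multiple testing uses Storey q-values:
π̂₀(λ) = #{p > λ}/(m(1−λ)) over λ ∈ {0, 0.05, …, 0.95}, smoothed with a
cubic smoothing spline (GCV-chosen penalty, the scipy analogue of the
customary `smooth.spline` fit), evaluated at λ = 0.95 and clipped to
(0, 1]; q-values are the step-up minimisation of π̂₀·m·p/rank, which reduces
exactly to Benjamini–Hochberg when π̂₀ = 1 (verified against statsmodels on
random p-vectors to 1e-12). DAP threshold: q < 0.05. Proteins with fewer
than two observed values in either group are flagged untestable and excluded
from the FDR input.

## Drug-response effect sizes

Log2 fold changes from week 0 to week 24 are computed per patient on raw
(batch-corrected) intensities — fold changes of measurements, not of their
log10 transforms — and compared between arms with pooled-SD Cohen's *d*
(drug minus placebo). Magnitude bands at |d|: < 0.2 negligible, < 0.5
small, < 0.8 medium, ≥ 0.8 large; the bands are exhaustive and disjoint,
and the es-DAP set is exactly medium ∪ large (|d| ≥ 0.5, with 0.5 itself
included as the lower edge of medium). No small-sample (Hedges) correction
is applied. Zero pooled variance yields d = 0 for equal means and signed
infinity otherwise (flagged).

## Trajectory clustering and arm-by-time ANOVA

The trajectory of a protein is the mean placebo-arm log2 fold change at each
post-baseline week. Proteins with a complete mean trajectory are clustered
by Ward's minimum-variance method (scipy linkage) cut at k = 3; clusters are
named by the rank of their centroid at the final week (max → increased,
min → decreased, middle → unchanged). Proteins with any missing week mean
are excluded from clustering and conservatively labelled unchanged. Proteins
are sorted lexicographically before linkage so results are independent of
input order; exact tie-breaking inside merges is left to scipy (ties have
probability ~0 on continuous data). The partition is a function of placebo
data only — drug-arm data never influence it.

Per cluster, drug vs placebo is tested by two-factor fixed-effects ANOVA
(treatment, week, interaction; Type-III sums of squares via sum-to-zero
contrasts) where the unit of observation is the per-protein arm mean at each
week — the quantity the trajectory plots display. Estimated marginal means
per treatment × week cell and Bonferroni-adjusted between-arm contrasts at
each week accompany the F table. A repeated-measures or mixed model (protein
as random effect) would be a defensible alternative; fixed effects were
chosen as the analysis of the plotted means, and the per-subject switch in
the fold-change cube allows rebuilding the table at other units.

## Set similarity and profile correlation

Protein sets are compared as signed membership vectors over a common
universe (+1 up, −1 down, 0 absent), so a disease-increased set and a
drug-decreased set built from the same proteins give a negative cosine —
the anti-disease directionality read-out. Heatmap ordering uses
average-linkage clustering of cosine distances. The per-subject serum/CSF
profile correlation is a pairwise-complete Pearson r over the proteins
observed in both fluids for that subject-week (minimum 3); patient week
groups are compared to controls Dunnett-style, with the family-wise max-|t|
null of the correlated many-to-one contrasts estimated by seeded Monte-Carlo
(default 100 000 draws) rather than multivariate-t quadrature — the MC error
of an adjusted p at this draw count is ≈ 0.002, negligible for the 0.05
decisions made with it. The divergence trajectory places each patient sample
at (down-set mean − its week-0 value, up-set mean − its week-0 value);
controls are centred on the control-group mean, so their cloud sits at the
origin by construction.

## Disease-progression model

Each patient's ALSFRS-R series is fitted with `score = −exp(a·week) + b` by
bounded nonlinear least squares (`a ∈ [1e-6, 1]` per week), multi-started
from a ∈ {0.001, 0.005, 0.02, 0.05, 0.1} with b₀ = max(score) + 1 and kept
at the best RSS; tolerances 1e-12. On noiseless data the fit is exact; a
constant series drives `a` to the lower bound and is flagged. Derived
quantities: aALSFRS-R (the fitted curve at a sampling week), the fixed-point
progression rate (the analytic derivative −a·exp(a·week), verified against
finite differences), and adj-a, the z-score of −log10 a within each
treatment arm using the sample (n−1) standard deviation — higher adj-a
means slower progression. Biomarker ranking correlates baseline log10
protein levels with a chosen target (adj-a, aALSFRS-R, or rate) by
pairwise-complete Pearson r (minimum 3 pairs), ranks by r, and reports the
|r| ≥ 0.5 flag plus top-5 tails.

With integer scores, noise SD 1 and 16 visits, the information content about
`a` is limited: the Cramér–Rao bound at a = 0.02/week already implies ≈ 21 %
relative standard error, so the observed ≈ 13 % median relative recovery
error is the estimation floor, not an optimizer artefact. Recovery tests
estimate that population median over 1000 simulated patients, a Monte-Carlo
size chosen to make the estimate of the median stable.

## Diagnostic-classifier framework

Mirrors a three-step design for tiny unbalanced cohorts. (1) SMOTE-style
oversampling: synthetic minority points x_i + u·(x_nn − x_i),
u ~ Uniform(0,1), x_nn one of the k nearest minority neighbours;
k = min(5, minority−1) adaptively, since fixed library defaults fail at
minority sizes this small (k = 2 at the design's 3 patients); minority count
raised to 9 for a 10 + 9 = 19-sample set (the design the framework mirrors is
deliberately not fully balanced). (2) A seeded stratified 13/6 split
(largest-remainder allocation puts 3 + 3 in the test set) and per-family
grid search with stratified twofold CV. (3) RFECV feature selection for
families exposing importances or coefficients; others keep the full feature
set (logged). Seven families: random forest, gradient boosting, AdaBoost,
extra trees, decision tree, XGBoost (exact greedy split finding — histogram
binning places thresholds on data points and generalises poorly at n = 13),
and a perceptron behind a standard scaler (linear-model margins depend on
feature scale). Metric: plain accuracy on the held-out test set and on
external validation sets (drug-naive and drug-exposed patient samples);
the best model maximises mean validation accuracy. The feature universe is
the proteins detected in every training sample; validation gaps are filled
with training medians. Oversampling before splitting leaks synthetic-point
information into the test set — the framework reproduces that design
faithfully and the test accuracy should be read accordingly; the external
validation sets are the honest figures.

## Synthetic cohort generator

The generator emulates the trial design: 10 controls (single draw per
fluid, batch 2), 20 patients (13 drug / 7 placebo) sampled at weeks
{0, 13, 24, 39, 48} in serum and {0, 24, 48} in CSF (batch 1), three
patients' week-0 samples re-emitted in batch 2 as bridges, ALSFRS-R recorded
every 4 weeks to week 60. True log10 abundance:

    L(p,s,t) = μ_p + disease_p·1[SALS] + slope_p·P_att(s,t)
               + batch_p·1[batch 2] + ε(p,s,t)

with μ_p ~ N(6.5, 0.8), noise SD 0.1, per-fluid batch factors N(0, 0.15)
(log10-additive = multiplicative on raw scale, matching the ratio-based
correction), and left-censoring below a log10 detection limit of 5.
10 % of proteins are inflammation-class (disease shift +0.3, positive
trend), 10 % UPR-class (negated signs), the rest null. The progression
burden P(s,t) = exp(a_s·t) − 1 ties protein trends to the patient's own
modelled clinical decline (it equals (b − aALSFRS) − 1, re-zeroed at
baseline; zero for controls), and drug exposure removes 80 % of the burden
increment accrued after exposure starts — the drug slows further change
rather than erasing accrued change, which keeps placebo trajectories
monotone through the open-label switch and week-0 patients comparable to
controls. Trend slopes |slope_p| ~ Uniform(0.2, 0.4) in log10 per unit
burden, centred on the disease-shift magnitude: a median progressor's
accrued longitudinal change over the trial then matches the cross-sectional
disease contrast. The clinical score is the model curve plus N(0, 1) noise,
rounded and clipped to [0, 48].

The noise draw ε belongs to the (protein, subject, week) sample, so the two
emissions of a bridge sample are aliquots of one physical sample differing
only by the batch factor; technical replicate noise between re-injections is
not modelled. Consequences worth knowing when reading test results: batch
factors are recovered exactly rather than with replicate error, so the
cross-batch control-vs-patient contrast is noisier in real data than here;
proteins are independent given the planted classes (no co-regulated modules
beyond them); intensity distributions are log-normal rather than
acquisition-realistic; and there is no patient dropout. Passing recovery
tests therefore demonstrate correctness of the estimators under the stated
model, not field performance.

## Problem sizes and tolerances

Recovery tests use the design's native sizes (1000 proteins, 30 subjects)
across 10–20 independently seeded cohorts and pool per-protein outcomes
across cohorts. Batch-correction exactness is asserted at 1e-10 relative,
Storey/BH agreement at 1e-12 absolute, derivative identities at 1e-4
relative with h = 1e-6, and curve-fit exactness at 1e-6. All simulations,
splits, oversampling and Monte-Carlo nulls are driven by explicit seeds;
rerunning any stage with the same configuration is bit-identical.

## Known limitations

- The progression model is a single exponential; it cannot represent
  plateaus or sigmoid decline, and near-constant series pin `a` at its
  bound.
- The ANOVA treats proteins as independent observations within a cluster;
  correlated proteins would understate the p-values.
- The Dunnett adjustment is Monte-Carlo, so adjusted p-values carry ~2e-3
  simulation error at the default draw count.
- The classifier framework inherits the oversample-then-split leakage of the
  design it reproduces (documented above).
- Storey's π̂₀ spline can be unstable for very small m; the estimate is
  floored at 1/m and capped at 1.
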