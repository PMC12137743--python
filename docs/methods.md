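# Methods

`trajphen` implements a subphenotyping workflow for ICU patients with acute
pancreatitis (AP): latent-class modeling of early vital-sign trajectories,
stability-based choice of the number of classes, survival contrasts between
the resulting subphenotypes, and phenotype-specific fluid-resuscitation
response surfaces. Because the underlying clinical registries are
credential-gated, the package ships a calibrated synthetic-cohort generator
so that every stage can be exercised, and its recovery properties measured,
without any data download.

## Trajectory model

For patient *i*, hour *h* ∈ {0,…,11} after ICU admission and channel
*c* ∈ {SBP, DBP, HR, RR, TEMP}, the observed standardized vital `y_ihc` is
modeled by a finite mixture over K latent classes. Conditional on class
*k*, the mean is a degree-*p* polynomial in scaled time `h_s = h/11`,

    y_ihc | k  ~  Normal( Σ_j β_kcj h_s^j ,  σ²_kc ),

independent across observed hours and channels. Class membership has
mixing probabilities π_k. The marginal log-likelihood sums, per patient,
the log of the π-weighted product of normal densities over the patient's
observed cells; hours missing any of the five channels are excluded from
the likelihood entirely (no imputation in the trajectory stage).

Estimation is EM:

- **E-step** — posterior τ_ik ∝ π_k exp(ℓ_ik), stabilized by log-sum-exp.
- **M-step** — π_k = mean_i τ_ik; β_kc by τ-weighted least squares of
  channel *c* on the polynomial time basis; σ²_kc the τ-weighted mean
  squared residual, floored at 1e-6 to rule out degenerate spikes.

EM is multimodal, so the fit runs from a k-means initialization (on
per-patient channel means) plus random Dirichlet posteriors, keeping the
restart with the best final log-likelihood. A restart is discarded when a
class's effective weight Σ_i τ_ik drops below p+2 (too few effective
observations to identify a degree-p curve). Convergence: relative
log-likelihood change below 1e-6, cap 500 iterations.

Defaults: order p = 3 (cubic curves accommodate the non-monotone early
trajectories seen clinically), 10 restarts for final fits, 2–3 restarts
inside resampling loops. Coefficients are reported on the `h_s` scale.

## Data preparation

Fixed order: (1) hourly aggregation — half-open bins [h, h+1) from ICU
admission, multiple measurements within an hour averaged; (2) complete-hour
filter — an hour is retained only if all five channels are present;
(3) inclusion — first ICU stay only, age ≥ 18 years, ICU LOS ≥ 24 h,
≥ 2 observed hours, applied in that order with per-reason exclusion counts;
(4) z-scoring per channel, pooling all patients and hours. Validation or
external panels are standardized with the development cohort's statistics
by default, which keeps the MSE assignment below scale-consistent;
standardizing each cohort separately is supported.

## Choosing K

For each K in 2–6 the cohort is subsampled without replacement (80% of
patients, 100 resamples by default), the mixture refit, and each pair's
modal co-assignment accumulated. The consensus matrix M_K holds
co-assignments divided by co-samplings. Stability summaries:

- A(K): area under the empirical CDF of the off-diagonal consensus values
  (100-bin histogram rule);
- Δ(K): A(2) for the first K, then the relative gain (A(K)−A(K−1))/A(K−1);
- per-cluster mean consensus of an average-linkage hierarchical clustering
  of 1−M_K cut at K clusters.

A value of K is admissible when every per-cluster mean consensus exceeds
0.8 and the smallest cluster share is at least 10%. The published
class-size sentence reads "a maximum of 10%", which would defeat its
purpose of suppressing tiny clusters; the package treats it as a minimum
share, with a `literal` mode available. Among admissible K, the chosen one
is the delta-area elbow: the largest K with Δ(K) ≥ 0.1 (falling back to
the admissible K with the largest gain). AIC, BIC, ICL = BIC + 2·entropy,
and normalized entropy 1 − E/(N ln K) from full-data fits accompany the
report as sensitivity evidence, not as hard criteria.

## Assignment and early prediction

External or truncated-window patients are assigned to the class whose mean
curves minimize the mean squared error over the patient's observed cells;
ties go to the lower class index. Early-prediction accuracy at horizon H
is the percent agreement between the H-hour MSE assignment and the
12-hour MSE assignment (the 12-hour MSE labels, not the posterior modal
labels, are the reference, keeping both sides of the comparison on the
same footing). Patients left with fewer than two observed hours after
truncation are excluded from the denominator and counted.

## Outcomes

Descriptives are median (Q1, Q3) for continuous variables and n (%) for
categorical ones; group differences use Kruskal–Wallis and Pearson
chi-square (no continuity correction). Prognosis contrasts come from Cox
proportional-hazards models (lifelines, Efron ties; day-resolution times
produce ties) with phenotype B — the hypertensive class — as reference;
crude and demographic-adjusted (age, gender, race) models are reported,
and constant covariates (e.g. race in a single-region cohort) are dropped
automatically. "Adjusted Kaplan–Meier" curves are direct-adjusted
(corrected-group-prognosis) survival: a Cox fit on phenotype + covariates,
averaging predicted curves over the pooled covariate distribution with
each patient's phenotype set to the target class. Comorbidities with
cohort prevalence strictly above 5% enter one multivariate Cox per
phenotype stratum. Two-sided α = 0.05 throughout, no multiplicity
correction.

## Fluid-response surfaces

Per phenotype, a random-forest ICU-death classifier is tuned by stratified
5-fold cross-validated AUROC over a small grid (trees {200, 500}, depth
{None, 6, 10}, min leaf {1, 5, 20}) on shared clinical features plus
day-1/day-2 fluid intake. The two-feature partial dependence PD(x1, x2)
is computed by brute force: the mean predicted death probability with
day-1 and day-2 volumes forced to the grid point and every other feature
kept at its observed joint values, over a 0–6000 mL grid in 100-mL cells.
Cells are cut into decile risk strata; the lowest-risk fluid range is the
bounding box (in cell edges) of the 4-connected stratum-1 component
containing the global PD minimum. The lactated-Ringer's contrast is an
age/gender/race-adjusted Cox HR of receipt vs non-receipt within each
phenotype stratum.

A structural note on the decile rule: stratum 1 always contains ~10% of
the grid cells, so for a smooth two-dimensional risk bowl its connected
component is an ellipse-like region of roughly 3.7×10⁶ mL² whatever the
bowl's steepness (a quantile cut is invariant to monotone transforms of
the risk surface). The recovered day-1 box therefore spans roughly
3200–5300 mL around a 4200-mL optimum even for a perfect classifier; the
box reliably covers the true optimum, but its edges are an order of
magnitude wider than the ±100 mL at which published range endpoints are
printed. Reproducing endpoints that sharp would require a different
(e.g. equal-risk-width or much finer-quantile) stratification.

## Missing data (feature table)

Variables with a missing rate strictly above 20% are dropped. The rest
are completed by four single imputations — column mean, and chained
(variable-by-variable, 5 iterations) imputation with regression trees,
random forests, and L1-regularized linear regression — combined cell-wise:
arithmetic mean for continuous cells, majority vote for categorical cells
with ties broken by method order. Observed cells are never modified.

## Synthetic cohort generator

The generator emulates the study conditions stage by stage:

- **Trajectories** — four classes with order-2 polynomial templates on the
  standardized scale encoding the clinical signatures (A: TEMP/HR/RR ≥ +1
  SD; B: SBP/DBP ≥ +1 SD; C: SBP/DBP ≤ −1 SD with mild compensatory
  tachycardia; D: TEMP/HR/RR ≤ −1 SD), mapped to natural units through
  fixed channel means/SDs (e.g. HR 88 ± 16 beats/min, TEMP 36.8 ± 0.7 °C).
  Hourly noise is Gaussian, SD 0.5 standardized units per channel —
  large enough that classification is imperfect, small enough that the
  four classes remain well separated; an AR(1) option (default ρ = 0,
  matching the model's conditional-independence assumption) supports
  robustness checks. Mixing proportions default to the development-cohort
  shares (14.1, 17.6, 27.0, 41.2)%, renormalized to sum to one.
- **Survival** — exponential event times with administrative censoring at
  30 days; class hazards are the reference-class hazard (calibrated to 5%
  30-day mortality, the hypertensive class's observed rate) times the
  adjusted hazard ratios 3.38 (A), 1.87 (C), 0.77 (D). Covariates (age,
  gender) multiply the hazard but are independent of class by default, so
  crude and adjusted contrasts share the same truth; an age-by-class
  shift switch introduces confounding for crude-vs-adjusted experiments.
  Lactated Ringer's multiplies the hazard by 0.48 in class C only.
- **Fluids** — truncated-normal day-1/day-2 volumes (floor 0 mL, spreads
  1100/900 mL keep the PD grid populated) centered at class-specific
  optima (A 4200/3500, B 4050/900, C 4500/2800, D 3300/2000 mL, the
  midpoints of the published lowest-risk ranges); ICU-death probability is
  logistic in the squared distance from the class optimum, curvature 0.5
  logit units per squared 1000 mL (risk roughly doubles 1500 mL from the
  optimum), with class baselines 9/3.5/5/1.5% anchored to observed ICU
  mortality by class.

What the generator does **not** emulate: correlated baseline labs and
comorbidities (only marginals are needed by the descriptive and imputation
stages), LOS dynamics, measurement artifacts/outliers, informative
missingness (drops are completely at random), and non-proportional
hazards. Passing recovery tests therefore demonstrates internal
correctness of the estimators under the model's own assumptions, not
robustness to real-EHR pathologies.

## Numerical and reproducibility choices

Variance floors 1e-6; log-sum-exp posteriors; ties in modal and MSE
assignment break to the lower class index and are logged; singular
polynomial designs reduce order with a warning; consensus pairs never
co-sampled are excluded from CDFs; a single global seed expands through
`numpy.random.SeedSequence` into per-stage seeds, and rerunning a
configuration reproduces byte-identical tables (checked by SHA-256 in the
run manifest).

Default problem sizes are chosen to make the full study comfortably
runnable on a laptop core: the demo pipeline uses n = 800 patients, K
scanned over 2–5 with 30 consensus resamples, and partial-dependence
backgrounds subsampled to 400 patients; recovery experiments use
n = 2612 (trajectory shares), 20 000 (survival contrasts), 10 000
(Ringer's), and 3000 (fluid surfaces).

## Known limitations

- The published trajectory coefficients, noise levels, EM settings and
  consensus parameters are not reported anywhere; templates and defaults
  here are stipulated, so agreement is measured against the generator's
  truth, not against the original cohorts.
- MSE assignment ignores class-specific residual variances and mixing
  weights; it matches the posterior-modal rule only when classes are well
  separated (the package reports both).
- The decile-based lowest-risk range is structurally wide (see above).
- Chained-imputation settings (5 iterations, single imputation per
  method) are pragmatic defaults; no pooled-inference (multiple
  imputation) machinery is provided.
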