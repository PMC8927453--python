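# Methods

`burnmech` compares the tensile mechanics of two skin-tissue populations
(full-thickness burned human vs porcine specimens) through a fixed chain of
stages: forward simulation or file input of force–displacement records,
extraction of five mechanical properties per specimen, a univariate
decision-tree comparison per property and loading rate, an effect-size and
sample-size block, and leave-one-out cross-validated (LOOCV) binary
classification. This note records the model, the statistical procedures, the
defaults, and the choices made where more than one defensible convention
exists.

## Constitutive model

The stress–strain response of skin up to rupture is described by the
two-parameter Veronda–Westmann hyperelastic law. With deviatoric invariants
Ī₁, Ī₂, the strain energy density is

    Ψ(Ī₁, Ī₂) = (μ/γ)(e^{γ(Ī₁−3)} − 1) − μ(Ī₂ − 3)

where μ (MPa) sets the stress scale and γ (dimensionless) the exponential
stiffening rate. For incompressible uniaxial extension with principal
stretch λ = 1 + ε (ε the nominal strain), Ī₁ = λ² + 2/λ and Ī₂ = 2λ + 1/λ²,
and the nominal (first Piola–Kirchhoff) stress is

    σ(λ) = 2μ(1 − λ⁻³)(λ e^{γ(Ī₁−3)} − 1)

which equals dΨ/dλ under those kinematics — the package's central
correctness oracle tests this identity by central differences on a (μ, γ, λ)
grid. Assumptions inherited from the model: incompressibility, isotropy,
rate independence (hyperelasticity), and no damage or softening — the model
cannot represent post-peak behavior, which is why fitting stops at the
ultimate point.

Small-strain behavior worth knowing: the ground-state tangent modulus of
this stress expression is zero; σ ≈ 6με² as ε → 0, so the toe of the curve
is quadratic, not linear.

## Property extraction

Nominal stress σ = F/A₀ and nominal strain ε = ΔL/L₀ use the initial gauge
area and length; units are fixed at N, mm, MPa (1 N/mm² = 1 MPa). The first
recorded point defines zero displacement and force by default; an optional
preload threshold re-zeros displacement at the first sample above a given
force instead (specimens are commonly preloaded to ~0.1 N, and the two
conventions differ only by a sub-toe offset). Strictly duplicated
displacement samples are collapsed keeping the first occurrence.

Per specimen, five properties are extracted:

| property | symbol | units | definition |
|---|---|---|---|
| ultimate tensile stress | σᵤ | MPa | peak nominal stress (first occurrence on ties) |
| ultimate tensile strain | εᵤ | – | strain at σᵤ |
| toughness | U | MJ/m³ | trapezoidal area under σ(ε) on [0, εᵤ] |
| shear-modulus-like scale | μ | MPa | Veronda–Westmann fit |
| stiffening exponent | γ | – | Veronda–Westmann fit |

### Parameter identification

(μ, γ) minimize the plain stress residual Σ(σᵢ − σ(μ, γ, εᵢ))² over the
points up to and including the ultimate point. Residuals are on the raw
stress scale (no log transform). Positivity is enforced by optimizing in
(log μ, log γ); the solver is Levenberg–Marquardt with an analytic Jacobian.
Initialization is a deterministic multi-start over the grid
μ₀ ∈ {10⁻³, 10⁻², 10⁻¹, 1, 10} MPa × γ₀ ∈ {0.5, 2, 8, 20, 50}: all 25
starts are screened by their initial cost and the best four are polished;
the lowest final residual wins, ties broken toward smaller γ. Convergence
tolerances are 10⁻¹² on the relative cost change and 10⁻¹⁴ on steps;
the exponent γ(Ī₁−3) is saturated at 500 inside the optimizer (so wandering
iterates stay finite) while the public stress/energy functions raise an
overflow error above 700 rather than returning infinity. R² is the
conventional coefficient of determination against the mean observed stress
over the fitted range. On noiseless forward-simulated curves the fit
recovers (μ, γ) to better than 10⁻⁶ relative; with 2 % force noise the
median parameter error stays below 5 % and R² stays above 0.99 for the 5th
percentile of replicates.

### Outlier filter

Within each tissue × rate group and for each of the five properties,
quartiles use linear interpolation between order statistics (the "type 7"
rule — stated because fences depend on it). A specimen is removed when any
property falls outside [Q1 − 3·IQR, Q3 + 3·IQR], the standard
extreme-outlier fence. The filter runs once; fences are not recomputed on
survivors. The alternative literal reading "value greater than 3·IQR" is
scale-dependent (it would remove nothing or everything depending on units)
and was rejected. Whether the filter should pool loading rates is not
determined by the study design this mirrors; grouping by tissue × rate was
chosen and is flagged as an assumption in the removal log. Groups smaller
than four pass through unfiltered with a warning.

## Univariate comparison

For each property at each rate, two samples (human vs porcine) enter a
fixed decision tree, every node two-tailed at the same α (default 0.01):

1. Shapiro–Wilk on each sample; both must pass (the conjunctive reading of
   "a pair of samples drawn from normal distributions").
2. Both normal → F-test for variance equality → pooled-variance t-test if
   not rejected, Welch t-test if rejected.
3. Otherwise → two-sample Kolmogorov–Smirnov on the **median-centered**
   samples; same shape → Wilcoxon rank-sum; different shape → Welch t-test
   (the recommended location test when neither normality nor a common shape
   holds).

Median-centering before the KS step is an interpretation: the raw
two-sample KS statistic responds to location as much as to shape, so a pure
shift between identically-shaped distributions would otherwise bypass the
rank-sum branch that is intended to handle exactly that case. The rank-sum
p-value is exact when the smaller sample has under 25 observations and the
data are tie-free, otherwise the normal approximation with continuity
correction is used. The full traversed path (test, statistic, p) is
recorded in every result.

No multiple-testing correction is applied across the 15 property × rate
comparisons; the pipeline mirrors a design in which each comparison is
reported at its nominal level, and the report states this. The empirical
type-I error of the whole tree under same-distribution nulls (normal and
exponential, n = 95 vs 38) is consistent with the nominal 1 % in
Monte-Carlo checks of 10⁴ replicates.

## Effect size, power, and sample size

Cohen's d uses the pooled standard deviation; the study-level summary is
the mean d over the five properties with all rates combined. Exact power of
the two-sample t-test comes from the noncentral t distribution with
noncentrality d·√(n₁n₂/(n₁+n₂)) and n₁+n₂−2 degrees of freedom.

Required sample sizes walk the total N upward, split it as
n_small = round(N/(1+r)), n_large = N − n_small for allocation ratio r, and
accept the first N whose exact power is within 10⁻⁴ of the target. The
tolerance deserves a sentence: the widely used desktop power calculators
report achieved power at limited display precision and their search stops
at the first N whose power rounds up to the target; accepting power ≥
target − 10⁻⁴ reproduces their published outputs exactly (for d = 1.4,
α = 0.01, power = 0.99, r = 2.5 this yields groups of 18 and 46, where a
strict ≥ threshold would give 19 and 48 because the exact power at 18/46 is
0.98991). Both the tolerance and the rounding convention are parameters and
are echoed in the report.

## Classification

The five-property vector feeds a logistic regression, one task per loading
rate plus a rate-combined task formed by row concatenation (rate is
deliberately not a feature). Assessment is leave-one-out: for each
specimen, features are standardized with the statistics of the n−1 training
rows only, the model is fitted, and the held-out positive-class (human)
probability is recorded. Hard labels use threshold 0.5. A weak L2 penalty
(weight 10⁻⁴ on standardized coefficients) keeps the likelihood bounded on
near-separable data; predicted labels are insensitive to it.

From the pooled out-of-fold probabilities and the confusion matrix, eight
metrics are computed: accuracy, sensitivity, specificity, F1, ROC-AUC (the
normalized Mann–Whitney statistic of the out-of-fold scores, mid-rank tie
handling), Matthews correlation coefficient, Fowlkes–Mallows index and
adjusted Rand index. FMI and ARI use the pair-counting (clustering) forms
evaluated on the 2×2 contingency table that the confusion matrix is; for
FMI this is a/√((a+b)(a+c)) over co-clustered pairs, **not** √(PPV·TPR) —
the two differ whenever the negative class is appreciable, and the
pair-counting form is the one consistent with reporting FMI alongside ARI
"from the confusion matrix". Zero-denominator metrics are reported as NaN
with a diagnostic note, never silently as 0.

Feature contributions are the normalized absolute standardized coefficients
|β_j|/Σ|β_k| of a full-data logistic fit. This fit uses a unit-strength
ridge rather than the weak 10⁻⁴ of the predictive model: on near-separable
data the unpenalized maximum-likelihood direction is arbitrary among
collinear features (ultimate stress and toughness are strongly collinear
with μ here), whereas the ridge solution shares credit between correlated
predictors and is stable across resamples. The contribution measure is an
interpretation of "factor analysis of the classifier" and is labeled as
such in reports.

## Synthetic study generator

No specimen-level data are publicly deposited for the study design this
package mirrors, so the generator produces populations with the statistical
structure the analysis assumes, and every downstream stage is tested
against it. Per tissue × rate population (six in the default study):

* (log μ, log γ) are jointly normal — lognormal marginals for positivity
  and right skew — with a within-population correlation of −0.7. The
  negative correlation emulates the well-known trade-off between the scale
  and exponent parameters of exponential-stiffening laws fitted to soft
  tissue; it is also what lets the multivariate separation between tissues
  exceed each property's marginal effect size, the same qualitative
  structure as a real study in which a pooled Cohen's d near 1.4 coexists
  with >95 % classification accuracy.
* rupture strain is truncated normal (lower bound 0.05), sd 0.035;
* gauge geometry is truncated normal around ASTM D638 type-V-like values
  (L₀ = 7.62 ± 0.25 mm, A₀ = 6.0 ± 0.6 mm²);
* force noise is multiplicative, i.i.d. Normal(0, 0.02) per point (a
  relative load-cell error model), with forces clamped at zero;
* curves are sampled on a uniform 200-point displacement grid spanning
  [0, rupture strain × L₀].

Default sample counts are 95/92/102 (human) and 38/39/38 (porcine) across
rates 0.3/2.0/8.0 mm/s. The population medians (μ: 0.080–0.097 MPa human
vs 0.042–0.0505 MPa porcine; γ: 4.50–4.70 vs 4.21–4.39; rupture strain:
0.605–0.645 vs 0.570–0.610, rising μ/γ and falling rupture strain with
rate) are **implementation constants, not tissue measurements**. They were
chosen once so that, on the extracted properties: distributions are
positive and right-skewed; μ carries the largest and ultimate strain the
smallest between-tissue standardized separation; and the pooled Cohen's d
over the five properties lands near 1.4. Under these defaults the pipeline
measures pooled d ≈ 1.43–1.49, all 15 univariate p-values below 10⁻³, and
LOOCV accuracies of 0.96–0.99 across seeds.

Loading rate never enters the forward model — the constitutive law is
rate-independent — so rates differ only through their population
parameters. What the generator does **not** emulate, and what passing tests
therefore cannot show about laboratory data: viscoelastic rate dependence
and stress relaxation, post-peak softening and progressive tearing,
anatomical-site and donor covariates, grip slippage and strain measurement
error (noise is on force only), and any correlation between geometry and
material parameters.

Reproducibility: the study seed feeds a seed tree (one child per
population, one grandchild per specimen plus one for parameter draws), so
identical config + seed reproduces every array bit for bit and records are
independent of how many populations precede them only through their seed
path.

## Problem sizes and runtimes

The default study is 404 specimens × 200 points; extraction (404 fits)
takes a few seconds and a full pipeline run under ten seconds on one core.
Monte-Carlo calibration checks use 10⁴ decision-tree replicates (tens of
seconds) and 10⁵ vectorized t-test replicates for the power oracle. These
sizes make every stage's statistical behavior measurable while keeping a
complete run interactive.

## Known limitations

* The decision tree's routing (normality → variance/shape → final test) is
  reconstructed from a prose description; other flowcharts are conceivable,
  and the median-centered KS step is this package's interpretation.
* The generator's six populations share one noise model and one geometry
  population; real studies have batch structure the generator lacks.
* The sample-size search reproduces desktop-calculator outputs by
  construction (rounded allocation, 10⁻⁴ power tolerance); with a strict
  power threshold its answers grow by one specimen near the boundary.
* Contribution shares are a linear-model attribution; they do not measure
  marginal univariate separations and will differ from them whenever
  features are correlated.
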