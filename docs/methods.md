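# Methods

## Models

**Standard arm.** Binary outcome $y_i\in\{0,1\}$ (hypertension), logit link
$\mu_i = \mathrm{logit}^{-1}(x_i^\top\beta)$, fitted by IRLS with
step-halving so the deviance never increases across iterations.
Convergence means the score $X^\top(y-\hat\mu)$ vanishes to $10^{-10}$ in
the max norm.  No penalisation anywhere: (quasi-)complete separation is
detected by a coefficient exceeding 30 in absolute value and reported via
the `converged` flag; downstream interval code refuses such fits rather
than printing meaningless Wald limits.

**Robust arm.** The Mallows-type quasi-likelihood estimator for binomial
regression.  Its estimating function replaces each observation's quasi-score
contribution $(y_i-\mu_i)x_i$ by

$$\nu(y_i;\mu_i)\,w(x_i)\,\mu_i' - a(\beta),\qquad
\nu(y;\mu)=\frac{\psi_c\!\big((y-\mu)/\sqrt{V}\big)}{\sqrt{V}},\quad V=\mu(1-\mu),$$

with $\mu_i'=\mu_i(1-\mu_i)x_i$ (logit link), Huber $\psi_c$, leverage
weights $w(x_i)=\sqrt{1-h_{ii}}$, and the correction
$a(\beta)=\frac1n\sum_i E[\nu]\,w(x_i)\,\mu_i'$ that restores Fisher
consistency after truncation.  Because $\nu\,\mu' = \psi_c(\varepsilon)\sqrt{V}\,x$,
the whole equation is $\sum_i[\psi_c(\varepsilon_i)-E\psi_c(\varepsilon_i)]\,w_i\sqrt{V_i}\,x_i=0$,
which is solved by a hybrid Powell root-finder started at the IRLS solution
(fallback: zero start).  For binary data the expectation is the exact
two-outcome sum — no quadrature is needed anywhere in the score.

With $c\to\infty$ and $w\equiv1$ the equation is the ordinary logistic
score, so the estimator reduces to the MLE; with leverage weights active
the $c\to\infty$ limit is a leverage-weighted score equation, deliberately
not the MLE.  The tests pin both facts.

**Variance.** Sandwich $\tfrac1n M^{-1}QM^{-\top}$; $M$ is the numerical
Jacobian (central differences, step $10^{-6}$) of the mean estimating
function — the Huber kinks make the analytic derivative piecewise, and the
finite-difference route is exact to first order away from the measure-zero
kink set — and $Q=\frac1n\sum_i E[\Psi_i\Psi_i^\top]$ under the fitted
Bernoulli model.  At $c=10^6$ on clean data the sandwich standard errors
agree with Fisher-information ones to well under 5%.

## Quasi-deviance in closed form

Nested robust fits are compared by

$$\Lambda_{QM}=2\sum_i\Big[Q_M(y_i,\hat\mu_i)-Q_M(y_i,\dot\mu_i)\Big],\qquad
Q_M(y_i,\mu_i)=\int_{\tilde s_i}^{\mu_i}\nu(y_i,t)\,w_i\,dt-\frac1n\sum_j\int_{\tilde t_j}^{\mu_j}E[\nu](t)\,w_j\,dt,$$

with $\tilde s_i$ the root of $\nu(y_i,\cdot)$ and $\tilde t$ a root of
$E[\nu](\cdot)$.  Both models use the full-model leverage weights so the two
sums weight observations identically.  For a binary outcome:

* $\tilde s_i=y_i$ exactly, and the integrands are piecewise elementary.
  The truncation boundary $|y-t|=c\sqrt{t(1-t)}$ is a quadratic in $t$ with
  roots $\tau_1=1/(1+c^2)$ (for $y=1$) and $\tau_0=c^2/(1+c^2)$ (for
  $y=0$); away from it $\nu(1,t)=1/t$, $\nu(0,t)=-1/(1-t)$, and on the
  truncated side $\pm c/\sqrt{t(1-t)}$, whose primitive is
  $\pm 2c\,\arcsin\sqrt t$.  All integrals are therefore evaluated by exact
  piecewise antiderivatives, matched for continuity; the unit tests
  cross-check them against adaptive quadrature split at the breakpoints.
* $E[\nu]$ rises from $-1$ at $t\to0$ to $+1$ at $t\to1$ and, for
  $c\ge1$, is identically zero on the whole central interval
  $[\tau_1,\tau_0]$ — the root $\tilde t$ is not unique, but the integral
  $\int_{\tilde t}^{\mu}E[\nu]$ is the same for every root, so the
  implementation anchors at $\tilde t=\tfrac12$, which is a root for every
  $c>0$.  No root-finding is performed.

$\Lambda_{QM}$ is referred to $\chi^2_1$ for the per-variant scan.  This is
a working reference: the exact asymptotic null of this test family is a
weighted chi-square.  The approximation is good enough that permuted-
phenotype scan p-values pass a Kolmogorov–Smirnov uniformity check for both
the standard and the robust scan (tested at 200 variants, n = 300).

## Influence diagnostics

Cook's distances use *exact* leave-one-out refits (never the one-step
hat-matrix shortcut): $D_i=\sum_j(\hat y_j-\hat y_j^{(i)})^2/(q\cdot\mathrm{MSE})$
where the full-model prediction vector is compared against the vector
predicted after refitting without observation $i$.  Two conventions are
config-exposed because the definitions admit both readings and they only
rescale every $D_i$ by a common factor (the influence ordering is
invariant): MSE as $\frac1n\sum(y_j-\hat y_j)^2$ (Brier-type, default) or
with an $n-q$ denominator, and $q$ as the number of estimated coefficients
including the intercept (default; $q=2$ for the age baseline) or excluding
it.  The flagging threshold defaults to $D_i>0.05$.

Exclusion impact reports the percent change of the *excess risk*
$(\mathrm{OR}-1)$ per year of age, i.e.
$(\mathrm{OR}_{\text{excl}}-1)/(\mathrm{OR}_{\text{ref}}-1)-1$, for both
estimators.  A structural note: for a binary outcome the Pearson residual
of an elderly unaffected individual is bounded by $\sqrt{\mu/(1-\mu)}$
(≈ 1.5–2 at realistic fitted risks), so Huber truncation at $c=1.345$
discounts such observations only mildly and the robust fit is *not*
systematically less exclusion-sensitive for them.  The young affected
outlier is the opposite case ($|\varepsilon|\approx\sqrt{(1-\mu)/\mu}\gg c$):
there the robust estimator's exclusion sensitivity is reliably smaller, and
that is the property the test suite asserts.

## Baseline construction and filters

Filters run in the fixed order (a) first measurement with complete
hypertension and age (earlier incomplete visits are skipped — "first
available" means first *complete*); (b) polymorphism: the non-majority
genotypes must be carried by at least two individuals (removing
monomorphisms and singletons); (c) individuals with strictly more than 5%
missing genotype calls are excluded; (d) variants with any remaining
missing call are removed.  Because (c) can turn a variant monomorphic, (b)
is re-checked once at the end so the output invariant (no monomorphic
variant) and filter idempotence both hold.  Missing gender/smoking never
drop an individual; they only exclude the pair from the χ² screen.  The
screen uses Pearson's χ² without continuity correction, inclusion at
p < 0.05 strictly; age is pre-committed to the model and never screened.

## Evaluation

LOOCV evaluates a *fixed* model formula (age + the scan-selected SNP);
per-fold re-selection is off by default and available for honest-CV
experiments.  Classification is positive iff the predicted probability is
≥ the cutoff; the cutoff-1.0 row follows the classify-none convention
(sensitivity 0, specificity 1, net benefit undefined/NaN).  Net benefit
NB(c) = sens·π − (1−spec)(1−π)·c/(1−c) equals the prevalence exactly at
c = 0 and never exceeds it.  AUC is trapezoidal over all distinct
thresholds, identical to the Mann–Whitney pair-counting probability with
ties at ½.  IDI is the difference of discrimination slopes (robust minus
standard).  Age quartile cutpoints use linearly interpolated empirical
quantiles.

## Synthetic cohort

The generator emulates a small unrelated-cohort genetic study: default 130
individuals × 500 variants, genotypes under Hardy–Weinberg equilibrium
with MAF uniform on [0.05, 0.5] (causal variants at MAF 0.3), ages from a
truncated normal (mean 52, sd 15, range [20, 95], median ≈ 52), disease
from a logistic model with age OR 1.085/year and one causal SNP of log-OR
0.8.  The intercept is calibrated deterministically (quadrature over the
age distribution × HWE enumeration, Brent root-finding) so the expected
prevalence is 33%; across seeds the realized prevalence averages 0.33 with
per-cohort binomial spread.  Gender and smoking are outcome-independent so
the covariate screen correctly excludes them.

Outlier mechanisms: `label_flip_extreme_age` (default) sets the three
oldest individuals normotensive and the youngest hypertensive;
`extreme_age_injection` additionally relocates them to the boundary of the
age range, making the planted records strictly more extreme than any
natural draw — the mechanism of choice for influence-recovery experiments,
because the Bernoulli phenotype draw itself produces occasional young
affected individuals that are genuine outliers of the identical phenotype
and otherwise compete with the planted ones.  Missingness is injected as
independent background dropout (default rate 0.001 per call, feeding the
per-variant filter) plus a constructed 2% of individuals with 8% of calls
masked (guaranteed above the 5% exclusion threshold, positions
randomized).  Longitudinal copies (up to 4) advance age one year per
visit, with a tenth of first visits missing the age so the
first-available-measurement rule is exercised.

What the generator does *not* emulate: linkage disequilibrium between
variants (dosages are independent), family structure or cryptic
relatedness, measurement error in age, genotype calling error, and
longitudinal phenotype change beyond deterministic aging.  Passing
recovery tests therefore demonstrates correctness of the estimators and
diagnostics under an idealized cohort, not performance on real pedigree
data or LD-structured genomes.

## Problem sizes and numerical choices

Simulation-backed tests use cohorts of 130–500 individuals, scans of
200–500 variants, and 20–200 seeded replicates — sizes at which every
statistical property under test is already identifiable.  The scan
power benchmark (one causal SNP of log-OR 0.8 at MAF 0.3 among 200 nulls,
n = 300) keeps every unstated effect null (balanced prevalence, zero age
coefficient, age retained in the baseline as a null covariate): with the
full cohort architecture active, case-control imbalance lowers the
non-centrality enough that no scan could rank the signal first at the
tested frequency, so the benchmark isolates exactly the stated signal.
Linear predictors are clipped at ±30 before the inverse logit (a pure
overflow guard), fitted probabilities at $10^{-12}$ from the boundary
inside the robust score, and scan ties break deterministically by position
then variant id.  All randomness flows through seeded numpy Generators;
every pipeline output is byte-identical under a fixed seed and config.

## Known limitations

* The χ²₁ reference for $\Lambda_{QM}$ is approximate (see above).
* The Huber constant is not identifiable from this package's data; c = 1.345
  is the conventional 95%-efficiency default and all robustness properties
  are additionally exercised at c ∈ {1.2, 2.0}.
* Whether leverage weights $w(x_i)$ or $w\equiv1$ should be used is a
  modelling choice; both are supported (`use_leverage_weights`), default
  on, matching the Mallows form of the estimating equation.
* Multi-allelic variants, imputation, LD-aware selection and
  multiple-testing correction are out of scope.
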