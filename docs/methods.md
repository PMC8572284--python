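# Methods

`raschval` implements a complete structural-validity workflow for polytomous
patient-reported outcome scales under the partial credit model (PCM), the
Rasch-family model for ordered categories. This note records the model, the
estimators, the diagnostics, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Model

Person *n* with ability θ_n (logits) answers item *i* with categories
0..m_i and thresholds δ_i1..δ_im on the same logit scale:

    P(X_ni = x | θ_n) = exp( Σ_{k ≤ x} (θ_n − δ_ik) ) /
                        Σ_h exp( Σ_{k ≤ h} (θ_n − δ_ik) ),

with the empty sum for x = 0 equal to 0. The package's native sign
convention is "higher θ → higher expected item score"; for
limitation-scored instruments that means more limitation. Some Rasch
software prints the opposite orientation for item locations (negative =
harder); that is a display convention and can be obtained by negating the
location column of any report table. A single internal convention avoids
sign errors in the diagnostics.

Key identities used throughout: the conditional score variance equals the
slope of the item characteristic curve, Var[X|θ] = dE[X|θ]/dθ, and the raw
total over complete responses is sufficient for θ.

## Estimation

**Items.** Thresholds are estimated by marginal maximum likelihood (MML):
the latent ability is integrated over a normal distribution with
Gauss–Hermite quadrature (41 nodes by default), and an EM algorithm
alternates expected category-count tables with per-item Newton updates of
the thresholds. The latent mean and SD are estimated alongside; the model is
identified by re-centring item locations (mean threshold per item) to sum to
zero, the latent mean absorbing the shift. Convergence is declared when the
relative change of the marginal log-likelihood drops below 1e-8 (default
cap 500 iterations, both configurable). A small phantom-person mass
(`smoothing`, default 0.05 persons spread over nodes and categories) keeps
thresholds finite when a category has no observations; this is routine for
testlet super-items with dozens of categories and is negligible at any
sample size where calibration is meaningful. Threshold standard errors come
from the empirical (outer-product) information of the marginal per-person
scores, computed with extreme-scoring persons excluded; the near-null shift
direction of this matrix (a consequence of the free latent mean) is handled
by a pseudo-inverse.

Some commercial Rasch software instead uses a proprietary pairwise
conditional algorithm. All downstream statistics here are defined on
model-expected scores and variances at the estimated parameters, so they are
agnostic to the calibration algorithm; estimates may differ from other
software by small shifts.

**Persons.** Given the calibration, abilities are Warm's weighted likelihood
estimates (WLE): the maximum-likelihood score equation plus the
bias-correction term I′(θ)/2I(θ), with I(θ) = Σ_i Var[X_i|θ]. Zero and
perfect raw totals, where the ML estimate diverges, are flagged extreme and
measured at the ML solution of the total pulled inward by 0.3 score points
(configurable). SE(θ̂) = I(θ̂)^{−1/2}. Persons with identical observed-item
patterns and totals share one numerical solve.

## Fit diagnostics

**Standardized residuals.** z_ni = (x_ni − E[X_ni|θ̂_n]) / √Var[X_ni|θ̂_n],
computed only for observed cells; cells with numerically zero conditional
variance are set missing with a warning.

**Residual shrinkage and "model df".** Because θ̂_n is estimated from the
same responses, residuals are shrunk: the share of person *n*'s information
carried by item *i* (the leverage h_ni = Var_ni / Σ_j Var_nj) is removed
from each cell's residual variance. Ignoring this makes every null
diagnostic conservative or biased, so it is built into the statistics:

Because the raw total is sufficient for θ in the PCM, the exact conditional
distribution of each response given the person's total,
P(x_i = x | r) ∝ p_i(x)·γ_{−i}(r − x), is available from the
elementary-symmetric-function (polynomial product) recursion; its moments
are what centre the diagnostics:

* **Item-trait interaction χ².** Persons are grouped into ability-ordered
  class intervals (default 3 strata for n ≤ 150, else min(10, n/50); ties
  kept together, strata under 10 persons merged toward a neighbour). For
  each item, each stratum contributes (Σ of x − E[x|r])² / Σ Var[x|r]; the
  per-item df is (number of non-empty strata − 1), and the total statistic
  sums items. Conditioning on the total matters: with expectations taken at
  θ̂ instead, the statistic is systematically off-centre — mildly
  conservative at 10 items and catastrophically anti-conservative at 2
  (a true-PCM two-super-item null rejected essentially always). In the
  conditional form the 10-item null mean matches its df with the 5%
  rejection rate inside the binomial band, while few-item analyses are
  conservative (threshold counts approach the sample size and overfit the
  conditional splits), which errs toward *not* declaring misfit.
* **Item fit residuals.** The sum of squared standardized residuals per item
  is moment-matched against Σ E[z²|r] and Σ Var(z²|r) from the same
  conditional distributions, then mapped to an approximate N(0,1) scale by
  the Wilson–Hilferty cube-root transform of the equivalent scaled
  chi-square. |fit residual| > 2.5 flags misfit; per-item χ² p-values are
  additionally judged at the Bonferroni level 0.05/I (0.0017 for 29 items).
* **Person fit residuals.** Same construction across a person's items; the
  mean Σ_i E[z²|r] is exact, the variance uses the leverage approximation
  Σ (E[z⁴]−1)(1−h)² (the exact route would need every pairwise joint
  distribution). Null mean ≈ 0.02, SD ≈ 1.1 in simulation. Persons beyond
  ±2.5 can be removed (refused if fewer than 10 would remain);
  re-application with the same estimates is idempotent.

**Threshold ordering.** An item is disordered when its threshold vector is
not strictly increasing; category-probability curve data on a θ grid are
exported for plotting. For ordered items every category is modal somewhere
on the continuum.

**PSI.** Person Separation Index = (Var(θ̂) − mean SE²)/Var(θ̂) over
non-extreme persons; ≤ 1, may be negative for uninformative data and is
reported as-is.

## Residual structure

**Local dependence (Q3).** Pearson correlations of residuals on
pairwise-complete cells (≥ 20 pairs by default); pairs more than 0.2 above
the mean off-diagonal correlation are flagged, sorted descending. The mean
is used as the reference because residual correlations have a negative
null expectation (≈ −1/(I−1)) once θ is estimated.

**DIF.** Per item and covariate, a two-way ANOVA of residuals on group,
class interval, and their interaction, with type-III (marginal) tests via
sum-to-zero contrasts so unbalanced groups are tolerated (statsmodels OLS +
anova_lm). The group main effect is uniform DIF, the interaction
non-uniform; flags use the Bonferroni level 0.05/I per covariate.

**Unidimensionality t-test.** PCA of the residual correlation matrix
(pairwise-complete, symmetrized; loadings from the first eigenvector,
deterministically oriented; zero loadings to the positive set). Items split
by loading sign; person abilities are re-estimated on each subset with the
full-calibration thresholds anchored; per person
t = (θ̂₁ − θ̂₂)/√(SE₁² + SE₂²) against a normal reference (df treated as
infinite, matching the practice in this literature). The scale passes when
the significant fraction is ≤ 5% or the Wilson 95% lower bound is ≤ 5%; both
numbers are reported because published usage is ambiguous between them. The
test proceeds whenever both sign groups are non-empty — two single-item
super-items are a legitimate and common configuration — with a warning when
a side has one item.

**Shared variance.** The fraction of common non-error variance between two
ability estimates is the disattenuated squared correlation
r²/(rel_A·rel_B), rel = (Var − mean SE²)/Var, clipped to [0, 1]. This is a
documented substitute for the unpublished "% common variance" computation of
commercial software and is treated as directional, not as a reproduction
target.

## Ordinal-to-interval conversion

For complete responses the raw total is sufficient, so each total r maps to
the θ solving TCC(θ) = r (monotone root-finding, tolerance 1e-8); extreme
totals use the 0.3 adjustment. The scaled column is the affine map of θ
anchored exactly to 0 at raw 0 and 100 at the maximum; the adjustment
affects only the curvature of the extreme θ entries, never the anchors.
Interior values of any published table embed that study's item parameters
and cannot be reproduced without its raw data; the machinery is validated by
monotonicity, anchor, and TCC round-trip invariants instead.

## Synthetic data generator

The generator draws from a generalized PCM with three violation knobs, each
paired with the diagnostic that should detect it: person-specific normal
testlet effects (local dependence → Q3), uniform DIF offsets (→ residual
ANOVA), and discriminations a_i ≠ 1 (item misfit → fit residuals; a < 1
tends positive). With all knobs neutral it reduces to a pure PCM, tying
generator and estimator together as mutual oracles.

The DASH-like preset emulates a realistic administration of a 30-item
upper-extremity scale in an outpatient sample: n = 109; five categories per
item; item locations spread −1.4..0.9 logits with unit threshold spacing;
an activity cluster (items 1–20) and an impairment cluster (items 22–30)
with testlet-effect SD 0.9 each; three under-discriminating impairment
items (26, 29, 30 at a = 0.5–0.6 — symptom items routinely misfit on this
instrument); an optional item 21 with 54% missingness; covariate marginals
57.8% male, median-split age, 36.7% surgical, 66.1% dominant side. The
testlet SD was set so the preset lands in the regime such studies report:
initial total χ² around three times its df with dozens of elevated residual
pairs, yet accommodated by two testlets (a two-super-item analysis whose χ²
has df 4 at n ≈ 100 and is non-significant most of the time), with PSI
decreasing when the dependence is absorbed. Features of real data the
generator does not emulate: item-specific category usage styles,
non-normal ability distributions, structured (non-random) missingness
beyond the optional item, and correlated covariates. Passing tests
therefore demonstrate internal coherence of the method under its own
assumptions plus power against the planted violations — not agreement with
any particular patient sample.

## Problem sizes and numerical choices

Simulation-based checks use n = 500–1000 persons and 10–20 items with
fixed seeds; null calibration uses 100–200 replicates; power checks 10–20
replicates; the three-run workflow n = 109 as in the preset. Brent
root-finding tolerances are 1e-10 (person measurement) and 1e-8 (TCC
inversion); EM tolerance 1e-8 relative log-likelihood; quadrature 41
Gauss–Hermite nodes. Ties in ability strata stay in one stratum; strata
empty for an item fold into their neighbour for that item's χ². Degenerate
inputs (single observed category, all-missing persons, single-level
covariates, zero estimate variance) raise errors naming the offender.

## Known limitations

* MML with a normal latent is a modelling choice; heavy-tailed or skewed
  ability distributions bias the latent SD and, mildly, the thresholds.
* The person fit residual's moment approximation is leverage-based, not
  conditional-exact; its null SD is slightly below 1.
* The DIF ANOVA treats residuals as exchangeable within group × stratum
  cells; with very small cells the interaction test is unstable (warned).
* The χ² calibration was verified at 10–29 items and n = 100–1000; very
  long tests or tiny samples may drift.
* Testlet super-items with many categories rely on the phantom-mass
  smoothing for finiteness; their individual threshold estimates are noisy
  even though the super-item's expected-score curve (all that the
  diagnostics use) is stable.
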