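# Methods

## The demand model and its fit

The exponential demand equation log10 Q = log10 Q0 + k(e^(−αQ0C) − 1) is
fitted per subject × substance by nonlinear least squares on
log10-transformed consumption, with k held fixed.  Zero-consumption
sessions (the terminal session produced by the "failed to earn one
reinforcer" stopping rule) are dropped before the log transform by
default; replacing zeros with a small positive constant is available as an
option (`FitConfig.zero_policy`).  At least three usable points are
required; fewer raises an explicit error, and solver non-convergence is
returned as a flagged result, never silent NaN.

Initialization and bounds: Q0 starts at the consumption observed at the
lowest price, α at 1e−3, both bounded below at 1e−12.  These choices are
robust for decaying curves and make fits reproducible; solver tolerances
default to 1e−12.  R² is computed on the log10 scale actually fitted
(1 − SSE/SST over the used points), not on raw consumption.  A series
with (numerically) zero log-consumption variance is a flat curve: α
collapses to its lower bound, the fit is exact, and the result is flagged
`flat`.

### Choosing k

Essential values are comparable only under a shared k, so k is selected
once per analysis, globally across substances (per-substance k is possible
by calling `choose_k` on subsets, but the global default is what makes the
cross-substance EV comparisons meaningful).  The default policy sets
k = (span of log10 mean consumption over all substance × price cells with
positive mean) + 0.5; averaging across subjects first keeps a single noisy
session from dictating the span.  Alternatives: a fixed user value, or a
joint nonlinear fit in which k is one extra parameter shared across all
curves (`shared_nls`).  Note that α trades off against k — fits of the
same data under different k give different α — which is exactly why one k
per analysis is enforced.

### Derived indices

EV = 1/(100·α·k^1.5).  Omax/Pmax are empirical by default: expenditure
price × consumption is maximized over the observed prices, ties broken
toward the lower price (a conservative estimate of the inelastic range).
A model-based Pmax is provided as the price at which the point elasticity
d log10 Q / d log10 C = −k·ln10·u·e^(−u) (u = αQ0C) first reaches −1,
found by Brent root-finding of k·ln10·u·e^(−u) = 1 on u ∈ (0, 1] — the
ascending branch, where expenditure peaks.  Two caveats are inherent to
the exponential form: no unit-elasticity point exists when k·ln10 ≤ e
(k ≲ 1.18), and because modeled consumption has a floor of Q0·10^(−k),
expenditure rises again at very high prices, so the empirical Pmax of a
long, shallow series can sit at the last observed price.  Both are
properties of the model, not of the implementation.

### Consumption entering the fit

The price variable is the FR requirement itself; conversion from earned
reinforcers to dose/kg happens upstream (in data preparation or in the
generator).  Where a price was visited repeatedly, the value entering the
fit is the last session at that price — the design escalates price between
sessions, so the last session is the stable one; a mean-based preparation
can be supplied instead since the fitter takes whatever series it is
given.

## The synthetic cohort

The generator emulates the statistical structure the analyses assume; its
defaults are one fixed description of a study and are not tuned per run.

* 19 subjects, four substances, k_true = 2.  Four subjects lose their
  nicotine data (catheter-failure analogue), reproducing the unequal
  regression df across substances that real studies show.
* Q0 and α are lognormal per substance (positivity and right skew typical
  of demand parameters).  Median Q0: sucrose 3.0, sweetened ethanol 1.5,
  ethanol 1.0 g/kg, nicotine 1.5 mg/kg per 12-h session; median α:
  5e−4, 2e−3, 5e−3, 1e−3 respectively (ethanol most elastic, sucrose
  least), with log-scale sds 0.30 (Q0) and 0.50 (α).
* Cross-substance dependence is imposed on log α only (the index the
  cross-substance analyses target), via a multivariate normal with unit
  diagonal correlation: 0.45 (sucrose–sweetened ethanol), 0.60 (sweetened
  ethanol–ethanol), 0.70 (ethanol–nicotine); other pairs independent.
  Other indices inherit correlation through the model.
* Sessions: consumption = 10^(model log10 + N(0, 0.05)); earned
  reinforcers = floor(consumption/dose) with doses 0.06, 0.03, 0.02 g/kg
  per 5-s sipper access and 0.03 mg/kg per infusion (the nicotine value is
  the standard unit infusion dose; the liquid per-access doses are
  explicitly arbitrary — no per-access volume is published for this
  design — chosen so that the elastic substances stop within the ladder).
  The ladder truncates at the first price earning < 1 reinforcer and that
  zero session is recorded; the fit's zero policy then handles it, keeping
  generator faithful and fitter explicit.
* Withdrawal indices (5 elevated plus-maze + 5 open-field metrics) are
  linear in the subject's true ethanol EV with Gaussian noise; slopes are
  parameterized by target correlations (−0.67 … +0.70, locomotion
  negative, freezing positive, open-arm/center weak) and marginal sds, so
  the association analyses have a known signal to recover.  Baseline
  tables are EV-independent with higher locomotion/lower freezing means,
  giving the paired tests a known direction.
* BEC = 10 + 60·volume + subject intercept (sd 12) + N(0, 28) over two
  tests per subject, volume ~ U(0.3, 2.0) g/kg — a moderate, realistic
  marginal R².
* PR co-administration: log responses = log(base) + 1.0·(log EV −
  mean log EV) + subject effect (sd 0.30) + session noise (sd 0.20), times
  a condition multiplier; base 200 (ethanol) / 250 (nicotine) presses.
  Default multipliers: ethanol responding ×1.5 under FR1 nicotine and
  ×1.4 under noncontingent nicotine; nicotine responding ×0.6 under FR1
  ethanol; all others 1.  The design has exactly seven valid
  primary/secondary combinations (no ethanol-primary with PR-secondary).
* One seed drives six independent child streams (parameters, demand noise,
  missingness, withdrawal, BEC, PR), so identical spec + seed reproduces
  every table byte-for-byte and adding subjects to one stage does not
  shuffle another.

What the generator does **not** emulate: within-session dynamics (totals
only), response-count data for the demand phase, non-lognormal individual
differences, floor/ceiling artifacts of real assays, or dependence between
withdrawal noise terms.  Passing recovery and calibration tests on this
generator therefore shows the estimators and tests are correct and
well-calibrated under the assumed structure — not that real data satisfy
that structure.

## Inferential procedures

* Simple regressions are computed in closed form on z-scored variables:
  β = Pearson r, R² = r², F = t² on (1, n−2) df.  Standardization is a
  deliberate choice (it makes β magnitudes comparable across outcomes);
  missing subjects are dropped pairwise, so df varies by row.
* Condition comparisons fit a per-subject random-intercept Gaussian model
  to the mean of the last two sessions per combination (the earlier
  sessions are protocol acclimation), by maximum likelihood — ML, not
  REML, because the compared models differ in fixed effects — and test by
  likelihood-ratio χ² with df = #conditions − 1.  Contrasts against the
  substance-alone baseline are Wald z tests, reported raw and
  Holm-adjusted (the main tables elsewhere report raw p; Holm columns are
  appended everywhere as extras).  An optional log1p transform of
  responses is available; untransformed is the default.  The two-factor
  omnibus uses sequential LRTs (substance, then condition, then the free
  cell-means model); interaction df comes from the parameter-count
  difference, which correctly yields 2 for the seven-cell design.
* The BEC regression is the same random-intercept LRT with a marginal R²
  (fixed-effect variance over total); with one measurement per subject the
  random intercept is unidentified and the routine falls back to OLS with
  a logged notice.
* Breakpoints consume a session's total responses greedily along the
  15-step ratio sequence; a ratio whose requirement is exactly exhausted
  counts as completed.  Response totals, not breakpoints, are the primary
  dependent measure.

## Numerical and degenerate-input choices

Monotone strictly-increasing prices ≥ 1 are enforced at construction;
non-finite inputs are rejected everywhere.  All-zero consumption series
are flagged degenerate (Omax 0 at the lowest price).  Ill-conditioned
multiple-regression designs warn (condition number > 1e6) but keep the
fit.  The permutation and Monte-Carlo tests in the suite are seeded and
the hypothesis property tests derandomized, so the suite is deterministic.

## Problem sizes

Calibration runs use 500 simulated studies for the type-I check (20
subjects each) and 200 for power (15 subjects) and correlation-detection
(19 subjects) checks; parameter-recovery uses 200 simulated subjects.
These sizes give binomial/Monte-Carlo error comfortably below the margins
being asserted while keeping a full run of the suite and the acceptance
script in the low minutes on a single CPU.

## Known limitations

Gaussian LMEs on raw response totals are mildly misspecified when session
noise is multiplicative (the generator's lognormal noise); the measured
type-I error of the condition LRT (~0.05–0.07 at 20 subjects) reflects
both this and small-sample LRT optimism.  The exponential demand model's
consumption floor (see above) makes empirical Pmax of near-flat curves
sit at the ladder end.  Cross-price/cross-commodity models and
within-session demand are out of scope.
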