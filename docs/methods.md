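# Methods

## The null model

A checkerboard combination experiment exposes a system (an enzyme, a cell
line, an organism) to a full factorial grid of two compounds' serial
dilutions. Each compound alone follows a four-parameter log-logistic
(Hill) marginal curve

    R_j(c) = b + (m_j - b) * o_j(c),      o_j(c) = 1 / (1 + (i_j / c)^h_j),

with a baseline `b` shared by both compounds (it is the readout of the
untreated system), maximal effect `m_j`, EC50 `i_j > 0` and Hill
coefficient `h_j > 0`. Classical Loewe additivity views the assay as a
single-step enzymatic reaction in which compounds compete for one binding
site; the occupancy `o` of a dose combination solves the isobole equation

    sum_j (c_j / i_j) * (1/o - 1)^(1/h_j) = 1.

The left side is continuous and strictly decreasing in `o` on (0, 1), from
+inf to 0, so the root exists and is unique whenever any dose is positive;
it is found by 100 iterations of vectorized bisection on
`o in [1e-12, 1 - 1e-12]` (interval width < 1e-30, i.e. machine precision).
Compounds dosed at zero drop out of the sum.

Classical Loewe maps occupancy to readout with a single shared maximum and
therefore cannot describe combinations whose marginals plateau at different
levels. The generalization implemented here keeps the occupancy equation
untouched and blends the compound-specific scalings by the fraction of
bound enzyme each compound accounts for:

    r = b + o * sum_j (m_j - b) * f_j,
    f_j = (c_j / i_j) * (1/o - 1)^(1/h_j),     sum_j f_j = 1.

Partial agonists (|m_j - b| smaller), neutral antagonists (m_j = b; the
compound competes for occupancy but contributes nothing to the readout sum
-- deliberately not special-cased away) and inverse agonists (m_j on the
opposite side of b) are all admissible. When all `m_j` coincide the
prediction reduces exactly to classical Loewe, and a compound combined
with itself reproduces its own marginal curve at the total dose (sham
self-additivity) -- both properties are enforced by the acceptance suite
against independent oracles (a direct root-finding solution of the
readout-form classical Loewe equation, and the closed form
`o = S/(1+S)`, `S = sum c_j/i_j`, for unit Hill coefficients).

No clamping is applied when compounds pull the readout in opposite
directions: the predicted readout is the occupancy-weighted blend of the
`m_j`, wherever that lands.

## Marginal fitting

Both marginal curves of a pair are fitted jointly by non-linear least
squares over 7 free parameters (one shared `b`, plus `m_j`, `log i_j`,
`h_j` per compound) with `scipy.optimize.least_squares` (trust-region
reflective, analytic Jacobian, xtol=ftol=gtol=1e-12). Untreated wells
enter as zero-dose observations of `b`. Fitting `log i_j` keeps the EC50
positive and makes `sd(log EC50)` -- the quality-screen quantity -- a
direct diagonal entry of the Gauss-Newton covariance
`sigma2 * (J'J)^{-1}` evaluated at the optimum.

Numerical choices:

- Initialization: `b` from the untreated (or least-dosed) readouts, `m_j`
  from the top-dose readouts, `i_j` the dose nearest the half-effect,
  `h_j = 1`; two additional starts at `h_j = 0.3` and `3.0` guard against
  slope-dependent local minima. Warm-started single fits are used for
  bootstrap refits.
- Bounds: `h_j in [0.1, 10]`, and `log i_j` within a factor 1e4 of the
  compound's tested dose range. The latter blocks the well-known
  unidentifiability ridge on which `m_j` and `i_j` drift to infinity
  together when the data never approach the plateau; without it a percent
  or so of bootstrap refits crawl along the ridge until the evaluation
  budget is exhausted.
- Degenerate data: a flat readout yields `m_j ~ b` and a singular
  Gauss-Newton Hessian; the curve is flagged non-invertible and the
  log-EC50 standard errors are reported as infinite (failing the quality
  screen) rather than as a spurious zero from a pseudo-inverse.

Residual variance is `sigma2 = SSR / df` with
`df = n_obs - 7`. A pair is analyzable only if `sd(log EC50) <= 10`
(natural log; inclusive comparison) for both compounds -- the threshold is
configurable. An optional natural-log pre-processing of the readouts
(`transform_growth`, default off) is available as a variance-stabilizing
instantaneous-growth-style transform for raw growth data; the synergy
machinery is agnostic to whether it is applied.

Small-sample behavior: at noise around 5% of the dynamic range on a
15-point mono design, the EC50 and Hill estimates show the classic
O(sigma^2) skew of nonlinear least squares (means a few percent high,
medians on the truth); `sigma2` itself is unbiased. The test suite checks
mean-unbiasedness at 2% noise, where the effect is below Monte-Carlo
resolution, and `sigma2` calibration at the full study noise.

## MeanR and MaxR

Let `d` be the length-`k` vector of replicate-averaged observed off-axis
readouts minus null predictions. Its null covariance combines measurement
noise and prediction uncertainty:

    V = sigma2 * diag(1/n_i) + Cp,

where `Cp` is the covariance of the predicted readouts induced by
marginal-parameter estimation error, estimated by a parametric residual
bootstrap: fitted mono-therapy values plus N(0, sigma2) noise, refit,
re-predict (default 100 resamples; at most 10% refit failures tolerated).

- MeanR: `R = d' V^{-1} d / k`, the average standardized deviation.
  Parametric reference: F(k, df) under normally distributed residuals.
- MaxR: `max_i |t_i|` with `t_i = d_i / sqrt(V_ii)`. The (1 - alpha)
  quantile of the null maximum is also the shared per-point threshold, so
  per-point synergy/antagonism calls are multiplicity-controlled by
  construction. Parametric reference: the maximum of correlated standard
  normals drawn from Corr(V), studentized by an independent
  `sqrt(chi2_df / df)` factor.

Call direction: with `decreasing_effect=True` (growth/viability readouts)
an observed readout below the prediction is synergy; the flag flips the
convention for assays where effect increases the readout. The overall call
comes from MeanR; MaxR localizes it. Bootstrap p-values use the
(r+1)/(B+1) estimator, so they are never exactly zero.

### The bootstrap null

When no replicates are available (the default `auto` rule: bootstrap
without replicates, parametric with), null distributions of both
statistics are resampled (default 1000 runs). Each run must reproduce the
full two-level randomness of the observed statistic -- the data noise AND
the noise of the variance estimates standing in the denominator:

1. a deviation vector `d_b ~ MVN(0, V)` (measurement error plus
   null-surface uncertainty);
2. a fresh residual-variance estimate, `sigma2_b = sigma2 * chi2_df / df`,
   scaling the whole of `V` (Cp is proportional to the residual variance
   it was estimated under);
3. a fresh Cp estimate, recomputed from a with-replacement resample of the
   stored bootstrap prediction samples.

Steps 2-3 matter. An 8x8 board with one replicate leaves only ~8 residual
degrees of freedom, so the observed MeanR statistic behaves like
F(k, df), far heavier-tailed than the chi2_k/k obtained by conditioning
on the observed `sigma2`; and the max statistic preferentially selects
points whose (noisy, ~50-resample) Cp diagonal entry happens to be
underestimated. Omitting step 2 or 3 measurably inflates the type-I error
(MaxR reached 18% at a nominal 5% in development runs); with both, the
500-board study gives MeanR 5.0% and MaxR 7.2%, inside the 99% binomial
band around the nominal level.

Degenerate noise-free boards (sigma2 and Cp both at numerical zero) are
reported as additive with statistic 0 and p = 1 when the deviations are at
rounding level, and as decisive rejections otherwise, instead of dividing
two rounding errors.

## Simulator and study sizes

`generate_board` draws one synthetic checkerboard: mono-therapy readouts
from the true curves, off-axis readouts from the null prediction plus an
optional injected additive shift (scalar, or per-point mapping), and
homoscedastic Gaussian noise everywhere -- matching the equal-variance
assumption of the tests. Identical spec + seed gives an identical board.

Default scenario (chosen once as a realistic screen-like setting): 8x8
board, i.e. 7 two-fold dilutions centered on each EC50 plus dose zero;
full agonist (b=0.1, m=1.0, EC50=1, h=1) with a partial agonist (m=0.6,
EC50=10, h=2); one replicate; noise SD 0.045 (5% of the full agonist's
dynamic range). Deviations are injected additively on the readout scale,
the geometry the tests measure.

Study sizes used by the test suite and the acceptance script, sized for a
single-CPU desk run: type-I study with 500 boards (bootstrap null with 200
runs, 50 Cp runs; board `i` gets seed `base + i`); power at deviations
0.02 and 0.05 readout units (~0.44 and ~1.1 noise SDs per point) with 100
boards each; spike localization (one point shifted by 6 noise SDs) over
100 boards.

What the simulator does not emulate: plate/edge effects, outliers,
heteroscedastic or non-Gaussian noise, dose-measurement error, and
time-course structure. Passing tests therefore demonstrate correctness of
the machinery and calibration under the model's own assumptions, not
robustness of the tests on messy real screens.

## Known limitations

- Equal variance across all wells is assumed throughout (as in the tests'
  derivation); there is no unequal-variance extension.
- Calls are per board at the configured alpha; no multiple-testing
  correction across boards of a screen is applied.
- The two-compound CSV/CLI pipeline is the supported surface; the
  occupancy/readout library routines themselves accept any number of
  compounds.
- The exact instantaneous-growth transform used for raw growth time
  courses is assay-specific; the built-in log transform is a configurable
  stand-in and is off by default.
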