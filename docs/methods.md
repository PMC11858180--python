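# Methods

## Design construction

`make_bbd` builds the canonical Box–Behnken run set for 3–7 factors: for
each factor pair (lexicographic order) the four sign combinations
(−−, +−, −+, ++) at ±1 with every other factor at 0, followed by the center
replicates. Coded levels of canonical designs are exact integers −1/0/+1 so
orthogonality checks are exact; arbitrary real coordinates are accepted for
prediction points. An optional seed permutes the run order through one
`numpy.random.Generator`; run ids travel with their settings, so the set of
runs is seed-invariant. Run tables recorded by lab software are ingested
as-is through `design_from_settings` / `read_run_table` — their run order is
an input, not something the package regenerates. `n_center` defaults to 5,
the standard choice for three factors (and the replication used by the
bundled experiment).

Coding is the affine map natural = offset + coded·step with
step = (high − low)/2 and offset = (low + high)/2. The center level is not
required to sit midway between low and high; with asymmetric spacing the
center simply codes off 0. The round trip is exact to floating-point
(tested at 1e−12).

## Model fitting

The full second-order polynomial (1 + k + k(k−1)/2 + k terms) is always
fitted, in coded units, by `numpy.linalg.lstsq` (QR-based; no explicit
normal-equation inversion). No term selection is performed even when
interactions are non-significant: dropping terms would change every partial
sum of squares and the stationary point, and a three-level design estimates
the full model comfortably. A rank-deficient model matrix raises
`SingularDesignError` naming the collinear columns (identified by pivoted
QR). Natural-unit display of coefficients is a presentation transform;
nothing downstream ever refits in natural units.

Report formatting mirrors common practice for these studies: coefficients to
2 decimals (3 when |b| < 0.1, so small interactions keep a leading digit),
R² to 4 decimals, optimum coordinates to 3 decimals, p-values below 1e−4
printed as "<0.0001".

## ANOVA

Term sums of squares are partial (Type III): each single-df term's SS is the
increase in residual SS when that one column is removed and the model refit.
For the orthogonal linear/interaction columns of a 3-factor BBD this reduces
to the closed forms 8b² and 4b², which the tests assert; the quadratic
columns are non-orthogonal to the intercept and to each other, so their
partial SS genuinely require the refit. Each term is tested with
F = MS(term)/MS(residual); the overall model row uses 9 and n−10 df.

Pure error pools the within-group squared deviations over every group of
runs with identical coded settings (groups matched exactly, tolerance 1e−9 —
replicates in a coded design are exact by construction); its df is
Σ(group size − 1). Lack of fit is the remainder of the residual, tested
against pure error. With no replicated runs `lack_of_fit` raises
`NoReplicatesError` and `anova_partition` reports the residual undecomposed.

F-tail probabilities go through the regularized incomplete beta function
(`scipy.special.betainc`); tests verify ≤1e−6 agreement with adaptive
quadrature of the F density and strict monotonicity in F.

## Optimization

The stationary point solves 2Bx = −g, where g holds the linear coefficients
and B has the quadratic coefficients on the diagonal and half the
interactions off it. The symmetric Hessian 2B is classified by
`numpy.linalg.eigvalsh` (symmetric solver, real eigenvalues guaranteed) with
a 1e−10 zero tolerance; condition numbers above 1e12 raise
`RidgeSystemError` and point the caller to `bounded_maximize`. Optimization
always uses full-precision fitted coefficients, never rounded report values.

`bounded_maximize` runs multi-start L-BFGS-B from every corner and the
center of the coded box (default [−1, 1]^k, the experimental region). For a
quadratic over a box this start set reliably covers both the interior and
boundary cases; agreement with a dense 101³ grid oracle to 1e−3 is asserted
in the tests. Stationary points outside the box are reported with
`interior=False` rather than silently clipped — predictions there
extrapolate beyond the data. The pipeline falls back to the box optimum
(with a warning in the report) when the stationary point is non-interior,
a saddle, or a ridge.

`validate_settings` evaluates the model at rounded, bench-achievable natural
settings and reports the gap below the box optimum — the quantity a
confirmation fermentation is compared against.

## Assay statistics

The DNS standard curve is a simple least-squares line
(`scipy.stats.linregress`) of A₅₂₀ on glucose concentration. Activity
conversion divides the glucose read off the curve (mg/mL → µmol/mL via the
180.16 g/mol molar mass) by the reaction time, with a configurable unit
definition defaulting to 1 U = 1 µmol glucose/min. Enzyme-unit conventions
vary between labs, so the definition is an explicit parameter
(`umol_per_unit`); design/ANOVA/optimization operate on already-converted
U/mL responses and are unaffected by it. Negative computed glucose
(absorbance below the intercept) clamps to zero activity with a warning.

Congo-red ranking sorts isolates by descending D/d with ties broken by
strain id, making the ranking a deterministic permutation of its input.
Single-factor screening returns the level with the highest mean activity,
ties to the lower (cheaper) level; its output is the natural center for a
follow-up design's factor definition.

## Synthetic data

`simulate_bbd_experiment` draws responses as truth polynomial + i.i.d.
Gaussian noise on a canonical BBD — exactly the data-generating process the
least-squares fit and the single-variance pure-error ANOVA assume. Defaults
emulate the bundled experiment's conditions: three factors, five center
replicates, and a noise SD of 0.31 U/mL (the square root of its pure-error
mean square) when a noisy truth is wanted. All randomness flows through one
explicitly passed, seeded `numpy.random.Generator`; no global state.
`simulate_response_batch` vectorizes many replicate experiments on one
design for Monte-Carlo calibration checks.

What the generator does *not* emulate — and what passing tests therefore do
not establish about real fermentations: heteroscedastic or non-Gaussian
measurement error, run-order drift or blocking effects, responses whose true
surface is not quadratic, and biological batch effects between replicate
center runs. The lack-of-fit type-I calibration (5 % ± 2 % over 2000
simulated tables) and the coefficient-recovery checks are statements about
the procedure under its own assumptions, not about any particular organism.

## Problem sizes and numerical choices

The bundled 17-run experiment makes every headline statistic deterministic
and sub-second. Monte-Carlo checks use 500 replicates for coefficient
recovery and optimum recovery, 2000 for the lack-of-fit type-I rate, and
10⁴ for the center-replicate variance convergence — sizes at which the
binomial/Monte-Carlo error is well inside the asserted bands while the whole
suite stays in seconds. SS conservation is asserted at 1e−8 relative
tolerance, coding round trips at 1e−12, zero-eigenvalue classification at
1e−10.

Per-coefficient 3-standard-error coverage in the recovery check is asserted
at ≥98 % per coefficient and ≥99 % pooled: normal theory gives 99.73 % per
coefficient, but the joint probability that all ten coefficients land inside
3 SE simultaneously is only ≈97 %, so a joint assertion at 99 % would be
miscalibrated by construction.

## Known limitations

- Only Box–Behnken designs are generated (3–7 factors). Central composite,
  Plackett–Burman and D-optimal designs are out of scope; externally
  constructed designs of any shape can still be analyzed through
  `design_from_settings`.
- Single-response optimization only; no desirability functions or
  steepest-ascent path following.
- Ordinary least squares only; no robust/weighted regression or response
  transforms.
- The ANOVA assumes a single error variance across the design (the pure
  error pools all replicate groups).
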