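# Methods

## The model and the inflation it hides

The four-parameter Sharpe-Schoolfield model describes a thermal performance
curve (TPC) as Arrhenius kinetics gated by reversible high-temperature
enzyme inactivation:

    B(T) = B0 · exp[(−E/k)(1/T − 1/T_ref)] / (1 + exp[(E_D/k)(1/T_h − 1/T)])

The denominator's reciprocal is the fraction of the enzyme pool that is
active at `T`; it is exactly ½ at `T = T_h` and strictly decreasing in
temperature.  Setting `T = T_ref` shows the model's true normalised rate is

    B(T_ref) = B0 / (1 + exp[(E_D/k)(1/T_h − 1/T_ref)])

so `B0` overestimates `B(T_ref)` by the *inflation fold*
`1 + exp[(E_D/k)(1/T_h − 1/T_ref)] ≥ 1`, which equals 2 at `T_ref = T_h`
and explodes as `T_ref` moves past `T_h`.  The package reports the fold and
its conventional log axis `log2(fold − 1)` (zero means `B0` is double the
truth); folds within 1e-15 of 1 report the log axis as `−inf` rather than
raising.

Differentiating `ln B` gives the interior peak: the active fraction at the
peak is `1 − E/E_D`, hence

    T_pk = E_D·T_h / (E_D + k·T_h·ln((E_D − E)/E)),

valid only for `E_D > E` (otherwise a `NoPeakError`, never a silent
number); the closed form is exercised against a brute-force grid/golden-
section argmax in the test suite (≤ 1e-5 K over 500 random parameter
sets).  `E_D = 2E` puts the peak exactly at `T_h`; for `E < E_D < 2E` the
peak lies above `T_h`.

Unbiased alternatives implemented alongside: the Boltzmann-Arrhenius model
(rise-only data; `B(T_ref) = B0` identically), Q10 estimation and
extrapolation (`Q10 = (B2/B1)^(10/(T2−T1))`, algebraically invertible), and
the intrinsic optimum temperature — the highest `T` at which the active
fraction still reaches a chosen level (default 0.99; levels ≤ 0.5 are
rejected as they would sit at or above `T_h`).

## Fitting

Estimation is nonlinear least squares on the linear rate scale with
unweighted residuals, using bounded trust-region least squares (the bounded
variant of Levenberg-Marquardt) with an analytic Jacobian.  Box constraints
`E ∈ (0, 30]`, `E_D ∈ (0, 50]` eV, `T_h ∈ [150, 450]` K, `B0 > 0` keep the
search sane; `E_D > E` is deliberately *not* enforced during the search
(that would bias the SSR) and is only checked when the peak is derived.

Starting values: `E = 0.65 eV` (the canonical biological activation
energy), `E_D = 3 eV`, `T_h` = temperature of the maximal observed rate
+ 2 K, `B0` = the rising-limb rate nearest `T_ref`.  Ten seeded restarts
jitter `B0`, `E`, `E_D` log-uniformly by ±50%; `T_h`, being a location
parameter in kelvin, is jittered additively by ±10 K.  Restarting stops
early once a fit exceeds R² = 0.9999, which cannot be meaningfully
improved.  All failures produce a structured "unfittable" result with a
reason code, never an exception; non-positive rates are dropped and counted
before fitting (the model is strictly positive).

Quality control follows standard TPC meta-analysis practice: a fit is
accepted iff R² ≥ 0.5 and at least 4 observations lie strictly below and
strictly above the fitted `T_pk` (ties at `T_pk` count on neither side;
duplicate temperatures are legitimate replicates).  R² uses total sum of
squares about the mean rate on the linear scale.

`bootstrap_b_at_tref` resamples curve points with replacement, refits
(warm-started from the full-data solution), and takes 2.5/97.5 percentiles
of the replicate `B(T_ref)` values; replicate failures are dropped and
counted, and the interval is flagged unreliable when more than half fail.

`tref_sweep` refits every curve across a reference-temperature range
(default −10…30 °C at the CLI).  Because changing `T_ref` is a pure
reparameterisation, predictions at any probe temperature are invariant
across the sweep — a property the tests assert — while `B0` itself moves.

## The synthetic population and its no-MCA certificate

Each synthetic curve is a negatively skewed beta density: shape parameters
`α ~ N(10, 3)` and `β = α − i`, `i ~ N(4, 2)`; the unit support is mapped
to `[0, j]` °C with width multiplier `j ~ N(25, 4)`; and a height offset
`k ~ N(3, 0.8)` raises every value.  Whole tuples are rejected and redrawn
until `α > β` (negative skew — mode right of centre) and both shapes
exceed 1 (so the density has an interior mode and the analytic peak
`T_pk = j(α−1)/(α+β−2)` is meaningful) with `j, k > 0`.

The density is normalised to **unit peak height** before the offset is
added, so every curve runs from baseline `k` to peak `1 + k`.  This choice
matters: a beta density integrates to 1, so narrow curves are intrinsically
taller, and adding `k` to raw density values couples low-temperature
performance to the thermal optimum — planting a genuine cold-adaptation
signal in a population whose purpose is to contain none.  With unit peak
height the true value at 7 °C is dominated by the independent offset `k`
and the association vanishes to sampling noise.

A population is accepted only with its *no-MCA certificate*: the reference
temperature (7 °C) must lie below the population's minimum true `T_pk`, and
the Pearson correlation between true value-at-7 °C and true `T_pk` must be
non-significant (p > 0.05); otherwise the seed is incremented and the
population regenerated (the accepted seed is recorded, and generation is a
pure function of it).  Default rendering uses 15 evenly spaced points per
curve with no measurement noise — enough for the ≥ 4-points-per-side QC
rule to be meaningful while keeping thousand-curve fits fast.

A second generator produces Sharpe-Schoolfield curves with known parameters
and mean-one multiplicative lognormal noise of chosen CV, for parameter-
recovery and bootstrap-coverage tests.

What the generator does *not* emulate: heteroscedastic or additive
measurement error, unbalanced temperature designs, replicate structure, or
curve shapes outside the beta family.  Passing tests therefore demonstrate
correctness of the estimators and the logic of the bias, not robustness to
every feature of empirical datasets.

## The MCA false-positive experiment

The fitted population (all converged fits with a defined peak; no R²
filtering, mirroring how such simulation studies treat estimates) is split
at `T_pk` = 15 °C into cold- and warm-adapted groups (boundary goes warm).
Two tests are run twice each — on `B0` and on `B(T_ref)`:

1. a two-sample Kolmogorov–Smirnov test between the groups.  D is the
   supremum ECDF distance evaluated at the union of observed points (exact
   under ties); the p-value is the asymptotic Kolmogorov distribution at
   `sqrt(n_a·n_b/(n_a+n_b))·D` (group sizes here are in the hundreds, where
   the asymptotic form is standard);
2. a Pearson correlation with `T_pk`, with a Fisher-z 95% CI and a t-test
   p-value (n − 2 df).

On certified populations the `B0` tests detect "cold adaptation" decisively
(KS D ≈ 0.15–0.23, p ≲ 1e-4; cold-group median `B0` above the warm-group
median) while `B(T_ref)` separates the groups at roughly half the distance
or less — the inflation, not the data, drives the signal.

**Known limitation.**  The Sharpe-Schoolfield curve cannot represent a bell
riding on a flat baseline: fits overshoot the flanks and undershoot the
peak, and the overshoot at 7 °C is slightly larger for curves peaking near
7 °C.  Combined with the certificate rule accepting the first seed with
p > 0.05 (which can leave a residual true correlation of r ≈ −0.05), the
fitted `B(T_ref)` comparison retains a weak spurious signal for many seeds
(KS p < 0.05), even though it is always far weaker than the `B0` signal.
Populations whose certified correlation happens to sit at ~0 show the clean
expected behaviour (D ≈ 0.06, p ≈ 0.35).  The corresponding strict
replication check in `tests/test_acceptance.py` documents this and is
expected to fail until the mismatch is addressed (e.g. by fitting a model
family able to represent baseline performance).

## The conditional inference tree

Fits are labelled by whether `B0` exceeds the peak rate `P_pk` (ties within
1e-12 relative label "below"); predictors are the three differences
`T_pk − T_h`, `T_pk − T_ref`, `T_h − T_ref` in kelvin.  At each node every
predictor is tested for association with the label via the absolute
difference of class means under the permutation null; p-values are
Bonferroni-adjusted across the three predictors, and a node is split only
when the minimum adjusted p falls below `α = 1e-10`.

Because 1e-10 is far below Monte-Carlo resolution, the stopping rule is a
dual criterion: the normal-approximation permutation p must undercut `α`
*and* the observed statistic must exceed every one of 10⁵ Monte-Carlo
permutation statistics (exact enumeration replaces Monte-Carlo for nodes
with n ≤ 10).  The cheap normal approximation is computed first and the
Monte-Carlo confirmation only runs when it could matter — a speed
optimisation that changes no decision.  Split thresholds are searched over
midpoints of consecutive distinct values of the winning predictor,
maximising the standardised two-sample statistic `|p_L − p_R|·sqrt(n_L n_R/n)`;
ties at a threshold route left; nodes smaller than 20 become leaves.
Training is order-invariant (stable sorts) and a pure function of its seed.

Trained on instances from a certified population refitted across a
reference-temperature sweep (−10…30 °C, which populates both label
classes), the tree reaches held-out MCC ≈ 0.84–0.91 with a shallow
structure splitting on a single temperature difference — the
severe-inflation regime is essentially a threshold phenomenon in these
differences, which is the point of exposing the tree alongside the exact
analytic label (`label_fit` agrees with direct `B0 > P_pk` evaluation by
construction, and the tests verify it against a numeric peak).

## Problem sizes and numerical choices

Default experiment sizes: 1,000 curves per MCA population (10 regenerated
populations in the acceptance tests), 15 grid points per curve, 150 curves
× 5 reference temperatures for tree instances, 500 random parameter sets
for the peak-formula cross-check, 100 noiseless curves for recovery, 10⁵
permutations per confirmed node test.  Exponentials are evaluated in
log-space (`logaddexp`) so extreme parameter sets underflow gracefully;
temperatures are kelvin everywhere internally, with °C only at file/CLI
boundaries (+273.15); every stochastic path is seeded and reproducible
bit-for-bit.
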