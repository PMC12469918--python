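# Methods

## Model

The package models whole-brain soluble Aβ42 in Tg2576 mice, `A(t)` in pg
per mg wet tissue over age `t` in months, coupled to a dimensionless
abstract factor `X(t)` standing in for whichever processes (tauopathy,
oxidative stress, inflammation, ...) are in mutual positive feedback with
amyloid:

    dA/dt = basal + V1  · Xⁿ/(K1ⁿ  + Xⁿ) − k2  · A
    dX/dt =         V1′ · Aⁿ/(K1′ⁿ + Aⁿ) − k2′ · X

Production of each variable is a Hill function of the other (ceiling `V`,
half-saturation `K`, coefficient `n`); removal is first order.  The Hill
coefficient is fixed at `n = 2`, the smallest integer for which the model
produces a sigmoidal course, but is carried as a parameter for sensitivity
work.  `basal` is an optional zeroth-order Aβ production term, zero in the
reference parameterization; it is provided so that variants with a linear
basal source can be explored structurally.

The model is phenomenological and organism-level: no monomer/oligomer/
fibril resolution, no spatial compartments, no pharmacokinetics.  `X` has
no committed physiological identity, and its initial value X(1) = 1 is a
scale convention.

## Target data

The fitting target is the published logistic summary of soluble Aβ42
in Tg2576 mice,

    A_logistic(t) = 34 + 2240 / (1 + (t/18)^(−5.9)),

sampled at integer months 1–27.  The typeset form of this curve composes a
natural exponential with a base-10 logarithm; the composition collapses to
the power law above, which is the only reading consistent with a 34 pg/mg
baseline at t = 1 and half-saturation at t = 18.  Only the soluble Aβ42
curve is modeled; insoluble Aβ42 and the Aβ40 fits are out of scope.

## Parameters

| name  | units            | default  | meaning                           |
|-------|------------------|----------|-----------------------------------|
| V1    | pg mg⁻¹ mo⁻¹     | 1.36×10⁶ | ceiling of X→A feedback          |
| K1    | –                | 10.7     | X half-saturation driving A       |
| k2    | mo⁻¹             | 450      | A removal (fixed; ~1.1 h turnover)|
| V1′   | mo⁻¹             | 0.998    | ceiling of A→X feedback          |
| K1′   | pg/mg            | 134.2    | A half-saturation driving X       |
| k2′   | mo⁻¹             | 0.00168  | X removal                         |
| n     | –                | 2        | Hill coefficient                  |
| A(1)  | pg/mg            | 34       | initial Aβ (fixed)                |
| X(1)  | –                | 1        | initial X (fixed, scale choice)   |

The defaults, shipped as `data/tg2576_fitted.yaml`, are the fitted values
rounded to three significant figures.  This rounding matters for the
goodness-of-fit statistic (below).

## Numerical integration

The system is stiff: A relaxes on the 1/k2 ≈ 0.002-month timescale while X
evolves over 1/k2′ ≈ 595 months.  Integration uses `scipy`'s LSODA (which
switches to BDF in the stiff regime) with relative tolerance 1e-8 and
absolute tolerances 1e-10 on A and 1e-12 on X.  Halving the tolerance
changes A(27) by far less than 0.1%.  Tiny negative solver excursions are
clamped to zero inside the right-hand side and in returned trajectories.
Interventions are parameter switches: integration proceeds segment by
segment with (A, X) carried continuously across each switch.  The time
origin is t = 1 month (adulthood); all headline numbers are evaluated on
integer months 1–27.

## Fitting and the log-ratio objective

The objective is `LogErr = Σᵢ |log10(A_pred(tᵢ)/A_target(tᵢ))|` over months
1–27.  The base-10 convention was resolved empirically before the main
build: refitting the target with a base-10 objective reproduces the shipped
parameter set (LogErr ≈ 0.535 at the unrounded optimum), whereas a
natural-log objective does not; the convention is pinned by a regression
test.  Note that the *shipped rounded* parameters score 0.658 against the
target — the difference from the unrounded optimum is dominated by the
rounding of K1′ and k2′, and the objective's sensitivity to it is itself a
useful identifiability diagnostic.

`k2`, `A(1)` and `X(1)` are always fixed.  The five free parameters are
optimized in log space within positive box bounds (default: three decades
either side of the shipped values).  Each start runs a trust-region
least-squares pass on the vector of log10 ratios — a smooth L2 surrogate
that shares the L1 objective's zero and is far better conditioned than
direct search on the kinked L1 sum — followed by a Nelder-Mead polish of
the true L1 objective.  One start sits at the geometric center of the
bounds; the remainder are drawn log-uniformly under the spec seed, making
fits reproducible.  All per-start final errors are reported.

The model is sloppy: near-zero objectives coexist with poorly determined
parameters along some directions, `k2′` above all (the same property that
makes k2′ interventions futile).  Recovery experiments therefore assert
median relative errors across seeded replicates, not worst-case ones, and
synthetic truths are drawn log-uniformly within a factor of 4 of the
shipped values — wide enough to exercise the fitter, narrow enough that the
sampled models remain in the regime where the Aβ course is informative.

## Interventions

A dose is `D = |1 − P/P0|`: production ceilings (V1, V1′) are scaled by
(1 − D) with D ≤ 1; removal rates (k2, k2′) by (1 + D), unbounded above.
Half-saturation constants are not dosed.  Success is A(27) ≤ threshold with
threshold 100 pg/mg by default (a configurable criterion, deliberately
stringent at <1/20 of the untreated final level).  Minimum doses are found
by bisection to a dose tolerance of 1e-3 (reported values are rounded to 2
decimals), relying on the monotone dose response that the test suite
verifies on dose grids.  Default search caps: 1 for production parameters,
2 for k2, 10 for k2′; an intervention that cannot reach the threshold
within its cap is reported infeasible, not an error.

Dose-response surfaces evaluate A(27) on a full grid (default 41×41;
coarser grids are used in tests).  The iso-effect contour A(27) = threshold
is extracted by per-ray bisection — for each grid value of one dose the
other is bisected with fresh simulations, never interpolation — refined to
within 0.5 pg/mg of the threshold, with rays cast along both axes so
contours hugging an axis are resolved.  The optimal combination is the
contour point minimizing the raw Euclidean distance R = √(d1² + d2²) from
the origin; axes are deliberately unscaled even though k2-doses can exceed
1.  Combined interventions share a start time.  The synergy report labels a
combination "synergistic" when both optimal doses fall below half (by
default) of the respective monotherapy minima, and "second intervention
hardly useful" when the optimal point lies on an axis.

## Fixed points and the drift picture

Steady states are found by substituting the A-nullcline
`A = (basal + V1·h(X))/k2` into the X-nullcline and scanning the resulting
scalar function on a log-spaced X grid (2000 points over [1e-6, 10·V1′/k2′])
for sign changes, each polished by bracketed root finding; for `basal = 0`
and n ≥ 2 the origin is appended analytically (both Hill terms and their
slopes vanish there).  Each point is classified from the Jacobian
eigenvalues; non-hyperbolic cases are flagged "degenerate" rather than
forced into a class.

With the fitted parameters the system has three fixed points: a stable
origin, a saddle near A* ≈ 3.3 pg/mg, and a high stable state at
A* ≈ 3021 pg/mg.  Because the saddle sits far below the 34 pg/mg starting
state, the mouse begins inside the high state's basin: the disease course
is a lifelong drift, not a bistable jump, and bistability would only become
trajectory-relevant if the feedback were orders of magnitude weaker (the
saddle-node collision appears below roughly V1/50 in the bifurcation scan).
A practical corollary verified in the tests: an intervention that meets
A(27) ≤ 100 usually leaves the high state (somewhat lowered) and its basin
intact — treatment slows the drift within the lifespan rather than
redirecting the asymptotic fate, which is why it must be sustained.

`basin_check` integrates from a given initial state and matches the
endpoint to a fixed point within 5% per component.  Ten lifespans (270
months) suffice for A but not for X, whose relaxation time is ~595 months,
so the horizon doubles adaptively (to at most 2×10⁴ months) before a
trajectory is declared undecided.

## Synthetic data: what it does and does not emulate

The generator produces (a) the exact logistic target, (b) perturbed
logistic curves (any constants), (c) multiplicative lognormal noise —
matching the log-scale objective and preserving positivity — and (d)
forward-simulated trajectories from known parameters.  It emulates the
*summary curve* of the measurements, not the measurements themselves: no
animal-to-animal variability, no sampling noise structure, no assay floor.
Passing tests therefore demonstrate correctness of the machinery and
reproducibility of the study's numbers on its stated inputs, not robustness
to real experimental noise (the noisy-fixture fitter tests probe that only
qualitatively).

## Known limitations

- Parameters are identifiable only along some directions; reported fits
  should be read jointly with `profile_objective` slices and per-start
  errors.
- The forward LogErr of the shipped rounded parameter set (0.658) differs
  from the unrounded optimum (~0.535); analyses that need the optimum
  should refit rather than rely on the rounded values.
- Interventions are idealized: instantaneous, permanent, side-effect-free
  parameter changes; no toxicity, cost, or pharmacokinetics.
- Staggered-start combinations are supported by the simulator but the
  surface/contour analysis assumes a shared start time.
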