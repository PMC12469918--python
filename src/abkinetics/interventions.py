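"""In-silico interventions on the feedback model.

A therapy is encoded as a permanent fractional change of one kinetic
parameter starting at some age: the dose is D = |1 - P/P0|, so production
ceilings (V1, V1') are scaled by (1 - D), capped at D = 1 (parameter driven
to zero), while removal rates (k2, k2') are scaled by (1 + D) with no upper
cap.  Success is judged by the end-of-life amyloid burden: A(27) at or below
a threshold (default 100 pg/mg, under 1/20 of the untreated final level).

The module finds minimum effective doses by bisection (the dose response is
monotone, which the tests verify), builds two-drug dose-response surfaces,
extracts the iso-effect contour A(27) = threshold, and reports the optimal
combination as the contour point closest to the origin in raw dose space —
the isobologram construction of classical combination pharmacology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import (KineticParams, SimulationError, Trajectory, simulate,
                       simulate_piecewise)

__all__ = [
    "PRODUCTION_PARAMS",
    "REMOVAL_PARAMS",
    "InterventionSpec",
    "DoseSearchResult",
    "DoseSurface",
    "ThresholdContour",
    "SynergyReport",
    "apply_dose",
    "run_intervention",
    "final_abeta",
    "min_effective_dose",
    "equal_dose_combination",
    "dose_surface",
    "threshold_contour",
    "synergy_report",
]

PRODUCTION_PARAMS = ("V1", "V1p")
REMOVAL_PARAMS = ("k2", "k2p")
DOSABLE_PARAMS = PRODUCTION_PARAMS + REMOVAL_PARAMS

#: default success criterion on A(27), pg/mg
DEFAULT_THRESHOLD = 100.0
#: dose bisection tolerance (doses are reported to 2 decimals)
DOSE_TOL = 1e-3
#: default search caps per parameter class
DEFAULT_DMAX = {"V1": 1.0, "V1p": 1.0, "k2": 2.0, "k2p": 10.0}


@dataclass(frozen=True)
class InterventionSpec:
    """A permanent dosed change of one parameter from ``t_start`` onward."""

    param_name: str
    dose: float
    t_start: float = 1.0

    def __post_init__(self) -> None:
        if self.param_name not in DOSABLE_PARAMS:
            raise ValueError(
                f"cannot dose {self.param_name!r}; interventions act on "
                f"{DOSABLE_PARAMS} (half-saturation constants are not dosed)")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.param_name in PRODUCTION_PARAMS and self.dose > 1:
            raise ValueError(
                "dose on a production ceiling is capped at 1 (parameter 0)")
        if not 1.0 <= self.t_start < 27.0:
            raise ValueError("t_start must lie in [1, 27) months")


def apply_dose(base: KineticParams, iv: InterventionSpec) -> KineticParams:
    """Return the parameter set with one dosed change applied.

    Dose D scales a production ceiling by (1 - D) and a removal rate by
    (1 + D); D = 0 leaves the parameters untouched.
    """
    p0 = getattr(base, iv.param_name)
    factor = (1.0 - iv.dose) if iv.param_name in PRODUCTION_PARAMS \
        else (1.0 + iv.dose)
    new = p0 * factor
    if iv.param_name in PRODUCTION_PARAMS and new == 0.0:
        new = 1e-300  # a fully suppressed ceiling; keeps the rate positive
    return base.replace(**{iv.param_name: new})


def run_intervention(
    base: KineticParams,
    ivs: list[InterventionSpec],
    eval_times=None,
    t_end: float = 27.0,
) -> Trajectory:
    """Simulate the model under zero or more permanent interventions.

    Interventions on distinct parameters may share or stagger start times;
    two interventions on the same parameter conflict and raise.  Delegates
    to piecewise integration with the dosed parameter set active from each
    start time onward.
    """
    names = [iv.param_name for iv in ivs]
    if len(set(names)) != len(names):
        raise ValueError("conflicting doses on the same parameter")
    if not ivs:
        return simulate(base, t_end=t_end, eval_times=eval_times)

    current = base
    at_start = [iv for iv in ivs if iv.t_start == 1.0]
    later = sorted((iv for iv in ivs if iv.t_start > 1.0),
                   key=lambda iv: iv.t_start)
    for iv in at_start:
        current = apply_dose(current, iv)
    changes = []
    for iv in later:
        current = apply_dose(current, iv)
        changes.append((iv.t_start, current))
    first = base if not at_start else changes_base(base, at_start)
    return simulate_piecewise(first, changes, eval_times=eval_times,
                              t_end=t_end)


def changes_base(base: KineticParams,
                 ivs: list[InterventionSpec]) -> KineticParams:
    out = base
    for iv in ivs:
        out = apply_dose(out, iv)
    return out


def final_abeta(base: KineticParams, ivs: list[InterventionSpec],
                t_end: float = 27.0) -> float:
    """A(t_end) in pg/mg under the given interventions."""
    traj = run_intervention(base, ivs, eval_times=[t_end], t_end=t_end)
    return float(traj.A[-1])


@dataclass(frozen=True)
class DoseSearchResult:
    """Outcome of a minimum-effective-dose bisection."""

    min_dose: float | None
    achieved_A27: float
    bracket: tuple
    feasible: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if not self.feasible:
            return (f"infeasible within cap (best A(27) = "
                    f"{self.achieved_A27:.1f} pg/mg)")
        return (f"min dose {self.min_dose:.3f} "
                f"(A(27) = {self.achieved_A27:.2f} pg/mg)")


def _bisect_dose(effect, d_max: float, threshold: float,
                 tol: float = DOSE_TOL) -> DoseSearchResult:
    """Smallest dose in [0, d_max] with effect(dose) <= threshold.

    Relies on the (numerically verified) monotone dose response.
    Infeasibility — even the cap fails — is a result, not an error.
    """
    a0 = effect(0.0)
    if a0 <= threshold:
        return DoseSearchResult(0.0, a0, (0.0, 0.0), True)
    a_cap = effect(d_max)
    if a_cap > threshold:
        return DoseSearchResult(None, a_cap, (d_max, d_max), False)
    lo, hi, a_hi = 0.0, d_max, a_cap
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        a_mid = effect(mid)
        if a_mid <= threshold:
            hi, a_hi = mid, a_mid
        else:
            lo = mid
    return DoseSearchResult(hi, a_hi, (lo, hi), True)


def min_effective_dose(
    base: KineticParams,
    param_name: str,
    t_start: float = 1.0,
    threshold: float = DEFAULT_THRESHOLD,
    d_max: float | None = None,
) -> DoseSearchResult:
    """Minimum dose on one parameter achieving A(27) <= threshold."""
    if d_max is None:
        d_max = DEFAULT_DMAX[param_name]
    if param_name in PRODUCTION_PARAMS and d_max > 1.0:
        raise ValueError("d_max on a production ceiling cannot exceed 1")

    def effect(dose):
        return final_abeta(base,
                           [InterventionSpec(param_name, dose, t_start)])

    return _bisect_dose(effect, d_max, threshold)


def equal_dose_combination(
    base: KineticParams,
    param_a: str,
    param_b: str,
    t_start: float = 1.0,
    threshold: float = DEFAULT_THRESHOLD,
    d_max: float | None = None,
) -> DoseSearchResult:
    """Minimum single dose applied simultaneously to two parameters."""
    if param_a == param_b:
        raise ValueError("combination requires two distinct parameters")
    if d_max is None:
        d_max = min(DEFAULT_DMAX[param_a], DEFAULT_DMAX[param_b])

    def effect(dose):
        return final_abeta(base, [InterventionSpec(param_a, dose, t_start),
                                  InterventionSpec(param_b, dose, t_start)])

    return _bisect_dose(effect, d_max, threshold)


@dataclass(frozen=True)
class DoseSurface:
    """A(27) on a grid of dose pairs, with the generating model attached."""

    param_pair: tuple
    dose_grid_1: np.ndarray
    dose_grid_2: np.ndarray
    A27: np.ndarray                      # shape (len(grid_1), len(grid_2))
    t_start: float
    base: KineticParams
    monotone: bool = True                # non-increasing along both axes?

    def edge_curve(self, axis: int) -> np.ndarray:
        """Monotherapy cut: A(27) along one axis with the other dose at 0."""
        return self.A27[:, 0] if axis == 0 else self.A27[0, :]


def dose_surface(
    base: KineticParams,
    param_pair: tuple,
    t_start: float = 1.0,
    grids: tuple | None = None,
    n_grid: int = 41,
) -> DoseSurface:
    """Evaluate A(27) over a full two-dose grid.

    Default grids span [0, 1] for production ceilings and [0, 1.5] for k2.
    Solver failures leave NaN cells; the surface is still returned.  The
    monotone flag records whether A(27) is non-increasing along both axes.
    """
    pa, pb = param_pair
    if grids is None:
        hi = {"V1": 1.0, "V1p": 1.0, "k2": 1.5, "k2p": 10.0}
        grids = (np.linspace(0.0, hi[pa], n_grid),
                 np.linspace(0.0, hi[pb], n_grid))
    g1, g2 = (np.asarray(g, dtype=float) for g in grids)
    if np.any(np.diff(g1) <= 0) or np.any(np.diff(g2) <= 0):
        raise ValueError("dose grids must be strictly ascending")
    A27 = np.full((g1.size, g2.size), np.nan)
    for i, d1 in enumerate(g1):
        for j, d2 in enumerate(g2):
            try:
                A27[i, j] = final_abeta(
                    base, [InterventionSpec(pa, d1, t_start),
                           InterventionSpec(pb, d2, t_start)])
            except SimulationError:
                pass
    with np.errstate(invalid="ignore"):
        monotone = (np.all(np.diff(A27, axis=0) <= 1e-6)
                    and np.all(np.diff(A27, axis=1) <= 1e-6))
    return DoseSurface(param_pair=(pa, pb), dose_grid_1=g1, dose_grid_2=g2,
                       A27=A27, t_start=t_start, base=base,
                       monotone=bool(monotone))


@dataclass(frozen=True)
class ThresholdContour:
    """Iso-effect locus A(27) = threshold and its closest point to zero dose."""

    points: np.ndarray                  # (n, 2) dose pairs on the contour
    optimal_point: tuple | None         # pair minimizing sqrt(d1^2 + d2^2)
    R: float                            # that minimal Euclidean distance
    threshold: float
    feasible: bool
    param_pair: tuple = ("", "")


def threshold_contour(
    surface: DoseSurface,
    threshold: float = DEFAULT_THRESHOLD,
    a_tol: float = 0.5,
) -> ThresholdContour:
    """Extract the A(27) = threshold contour of a dose surface.

    For each grid value of one dose the other dose is bisected (by fresh
    simulation, not interpolation) until A(27) is within ``a_tol`` pg/mg of
    the threshold; rays are cast along both axes so contours hugging either
    axis are resolved.  The optimal combination is the contour point with
    the shortest Euclidean distance R to the origin, doses unscaled.
    """
    pa, pb = surface.param_pair
    base, t0 = surface.base, surface.t_start

    def a27(d1, d2):
        return final_abeta(base, [InterventionSpec(pa, d1, t0),
                                  InterventionSpec(pb, d2, t0)])

    def ray(var_max, f):
        """Bisect the varying dose on [0, var_max] for A(27) = threshold."""
        hi_val = f(var_max)
        lo_val = f(0.0)
        if lo_val <= threshold or hi_val > threshold:
            return None
        lo, hi = 0.0, var_max
        val_hi = hi_val          # value at the feasible endpoint hi
        while hi - lo > DOSE_TOL or abs(val_hi - threshold) > a_tol:
            mid = 0.5 * (lo + hi)
            val = f(mid)
            if val <= threshold:
                hi, val_hi = mid, val
            else:
                lo = mid
            if hi - lo < 1e-12:
                break
        return hi

    pts = []
    for d1 in surface.dose_grid_1:
        d2 = ray(surface.dose_grid_2[-1], lambda v: a27(d1, v))
        if d2 is not None:
            pts.append((float(d1), float(d2)))
    for d2 in surface.dose_grid_2:
        d1 = ray(surface.dose_grid_1[-1], lambda v: a27(v, d2))
        if d1 is not None:
            pts.append((float(d1), float(d2)))

    if not pts:
        return ThresholdContour(points=np.empty((0, 2)), optimal_point=None,
                                R=np.inf, threshold=threshold, feasible=False,
                                param_pair=surface.param_pair)
    points = np.array(sorted(pts))
    dist = np.hypot(points[:, 0], points[:, 1])
    k = int(np.argmin(dist))
    return ThresholdContour(points=points,
                            optimal_point=(float(points[k, 0]),
                                           float(points[k, 1])),
                            R=float(dist[k]), threshold=threshold,
                            feasible=True, param_pair=surface.param_pair)


@dataclass(frozen=True)
class SynergyReport:
    """Optimal combined doses against the two monotherapy minimum doses."""

    param_pair: tuple
    combined_doses: tuple | None
    mono_doses: tuple
    R: float
    category: str
    synergy_fraction: float = 0.5       # "substantially smaller" cutoff

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.combined_doses is None:
            return f"{self.param_pair}: threshold not attainable"
        a, b = self.param_pair
        return (f"{a}+{b}: optimal ({self.combined_doses[0]:.2f}, "
                f"{self.combined_doses[1]:.2f}), mono ({self.mono_doses[0]}, "
                f"{self.mono_doses[1]}) -> {self.category}")


def synergy_report(
    contour: ThresholdContour,
    mono_a: DoseSearchResult,
    mono_b: DoseSearchResult,
    synergy_fraction: float = 0.5,
    axis_tol: float = 0.02,
) -> SynergyReport:
    """Classify a combination against its monotherapies.

    'synergistic' if both combined doses fall below ``synergy_fraction`` of
    the respective monotherapy minimum; 'second intervention hardly useful'
    if the optimal point sits on (within ``axis_tol`` of) one axis; plain
    'combination' otherwise; 'infeasible' if the contour never attains the
    threshold.
    """
    monos = (mono_a.min_dose if mono_a.feasible else np.inf,
             mono_b.min_dose if mono_b.feasible else np.inf)
    if not contour.feasible:
        return SynergyReport(contour.param_pair, None, monos, np.inf,
                             "infeasible", synergy_fraction)
    d1, d2 = contour.optimal_point
    if d1 <= axis_tol or d2 <= axis_tol:
        category = "second intervention hardly useful"
    elif d1 < synergy_fraction * monos[0] and d2 < synergy_fraction * monos[1]:
        category = "synergistic"
    else:
        category = "combination"
    return SynergyReport(contour.param_pair, (d1, d2), monos, contour.R,
                         category, synergy_fraction)
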