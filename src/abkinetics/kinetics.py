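"""Two-variable vicious-cycle kinetics of amyloid-beta accumulation.

The model couples the soluble Aβ42 concentration A (pg/mg) to an abstract
dimensionless disease factor X (tauopathy, oxidative stress, inflammation,
...) through mutual positive feedback:

    dA/dt = basal + V1  * X^n / (K1^n  + X^n) - k2  * A
    dX/dt =         V1' * A^n / (K1'^n + A^n) - k2' * X

Each variable stimulates the other's production through a Hill function
(ceiling V, half-saturation K, coefficient n) and decays with first-order
kinetics.  The system is stiff: soluble Aβ turns over in about an hour
(k2 = 450 / month) while X evolves over the lifetime of the mouse
(k2' ~ 0.002 / month), a timescale separation of roughly 1e5.

A purely linear scheme (constant production, first-order removal) is
provided as a null model: its closed-form solution relaxes monotonically
toward k1/k2 with its fastest growth at the start, so it can never produce
the slow-fast-slow sigmoidal time course observed in the mice.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "KineticParams",
    "LinearParams",
    "Trajectory",
    "SimulationError",
    "feedback_rhs",
    "simulate",
    "simulate_piecewise",
    "linear_solution",
    "is_sigmoidal",
    "load_params",
    "save_params",
    "default_params",
]

_RATE_FIELDS = ("V1", "K1", "k2", "V1p", "K1p", "k2p")

#: packaged fitted parameter set for the Tg2576 soluble Aβ42 time course
DEFAULT_PARAMS_FILE = Path(__file__).parent / "data" / "tg2576_fitted.yaml"


@dataclass(frozen=True)
class KineticParams:
    """Parameter set of the coupled feedback model.

    Defaults are the fitted values for the Tg2576 soluble Aβ42 course
    (k2, A_init and X_init held fixed during that fit).  ``basal`` is an
    optional zeroth-order Aβ production term, zero in the reference model.
    """

    V1: float = 1.36e6      # pg mg^-1 mo^-1, ceiling of the A feedback
    K1: float = 10.7        # dimensionless, half-saturation of X driving A
    k2: float = 450.0       # mo^-1, first-order removal of A (1.1 h turnover)
    V1p: float = 0.998      # mo^-1, ceiling of the X feedback
    K1p: float = 134.2      # pg/mg, half-saturation of A driving X
    k2p: float = 0.00168    # mo^-1, first-order removal of X
    hill_n: int = 2         # Hill coefficient, smallest integer giving a sigmoid
    A_init: float = 34.0    # pg/mg at t = 1 month
    X_init: float = 1.0     # dimensionless at t = 1 month
    basal: float = 0.0      # pg mg^-1 mo^-1, optional basal Aβ production

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            if not getattr(self, name) > 0:
                raise ValueError(f"KineticParams.{name} must be > 0")
        if not (isinstance(self.hill_n, (int, np.integer)) and self.hill_n >= 1):
            raise ValueError("hill_n must be an integer >= 1")
        if self.A_init < 0 or self.X_init < 0 or self.basal < 0:
            raise ValueError("A_init, X_init and basal must be >= 0")

    def replace(self, **changes) -> "KineticParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hill_n"] = int(d["hill_n"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParams":
        return cls(**d)


def default_params() -> KineticParams:
    """The packaged fitted Tg2576 parameter set (same as ``KineticParams()``)."""
    return load_params(DEFAULT_PARAMS_FILE)


def load_params(path: str | Path) -> KineticParams:
    """Read a parameter set from flat YAML/JSON (field names as keys)."""
    with open(path) as fh:
        return KineticParams.from_dict(yaml.safe_load(fh))


def save_params(p: KineticParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(p.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class LinearParams:
    """Null model: constant production k1, first-order removal k2."""

    k1: float               # pg mg^-1 mo^-1
    k2: float               # mo^-1
    A_init: float = 34.0    # pg/mg at t = 1

    def __post_init__(self) -> None:
        if self.k1 < 0:
            raise ValueError("k1 must be >= 0")
        if not self.k2 > 0:
            raise ValueError("k2 must be > 0")


@dataclass(frozen=True)
class Trajectory:
    """Integrated time course: months, A (pg/mg) and X (dimensionless)."""

    times: np.ndarray
    A: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "A", np.asarray(self.A, dtype=float))
        object.__setattr__(self, "X", np.asarray(self.X, dtype=float))
        if not (self.times.shape == self.A.shape == self.X.shape):
            raise ValueError("times, A and X must have identical shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_months": self.times, "A_pg_per_mg": self.A,
             "X_dimensionless": self.X}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(df["time_months"].to_numpy(), df["A_pg_per_mg"].to_numpy(),
                   df["X_dimensionless"].to_numpy())


class SimulationError(RuntimeError):
    """Integration failure; carries the last time the solver reached."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


def feedback_rhs(A: float, X: float, p: KineticParams) -> tuple[float, float]:
    """Right-hand side of the coupled feedback system at state (A, X).

    Returns (dA/dt, dX/dt) in (pg mg^-1 mo^-1, mo^-1).  The state must be
    non-negative; both Hill production terms vanish at the origin, which is
    therefore always a fixed point of the basal-free model.
    """
    if A < 0 or X < 0:
        raise ValueError("feedback_rhs requires a non-negative state")
    n = p.hill_n
    dA = p.basal + p.V1 * X**n / (p.K1**n + X**n) - p.k2 * A
    dX = p.V1p * A**n / (p.K1p**n + A**n) - p.k2p * X
    return dA, dX


def _rhs_vec(p: KineticParams):
    n, V1, K1n, k2 = p.hill_n, p.V1, p.K1**p.hill_n, p.k2
    V1p, K1pn, k2p, basal = p.V1p, p.K1p**p.hill_n, p.k2p, p.basal

    def rhs(t, y):
        A, X = y
        # tiny negative excursions from the solver are treated as zero
        A = A if A > 0 else 0.0
        X = X if X > 0 else 0.0
        An, Xn = A**n, X**n
        return (basal + V1 * Xn / (K1n + Xn) - k2 * y[0],
                V1p * An / (K1pn + An) - k2p * y[1])

    return rhs


# solver contract: stiff-capable method, relative tolerance 1e-8, absolute
# tolerances 1e-10 on A (pg/mg scale) and 1e-12 on X
_SOLVER = dict(method="LSODA", rtol=1e-8, atol=(1e-10, 1e-12))


def _integrate(p, t_span, y0, eval_times, rtol=None):
    kw = dict(_SOLVER)
    if rtol is not None:
        kw["rtol"] = rtol
    sol = solve_ivp(_rhs_vec(p), t_span, y0, t_eval=eval_times,
                    dense_output=eval_times is None, **kw)
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else t_span[0]
        raise SimulationError(f"integration failed at t={last:.4g}: "
                              f"{sol.message}", last_time=last)
    if not np.all(np.isfinite(sol.y)):
        raise SimulationError("state blow-up (non-finite values)",
                              last_time=float(sol.t[-1]))
    return sol


def simulate(
    p: KineticParams,
    t_start: float = 1.0,
    t_end: float = 27.0,
    eval_times=None,
    rtol: float | None = None,
) -> Trajectory:
    """Integrate the feedback model from (A_init, X_init) at ``t_start``.

    Time is the age of the mouse in months; the default window [1, 27]
    spans adulthood to end of life.  ``eval_times`` defaults to integer
    months within the window.  A stiff-capable solver is required because A
    relaxes ~1e5 times faster than X.
    """
    if not t_start < t_end:
        raise ValueError("t_start must be < t_end")
    if eval_times is None:
        eval_times = np.arange(np.ceil(t_start), np.floor(t_end) + 1)
    eval_times = np.asarray(eval_times, dtype=float)
    if np.any(eval_times < t_start) or np.any(eval_times > t_end):
        raise ValueError("eval_times must lie within [t_start, t_end]")
    sol = _integrate(p, (t_start, t_end), (p.A_init, p.X_init),
                     eval_times, rtol=rtol)
    A, X = np.clip(sol.y[0], 0.0, None), np.clip(sol.y[1], 0.0, None)
    return Trajectory(times=sol.t, A=A, X=X)


def simulate_piecewise(
    p: KineticParams,
    changes: list[tuple[float, KineticParams]],
    eval_times=None,
    t_start: float = 1.0,
    t_end: float = 27.0,
    rtol: float | None = None,
) -> Trajectory:
    """Integrate with a piecewise-constant parameter schedule.

    ``changes`` is a list of (month, params) switches, strictly increasing in
    time within (t_start, t_end); the state (A, X) is carried continuously
    across each switch.  An empty schedule reduces to :func:`simulate`.
    Parameter switches model interventions applied instantaneously and
    permanently (no pharmacokinetic onset).
    """
    if eval_times is None:
        eval_times = np.arange(np.ceil(t_start), np.floor(t_end) + 1)
    eval_times = np.asarray(eval_times, dtype=float)
    if not changes:
        return simulate(p, t_start, t_end, eval_times, rtol=rtol)
    switch_times = [c[0] for c in changes]
    if np.any(np.diff(switch_times) <= 0):
        raise ValueError("change times must be strictly increasing")
    if switch_times[0] <= t_start or switch_times[-1] >= t_end:
        raise ValueError("change times must lie strictly inside "
                         "(t_start, t_end)")

    bounds = [t_start] + switch_times + [t_end]
    param_sets = [p] + [c[1] for c in changes]
    y = (p.A_init, p.X_init)
    times_out, A_out, X_out = [], [], []
    for i, pi in enumerate(param_sets):
        lo, hi = bounds[i], bounds[i + 1]
        last = i == len(param_sets) - 1
        mask = ((eval_times >= lo) & (eval_times < hi)) if not last else (
            (eval_times >= lo) & (eval_times <= hi))
        seg_eval = np.unique(np.concatenate([eval_times[mask], [hi]]))
        sol = _integrate(pi, (lo, hi), y, seg_eval, rtol=rtol)
        y = (sol.y[0][-1], sol.y[1][-1])
        keep = np.isin(sol.t, eval_times[mask])
        times_out.append(sol.t[keep])
        A_out.append(sol.y[0][keep])
        X_out.append(sol.y[1][keep])
    return Trajectory(
        times=np.concatenate(times_out),
        A=np.clip(np.concatenate(A_out), 0.0, None),
        X=np.clip(np.concatenate(X_out), 0.0, None),
    )


def linear_solution(p: LinearParams, t):
    """Closed-form course of the linear null model for t >= 1 month.

    A(t) = k1/k2 + (A(1) - k1/k2) * exp(-k2 (t - 1)).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 1):
        raise ValueError("linear_solution is defined for t >= 1")
    ss = p.k1 / p.k2
    out = ss + (p.A_init - ss) * np.exp(-p.k2 * (t - 1.0))
    return float(out) if out.ndim == 0 else out


def is_sigmoidal(values) -> tuple[bool, int]:
    """Whether a time course shows slow-fast-slow growth.

    Accepts a :class:`Trajectory` (its A values are used) or a 1-D sequence
    sampled on a uniform grid.  Returns ``(flag, i)`` where ``i`` indexes the
    interval of maximal growth; the course is called sigmoidal iff that
    interval is strictly interior (growth accelerates before it slows).
    """
    if isinstance(values, Trajectory):
        values = values.A
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 points to assess sigmoidality")
    diffs = np.diff(v)
    i = int(np.argmax(diffs))
    return 0 < i < diffs.size - 1, i
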