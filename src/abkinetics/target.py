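"""Logistic target curve for soluble Aβ42 in Tg2576 mice, plus synthetic variants.

The observable modeled throughout this package is the whole-brain soluble
Aβ42 concentration (pg per mg wet tissue) of Tg2576 transgenic mice as a
function of age in months.  Longitudinal measurements of this quantity are
well summarized by a four-parameter logistic curve,

    A(t) = baseline + amplitude / (1 + (t / midpoint)**(-steepness)),

and it is this curve, sampled at integer months 1..27, that serves as the
fitting target for the kinetic model.  This module also provides perturbed
and noisy variants of the curve so that the fitting machinery can be
exercised against synthetic data with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LogisticParams",
    "TargetSeries",
    "logistic_value",
    "make_target_series",
    "add_multiplicative_noise",
]

#: default sampling grid: integer months 1..27 (adulthood to end of life)
DEFAULT_MONTHS = np.arange(1, 28, dtype=float)


@dataclass(frozen=True)
class LogisticParams:
    """Constants of the logistic description of soluble Aβ42 vs. age.

    Defaults are the published fit for Tg2576 mice: a 34 pg/mg baseline,
    a 2240 pg/mg rise, half-saturation at 18 months, and a dimensionless
    steepness of 5.9 applied to the base-10 logarithm of relative age.
    """

    baseline: float = 34.0      # pg/mg, A at very young age
    amplitude: float = 2240.0   # pg/mg, total rise to the old-age plateau
    steepness: float = 5.9      # dimensionless
    midpoint: float = 18.0      # months, age of half-maximal rise

    def __post_init__(self) -> None:
        for name in ("baseline", "amplitude", "steepness", "midpoint"):
            if not getattr(self, name) > 0:
                raise ValueError(f"LogisticParams.{name} must be > 0")


def logistic_value(t, p: LogisticParams = LogisticParams()):
    """Evaluate the logistic age curve at time ``t`` (months).

    The curve is written with a natural exponential of a base-10 log,
    ``exp(-steepness * ln(10) * log10(t/midpoint))``, which collapses to the
    power law ``(t/midpoint)**(-steepness)``; at ``t == midpoint`` the value
    is ``baseline + amplitude/2``.

    Parameters
    ----------
    t : float or array-like
        Age in months, strictly positive.
    p : LogisticParams
        Curve constants; defaults to the Tg2576 soluble Aβ42 fit.

    Returns
    -------
    float or ndarray
        Concentration in pg/mg.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("logistic_value requires t > 0 (log of relative age)")
    out = p.baseline + p.amplitude / (1.0 + (t / p.midpoint) ** (-p.steepness))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TargetSeries:
    """A sampled concentration time course: ordered months and pg/mg values."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.size == 0:
            raise ValueError("TargetSeries must contain at least one point")
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have identical shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values <= 0):
            raise ValueError("concentrations must be positive")

    def __len__(self) -> int:
        return int(self.times.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_months": self.times, "abeta_pg_per_mg": self.values}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TargetSeries":
        df = pd.read_csv(path)
        return cls(
            times=df["time_months"].to_numpy(),
            values=df["abeta_pg_per_mg"].to_numpy(),
        )


def make_target_series(
    p: LogisticParams = LogisticParams(), times=None
) -> TargetSeries:
    """Sample the logistic curve on a time grid (default: months 1..27)."""
    t = DEFAULT_MONTHS if times is None else np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("times must be non-empty")
    return TargetSeries(times=t, values=logistic_value(t, p))


def add_multiplicative_noise(
    s: TargetSeries, sigma: float, seed: int
) -> TargetSeries:
    """Multiply each value by exp(N(0, sigma^2)) noise, reproducibly.

    Lognormal multiplicative noise matches the log-ratio error metric used by
    the fitter and keeps concentrations positive.  ``sigma=0`` returns the
    input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return s
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma, size=len(s))
    return TargetSeries(times=s.times, values=s.values * np.exp(eps))
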