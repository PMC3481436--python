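"""Exogenous inputs: monocyte differentiation rate and myocyte density.

Post-MI, monocytes infiltrate the infarct and differentiate into
unactivated macrophages at a rate M(t) that rises to a peak within the
first week and subsides; the surviving myocyte density Mc(t) declines
monotonically from its healthy value toward a plateau.  Only the
unactivated-pool balance

    dM_un/dt = M(t) - mu * M_un

links M(t) to a measurable macrophage time course, with solution

    M_un(t) = M_un(0) e^{-mu t} + int_0^t e^{-mu (t-s)} M(s) ds,

so M(t) can be estimated from a fitted M_un curve by differentiating:
M(t) = dM_un/dt + mu * M_un.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

__all__ = [
    "TimeSeries",
    "InputProfile",
    "unactivated_from_rate",
    "rate_from_unactivated",
    "fit_input_profiles",
    "baseline_profile",
    "mi_profile",
    "read_timeseries_csv",
    "write_timeseries_csv",
]

logger = logging.getLogger(__name__)

#: healthy myocyte density in the left ventricle, cells/ml
HEALTHY_MYOCYTE_DENSITY = 6e9
#: healthy (unactivated) macrophage density, cells/ml.  The source text also
#: quotes 5e3 cells/ml for total macrophages in controls; 2000 cells/ml is the
#: value used as the initial unactivated density and is adopted throughout.
HEALTHY_MACROPHAGE_DENSITY = 2000.0


@dataclass(frozen=True)
class TimeSeries:
    """Discrete measurements of one species: day, value, optional SE."""

    days: tuple
    values: tuple
    se: Optional[tuple] = None
    species: str = ""

    def __post_init__(self):
        days = tuple(float(d) for d in self.days)
        values = tuple(float(v) for v in self.values)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "values", values)
        if self.se is not None:
            object.__setattr__(self, "se", tuple(float(s) for s in self.se))
        if len(days) != len(values):
            raise ValueError("days and values must have equal length")
        if self.se is not None and len(self.se) != len(days):
            raise ValueError("se length must match days")
        if len(days) >= 2 and np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing")
        if any(v < 0 for v in values):
            raise ValueError("values must be non-negative")

    def __len__(self) -> int:
        return len(self.days)


@dataclass(frozen=True)
class InputProfile:
    """Continuous input functions on [0, t_max] days."""

    monocyte_rate: Callable[[float], float]    # cells/ml/day
    myocyte_density: Callable[[float], float]  # cells/ml
    t_max: float = 30.0

    def check(self, n_grid: int = 301) -> None:
        """Verify non-negativity/finiteness and monotone myocyte decline."""
        t = np.linspace(0.0, self.t_max, n_grid)
        m = np.array([self.monocyte_rate(ti) for ti in t], dtype=float)
        mc = np.array([self.myocyte_density(ti) for ti in t], dtype=float)
        if np.any(~np.isfinite(m)) or np.any(m < 0):
            raise ValueError("monocyte_rate must be finite and non-negative")
        if np.any(~np.isfinite(mc)) or np.any(mc < 0):
            raise ValueError("myocyte_density must be finite and non-negative")
        if np.any(np.diff(mc) > 1e-9 * max(1.0, mc.max())):
            raise ValueError("myocyte_density must be non-increasing")


# ---------------------------------------------------------------------------
# forward convolution and its inversion
# ---------------------------------------------------------------------------

def unactivated_from_rate(m0: float, mu: float,
                          rate: Callable[[float], float],
                          t_grid: Sequence[float]) -> TimeSeries:
    """Unactivated-macrophage density driven by a differentiation rate.

    Evaluates M_un(t) = m0 e^{-mu t} + int_0^t e^{-mu(t-s)} rate(s) ds on
    ``t_grid`` by integrating the equivalent linear ODE with tight
    tolerances.
    """
    if m0 < 0:
        raise ValueError("m0 must be non-negative")
    if mu <= 0:
        raise ValueError("mu must be positive")
    t_grid = np.asarray(t_grid, dtype=float)

    def f(t, y):
        r = float(rate(t))
        if r < 0:
            raise ValueError(f"negative rate sample at t={t}")
        return [r - mu * y[0]]

    t0, t1 = float(t_grid[0]), float(t_grid[-1])
    if t0 != 0.0:
        raise ValueError("t_grid must start at 0")
    if len(t_grid) == 1:
        return TimeSeries(days=(0.0,), values=(m0,), species="m_un")
    sol = solve_ivp(f, (t0, t1), [m0], t_eval=t_grid,
                    rtol=1e-10, atol=1e-10 * max(m0, 1.0), method="LSODA")
    if not sol.success:
        raise RuntimeError(f"convolution integration failed: {sol.message}")
    values = np.maximum(sol.y[0], 0.0)
    return TimeSeries(days=tuple(t_grid), values=tuple(values), species="m_un")


def rate_from_unactivated(series: TimeSeries, mu: float,
                          t_grid: Optional[Sequence[float]] = None) -> TimeSeries:
    """Estimate the monocyte differentiation rate from an M_un time course.

    Inverts the convolution via M(t) = dM_un/dt + mu*M_un on a monotone
    cubic (PCHIP) interpolant of the series; negative finite-difference
    estimates are clipped at zero with a warning.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if len(series) < 2:
        raise ValueError("need at least 2 points to estimate a rate")
    days = np.asarray(series.days, dtype=float)
    vals = np.asarray(series.values, dtype=float)
    interp = PchipInterpolator(days, vals)
    deriv = interp.derivative()
    t = days if t_grid is None else np.asarray(t_grid, dtype=float)
    rate = deriv(t) + mu * interp(t)
    if np.any(rate < 0):
        logger.warning("rate_from_unactivated: clipping %d negative estimates at 0",
                       int(np.sum(rate < 0)))
        rate = np.maximum(rate, 0.0)
    return TimeSeries(days=tuple(t), values=tuple(rate), species="monocyte_rate")


# ---------------------------------------------------------------------------
# profile fitting
# ---------------------------------------------------------------------------

def _myocyte_form(t, mc0, f, r):
    return mc0 * (f + (1.0 - f) * np.exp(-r * t))


def fit_input_profiles(monocyte_data: TimeSeries,
                       myocyte_data: TimeSeries,
                       mu: float = 0.2,
                       t_max: float = 30.0) -> InputProfile:
    """Build continuous input profiles from discrete time courses.

    ``monocyte_data`` is an unactivated-macrophage time course: it is
    interpolated (PCHIP) and inverted to a differentiation rate.  The
    myocyte series is fit to the monotone form
    ``mc0 * (f + (1-f) exp(-r t))`` anchored at its day-0 value; a single
    data point fixes ``mc0`` and uses the default decay shape
    (f=0.5, r=0.5/day).
    """
    if len(myocyte_data) == 0:
        raise ValueError("empty myocyte series")
    days = np.asarray(myocyte_data.days, dtype=float)
    vals = np.asarray(myocyte_data.values, dtype=float)
    mc0 = vals[0] if days[0] == 0 else vals[0]
    if len(myocyte_data) < 3:
        f_hat, r_hat = 0.5, 0.5
    else:
        def resid(x):
            f, r = x
            return (_myocyte_form(days, mc0, f, r) - vals) / max(mc0, 1.0)
        fit = least_squares(resid, x0=[0.5, 0.5],
                            bounds=([0.0, 1e-4], [1.0, 10.0]))
        f_hat, r_hat = fit.x
    # the fitted form is non-increasing by construction for f in [0,1], r>0

    if len(monocyte_data) < 2:
        raise ValueError("need at least 2 monocyte/macrophage points")
    mdays = np.asarray(monocyte_data.days, dtype=float)
    if mdays[0] > 0:  # anchor at healthy baseline
        mdays = np.concatenate([[0.0], mdays])
        mvals = np.concatenate([[HEALTHY_MACROPHAGE_DENSITY],
                                np.asarray(monocyte_data.values, float)])
    else:
        mvals = np.asarray(monocyte_data.values, dtype=float)
    fine = np.linspace(0.0, min(t_max, mdays[-1]), 241)
    anchored = TimeSeries(days=tuple(mdays), values=tuple(mvals), species="m_un")
    rate_ts = rate_from_unactivated(anchored, mu, t_grid=fine)
    rate_interp = PchipInterpolator(fine, np.asarray(rate_ts.values))
    last_rate = float(rate_ts.values[-1])
    t_data_end = fine[-1]

    def monocyte_rate(t):
        t = float(t)
        if t <= t_data_end:
            return max(float(rate_interp(t)), 0.0)
        return last_rate  # hold beyond the data window

    def myocyte_density(t):
        return float(_myocyte_form(np.clip(t, 0.0, None), mc0, f_hat, r_hat))

    profile = InputProfile(monocyte_rate, myocyte_density, t_max=t_max)
    profile.check()
    return profile


# ---------------------------------------------------------------------------
# canonical profiles
# ---------------------------------------------------------------------------

def baseline_profile(rate: float = 400.0,
                     myocyte_density: float = HEALTHY_MYOCYTE_DENSITY,
                     t_max: float = 1000.0) -> InputProfile:
    """Healthy-homeostasis inputs: constant differentiation rate and myocytes.

    The default rate mu * 2000 = 400 cells/ml/day holds the unactivated pool
    at its healthy 2000 cells/ml.
    """
    return InputProfile(lambda t: rate, lambda t: myocyte_density, t_max=t_max)


def constant_profile(rate: float, myocyte_density: float,
                     t_max: float = 1000.0) -> InputProfile:
    """Constant inputs (used for steady-state search and calibration)."""
    return InputProfile(lambda t: float(rate), lambda t: float(myocyte_density),
                        t_max=t_max)


def mi_profile(base_rate: float,
               peak_multiplier: float = 5.0,
               pulse_shape: float = 3.0,
               pulse_scale: float = 1.75,
               mc0: float = HEALTHY_MYOCYTE_DENSITY,
               plateau_fraction: float = 0.5,
               decline_rate: float = 0.5,
               t_max: float = 30.0) -> InputProfile:
    """Default myocardial-infarction input scenario.

    Monocyte differentiation: baseline plus a gamma-density pulse
    (shape 3, scale 1.75 d -> mode at day 3.5, negligible by day 28),
    normalized so the peak total rate is ``peak_multiplier`` times the
    baseline.  Myocyte density declines from ``mc0`` to a plateau
    ``plateau_fraction * mc0`` with rate ``decline_rate``/day.
    """
    k, th = pulse_shape, pulse_scale
    t_peak = (k - 1.0) * th

    def pulse(t):
        t = np.clip(t, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(t > 0, t ** (k - 1) * np.exp(-t / th), 0.0)
        return raw / (t_peak ** (k - 1) * np.exp(-t_peak / th))

    amp = (peak_multiplier - 1.0) * base_rate

    def monocyte_rate(t):
        return float(base_rate + amp * pulse(t))

    def myocyte_density(t):
        return float(_myocyte_form(np.clip(t, 0.0, None), mc0,
                                   plateau_fraction, decline_rate))

    return InputProfile(monocyte_rate, myocyte_density, t_max=t_max)


# ---------------------------------------------------------------------------
# CSV I/O (columns: day,value,se,species)
# ---------------------------------------------------------------------------

def write_timeseries_csv(series_list: Sequence[TimeSeries], path) -> None:
    rows = []
    for ts in series_list:
        se = ts.se if ts.se is not None else [np.nan] * len(ts)
        for d, v, s in zip(ts.days, ts.values, se):
            rows.append({"day": d, "value": v, "se": s, "species": ts.species})
    pd.DataFrame(rows, columns=["day", "value", "se", "species"]).to_csv(
        path, index=False)


def read_timeseries_csv(path) -> List[TimeSeries]:
    df = pd.read_csv(path)
    out = []
    for species, grp in df.groupby("species", sort=False):
        grp = grp.sort_values("day")
        se = None
        if "se" in grp and not grp["se"].isna().all():
            se = tuple(grp["se"].astype(float))
        out.append(TimeSeries(days=tuple(grp["day"].astype(float)),
                              values=tuple(grp["value"].astype(float)),
                              se=se, species=str(species)))
    return out
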