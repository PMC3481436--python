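"""Six-state vector field for macrophage polarization post-MI.

States (densities cells/ml, concentrations pg/ml)::

    x1 = m_un    unactivated macrophages
    x2 = m1      classically activated (M1) macrophages
    x3 = m2      alternatively activated (M2) macrophages
    x4 = il10    interleukin-10
    x5 = t_alpha tumour necrosis factor alpha
    x6 = il1     interleukin-1

Exogenous inputs: the monocyte differentiation rate M(t) feeding the
unactivated pool, and the myocyte density Mc(t) acting as a cytokine
source.  Unactivated macrophages are activated to M1 by IL-1 and
TNF-alpha and to M2 by IL-10 through saturating Hill terms; M1 and M2
interconvert; all macrophages leave by lymphatic emigration (rate mu,
no local death).  M2 secretes IL-10 under self-inhibition; M1 and
myocytes secrete TNF-alpha and IL-1, both inhibited by IL-10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .params import ModelParams

__all__ = ["ModelState", "hill_up", "hill_down", "rhs", "rhs_saturated"]

#: tolerance for integrator micro-undershoot below zero
_NEG_TOL = 1e-12

STATE_NAMES = ("m_un", "m1", "m2", "il10", "t_alpha", "il1")


@dataclass(frozen=True)
class ModelState:
    """One point of the six-dimensional state space (all components >= 0)."""

    m_un: float
    m1: float
    m2: float
    il10: float
    t_alpha: float
    il1: float

    def as_array(self) -> np.ndarray:
        return np.array([self.m_un, self.m1, self.m2,
                         self.il10, self.t_alpha, self.il1], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "ModelState":
        y = np.asarray(y, dtype=float)
        if y.shape != (6,):
            raise ValueError(f"expected 6 components, got shape {y.shape}")
        return cls(*map(float, y))

    def validate(self) -> None:
        for name, v in zip(STATE_NAMES, self.as_array()):
            if not math.isfinite(v):
                raise ValueError(f"state component {name} is not finite")
            if v < -_NEG_TOL:
                raise ValueError(f"state component {name} is negative: {v}")


def hill_up(x: float, c: float):
    """Saturating promotion term x/(x+c) in [0, 1)."""
    if np.any(np.asarray(c) <= 0):
        raise ValueError("Hill constant c must be positive")
    x = np.maximum(x, 0.0)
    return x / (x + c)


def hill_down(c: float, x: float):
    """Saturating inhibition term c/(c+x) in (0, 1]; complement of hill_up."""
    if np.any(np.asarray(c) <= 0):
        raise ValueError("Hill constant c must be positive")
    x = np.maximum(x, 0.0)
    return c / (c + x)


def rhs(t: float, y: Sequence[float], p: ModelParams, u) -> np.ndarray:
    """Time derivative of the six states.

    ``u`` provides ``u.monocyte_rate(t)`` (cells/ml/day) and
    ``u.myocyte_density(t)`` (cells/ml).  States are clamped at zero
    before Hill evaluation to tolerate integrator micro-undershoot.
    """
    y = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError(f"non-finite state at t={t}: {y}")
    if np.any(y < -1e-6):
        raise ValueError(f"negative state at t={t}: {y}")
    m_un, m1, m2, il10, ta, il1 = np.maximum(y, 0.0)

    h_il1 = hill_up(il1, p.c_il1)      # IL-1 promotion of M1
    h_ta = hill_up(ta, p.c_ta)         # TNF-alpha promotion of M1
    h_il10 = hill_up(il10, p.c_il10)   # IL-10 promotion of M2
    inh_self = hill_down(p.c1, il10)   # IL-10 self-inhibition of secretion
    inh = hill_down(p.c, il10)         # IL-10 inhibition of TNF/IL-1 secretion

    m_in = float(u.monocyte_rate(t))
    mc = float(u.myocyte_density(t))
    if m_in < 0 or mc < 0:
        raise ValueError(f"negative input at t={t}")

    act_m1 = (p.k2 * h_il1 + p.k3 * h_ta) * m_un
    act_m2 = p.k4 * h_il10 * m_un

    d_m_un = m_in - act_m1 - act_m2 - p.mu * m_un
    d_m1 = act_m1 + p.k1p * m2 - p.k1 * m1 - p.mu * m1
    d_m2 = act_m2 + p.k1 * m1 - p.k1p * m2 - p.mu * m2
    d_il10 = p.k5 * m2 * inh_self - p.d_il10 * il10
    d_ta = (p.k6 * m1 + p.lam * mc) * inh - p.d_ta * ta
    d_il1 = (p.k7 * m1 + p.lam * mc) * inh - p.d_il1 * il1

    return np.array([d_m_un, d_m1, d_m2, d_il10, d_ta, d_il1])


def rhs_saturated(y: Sequence[float], p: ModelParams) -> np.ndarray:
    """Zero-input vector field with every Hill factor replaced by 1.

    This is the bilinear comparison system whose Lyapunov derivative
    equals the quadratic form built by :func:`mimacro.stability.quadratic_bound`
    exactly; it serves as an independent oracle for the bound construction.
    """
    m_un, m1, m2, il10, ta, il1 = np.asarray(y, dtype=float)
    act_m1 = (p.k2 + p.k3) * m_un
    act_m2 = p.k4 * m_un
    return np.array([
        -act_m1 - act_m2 - p.mu * m_un,
        act_m1 + p.k1p * m2 - (p.k1 + p.mu) * m1,
        act_m2 + p.k1 * m1 - (p.k1p + p.mu) * m2,
        p.k5 * m2 - p.d_il10 * il10,
        p.k6 * m1 - p.d_ta * ta,
        p.k7 * m1 - p.d_il1 * il1,
    ])
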