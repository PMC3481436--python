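"""Lyapunov analysis of the zero-input system.

The candidate Lyapunov function is V(x) = 1/2 sum x_i^2.  Along
zero-input trajectories its derivative mixes negative diagonal terms with
Hill-modulated cross terms.  Saturating every Hill factor at 1 yields a
pure quadratic form x'Qx; with the default parameter set Q has the
printed coefficients

    diag:  1.6, 0.275, 0.25, 2.5, 55, 10.5
    cross: 1.1 x1x2, 0.3 x1x3, 0.125 x2x3,
           5e-4 x3x4, 7e-4 x2x5, 6e-4 x2x6

and is certified negative definite by its eigenvalues (a complete test,
unlike the hand completed-square decomposition, which is validated
separately with its rounding slack reported term by term).

A caveat the numerical checks here surface: saturating the Hill factor at
1 inside the *stabilizing* -k_i h x1^2 terms makes them more negative, so
x'Qx is not a pointwise upper bound on V-dot over the whole orthant (e.g.
at x = (1,0,0,0,0,0), V-dot = -mu > x'Qx = -(mu+k2+k3+k4)).
:func:`pointwise_bound_dominates` reports exactly where the claimed
domination fails.  Global asymptotic stability of the zero-input system
is nevertheless true: total cell mass N = x1+x2+x3 obeys dN/dt = -mu N,
and the cytokines decay once their cell sources vanish.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
from scipy.linalg import eigh

from .inputs import constant_profile
from .model import ModelParams, rhs
from .params import bound_coefficients

__all__ = [
    "StabilityCertificate",
    "lyapunov_value",
    "lyapunov_derivative",
    "quadratic_bound",
    "sos_decomposition_check",
    "pointwise_bound_dominates",
    "PRINTED_SOS_TERMS",
]

_ZERO_INPUT = constant_profile(0.0, 0.0, t_max=1e9)

# index pairs for the destabilizing cross terms (0-based)
_CROSS_INDEX = {"x1x2": (0, 1), "x1x3": (0, 2), "x2x3": (1, 2),
                "x3x4": (2, 3), "x2x5": (1, 4), "x2x6": (1, 5)}


@dataclass(frozen=True)
class StabilityCertificate:
    """Eigenvalue certificate for the saturated quadratic bound."""

    bound_matrix: np.ndarray            # symmetric 6x6
    eigenvalues: np.ndarray             # ascending
    verdict: str                        # "globally_stable" | "indeterminate"
    printed_check: Dict[str, float]     # the twelve bound coefficients

    def to_dict(self) -> dict:
        return {
            "bound_matrix": self.bound_matrix.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "verdict": self.verdict,
            "printed_check": dict(self.printed_check),
        }


def lyapunov_value(s: Sequence[float]) -> float:
    """V(x) = 1/2 sum of squared state components."""
    y = np.asarray(s, dtype=float)
    return float(0.5 * np.dot(y, y))


def lyapunov_derivative(s: Sequence[float], p: ModelParams) -> float:
    """V-dot(x) = x . f(x) for the zero-input vector field."""
    y = np.asarray(s, dtype=float)
    return float(np.dot(y, rhs(0.0, y, p, _ZERO_INPUT)))


def quadratic_bound(p: ModelParams) -> StabilityCertificate:
    """Symmetric matrix of the Hill-saturated quadratic form and its verdict.

    Q is built so that x'Qx reproduces the saturated form exactly:
    negative diagonal entries, half the cross coefficients off-diagonal.
    Verdict is ``globally_stable`` iff all eigenvalues are strictly
    negative.
    """
    coeffs = bound_coefficients(p)
    q = np.zeros((6, 6))
    for i, key in enumerate(["x1^2", "x2^2", "x3^2", "x4^2", "x5^2", "x6^2"]):
        q[i, i] = -coeffs[key]
    for key, (i, j) in _CROSS_INDEX.items():
        q[i, j] = q[j, i] = 0.5 * coeffs[key]
    evals = eigh(q, eigvals_only=True)
    verdict = "globally_stable" if np.all(evals < 0) else "indeterminate"
    return StabilityCertificate(bound_matrix=q, eigenvalues=evals,
                                verdict=verdict, printed_check=coeffs)


#: Printed completed-square decomposition of the default quadratic bound:
#: standalone diagonal terms plus weighted squares a*(x_i - b*x_j)^2.
PRINTED_SOS_TERMS = {
    "standalone": {"x1": 0.02, "x2": 0.02, "x3": 0.05,
                   "x4": 0.5, "x5": 5.0, "x6": 0.5},
    "squares": [  # (weight, i, b, j) for weight * (x_i - b x_j)^2
        (1.28, 0, 0.429, 1),
        (0.30, 0, 0.5, 2),
        (0.25, 2, 0.25, 1),
        (2.0, 3, 0.000125, 2),
        (50.0, 4, 0.000007, 1),
        (10.0, 5, 0.00003, 1),
    ],
}


def sos_decomposition_check(p: ModelParams) -> Dict[str, Dict[str, float]]:
    """Term-by-term comparison of the printed completed-square form.

    Expands the printed sum-of-squares decomposition into monomial
    coefficients and reports, per monomial, the quadratic-bound
    coefficient, the expansion coefficient and the signed slack
    (bound minus expansion, on diagonal magnitudes; cross terms compared
    on the destabilizing coefficients).  Slack near zero means the hand
    decomposition balances; a large negative diagonal slack means the
    decomposition overdraws that square.
    """
    coeffs = bound_coefficients(p)
    # expand the SOS into monomials
    diag = np.array([PRINTED_SOS_TERMS["standalone"][f"x{i+1}"]
                     for i in range(6)], dtype=float)
    cross: Dict[tuple, float] = {}
    for w, i, b, j in PRINTED_SOS_TERMS["squares"]:
        diag[i] += w
        diag[j] += w * b * b
        key = (min(i, j), max(i, j))
        cross[key] = cross.get(key, 0.0) - 2.0 * w * b  # cross term of (xi - b xj)^2
    report: Dict[str, Dict[str, float]] = {}
    for i in range(6):
        key = f"x{i+1}^2"
        sos = diag[i]
        bound = coeffs[key]
        report[key] = {"bound": bound, "sos": sos, "slack": bound - sos}
    for name, (i, j) in _CROSS_INDEX.items():
        sos = -cross.get((i, j), 0.0)  # SOS contributes -cross to the negated form
        bound = coeffs[name]
        report[name] = {"bound": bound, "sos": sos, "slack": bound - sos}
    return report


def pointwise_bound_dominates(p: ModelParams, n_samples: int = 1000,
                              seed: int = 1,
                              cell_scale: float = 5000.0,
                              cytokine_scale: float = 20.0) -> dict:
    """Monte-Carlo check of V-dot(x) <= x'Qx over the non-negative orthant.

    Samples states uniformly (cells in [0, cell_scale], cytokines in
    [0, cytokine_scale]) and compares the true zero-input Lyapunov
    derivative with the saturated quadratic form.  Returns the verdict,
    the number of violations and the worst counterexample; with the
    default parameter set the domination fails on a large sub-region
    (see the module docstring), and the report quantifies it.
    """
    rng = np.random.default_rng(seed)
    cert = quadratic_bound(p)
    q = cert.bound_matrix
    states = rng.uniform(0.0, 1.0, size=(n_samples, 6))
    states[:, :3] *= cell_scale
    states[:, 3:] *= cytokine_scale
    n_viol = 0
    worst_gap = -np.inf
    worst_state = None
    for x in states:
        vdot = lyapunov_derivative(x, p)
        qform = float(x @ q @ x)
        gap = vdot - qform
        if gap > 1e-9 * max(1.0, abs(qform)):
            n_viol += 1
            if gap > worst_gap:
                worst_gap, worst_state = gap, x.copy()
    return {
        "dominates": n_viol == 0,
        "n_samples": int(n_samples),
        "n_violations": int(n_viol),
        "worst_gap": None if worst_state is None else float(worst_gap),
        "worst_state": None if worst_state is None else worst_state.tolist(),
    }
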