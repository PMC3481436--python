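"""Model parameters: kinetic rates, decay constants and Hill constants.

The six-state model couples three macrophage pools (unactivated, M1, M2)
to three cytokines (IL-10, TNF-alpha, IL-1).  Rates are per day, cell
densities cells/ml, cytokine concentrations pg/ml.

The default rate constants are reconstructed from the printed coefficients
of the quadratic Lyapunov-derivative bound, which pins the sums
``mu + k1``, ``mu + k1p``, ``k1 + k1p``, ``mu + k2 + k3 + k4``, the three
cytokine decay rates and the three secretion rates exactly.  The Hill
half-saturation constants and the myocyte secretion rate ``lam`` are not
pinned by that bound (every Hill factor there is saturated at 1); they are
free calibration targets — see :mod:`mimacro.calibration` — with documented
fallback defaults of 1.0 pg/ml.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, replace, asdict
from fractions import Fraction
from typing import Dict, List

__all__ = [
    "ModelParams",
    "default_params",
    "bound_coefficients",
    "validate",
    "LOCKED_RATE_FIELDS",
]

#: Fields whose values are fixed by the printed quadratic-bound coefficients.
#: Calibration must never touch these.
LOCKED_RATE_FIELDS = (
    "mu", "k1", "k1p", "k2", "k3", "k4",
    "k5", "k6", "k7", "d_il10", "d_ta", "d_il1",
)


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the six-state macrophage/cytokine model."""

    mu: float      # macrophage emigration rate to the lymphatics, 1/day
    k1: float      # M1 -> M2 transition rate, 1/day
    k1p: float     # M2 -> M1 transition rate, 1/day
    k2: float      # IL-1-driven M1 activation rate, 1/day
    k3: float      # TNF-alpha-driven M1 activation rate, 1/day
    k4: float      # IL-10-driven M2 activation rate, 1/day
    k5: float      # IL-10 secretion per M2 cell, pg/ml/day per cell/ml
    k6: float      # TNF-alpha secretion per M1 cell, same unit family
    k7: float      # IL-1 secretion per M1 cell, same unit family
    lam: float     # cytokine secretion per myocyte, same unit family
    d_il10: float  # IL-10 decay rate, 1/day
    d_ta: float    # TNF-alpha decay rate, 1/day
    d_il1: float   # IL-1 decay rate, 1/day
    c_il1: float   # half-saturation of IL-1-driven M1 activation, pg/ml
    c_ta: float    # half-saturation of TNF-alpha-driven M1 activation, pg/ml
    c_il10: float  # half-saturation of IL-10-driven M2 activation, pg/ml
    c1: float      # IL-10 self-inhibition Hill constant, pg/ml
    c: float       # IL-10 inhibition constant on TNF-alpha/IL-1 secretion, pg/ml

    def with_updates(self, **kwargs: float) -> "ModelParams":
        return replace(self, **kwargs)

    # -- serialization ------------------------------------------------

    def to_dict(self) -> Dict[str, float]:
        return {k: float(v) for k, v in asdict(self).items()}

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: Dict[str, float]) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        missing = known - set(d)
        if missing:
            raise ValueError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def from_json(cls, path) -> "ModelParams":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def default_params() -> ModelParams:
    """Reconstructed default parameter set.

    The rate constants solve the linear system implied by the printed
    quadratic-bound coefficients:

    * ``mu + k1 = 0.275``, ``mu + k1p = 0.25``, ``k1 + k1p = 0.125``
      -> ``mu = 0.2``, ``k1 = 0.075``, ``k1p = 0.05`` (unique solution);
    * ``k2 + k3 = 1.1`` split equally (no printed basis for asymmetry),
      ``k4 = 0.3`` (consistent with ``mu + k2 + k3 + k4 = 1.6``);
    * decay rates ``2.5, 55, 10.5`` /day; secretion rates
      ``5e-4, 7e-4, 6e-4``.

    Hill constants default to 1.0 pg/ml and ``lam`` to a homeostatic
    placeholder; both are replaced by :func:`mimacro.calibration.calibrate_to_equilibrium`
    for quantitative work.
    """
    return ModelParams(
        mu=0.2, k1=0.075, k1p=0.05,
        k2=0.55, k3=0.55, k4=0.3,
        k5=0.0005, k6=0.0007, k7=0.0006,
        lam=3.5e-8,
        d_il10=2.5, d_ta=55.0, d_il1=10.5,
        c_il1=1.0, c_ta=1.0, c_il10=1.0, c1=1.0, c=1.0,
    )


def _frac(x: float) -> Fraction:
    # exact rational view of a float that was written as a short decimal
    return Fraction(repr(float(x)))


def bound_coefficients(p: ModelParams) -> Dict[str, float]:
    """Coefficients of the Hill-saturated quadratic bound on the Lyapunov derivative.

    Diagonal entries are the (positive) magnitudes of the squared-state
    coefficients; cross entries the coefficients of the destabilizing
    bilinear terms.  Sums are taken in exact rational arithmetic so that
    e.g. ``mu + k1`` reproduces the printed 0.275 without float drift.

    Raises ``ValueError`` on a non-positive parameter.
    """
    bad = validate(p)
    if bad:
        raise ValueError("invalid parameters: " + "; ".join(bad))
    f = _frac
    coeffs = {
        "x1^2": f(p.mu) + f(p.k2) + f(p.k3) + f(p.k4),
        "x2^2": f(p.mu) + f(p.k1),
        "x3^2": f(p.k1p) + f(p.mu),
        "x4^2": f(p.d_il10),
        "x5^2": f(p.d_ta),
        "x6^2": f(p.d_il1),
        "x1x2": f(p.k2) + f(p.k3),
        "x1x3": f(p.k4),
        "x2x3": f(p.k1) + f(p.k1p),
        "x3x4": f(p.k5),
        "x2x5": f(p.k6),
        "x2x6": f(p.k7),
    }
    return {k: float(v) for k, v in coeffs.items()}


def validate(p: ModelParams) -> List[str]:
    """Return a list of invariant violations (empty when the set is valid)."""
    violations = []
    for f in fields(ModelParams):
        v = getattr(p, f.name)
        if not (isinstance(v, (int, float)) and v == v and abs(v) != float("inf")):
            violations.append(f"{f.name}: not a finite number")
        elif v <= 0:
            violations.append(f"{f.name}: must be strictly positive, got {v}")
    return violations
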