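"""Pseudo-experimental datasets with the study's sampling design.

No deposited measurements exist for this system; the comparison data in
the source study are figure-level.  This module simulates the model and
samples it at the published measurement days with multiplicative
log-normal noise, producing mean +/- SE tables a downstream fitting stage
can consume exactly like real assay data:

* total macrophages at days 1, 3, 5, 7, 14, 21, 28;
* IL-10 at days 0.25, 3, 5;
* IL-1 at days 0.25, 1, 3, 5, 7, 21;
* TNF-alpha at days 0.25, 1, 3, 5, 7, 14, 21.

M1 and M2 are not directly sampled by default (assays measure total
macrophages plus phenotype markers); ``include_phenotypes=True`` emits
them for parameter-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .inputs import InputProfile, TimeSeries, write_timeseries_csv, read_timeseries_csv
from .model import ModelParams, ModelState
from .simulate import integrate

__all__ = ["SAMPLING_DAYS", "SyntheticDataset", "generate",
           "normalize_to_baseline", "DEFAULT_INITIAL_STATE"]

SAMPLING_DAYS: Dict[str, tuple] = {
    "macrophages": (1.0, 3.0, 5.0, 7.0, 14.0, 21.0, 28.0),
    "il10": (0.25, 3.0, 5.0),
    "il1": (0.25, 1.0, 3.0, 5.0, 7.0, 21.0),
    "t_alpha": (0.25, 1.0, 3.0, 5.0, 7.0, 14.0, 21.0),
}

#: post-MI initial state: healthy unactivated pool, no polarized cells,
#: trace cytokine concentrations of 0.1 pg/ml
DEFAULT_INITIAL_STATE = ModelState(2000.0, 0.0, 0.0, 0.1, 0.1, 0.1)

_N_REP_DEFAULT = 5


@dataclass(frozen=True)
class SyntheticDataset:
    """Per-species noisy time courses plus the generating ground truth."""

    series: Dict[str, TimeSeries]
    truth_params: ModelParams
    truth_inputs: InputProfile
    seed: int
    noise_cv: float
    initial_state: ModelState = DEFAULT_INITIAL_STATE

    def to_csv(self, path) -> None:
        write_timeseries_csv(list(self.series.values()), path)

    def with_series(self, series: Dict[str, TimeSeries]) -> "SyntheticDataset":
        return SyntheticDataset(series=series, truth_params=self.truth_params,
                                truth_inputs=self.truth_inputs, seed=self.seed,
                                noise_cv=self.noise_cv,
                                initial_state=self.initial_state)


def _sample_trajectory(traj, species: str, days) -> np.ndarray:
    if species == "macrophages":
        return np.array([traj.at(d)[:3].sum() for d in days])
    return np.array([traj.at(d)[{"m1": 1, "m2": 2, "il10": 3,
                                 "t_alpha": 4, "il1": 5}[species]] for d in days])


def generate(p: ModelParams, u: InputProfile, noise_cv: float = 0.2,
             seed: int = 0, n_rep: int = _N_REP_DEFAULT,
             include_phenotypes: bool = False,
             s0: ModelState = DEFAULT_INITIAL_STATE) -> SyntheticDataset:
    """Simulate the model and emit noisy design-day samples.

    Noise is multiplicative log-normal with coefficient of variation
    ``noise_cv`` and unit mean (sigma^2 = ln(1 + cv^2), mu = -sigma^2/2),
    preserving non-negativity and the expected value; the reported SE is
    ``noise_cv * mean / sqrt(n_rep)``.  Deterministic for a fixed seed.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    t_end = max(max(days) for days in SAMPLING_DAYS.values())
    traj = integrate(s0, p, u, (0.0, min(t_end, u.t_max)), samples_per_day=8)

    designs = dict(SAMPLING_DAYS)
    if include_phenotypes:
        designs["m1"] = SAMPLING_DAYS["macrophages"]
        designs["m2"] = SAMPLING_DAYS["macrophages"]

    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    series: Dict[str, TimeSeries] = {}
    for species, days in designs.items():
        clean = _sample_trajectory(traj, species, days)
        if noise_cv > 0:
            factors = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma,
                                    size=len(days))
            noisy = clean * factors
        else:
            noisy = clean.copy()
        se = noise_cv * np.maximum(clean, 0.0) / np.sqrt(n_rep)
        series[species] = TimeSeries(days=tuple(days), values=tuple(noisy),
                                     se=tuple(se), species=species)
    return SyntheticDataset(series=series, truth_params=p, truth_inputs=u,
                            seed=seed, noise_cv=noise_cv, initial_state=s0)


def normalize_to_baseline(ds: SyntheticDataset,
                          baseline: Dict[str, float]) -> SyntheticDataset:
    """Divide each species' values (and SEs) by its control-group baseline."""
    out: Dict[str, TimeSeries] = {}
    for species, ts in ds.series.items():
        b = float(baseline.get(species, 1.0))
        if b <= 0:
            raise ValueError(f"baseline for {species} must be positive")
        se = None if ts.se is None else tuple(s / b for s in ts.se)
        out[species] = TimeSeries(days=ts.days,
                                  values=tuple(v / b for v in ts.values),
                                  se=se, species=species)
    return ds.with_series(out)
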