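"""Synthetic dose-survival experiments and caliper growth logs.

Two generators, both fully seeded:

* :func:`simulate_survival_experiment` emulates a plate-based luminescence
  viability readout: each well's signal is a baseline times the LQ surviving
  fraction at its dose, times a mean-1 multiplicative lognormal noise term.
  Untreated control wells carry the same noise around the baseline, so the
  expected normalized survival at dose d is exactly S(d).

* :func:`simulate_invivo_growth` emulates caliper measurements of flank
  xenografts under fractionated irradiation: exponential volume growth with
  an instantaneous multiplicative cell kill S(d) at each fraction, with
  length/width back-computed from volume at a fixed length:width aspect
  ratio and optionally perturbed. It is a deliberately simple kinetic
  sketch for exercising the growth metrics, not a tumor-kinetics claim.

The lognormal noise uses the mean-1 parameterization
sigma^2 = ln(1 + cv^2), mu = -sigma^2/2, appropriate for strictly positive,
right-skewed assay signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import DoseSurvivalDataset, normalize_signal_table
from .exceptions import DesignError
from .lq import lq_survival

__all__ = [
    "DEFAULT_DOSE_GRID",
    "StratumSpec",
    "SurvivalSimulationDesign",
    "simulate_survival_experiment",
    "Regimen",
    "GrowthSimulationDesign",
    "simulate_invivo_growth",
    "lognormal_factors",
]

#: default single-dose grid (Gy), spanning the 0-30 Gy range used for NPC models
DEFAULT_DOSE_GRID = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 16.0, 20.0, 25.0, 30.0)

#: caliper schedule: every other day over four weeks
DEFAULT_MEASUREMENT_DAYS = tuple(range(0, 29, 2))


def lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with coefficient of variation cv."""
    if cv < 0:
        raise DesignError("noise cv must be >= 0")
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=size)


@dataclass(frozen=True)
class StratumSpec:
    """True LQ parameters of one simulated stratum."""

    model_system: str
    oxygen_condition: str
    assay_day: int
    alpha: float
    beta: float


@dataclass(frozen=True)
class SurvivalSimulationDesign:
    """Design of a simulated single-dose survival experiment.

    Defaults mirror the NPC organoid study conditions: an 11-point dose grid
    spanning 0-30 Gy, 3 replicate wells per dose, 10% multiplicative noise,
    and 3 untreated control wells per stratum.
    """

    strata: tuple[StratumSpec, ...]
    dose_grid: tuple[float, ...] = DEFAULT_DOSE_GRID
    replicates_per_dose: int = 3
    noise_cv: float = 0.10
    n_control_wells: int = 3
    baseline_signal: float = 10_000.0
    seed: int = 0

    def __post_init__(self):
        if not self.strata:
            raise DesignError("at least one stratum required")
        if len(self.dose_grid) == 0:
            raise DesignError("dose grid must be nonempty")
        if any(d < 0 for d in self.dose_grid):
            raise DesignError("doses must be >= 0")
        if self.replicates_per_dose < 1 or self.n_control_wells < 1:
            raise DesignError("replicates_per_dose and n_control_wells must be >= 1")
        if self.noise_cv < 0 or self.baseline_signal <= 0:
            raise DesignError("noise_cv must be >= 0 and baseline_signal > 0")
        for s in self.strata:
            if s.alpha < 0 or s.beta < 0:
                raise DesignError("true alpha and beta must be >= 0")


def simulate_survival_experiment(
    design: SurvivalSimulationDesign,
) -> tuple[DoseSurvivalDataset, pd.DataFrame]:
    """Simulate raw well signals and the normalized dataset.

    Returns ``(dataset, signals)`` where ``signals`` is the raw table in the
    input-CSV dialect (including control wells) and ``dataset`` is the
    per-stratum normalized :class:`DoseSurvivalDataset`. Identical designs
    and seeds give identical output.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for spec in design.strata:
        ctrl_noise = lognormal_factors(rng, design.noise_cv, design.n_control_wells)
        for i in range(design.n_control_wells):
            rows.append(
                (spec.model_system, spec.oxygen_condition, spec.assay_day,
                 0.0, f"ctrl{i + 1}", design.baseline_signal * ctrl_noise[i], 1)
            )
        for dose in design.dose_grid:
            s_true = lq_survival(spec.alpha, spec.beta, float(dose))
            eps = lognormal_factors(rng, design.noise_cv, design.replicates_per_dose)
            for r in range(design.replicates_per_dose):
                rows.append(
                    (spec.model_system, spec.oxygen_condition, spec.assay_day,
                     float(dose), f"rep{r + 1}", design.baseline_signal * s_true * eps[r], 0)
                )
    signals = pd.DataFrame(
        rows,
        columns=["model_system", "oxygen_condition", "assay_day",
                 "dose_gy", "replicate_id", "signal", "is_control"],
    )
    return normalize_signal_table(signals), signals


@dataclass(frozen=True)
class Regimen:
    """A fractionation arm: ``dose_per_fraction`` Gy on each day in ``fraction_days``.

    An empty ``fraction_days`` tuple is an untreated control arm.
    """

    name: str
    dose_per_fraction: float = 0.0
    fraction_days: tuple[int, ...] = ()

    def __post_init__(self):
        if self.fraction_days and self.dose_per_fraction <= 0:
            raise DesignError("treated regimens need a positive dose per fraction")


@dataclass(frozen=True)
class GrowthSimulationDesign:
    """Design of a simulated xenograft irradiation experiment.

    Defaults follow the in-vivo study layout: 7 animals per group, treatment
    started at ~200 mm^3, caliper readings every other day. ``alpha`` and
    ``beta`` are the LQ parameters governing the per-fraction kill (hypoxic
    organoid day-21 values by default: a flank PDX carries substantial
    hypoxic volume even at 200-300 mm^3).
    """

    regimens: tuple[Regimen, ...]
    n_animals_per_group: int = 7
    initial_volume: float = 200.0
    growth_rate: float = np.log(2) / 7.0  # one doubling per week
    alpha: float = 0.0254
    beta: float = 0.0013
    measurement_days: tuple[int, ...] = DEFAULT_MEASUREMENT_DAYS
    caliper_noise_cv: float = 0.0
    aspect_ratio: float = 1.3  # length : width
    seed: int = 0

    def __post_init__(self):
        if not self.regimens:
            raise DesignError("at least one regimen required")
        if self.initial_volume <= 0:
            raise DesignError("initial volume must be positive")
        if self.n_animals_per_group < 1:
            raise DesignError("need at least one animal per group")
        if self.aspect_ratio < 1.0:
            raise DesignError("aspect_ratio (length/width) must be >= 1")
        if self.caliper_noise_cv < 0:
            raise DesignError("caliper_noise_cv must be >= 0")


def _volume_at(design: GrowthSimulationDesign, regimen: Regimen, day: int) -> float:
    """Noise-free volume: exponential growth with instant kill at each fraction
    on or before ``day``."""
    kill = 1.0
    for f_day in regimen.fraction_days:
        if f_day <= day:
            kill *= lq_survival(design.alpha, design.beta, regimen.dose_per_fraction)
    return design.initial_volume * np.exp(design.growth_rate * day) * kill


def simulate_invivo_growth(design: GrowthSimulationDesign) -> pd.DataFrame:
    """Simulate a caliper log (``animal_id, group, day, length_mm, width_mm``).

    Length and width are recovered from the noise-free volume through
    V = L * W^2 / 2 with L = aspect_ratio * W, then each dimension gets an
    independent mean-1 lognormal perturbation of CV ``caliper_noise_cv``.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for regimen in design.regimens:
        for a in range(design.n_animals_per_group):
            animal = f"{regimen.name}_m{a + 1}"
            for day in design.measurement_days:
                v = _volume_at(design, regimen, int(day))
                width = (2.0 * v / design.aspect_ratio) ** (1.0 / 3.0)
                length = design.aspect_ratio * width
                noise = lognormal_factors(rng, design.caliper_noise_cv, 2)
                rows.append(
                    (animal, regimen.name, int(day), length * noise[0], width * noise[1])
                )
    return pd.DataFrame(rows, columns=["animal_id", "group", "day", "length_mm", "width_mm"])
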