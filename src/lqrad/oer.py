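"""Alpha/beta summaries and the oxygen enhancement ratio (OER).

Here OER is the ratio of the hypoxic to the normoxic alpha/beta ratio for
the same model system. Radiobiologically it is read as the multiplicative
boost to the physical dose per fraction needed for a hypoxic population to
sustain the same biological effect as its normoxic counterpart.

Per-day alpha/beta ratios from repeated assays are combined by arithmetic
mean; the two arms can then be combined either as the ratio of the two mean
ratios (``ratio_of_means``, default) or as the mean of day-matched ratio
quotients (``mean_of_ratios``). The two rules differ under day-to-day
variation and both are exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .exceptions import UndefinedRatioError

__all__ = [
    "alpha_beta_ratio",
    "alpha_beta_ratio_se",
    "AlphaBetaSummary",
    "summarize_across_days",
    "compute_oer",
    "OERResult",
]


def alpha_beta_ratio(params) -> float:
    """alpha/beta (Gy) of a fitted parameter set.

    ``params`` is anything with ``alpha`` and ``beta`` attributes (an
    :class:`~lqrad.lq.LQResults` or :class:`~lqrad.lq.LQParameters`).
    Raises :class:`UndefinedRatioError` when beta = 0.
    """
    if params.beta <= 0:
        raise UndefinedRatioError("alpha/beta undefined for beta = 0")
    return params.alpha / params.beta


def alpha_beta_ratio_se(params) -> float:
    """Delta-method standard error of alpha/beta.

    For r = alpha/beta,

        Var(r) = (1/beta)^2 Var(alpha) + (alpha/beta^2)^2 Var(beta)
                 - 2 (alpha/beta^3) Cov(alpha, beta)

    A negative variance (inconsistent covariance input) raises.
    """
    if params.beta <= 0:
        raise UndefinedRatioError("alpha/beta undefined for beta = 0")
    a, b = params.alpha, params.beta
    var = (
        (params.se_alpha / b) ** 2
        + (a * params.se_beta / b**2) ** 2
        - 2.0 * (a / b**3) * params.cov_alpha_beta
    )
    if var < 0:
        raise ValueError("negative ratio variance: covariance inconsistent with SEs")
    return math.sqrt(var)


@dataclass(frozen=True)
class AlphaBetaSummary:
    """Per-day alpha/beta ratios of one (system, condition) arm and their mean."""

    model_system: str
    oxygen_condition: str
    per_day_ratios: Mapping[int, float]
    method: str = "mean_of_ratios"
    mean_ratio: float = field(init=False)

    def __post_init__(self):
        if not self.per_day_ratios:
            raise ValueError("at least one per-day ratio required")
        vals = list(self.per_day_ratios.values())
        if any(v <= 0 for v in vals):
            raise ValueError("alpha/beta ratios must be positive")
        object.__setattr__(self, "per_day_ratios", dict(self.per_day_ratios))
        object.__setattr__(self, "mean_ratio", sum(vals) / len(vals))

    def to_dict(self) -> dict:
        return {
            "model_system": self.model_system,
            "oxygen_condition": self.oxygen_condition,
            "per_day": {int(k): float(v) for k, v in sorted(self.per_day_ratios.items())},
            "mean": float(self.mean_ratio),
        }


def summarize_across_days(fits: Sequence) -> AlphaBetaSummary:
    """Combine per-day LQ fits of one (system, condition) arm.

    ``fits`` are objects carrying ``model_system``, ``oxygen_condition``,
    ``assay_day``, ``alpha`` and ``beta``. All must belong to the same arm
    and have distinct days; the summary mean is the arithmetic mean of the
    per-day alpha/beta values.
    """
    if not fits:
        raise ValueError("no fits to summarize")
    systems = {f.model_system for f in fits}
    conditions = {f.oxygen_condition for f in fits}
    if len(systems) != 1 or len(conditions) != 1:
        raise ValueError(f"mixed strata: systems={systems}, conditions={conditions}")
    days = [f.assay_day for f in fits]
    if len(set(days)) != len(days):
        raise ValueError("duplicate assay days in summary input")
    ratios = {int(f.assay_day): alpha_beta_ratio(f) for f in fits}
    return AlphaBetaSummary(systems.pop(), conditions.pop(), ratios)


@dataclass(frozen=True)
class OERResult:
    """Oxygen enhancement ratio with the two arm summaries that produced it."""

    oer: float
    hypoxic_summary: AlphaBetaSummary
    normoxic_summary: AlphaBetaSummary
    combination_rule: str
    se_oer: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "system": self.hypoxic_summary.model_system,
            "hypoxic": self.hypoxic_summary.to_dict(),
            "normoxic": self.normoxic_summary.to_dict(),
            "oer": float(self.oer),
            "rule": self.combination_rule,
            "se_oer": self.se_oer,
        }


def compute_oer(
    hypoxic: AlphaBetaSummary,
    normoxic: AlphaBetaSummary,
    rule: str = "ratio_of_means",
) -> OERResult:
    """OER = (alpha/beta under hypoxia) / (alpha/beta under normoxia).

    ``ratio_of_means`` divides the two arm means; ``mean_of_ratios``
    averages the per-day quotients and requires both arms to cover the
    same assay days (a mismatch raises rather than silently intersecting).
    """
    if hypoxic.model_system != normoxic.model_system:
        raise ValueError(
            f"mismatched systems: {hypoxic.model_system} vs {normoxic.model_system}"
        )
    if rule == "ratio_of_means":
        if normoxic.mean_ratio <= 0:
            raise ZeroDivisionError("normoxic mean ratio must be positive")
        value = hypoxic.mean_ratio / normoxic.mean_ratio
    elif rule == "mean_of_ratios":
        h_days = set(hypoxic.per_day_ratios)
        n_days = set(normoxic.per_day_ratios)
        if h_days != n_days:
            raise ValueError(f"day sets differ: hypoxic {sorted(h_days)} vs normoxic {sorted(n_days)}")
        quotients = [
            hypoxic.per_day_ratios[d] / normoxic.per_day_ratios[d] for d in sorted(h_days)
        ]
        value = sum(quotients) / len(quotients)
    else:
        raise ValueError(f"unknown combination rule {rule!r}")
    return OERResult(value, hypoxic, normoxic, rule)
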