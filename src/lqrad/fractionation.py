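"""Biologically effective dose (BED) and isoeffect fractionation design.

A course of n fractions of d Gy each has

    BED = n * d * (1 + d / (alpha/beta))        [Gy, subscripted by alpha/beta]

BED puts schemes with different doses per fraction on a common effect scale
for a tissue with the given alpha/beta. The design workflow implemented here
starts from a reference scheme (conventionally 2 Gy x 30, alpha/beta 10 Gy,
BED 72 Gy_10), scales each candidate physical dose per fraction by the OER
to compensate hypoxia, and solves for the integer fraction count whose BED
(at the hypoxic alpha/beta) is closest to the reference BED.

BEDs computed with different alpha/beta values are not directly comparable;
comparisons across schemes carrying different alpha/beta tags warn.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import pandas as pd

__all__ = [
    "bed",
    "oer_corrected_dose",
    "dose_for_bed",
    "isoeffective_fractions",
    "IsoeffectiveSolution",
    "DoseScheme",
    "bed_ratio",
    "scheme_table",
    "schemes_to_frame",
    "render_scheme_table",
]


def bed(n_fractions: int, dose_per_fraction: float, alpha_beta: float) -> float:
    """BED (Gy) of ``n_fractions`` fractions of ``dose_per_fraction`` Gy."""
    n = int(n_fractions)
    if n < 1:
        raise ValueError("n_fractions must be >= 1")
    if dose_per_fraction < 0:
        raise ValueError("dose_per_fraction must be >= 0")
    if alpha_beta <= 0:
        raise ValueError("alpha_beta must be positive")
    d = float(dose_per_fraction)
    return n * d * (1.0 + d / alpha_beta)


def oer_corrected_dose(reference_dose_per_fraction: float, oer: float) -> float:
    """Physical dose per fraction boosted by the OER (e.g. 1.8 Gy x 1.4 = 2.52 Gy)."""
    if reference_dose_per_fraction <= 0:
        raise ValueError("dose must be positive")
    if oer <= 0:
        raise ValueError("OER must be positive")
    return reference_dose_per_fraction * oer


def dose_for_bed(n_fractions: int, alpha_beta: float, target_bed: float) -> float:
    """Dose per fraction achieving ``target_bed`` in ``n_fractions`` fractions.

    Positive root of the per-fraction quadratic:
    d = (ab/2) * (-1 + sqrt(1 + 4*target/(n*ab))); exact inverse of bed().
    """
    n = int(n_fractions)
    if n < 1:
        raise ValueError("n_fractions must be >= 1")
    if alpha_beta <= 0 or target_bed <= 0:
        raise ValueError("alpha_beta and target_bed must be positive")
    ab = float(alpha_beta)
    return 0.5 * ab * (-1.0 + math.sqrt(1.0 + 4.0 * target_bed / (n * ab)))


class IsoeffectiveSolution(NamedTuple):
    n_fractions: int
    achieved_bed: float


def isoeffective_fractions(
    dose_per_fraction: float, alpha_beta: float, target_bed: float
) -> IsoeffectiveSolution:
    """Integer fraction count whose BED is closest to ``target_bed``.

    Rounds the real-valued solution to the nearest integer (minimum 1) and
    verifies local optimality among neighbouring counts. A target smaller
    than half of a single fraction's BED admits no sensible scheme.
    """
    if dose_per_fraction <= 0 or alpha_beta <= 0 or target_bed <= 0:
        raise ValueError("all inputs must be positive")
    per_fraction = bed(1, dose_per_fraction, alpha_beta)
    if target_bed < 0.5 * per_fraction:
        raise ValueError(
            f"target BED {target_bed:g} Gy is below half of one fraction's "
            f"BED ({per_fraction:g} Gy): no valid scheme"
        )
    n = max(1, round(target_bed / per_fraction))
    candidates = [m for m in (n - 1, n, n + 1) if m >= 1]
    n_best = min(candidates, key=lambda m: (abs(m * per_fraction - target_bed), m))
    return IsoeffectiveSolution(n_best, bed(n_best, dose_per_fraction, alpha_beta))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class DoseScheme:
    """One fractionation scheme with its BED bookkeeping.

    ``bed`` and ``total_physical_dose`` are derived from the other fields at
    construction; ``oer_applied`` records the oxygen correction factor that
    produced ``dose_per_fraction`` (1 when none was applied).
    """

    name: str
    dose_per_fraction: float
    n_fractions: int
    alpha_beta: float
    oer_applied: float = 1.0
    bed: float = None  # type: ignore[assignment]
    total_physical_dose: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.dose_per_fraction <= 0:
            raise ValueError("dose_per_fraction must be positive")
        if int(self.n_fractions) < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.alpha_beta <= 0:
            raise ValueError("alpha_beta must be positive")
        if self.oer_applied < 1.0:
            raise ValueError("oer_applied must be >= 1")
        object.__setattr__(self, "n_fractions", int(self.n_fractions))
        object.__setattr__(
            self, "bed", bed(self.n_fractions, self.dose_per_fraction, self.alpha_beta)
        )
        object.__setattr__(
            self, "total_physical_dose", self.n_fractions * self.dose_per_fraction
        )

    @property
    def bed_reported(self) -> int:
        """BED rounded half-away-from-zero to an integer for table display."""
        return _round_half_away(self.bed)


def scheme_table(
    reference: DoseScheme,
    oer: float,
    hypoxic_alpha_beta: float,
    candidate_doses_per_fraction: Sequence[float],
) -> list[DoseScheme]:
    """Reference scheme plus OER-corrected, BED-matched candidate schemes.

    Each candidate dose per fraction is multiplied by ``oer`` and the
    fraction count is solved so that its BED at ``hypoxic_alpha_beta`` is
    closest to the reference scheme's BED. Row order: reference first, then
    candidates as given.
    """
    if oer < 1.0:
        raise ValueError("oer must be >= 1")
    rows = [reference]
    for i, d in enumerate(candidate_doses_per_fraction, start=1):
        d_corr = oer_corrected_dose(d, oer)
        sol = isoeffective_fractions(d_corr, hypoxic_alpha_beta, reference.bed)
        rows.append(
            DoseScheme(
                name=f"candidate_{i} ({d:g} Gy x OER)",
                dose_per_fraction=d_corr,
                n_fractions=sol.n_fractions,
                alpha_beta=hypoxic_alpha_beta,
                oer_applied=oer,
            )
        )
    return rows


def bed_ratio(a: DoseScheme, b: DoseScheme) -> float:
    """BED(a)/BED(b); warns when the schemes carry different alpha/beta tags,
    since BEDs on different effect scales are not directly comparable."""
    if not math.isclose(a.alpha_beta, b.alpha_beta):
        warnings.warn(
            f"comparing BEDs computed with alpha/beta {a.alpha_beta:g} vs "
            f"{b.alpha_beta:g} Gy: these are on different effect scales",
            stacklevel=2,
        )
    return a.bed / b.bed


def schemes_to_frame(schemes: Sequence[DoseScheme]) -> pd.DataFrame:
    """Tabulate schemes; BED is shown both at full precision and as the
    integer-reported value."""
    return pd.DataFrame(
        {
            "scheme": [s.name for s in schemes],
            "dose_per_fraction_gy": [round(s.dose_per_fraction, 4) for s in schemes],
            "n_fractions": [s.n_fractions for s in schemes],
            "alpha_beta_gy": [round(s.alpha_beta, 4) for s in schemes],
            "oer_applied": [round(s.oer_applied, 4) for s in schemes],
            "total_physical_dose_gy": [round(s.total_physical_dose, 4) for s in schemes],
            "bed_gy": [round(s.bed, 4) for s in schemes],
            "bed_reported_gy": [s.bed_reported for s in schemes],
        }
    )


def render_scheme_table(schemes: Sequence[DoseScheme]) -> str:
    """Aligned text table: dose per fraction, fraction count, reported BED."""
    header = f"{'Dose scheme':<28} {'Dose/fx (Gy)':>12} {'Fractions':>10} {'BED (Gy)':>9}"
    lines = [header, "-" * len(header)]
    for s in schemes:
        lines.append(
            f"{s.name:<28} {s.dose_per_fraction:>12.4g} {s.n_fractions:>10d} {s.bed_reported:>9d}"
        )
    return "\n".join(lines)
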