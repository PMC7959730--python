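"""Dose-survival datasets and viability normalization.

The raw readout of a luminescence viability assay is a per-well signal.
Survival fractions are obtained by dividing each treated-well signal by the
mean signal of the untreated control wells of the same stratum (one stratum =
one model system x oxygen condition x assay day). Values above 1 are kept:
they are legitimate noise above the control mean, not errors.

CSV dialect (header row, UTF-8)::

    model_system, oxygen_condition, assay_day, dose_gy, replicate_id, signal, is_control

with ``is_control`` in {0, 1}. :func:`read_signals_csv` normalizes per
stratum and returns a :class:`DoseSurvivalDataset`.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, NormalizationError

MODEL_SYSTEMS = ("organoid", "spheroid", "monolayer")
OXYGEN_CONDITIONS = ("normoxic_21pct", "hypoxic_1pct")

#: columns of the normalized survival table
SURVIVAL_COLUMNS = (
    "model_system",
    "oxygen_condition",
    "assay_day",
    "dose_gy",
    "replicate_id",
    "survival_fraction",
)

#: columns of the raw signal table
SIGNAL_COLUMNS = (
    "model_system",
    "oxygen_condition",
    "assay_day",
    "dose_gy",
    "replicate_id",
    "signal",
    "is_control",
)

STRATUM_KEYS = ["model_system", "oxygen_condition", "assay_day"]


def normalize_viability(raw_signals: Iterable[float], control_signals: Iterable[float]) -> np.ndarray:
    """Express raw viability signals relative to the untreated-control mean.

    Parameters
    ----------
    raw_signals
        Per-well signals of treated wells; nonnegative.
    control_signals
        Per-well signals of untreated wells from the same stratum; must be
        nonempty with positive mean.

    Returns
    -------
    ndarray of survival fractions, ``raw / mean(control)``. Values above 1
    are permitted (noise above control).
    """
    raw = np.asarray(list(raw_signals), dtype=float)
    ctrl = np.asarray(list(control_signals), dtype=float)
    if raw.size == 0:
        raise NormalizationError("no raw signals to normalize")
    if ctrl.size == 0:
        raise NormalizationError("no control signals for normalization")
    if np.any(raw < 0) or np.any(ctrl < 0):
        raise NormalizationError("viability signals must be nonnegative")
    if not np.all(np.isfinite(raw)) or not np.all(np.isfinite(ctrl)):
        raise NormalizationError("viability signals must be finite")
    mean_ctrl = float(ctrl.mean())
    if mean_ctrl <= 0:
        raise NormalizationError("control signals have non-positive mean")
    return raw / mean_ctrl


class DoseSurvivalDataset:
    """Replicate survival fractions indexed by stratum and dose.

    A thin, validated wrapper around a long-format :class:`pandas.DataFrame`
    with the columns in :data:`SURVIVAL_COLUMNS`. Each stratum used for LQ
    fitting must contain at least three distinct positive doses.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in SURVIVAL_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        frame = frame.copy()
        frame["assay_day"] = frame["assay_day"].astype(int)
        frame["dose_gy"] = frame["dose_gy"].astype(float)
        frame["survival_fraction"] = frame["survival_fraction"].astype(float)
        self._validate(frame)
        self.frame = frame.reset_index(drop=True)

    @staticmethod
    def _validate(frame: pd.DataFrame) -> None:
        doses = frame["dose_gy"].to_numpy()
        surv = frame["survival_fraction"].to_numpy()
        if not np.all(np.isfinite(doses)) or np.any(doses < 0):
            raise ValueError("doses must be finite and >= 0")
        if not np.all(np.isfinite(surv)) or np.any(surv <= 0):
            raise ValueError("survival fractions must be finite and > 0")
        bad_sys = set(frame["model_system"]) - set(MODEL_SYSTEMS)
        if bad_sys:
            raise ValueError(f"unknown model_system values: {sorted(bad_sys)}")
        bad_cond = set(frame["oxygen_condition"]) - set(OXYGEN_CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown oxygen_condition values: {sorted(bad_cond)}")
        if np.any(frame["assay_day"].to_numpy() <= 0):
            raise ValueError("assay_day must be positive")

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "DoseSurvivalDataset":
        return cls(pd.DataFrame.from_records(list(records)))

    def strata(self) -> Iterator[tuple[tuple, pd.DataFrame]]:
        """Yield ``((system, condition, day), sub-frame)`` pairs."""
        for key, sub in self.frame.groupby(STRATUM_KEYS, sort=True):
            yield key, sub

    def stratum(self, model_system: str, oxygen_condition: str, assay_day: int) -> pd.DataFrame:
        mask = (
            (self.frame["model_system"] == model_system)
            & (self.frame["oxygen_condition"] == oxygen_condition)
            & (self.frame["assay_day"] == int(assay_day))
        )
        sub = self.frame[mask]
        if sub.empty:
            raise KeyError(
                f"no data for stratum ({model_system}, {oxygen_condition}, {assay_day})"
            )
        return sub

    def check_fittable(self, sub: pd.DataFrame | None = None) -> None:
        """Raise :class:`InsufficientDataError` unless every stratum (or the
        given one) has >= 3 distinct positive doses."""
        frames = [sub] if sub is not None else [s for _, s in self.strata()]
        for fr in frames:
            n_pos = fr.loc[fr["dose_gy"] > 0, "dose_gy"].nunique()
            if n_pos < 3:
                key = tuple(fr.iloc[0][k] for k in STRATUM_KEYS) if len(fr) else ()
                raise InsufficientDataError(
                    f"stratum {key}: {n_pos} distinct positive doses (< 3)"
                )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:
        n_strata = self.frame.groupby(STRATUM_KEYS).ngroups
        return f"<DoseSurvivalDataset: {len(self.frame)} wells, {n_strata} strata>"


def normalize_signal_table(signals: pd.DataFrame) -> DoseSurvivalDataset:
    """Normalize a raw signal table (``SIGNAL_COLUMNS`` dialect) per stratum.

    Treated wells are divided by the mean signal of the ``is_control == 1``
    wells of the same (system, condition, day) stratum.
    """
    missing = [c for c in SIGNAL_COLUMNS if c not in signals.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    out = []
    for key, sub in signals.groupby(STRATUM_KEYS, sort=True):
        ctrl = sub.loc[sub["is_control"].astype(int) == 1, "signal"]
        treated = sub[sub["is_control"].astype(int) == 0]
        if ctrl.empty:
            raise NormalizationError(f"stratum {key}: no control wells")
        sf = normalize_viability(treated["signal"].to_numpy(), ctrl.to_numpy())
        block = treated[["model_system", "oxygen_condition", "assay_day", "dose_gy", "replicate_id"]].copy()
        block["survival_fraction"] = sf
        out.append(block)
    if not out:
        raise InsufficientDataError("signal table contains no treated wells")
    return DoseSurvivalDataset(pd.concat(out, ignore_index=True))


def read_signals_csv(path) -> DoseSurvivalDataset:
    """Read the raw-signal CSV dialect and normalize per stratum."""
    return normalize_signal_table(pd.read_csv(path))


def read_survival_csv(path) -> DoseSurvivalDataset:
    """Read an already-normalized survival table."""
    return DoseSurvivalDataset(pd.read_csv(path))
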