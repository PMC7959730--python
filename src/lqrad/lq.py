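"""The linear-quadratic (LQ) cell-survival model and its fitting machinery.

The LQ model describes the surviving fraction of cells after a single
radiation dose *d* (Gy) as

    S(d) = exp(-alpha * d - beta * d**2)

with alpha (Gy^-1) the single-hit and beta (Gy^-2) the double-hit kill
coefficient. The ratio alpha/beta (Gy) is the dose at which the two
contributions are equal and governs sensitivity to fraction size.

Fitting follows the statsmodels pattern: build an :class:`LQModel` from the
data, call :meth:`LQModel.fit`, and read estimates, standard errors and
diagnostics off the returned :class:`LQResults`.

Two fit domains are supported. ``log_survival`` (default) performs
least squares on -ln S, which is linear in (d, d^2) with no intercept, so
the estimate is deterministic and needs no starting values; nonnegativity
of (alpha, beta) is enforced by NNLS. ``survival`` performs bounded
nonlinear least squares on S itself. The two agree on noiseless data but
weight noise differently; standard errors come from the local curvature of
whichever objective was minimized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .data import DoseSurvivalDataset
from .exceptions import DegenerateFitError, InsufficientDataError

__all__ = ["lq_survival", "LQModel", "LQResults", "LQParameters", "fit_lq", "goodness_of_fit"]


def lq_survival(alpha: float, beta: float, dose):
    """Surviving fraction S(d) = exp(-alpha*d - beta*d^2).

    ``dose`` may be a scalar or array; alpha, beta, dose must be >= 0.
    S(0) = 1 and S is strictly decreasing in dose when alpha or beta > 0.
    """
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be nonnegative")
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be nonnegative")
    out = np.exp(-(alpha * d + beta * d * d))
    return float(out) if np.isscalar(dose) or d.ndim == 0 else out


@dataclass(frozen=True)
class LQParameters:
    """Fitted LQ parameters for one stratum, with uncertainties.

    ``alpha_beta_ratio`` is ``None`` when beta = 0 (the ratio is undefined,
    not infinite). ``r_squared`` is computed on the fit domain and may be
    negative for a fit worse than the mean.
    """

    alpha: float
    beta: float
    se_alpha: float
    se_beta: float
    cov_alpha_beta: float
    alpha_beta_ratio: Optional[float]
    r_squared: float
    n_observations: int
    fit_domain: str
    model_system: Optional[str] = None
    oxygen_condition: Optional[str] = None
    assay_day: Optional[int] = None
    boundary_hit: bool = False


class LQModel:
    """LQ dose-survival model for a single experimental stratum.

    Parameters
    ----------
    dose : array-like of Gy, >= 0
    survival : array-like of survival fractions, > 0 (values > 1 allowed)
    fit_domain : {"log_survival", "survival"}
    weights : optional per-observation weights (uniform if omitted)
    log_floor : positive floor applied to survival before the log transform
        (survival-domain fits are unaffected); default 1e-6
    use_dose_means : fit on per-dose mean survival instead of all replicate
        points; off by default so replicate scatter informs the SEs
    """

    def __init__(
        self,
        dose,
        survival,
        *,
        fit_domain: str = "log_survival",
        weights=None,
        log_floor: float = 1e-6,
        use_dose_means: bool = False,
        model_system: str | None = None,
        oxygen_condition: str | None = None,
        assay_day: int | None = None,
    ):
        if fit_domain not in ("log_survival", "survival"):
            raise ValueError(f"unknown fit_domain {fit_domain!r}")
        if log_floor <= 0:
            raise ValueError("log_floor must be positive")
        dose = np.asarray(dose, dtype=float)
        survival = np.asarray(survival, dtype=float)
        if dose.shape != survival.shape or dose.ndim != 1:
            raise ValueError("dose and survival must be 1-d arrays of equal length")
        if np.any(dose < 0) or not np.all(np.isfinite(dose)):
            raise ValueError("doses must be finite and >= 0")
        if np.any(survival <= 0) or not np.all(np.isfinite(survival)):
            raise ValueError("survival fractions must be finite and > 0")
        if weights is not None:
            weights = np.asarray(weights, dtype=float)
            if weights.shape != dose.shape or np.any(weights < 0):
                raise ValueError("weights must be nonnegative, one per observation")
        if use_dose_means:
            df = pd.DataFrame({"d": dose, "s": survival})
            g = df.groupby("d", sort=True)["s"].mean()
            dose, survival = g.index.to_numpy(), g.to_numpy()
            weights = None

        if np.unique(dose[dose > 0]).size < 3:
            raise InsufficientDataError(
                "need >= 3 distinct positive doses to fit alpha and beta"
            )

        self.dose = dose
        self.survival = survival
        self.fit_domain = fit_domain
        self.weights = weights
        self.log_floor = float(log_floor)
        self.model_system = model_system
        self.oxygen_condition = oxygen_condition
        self.assay_day = assay_day

    @classmethod
    def from_dataset(
        cls,
        dataset: DoseSurvivalDataset,
        model_system: str,
        oxygen_condition: str,
        assay_day: int,
        **options,
    ) -> "LQModel":
        sub = dataset.stratum(model_system, oxygen_condition, assay_day)
        return cls(
            sub["dose_gy"].to_numpy(),
            sub["survival_fraction"].to_numpy(),
            model_system=model_system,
            oxygen_condition=oxygen_condition,
            assay_day=assay_day,
            **options,
        )

    # -- fitting -----------------------------------------------------------

    def _weights(self) -> np.ndarray:
        return np.ones_like(self.dose) if self.weights is None else self.weights

    def fit(self) -> "LQResults":
        if self.fit_domain == "log_survival":
            return self._fit_log()
        return self._fit_survival()

    def _fit_log(self) -> "LQResults":
        y = -np.log(np.maximum(self.survival, self.log_floor))
        X = np.column_stack([self.dose, self.dose**2])
        w = self._weights()
        sw = np.sqrt(w)
        coef, _ = optimize.nnls(X * sw[:, None], y * sw)
        alpha, beta = float(coef[0]), float(coef[1])
        boundary = bool(alpha == 0.0 or beta == 0.0)
        resid = y - X @ coef
        n, p = len(y), 2
        ssr = float(w @ resid**2)
        dof = max(n - p, 1)
        s2 = ssr / dof
        xtx = (X * w[:, None]).T @ X
        try:
            cov = s2 * np.linalg.inv(xtx)
        except np.linalg.LinAlgError:  # collinear design (cannot happen with >=3 doses)
            cov = np.full((2, 2), np.nan)
        rsq = _r_squared(y, X @ coef, w)
        return LQResults(self, alpha, beta, cov, rsq, n, boundary)

    def _fit_survival(self) -> "LQResults":
        w = self._weights()
        # start from the deterministic log-domain solution
        p0 = self._fit_log()
        sigma = None if self.weights is None else 1.0 / np.sqrt(np.maximum(w, 1e-12))

        def f(d, a, b):
            return np.exp(-(a * d + b * d * d))

        popt, pcov = optimize.curve_fit(
            f,
            self.dose,
            self.survival,
            p0=[max(p0.alpha, 1e-6), max(p0.beta, 1e-8)],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            sigma=sigma,
            maxfev=10000,
        )
        alpha, beta = float(popt[0]), float(popt[1])
        boundary = bool(np.isclose(alpha, 0.0) or np.isclose(beta, 0.0))
        pred = f(self.dose, alpha, beta)
        rsq = _r_squared(self.survival, pred, w)
        return LQResults(self, alpha, beta, np.asarray(pcov, float), rsq, len(self.dose), boundary)


def _r_squared(y: np.ndarray, yhat: np.ndarray, w: np.ndarray) -> float:
    ybar = float(w @ y) / float(w.sum())
    sst = float(w @ (y - ybar) ** 2)
    if sst == 0.0:
        raise DegenerateFitError("zero response variance: R^2 undefined")
    ssr = float(w @ (y - yhat) ** 2)
    return 1.0 - ssr / sst


class LQResults:
    """Fit results: estimates, uncertainties, diagnostics.

    Attributes
    ----------
    params : pandas.Series with index ("alpha", "beta")
    bse : pandas.Series of standard errors (local-curvature based)
    rsquared : float, on the fit domain
    nobs : int
    boundary_hit : True when the nonnegativity constraint is active
    """

    def __init__(self, model: LQModel, alpha, beta, cov, rsquared, nobs, boundary_hit):
        self.model = model
        self.params = pd.Series([alpha, beta], index=["alpha", "beta"])
        self._cov = np.asarray(cov, dtype=float)
        self.rsquared = float(rsquared)
        self.nobs = int(nobs)
        self.boundary_hit = bool(boundary_hit)

    # scalar accessors
    @property
    def alpha(self) -> float:
        return float(self.params["alpha"])

    @property
    def beta(self) -> float:
        return float(self.params["beta"])

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self._cov)), index=["alpha", "beta"])

    @property
    def se_alpha(self) -> float:
        return float(self.bse["alpha"])

    @property
    def se_beta(self) -> float:
        return float(self.bse["beta"])

    @property
    def cov_alpha_beta(self) -> float:
        return float(self._cov[0, 1])

    def cov_params(self) -> pd.DataFrame:
        idx = ["alpha", "beta"]
        return pd.DataFrame(self._cov, index=idx, columns=idx)

    @property
    def alpha_beta_ratio(self) -> Optional[float]:
        """alpha/beta in Gy; None when beta = 0 (undefined, not infinite)."""
        return self.alpha / self.beta if self.beta > 0 else None

    @property
    def fit_domain(self) -> str:
        return self.model.fit_domain

    @property
    def n_observations(self) -> int:
        return self.nobs

    @property
    def r_squared(self) -> float:
        return self.rsquared

    @property
    def model_system(self):
        return self.model.model_system

    @property
    def oxygen_condition(self):
        return self.model.oxygen_condition

    @property
    def assay_day(self):
        return self.model.assay_day

    def predict(self, dose):
        return lq_survival(self.alpha, self.beta, dose)

    def to_parameters(self) -> LQParameters:
        return LQParameters(
            alpha=self.alpha,
            beta=self.beta,
            se_alpha=self.se_alpha,
            se_beta=self.se_beta,
            cov_alpha_beta=self.cov_alpha_beta,
            alpha_beta_ratio=self.alpha_beta_ratio,
            r_squared=self.rsquared,
            n_observations=self.nobs,
            fit_domain=self.fit_domain,
            model_system=self.model_system,
            oxygen_condition=self.oxygen_condition,
            assay_day=self.assay_day,
            boundary_hit=self.boundary_hit,
        )

    def summary(self) -> str:
        ratio = self.alpha_beta_ratio
        lines = [
            "Linear-quadratic survival fit",
            "=" * 46,
            f"stratum:        {self.model_system} / {self.oxygen_condition} / day {self.assay_day}",
            f"fit domain:     {self.fit_domain}",
            f"n observations: {self.nobs}",
            "-" * 46,
            f"alpha  {self.alpha:12.6f} Gy^-1   (SE {self.se_alpha:.6f})",
            f"beta   {self.beta:12.6f} Gy^-2   (SE {self.se_beta:.6f})",
            f"alpha/beta  {'undefined (beta = 0)' if ratio is None else f'{ratio:9.4f} Gy'}",
            f"R^2    {self.rsquared:12.6f}",
        ]
        if self.boundary_hit:
            lines.append("note: nonnegativity constraint active (boundary fit)")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<LQResults alpha={self.alpha:.4g} beta={self.beta:.4g} "
            f"R2={self.rsquared:.4f} n={self.nobs}>"
        )


def fit_lq(
    dataset: DoseSurvivalDataset,
    model_system: str,
    oxygen_condition: str,
    assay_day: int,
    **options,
) -> LQResults:
    """Fit the LQ model to one stratum of a dataset (convenience wrapper)."""
    dataset.check_fittable(dataset.stratum(model_system, oxygen_condition, assay_day))
    return LQModel.from_dataset(dataset, model_system, oxygen_condition, assay_day, **options).fit()


def goodness_of_fit(alpha: float, beta: float, dose, survival, fit_domain: str = "log_survival",
                    log_floor: float = 1e-6) -> float:
    """R^2 = 1 - SS_res/SS_tot of given LQ parameters on given data.

    Computed on the requested domain; 1 for a perfect fit, 0 for a fit no
    better than the mean response, negative for worse.
    """
    dose = np.asarray(dose, dtype=float)
    survival = np.asarray(survival, dtype=float)
    w = np.ones_like(dose)
    if fit_domain == "log_survival":
        y = -np.log(np.maximum(survival, log_floor))
        yhat = alpha * dose + beta * dose**2
    elif fit_domain == "survival":
        y = survival
        yhat = np.exp(-(alpha * dose + beta * dose**2))
    else:
        raise ValueError(f"unknown fit_domain {fit_domain!r}")
    return _r_squared(y, yhat, w)
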