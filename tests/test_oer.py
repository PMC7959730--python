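"""Alpha/beta summaries and oxygen enhancement ratio."""

import math
from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lqrad import (
    AlphaBetaSummary,
    LQModel,
    alpha_beta_ratio,
    alpha_beta_ratio_se,
    compute_oer,
    lq_survival,
    summarize_across_days,
)
from lqrad.exceptions import UndefinedRatioError


def params(**kw):
    defaults = dict(alpha=0.05, beta=0.005, se_alpha=0.0, se_beta=0.0, cov_alpha_beta=0.0,
                    model_system="organoid", oxygen_condition="hypoxic_1pct", assay_day=14)
    defaults.update(kw)
    return SimpleNamespace(**defaults)


class TestAlphaBetaRatio:
    def test_published_hypoxic_d21_values(self):
        assert alpha_beta_ratio(params(alpha=0.0254, beta=0.0013)) == pytest.approx(19.538, abs=5e-4)

    def test_unit_ratio(self):
        assert alpha_beta_ratio(params(alpha=0.1, beta=0.1)) == 1.0

    def test_zero_beta_guarded(self):
        with pytest.raises(UndefinedRatioError):
            alpha_beta_ratio(params(alpha=0.05, beta=0.0))


class TestDeltaMethodSE:
    def test_zero_uncertainty_gives_zero(self):
        assert alpha_beta_ratio_se(params()) == 0.0

    def test_published_normoxic_d21_ses(self):
        # sqrt((0.0105/0.0054)^2 + (0.0873*0.0012/0.0054^2)^2) per the delta formula
        se = alpha_beta_ratio_se(
            params(alpha=0.0873, beta=0.0054, se_alpha=0.0105, se_beta=0.0012)
        )
        expected = math.hypot(0.0105 / 0.0054, 0.0873 * 0.0012 / 0.0054**2)
        assert se == pytest.approx(expected, rel=1e-12)
        assert se == pytest.approx(4.0851, abs=5e-4)

    def test_inconsistent_covariance_raises(self):
        with pytest.raises(ValueError):
            alpha_beta_ratio_se(
                params(se_alpha=1e-6, se_beta=1e-6, cov_alpha_beta=1.0)
            )

    def test_agrees_with_bootstrap(self):
        """Delta-method ratio SE within 25% of a residual bootstrap
        (resampling the log-domain residuals, 2000 replicates)."""
        rng = np.random.default_rng(5)
        doses = np.tile([0.0, 0.5, 1, 2, 4, 8, 12, 16, 20, 25, 30], 3)
        s = lq_survival(0.0873, 0.0054, doses) * np.exp(rng.normal(0, 0.1, doses.size))
        res = LQModel(doses, s).fit()
        delta_se = alpha_beta_ratio_se(res)

        y_fit = res.alpha * doses + res.beta * doses**2
        resid = -np.log(s) - y_fit
        boot = []
        for _ in range(2000):
            y_star = y_fit + rng.choice(resid, resid.size, replace=True)
            r = LQModel(doses, np.exp(-y_star)).fit()
            if r.alpha_beta_ratio is not None:
                boot.append(r.alpha_beta_ratio)
        boot_se = float(np.std(boot, ddof=1))
        assert abs(delta_se - boot_se) / boot_se <= 0.25


class TestSummarizeAcrossDays:
    def test_published_hypoxic_mean(self):
        s = AlphaBetaSummary("organoid", "hypoxic_1pct", {14: 15.6889, 21: 19.6918})
        assert s.mean_ratio == pytest.approx(17.6904, abs=5e-5)
        assert round(s.mean_ratio, 1) == 17.7

    def test_published_normoxic_mean(self):
        s = AlphaBetaSummary("organoid", "normoxic_21pct", {14: 9.3494, 21: 16.2259})
        assert s.mean_ratio == pytest.approx(12.7877, abs=5e-5)

    def test_single_day(self):
        s = AlphaBetaSummary("organoid", "hypoxic_1pct", {14: 10.0})
        assert s.mean_ratio == 10.0

    def test_from_fit_objects_and_permutation_invariance(self):
        fits = [
            params(alpha=0.046, beta=0.0029, assay_day=14),
            params(alpha=0.0254, beta=0.0013, assay_day=21),
        ]
        a = summarize_across_days(fits)
        b = summarize_across_days(fits[::-1])
        assert a.mean_ratio == b.mean_ratio
        assert a.per_day_ratios == b.per_day_ratios

    def test_mixed_strata_rejected(self):
        fits = [params(assay_day=14), params(assay_day=21, oxygen_condition="normoxic_21pct")]
        with pytest.raises(ValueError, match="mixed strata"):
            summarize_across_days(fits)

    def test_duplicate_days_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            summarize_across_days([params(assay_day=14), params(assay_day=14)])


HYP = AlphaBetaSummary("organoid", "hypoxic_1pct", {14: 15.6889, 21: 19.6918})
NORM = AlphaBetaSummary("organoid", "normoxic_21pct", {14: 9.3494, 21: 16.2259})


class TestOER:
    def test_published_ratio_of_means(self):
        r = compute_oer(HYP, NORM, rule="ratio_of_means")
        assert r.oer == pytest.approx(1.3834, abs=5e-5)
        assert round(r.oer, 1) == 1.4

    def test_published_mean_of_ratios(self):
        r = compute_oer(HYP, NORM, rule="mean_of_ratios")
        expected = (15.6889 / 9.3494 + 19.6918 / 16.2259) / 2
        assert r.oer == pytest.approx(expected, rel=1e-12)
        assert r.oer == pytest.approx(1.4458, abs=5e-4)

    def test_identical_summaries_give_unity(self):
        assert compute_oer(HYP, HYP).oer == 1.0

    def test_reciprocal_property(self):
        fwd = compute_oer(HYP, NORM).oer
        # swap the roles of the two arms; condition labels travel with them
        rev = NORM.mean_ratio / HYP.mean_ratio
        assert fwd * rev == pytest.approx(1.0, rel=1e-12)

    def test_mismatched_systems_rejected(self):
        other = AlphaBetaSummary("spheroid", "normoxic_21pct", {14: 9.0, 21: 16.0})
        with pytest.raises(ValueError, match="mismatched systems"):
            compute_oer(HYP, other)

    def test_day_mismatch_rejected_for_mean_of_ratios(self):
        norm_partial = AlphaBetaSummary("organoid", "normoxic_21pct", {14: 9.3494})
        with pytest.raises(ValueError, match="day sets differ"):
            compute_oer(HYP, norm_partial, rule="mean_of_ratios")

    @settings(max_examples=40, derandomize=True)
    @given(scale=st.floats(0.01, 100))
    def test_scale_invariance(self, scale):
        """Multiplying all alpha and beta in both arms by one constant leaves
        the OER unchanged."""
        pairs = {
            "hypoxic_1pct": {14: (0.0460, 0.0029), 21: (0.0254, 0.0013)},
            "normoxic_21pct": {14: (0.0131, 0.0014), 21: (0.0873, 0.0054)},
        }

        def summary(cond, c):
            ratios = {
                d: alpha_beta_ratio(params(alpha=c * a, beta=c * b))
                for d, (a, b) in pairs[cond].items()
            }
            return AlphaBetaSummary("organoid", cond, ratios)

        base = compute_oer(summary("hypoxic_1pct", 1.0), summary("normoxic_21pct", 1.0)).oer
        scaled = compute_oer(summary("hypoxic_1pct", scale), summary("normoxic_21pct", scale)).oer
        assert scaled == pytest.approx(base, rel=1e-9)

    @settings(max_examples=40, derandomize=True)
    @given(bump=st.floats(0.1, 20))
    def test_monotone_in_hypoxic_ratio(self, bump):
        bumped = AlphaBetaSummary(
            "organoid", "hypoxic_1pct",
            {14: 15.6889 + bump, 21: 19.6918},
        )
        assert compute_oer(bumped, NORM).oer > compute_oer(HYP, NORM).oer
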