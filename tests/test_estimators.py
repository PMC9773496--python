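"""Random-effects meta-regression: oracles, closed forms, symmetries.

The REML oracle maximises an independently written restricted
log-likelihood by grid search with local refinement; the DL oracle is the
closed-form moment expression.  R's metafor (via Rscript) provides a fully
external cross-check on one fixture.
"""

import subprocess
import textwrap

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from metaepi import RandomEffectsMetaAnalysis, RandomEffectsMetaRegression
from metaepi.estimators import tau2_dl, tau2_reml
from metaepi.exceptions import DegenerateDesignError

# fixed 6-trial fixture: log-ORs, variances, primary-care indicator
FIXTURE_Y = np.array([-0.62, 0.11, -0.45, -1.02, 0.27, -0.30])
FIXTURE_V = np.array([0.09, 0.16, 0.04, 0.25, 0.12, 0.06])
FIXTURE_X = np.array([1.0, 1.0, 0.0, 0.0, 1.0, 0.0])


def reml_loglik_oracle(tau2, y, v, X):
    """Restricted log-likelihood, written directly from its definition."""
    w = 1.0 / (v + tau2)
    W = np.diag(w)
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ W @ y)
    r = y - X @ beta
    return (
        -0.5 * np.sum(np.log(v + tau2))
        - 0.5 * np.log(np.linalg.det(xtwx))
        - 0.5 * r @ W @ r
    )


def reml_oracle_tau2(y, v, X, hi=2.0):
    """Grid search on [0, hi] at 1e-4, refined locally to high precision."""
    grid = np.arange(0.0, hi + 1e-4, 1e-4)
    lls = np.array([reml_loglik_oracle(t, y, v, X) for t in grid])
    i = int(np.argmax(lls))
    lo = max(0.0, grid[i] - 2e-4)
    up = min(hi, grid[i] + 2e-4)
    res = minimize_scalar(
        lambda t: -reml_loglik_oracle(t, y, v, X),
        bounds=(lo, up),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def design(x):
    return np.column_stack([np.ones(len(x)), x])


class TestREML:
    def test_reml_matches_likelihood_grid_oracle(self):
        oracle = reml_oracle_tau2(FIXTURE_Y, FIXTURE_V, design(FIXTURE_X))
        tau2, converged, _ = tau2_reml(design(FIXTURE_X), FIXTURE_Y, FIXTURE_V)
        assert converged
        assert tau2 == pytest.approx(oracle, abs=1e-6)

    def test_reml_oracle_agreement_on_varied_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            k = int(rng.integers(4, 12))
            x = (rng.random(k) < 0.4).astype(float)
            if x.sum() in (0, k):
                x[0], x[-1] = 1.0, 0.0
            y = rng.normal(-0.2, 0.5, k)
            v = rng.uniform(0.02, 0.4, k)
            X = design(x)
            tau2, converged, _ = tau2_reml(X, y, v)
            assert converged
            assert tau2 == pytest.approx(reml_oracle_tau2(y, v, X), abs=1e-6)

    def test_no_variation_gives_zero_tau2_and_zero_coef(self):
        y = np.full(5, -0.4)
        v = np.array([0.1, 0.2, 0.1, 0.3, 0.2])
        x = np.array([1.0, 0.0, 1.0, 0.0, 0.0])
        reg = RandomEffectsMetaRegression().fit(x, y, v)
        assert reg.tau2_ == pytest.approx(0.0, abs=1e-12)
        assert reg.coef_[0] == pytest.approx(0.0, abs=1e-12)


class TestDL:
    def test_dl_matches_closed_form_moment_expression(self):
        X = design(FIXTURE_X)
        w = 1.0 / FIXTURE_V
        W = np.diag(w)
        H = X @ np.linalg.inv(X.T @ W @ X) @ X.T @ W
        r = FIXTURE_Y - H @ FIXTURE_Y
        q_e = float(r @ W @ r)
        P = W - W @ X @ np.linalg.inv(X.T @ W @ X) @ X.T @ W
        expected = max(0.0, (q_e - (len(FIXTURE_Y) - 2)) / np.trace(P))
        assert tau2_dl(X, FIXTURE_Y, FIXTURE_V) == pytest.approx(expected, abs=1e-12)

    def test_negative_moment_estimate_truncated_at_zero(self):
        y = np.array([0.0, 0.01, -0.01, 0.0])
        v = np.full(4, 1.0)  # sampling variance dwarfs spread
        assert tau2_dl(design(np.array([1.0, 0, 1, 0])), y, v) == 0.0


class TestWLSClosedForms:
    def test_equal_variances_reduce_to_group_mean_difference(self):
        # with equal total variances WLS = OLS, so the setting coefficient
        # is mean(PC) - mean(ST) = -0.1 - 0.1 = -0.2
        y = np.array([0.0, 0.2, -0.2, 0.0])
        x = np.array([0.0, 0.0, 1.0, 1.0])
        v = np.full(4, 0.04)
        reg = RandomEffectsMetaRegression().fit(x, y, v)
        assert reg.coef_[0] == pytest.approx(-0.2, abs=1e-12)
        assert np.exp(reg.coef_[0]) == pytest.approx(0.8187, abs=1e-4)

    def test_fixed_tau2_zero_equals_inverse_variance_wls(self):
        y = np.array([-0.5, 0.2, -0.1])
        x = np.array([1.0, 0.0, 0.0])
        v = np.array([0.04, 0.09, 0.16])
        reg = RandomEffectsMetaRegression(tau2_fixed=0.0).fit(x, y, v)
        X = design(x)
        W = np.diag(1.0 / v)
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        cov = np.linalg.inv(X.T @ W @ X)
        assert reg.params_ == pytest.approx(beta, abs=1e-12)
        assert reg.bse_ == pytest.approx(np.sqrt(np.diag(cov)), abs=1e-12)


class TestModelInvariances:
    @pytest.mark.parametrize("method", ["reml", "dl"])
    def test_group_relabelling_negates_coefficient(self, method):
        reg = RandomEffectsMetaRegression(method=method).fit(FIXTURE_X, FIXTURE_Y, FIXTURE_V)
        flipped = RandomEffectsMetaRegression(method=method).fit(
            1.0 - FIXTURE_X, FIXTURE_Y, FIXTURE_V
        )
        assert flipped.coef_[0] == pytest.approx(-reg.coef_[0], abs=1e-8)
        assert flipped.bse_[1] == pytest.approx(reg.bse_[1], abs=1e-8)
        assert flipped.tau2_ == pytest.approx(reg.tau2_, abs=1e-8)

    def test_constant_shift_changes_only_intercept(self):
        reg = RandomEffectsMetaRegression().fit(FIXTURE_X, FIXTURE_Y, FIXTURE_V)
        shifted = RandomEffectsMetaRegression().fit(FIXTURE_X, FIXTURE_Y + 3.0, FIXTURE_V)
        assert shifted.coef_[0] == pytest.approx(reg.coef_[0], abs=1e-8)
        assert shifted.intercept_ == pytest.approx(reg.intercept_ + 3.0, abs=1e-8)

    def test_rank_deficient_design_raises(self):
        with pytest.raises(DegenerateDesignError):
            RandomEffectsMetaRegression().fit(
                np.column_stack([FIXTURE_X, FIXTURE_X]), FIXTURE_Y, FIXTURE_V
            )

    def test_sklearn_get_set_params_round_trip(self):
        reg = RandomEffectsMetaRegression(method="dl", ci_method="kh")
        params = reg.get_params()
        clone = RandomEffectsMetaRegression().set_params(**params)
        assert clone.get_params() == params


class TestExternalCrossCheck:
    def test_agrees_with_metafor(self):
        """REML and DL fits match R metafor on the 6-trial fixture."""
        script = textwrap.dedent(
            """
            suppressMessages(library(metafor))
            y <- c(-0.62, 0.11, -0.45, -1.02, 0.27, -0.30)
            v <- c(0.09, 0.16, 0.04, 0.25, 0.12, 0.06)
            x <- c(1, 1, 0, 0, 1, 0)
            fr <- rma(y, v, mods = ~x, method = "REML", control = list(tol = 1e-10))
            fd <- rma(y, v, mods = ~x, method = "DL")
            cat(sprintf("%.10f %.10f %.10f %.10f %.10f %.10f",
                fr$tau2, fr$beta[2], fr$se[2], fd$tau2, fd$beta[2], fd$se[2]))
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        r_reml_tau2, r_reml_b, r_reml_se, r_dl_tau2, r_dl_b, r_dl_se = map(
            float, out.stdout.split()
        )
        reml = RandomEffectsMetaRegression(method="reml").fit(FIXTURE_X, FIXTURE_Y, FIXTURE_V)
        dl = RandomEffectsMetaRegression(method="dl").fit(FIXTURE_X, FIXTURE_Y, FIXTURE_V)
        assert reml.tau2_ == pytest.approx(r_reml_tau2, abs=1e-5)
        assert reml.coef_[0] == pytest.approx(r_reml_b, abs=1e-5)
        assert reml.bse_[1] == pytest.approx(r_reml_se, abs=1e-5)
        assert dl.tau2_ == pytest.approx(r_dl_tau2, abs=1e-8)
        assert dl.coef_[0] == pytest.approx(r_dl_b, abs=1e-8)
        assert dl.bse_[1] == pytest.approx(r_dl_se, abs=1e-8)


class TestMetaAnalysisEstimator:
    def test_single_study_passthrough(self):
        ma = RandomEffectsMetaAnalysis().fit([0.3], [0.04])
        assert ma.effect_ == 0.3 and ma.se_ == pytest.approx(0.2)
        assert ma.tau2_ is None and ma.i2_ is None and ma.df_ == 0

    def test_statsmodels_dl_cross_check(self):
        from statsmodels.stats.meta_analysis import combine_effects

        y = np.array([-0.5, 0.1, -0.3, 0.4, -0.2])
        v = np.array([0.04, 0.09, 0.05, 0.12, 0.07])
        ours = RandomEffectsMetaAnalysis(method="dl").fit(y, v)
        ref = combine_effects(y, v, method_re="dl")
        assert ours.tau2_ == pytest.approx(float(ref.tau2), abs=1e-10)
        assert ours.effect_ == pytest.approx(float(ref.mean_effect_re), abs=1e-10)
        assert ours.q_ == pytest.approx(float(ref.q), abs=1e-10)
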