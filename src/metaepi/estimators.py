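"""Random-effects meta-regression and meta-analysis estimators.

The model for effect sizes :math:`y_i` with known sampling variances
:math:`v_i` and moderator row vectors :math:`x_i` is

.. math::

    y_i = x_i \\beta + u_i + \\varepsilon_i,\\qquad
    u_i \\sim N(0, \\tau^2),\\quad \\varepsilon_i \\sim N(0, v_i),

with the between-study variance :math:`\\tau^2` estimated either by
restricted maximum likelihood (REML, Fisher scoring) or by the
DerSimonian-Laird method of moments (its generalisation to models with
moderators).  Coefficients are then weighted least squares with weights
:math:`w_i = 1/(v_i + \\hat\\tau^2)` and covariance
:math:`(X^T W X)^{-1}`; the Knapp-Hartung small-sample adjustment scales
that covariance by the weighted residual mean square and uses a
:math:`t_{n-p}` reference distribution.

Both estimators follow scikit-learn conventions (``fit`` with the sampling
variances as a fit parameter, fitted attributes with trailing underscores,
``get_params``/``set_params``) so they compose with sklearn tooling.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from scipy.optimize import brentq
from sklearn.base import BaseEstimator

from .exceptions import ConvergenceWarning, DegenerateDesignError

_TAU2_METHODS = ("reml", "dl")
_CI_METHODS = ("wald", "kh")


def _check_Xyv(X, y, v):
    y = np.asarray(y, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    n = y.shape[0]
    if X is None:
        X = np.empty((n, 0))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n or v.shape[0] != n:
        raise ValueError("X, y and sample_variance must have matching first dimensions")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(v)) and np.all(np.isfinite(X))):
        raise ValueError("inputs must be finite")
    if np.any(v <= 0):
        raise ValueError("sampling variances must be strictly positive")
    return X, y, v


def _projection_traces(design, y, w):
    """P = W - W X (X'WX)^-1 X'W for W = diag(w); returns Py, tr(P), tr(P@P)."""
    Xw = design * w[:, None]                     # W X
    xtwx = design.T @ Xw                         # X'WX
    xtwx_inv = np.linalg.inv(xtwx)
    # full n x n projector; n is at most a few hundred here
    P = np.diag(w) - Xw @ xtwx_inv @ Xw.T
    return P @ y, float(np.trace(P)), float(np.sum(P * P))


def _wls(design, y, w):
    xtwx = design.T @ (design * w[:, None])
    xtwx_inv = np.linalg.inv(xtwx)
    beta = xtwx_inv @ (design.T @ (w * y))
    return beta, xtwx_inv


def tau2_dl(design: np.ndarray, y: np.ndarray, v: np.ndarray) -> float:
    """DerSimonian-Laird moment estimator of tau^2, truncated at zero.

    Uses fixed-effect weights w = 1/v; the residual heterogeneity statistic
    Q_E is referred to its expectation n - p + tau^2 * tr(P).
    """
    n, p = design.shape
    w = 1.0 / v
    beta, _ = _wls(design, y, w)
    resid = y - design @ beta
    q_e = float(np.sum(w * resid**2))
    _, tr_p, _ = _projection_traces(design, y, w)
    if tr_p <= 0:
        return 0.0
    return max(0.0, (q_e - (n - p)) / tr_p)


def reml_loglik(design: np.ndarray, y: np.ndarray, v: np.ndarray, tau2: float) -> float:
    """Restricted log-likelihood of tau^2 (additive constants dropped)."""
    w = 1.0 / (v + tau2)
    Xw = design * w[:, None]
    xtwx = design.T @ Xw
    beta = np.linalg.solve(xtwx, design.T @ (w * y))
    resid = y - design @ beta
    return float(
        -0.5 * np.sum(np.log(v + tau2))
        - 0.5 * np.linalg.slogdet(xtwx)[1]
        - 0.5 * np.sum(w * resid**2)
    )


def _reml_score(design: np.ndarray, y: np.ndarray, v: np.ndarray, tau2: float):
    """REML score dl/d(tau^2) = (y'PPy - tr P)/2 and the information tr(PP)/2."""
    w = 1.0 / (v + tau2)
    py, tr_p, tr_pp = _projection_traces(design, y, w)
    return 0.5 * (float(py @ py) - tr_p), 0.5 * tr_pp


def tau2_reml(
    design: np.ndarray,
    y: np.ndarray,
    v: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[float, bool, int]:
    """REML estimate of tau^2, truncated at zero.

    Returns (tau2, converged, n_iter).  The estimate solves the REML score
    equation.  A non-positive score at tau^2 = 0 puts the maximiser on the
    boundary.  Otherwise Fisher scoring steps (update
    (y'PPy - tr P)/tr(PP)), started from the DerSimonian-Laird estimate,
    run until |delta tau^2| < tol; as soon as an iterate lands on the far
    side of the root (negative score) the bracket is closed with Brent
    root-finding, which sidesteps the slow linear tail of plain scoring.
    """
    score0, _ = _reml_score(design, y, v, 0.0)
    if score0 <= 0:
        return 0.0, True, 1
    score_fn = lambda t: _reml_score(design, y, v, t)[0]
    lo = 0.0  # score(lo) > 0: root is above
    tau2 = max(tau2_dl(design, y, v), tol)
    for it in range(1, max_iter + 1):
        score, info = _reml_score(design, y, v, tau2)
        if score < 0:
            root = float(brentq(score_fn, lo, tau2, xtol=1e-12, maxiter=200))
            return root, True, it
        lo = tau2
        if info <= 0:
            return tau2, True, it
        step = score / info
        tau2_new = max(0.0, tau2 + step)
        if abs(tau2_new - tau2) < tol:
            return tau2_new, True, it
        tau2 = tau2_new
    return tau2, False, max_iter


class RandomEffectsMetaRegression(BaseEstimator):
    """Meta-regression of effect sizes on moderators with residual tau^2.

    Parameters
    ----------
    method : {"reml", "dl"}, default "reml"
        Between-study variance estimator.
    ci_method : {"wald", "kh"}, default "wald"
        Wald normal intervals, or the Knapp-Hartung adjustment (scaled
        covariance, t reference with n - p degrees of freedom).
    fit_intercept : bool, default True
    tau2_fixed : float or None
        If given, tau^2 is held at this value instead of being estimated
        (0.0 gives the fixed-effect / inverse-variance fit).
    tol, max_iter : REML stopping rule on |delta tau^2|.

    Attributes (after ``fit``)
    --------------------------
    coef_ : moderator coefficients (excludes the intercept).
    intercept_ : fitted intercept (0.0 when fit_intercept=False).
    params_, bse_, cov_params_ : full coefficient vector (intercept first
        when present), standard errors and covariance.
    tau2_ : residual between-study variance.
    qe_ : residual heterogeneity statistic Q_E at fixed-effect weights.
    converged_, n_iter_ : REML iteration outcome.
    """

    def __init__(
        self,
        method: str = "reml",
        ci_method: str = "wald",
        fit_intercept: bool = True,
        tau2_fixed: float | None = None,
        tol: float = 1e-8,
        max_iter: int = 100,
    ):
        self.method = method
        self.ci_method = ci_method
        self.fit_intercept = fit_intercept
        self.tau2_fixed = tau2_fixed
        self.tol = tol
        self.max_iter = max_iter

    def _design(self, X: np.ndarray) -> np.ndarray:
        if self.fit_intercept:
            return np.column_stack([np.ones(X.shape[0]), X])
        return X

    def fit(self, X, y, sample_variance):
        """Fit to effects ``y`` with known sampling variances."""
        if self.method not in _TAU2_METHODS:
            raise ValueError(f"method must be one of {_TAU2_METHODS}")
        if self.ci_method not in _CI_METHODS:
            raise ValueError(f"ci_method must be one of {_CI_METHODS}")
        X, y, v = _check_Xyv(X, y, sample_variance)
        design = self._design(X)
        n, p = design.shape
        if p == 0:
            raise ValueError("model has no parameters; need moderators or an intercept")
        if n <= p:
            raise ValueError(f"need more observations ({n}) than parameters ({p})")
        if np.linalg.matrix_rank(design) < p:
            raise DegenerateDesignError(
                "design matrix is rank deficient (collinear or constant moderators)"
            )

        w_fe = 1.0 / v
        beta_fe, _ = _wls(design, y, w_fe)
        resid_fe = y - design @ beta_fe
        self.qe_ = float(np.sum(w_fe * resid_fe**2))

        if self.tau2_fixed is not None:
            tau2, converged, n_iter = float(self.tau2_fixed), True, 0
        elif self.method == "dl":
            tau2, converged, n_iter = tau2_dl(design, y, v), True, 0
        else:
            tau2, converged, n_iter = tau2_reml(design, y, v, self.tol, self.max_iter)
            if not converged:
                warnings.warn(
                    "REML iteration for tau^2 did not converge; returning last iterate",
                    ConvergenceWarning,
                )
        self.tau2_ = tau2
        self.converged_ = converged
        self.n_iter_ = n_iter

        w = 1.0 / (v + tau2)
        beta, cov = _wls(design, y, w)
        resid = y - design @ beta
        if self.ci_method == "kh":
            s2 = float(np.sum(w * resid**2)) / (n - p)
            cov = cov * s2
        self.params_ = beta
        self.cov_params_ = cov
        self.bse_ = np.sqrt(np.diag(cov))
        self.df_resid_ = n - p
        self.n_features_in_ = X.shape[1]
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = beta
        return self

    def predict(self, X) -> np.ndarray:
        """Model-implied mean effect at moderator values ``X``."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """(p, 2) confidence limits for the full coefficient vector."""
        if self.ci_method == "kh":
            crit = stats.t.ppf(1 - alpha / 2, self.df_resid_)
        else:
            crit = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params_ - crit * self.bse_, self.params_ + crit * self.bse_])


def i2_from_q(Q: float, df: int) -> float:
    """I^2 = max(0, (Q - df)/Q) * 100, the share of variability beyond chance."""
    if df < 1 or Q <= 0:
        return 0.0
    return max(0.0, (Q - df) / Q) * 100.0


def i2_confidence_interval(Q: float, df: int, alpha: float = 0.05) -> tuple[float, float]:
    """Test-based 95% CI for I^2 via the log-H statistic (Higgins-Thompson).

    H = sqrt(Q/df); ln(H) gets a normal interval with standard error

    * Q > k:  0.5 * (ln Q - ln df) / (sqrt(2Q) - sqrt(2k - 3))
    * Q <= k: sqrt( (1 - 1/(3 (k-2)^2)) / (2 (k-2)) )

    where k = df + 1 studies.  Limits are mapped back through
    I^2 = 100 * (H^2 - 1)/H^2 and truncated to [0, 100].  With df = 1 and
    Q <= 2 the small-Q variance formula is undefined and the maximally wide
    interval (0, 100) is returned.
    """
    if df < 1:
        raise ValueError("I^2 confidence interval requires df >= 1")
    k = df + 1
    Q = max(float(Q), 1e-12)
    h = max(1.0, np.sqrt(Q / df))
    if Q > k:
        se_ln_h = 0.5 * (np.log(Q) - np.log(df)) / (np.sqrt(2 * Q) - np.sqrt(2 * k - 3))
    elif k > 2:
        se_ln_h = np.sqrt((1.0 - 1.0 / (3.0 * (k - 2) ** 2)) / (2.0 * (k - 2)))
    else:
        return (0.0, 100.0)
    z = stats.norm.ppf(1 - alpha / 2)
    h_low = max(1.0, np.exp(np.log(h) - z * se_ln_h))
    h_high = max(1.0, np.exp(np.log(h) + z * se_ln_h))
    to_i2 = lambda hh: max(0.0, min(100.0, 100.0 * (hh**2 - 1.0) / hh**2))
    return (to_i2(h_low), to_i2(h_high))


class RandomEffectsMetaAnalysis(BaseEstimator):
    """Univariate random-effects pooling of effect sizes.

    The intercept-only special case of the meta-regression: pooled effect
    with weights 1/(v_i + tau^2), Cochran's Q at fixed-effect weights, I^2
    with its test-based confidence interval, and a Wald or Knapp-Hartung
    interval for the pooled effect.

    Attributes (after ``fit``)
    --------------------------
    effect_, se_ : pooled estimate and its standard error.
    ci_low_, ci_high_ : confidence limits (same scale as the inputs).
    tau2_, q_, df_, i2_, i2_ci_ : heterogeneity summaries.
    k_ : number of studies pooled.
    """

    def __init__(
        self,
        method: str = "reml",
        ci_method: str = "wald",
        tau2_fixed: float | None = None,
        alpha: float = 0.05,
        tol: float = 1e-8,
        max_iter: int = 100,
    ):
        self.method = method
        self.ci_method = ci_method
        self.tau2_fixed = tau2_fixed
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, y, sample_variance):
        y = np.asarray(y, dtype=float).ravel()
        v = np.asarray(sample_variance, dtype=float).ravel()
        k = y.shape[0]
        if k < 1:
            raise ValueError("need at least one effect to pool")
        self.k_ = k
        if k == 1:
            # heterogeneity is not applicable with a single study
            self.effect_ = float(y[0])
            self.se_ = float(np.sqrt(v[0]))
            z = stats.norm.ppf(1 - self.alpha / 2)
            self.ci_low_ = self.effect_ - z * self.se_
            self.ci_high_ = self.effect_ + z * self.se_
            self.tau2_ = None
            self.q_ = None
            self.df_ = 0
            self.i2_ = None
            self.i2_ci_ = (None, None)
            self.converged_ = True
            return self
        reg = RandomEffectsMetaRegression(
            method=self.method,
            ci_method=self.ci_method,
            fit_intercept=True,
            tau2_fixed=self.tau2_fixed,
            tol=self.tol,
            max_iter=self.max_iter,
        ).fit(np.empty((k, 0)), y, v)
        self.effect_ = float(reg.params_[0])
        self.se_ = float(reg.bse_[0])
        ci = reg.conf_int(self.alpha)
        self.ci_low_, self.ci_high_ = float(ci[0, 0]), float(ci[0, 1])
        self.tau2_ = float(reg.tau2_)
        self.q_ = float(reg.qe_)
        self.df_ = k - 1
        self.i2_ = i2_from_q(self.q_, self.df_)
        self.i2_ci_ = i2_confidence_interval(self.q_, self.df_, self.alpha)
        self.converged_ = reg.converged_
        return self
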