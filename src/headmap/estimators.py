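"""Direct-mapping estimators: OLS, CLAD, fractional logit, GLM.

All estimators follow the scikit-learn protocol — parameters in
``__init__``, data in ``fit(X, y)``, fitted attributes with a trailing
underscore, prediction via ``predict(X)`` — and therefore compose with
sklearn pipelines and model selection. Standard fits (OLS, GLM,
fractional logit, median regression) are delegated to statsmodels; the
censored least absolute deviations (CLAD) iterative trimming algorithm
is implemented here.

CLAD addresses the utility ceiling: observed utilities are censored at
1 (full health), which biases mean-regression slopes toward zero. The
estimator alternates a median (LAD) fit with trimming of observations
whose fitted values reach the censoring point, and is consistent under
upper censoring without distributional assumptions on the noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .models import MappingModel

__all__ = [
    "FitResult",
    "OLSRegressor",
    "CLADRegressor",
    "FractionalLogitRegressor",
    "GLMRegressor",
    "fit_ols",
    "fit_clad",
    "fit_flogit",
    "fit_glm",
    "SingularDesignError",
    "DegenerateCensoringError",
    "BoundsError",
    "ConfigurationError",
]


class SingularDesignError(ValueError):
    """Design matrix is rank deficient (e.g. duplicated predictor)."""


class DegenerateCensoringError(ValueError):
    """Every response sits at the censoring point; CLAD is unidentified."""


class BoundsError(ValueError):
    """A response lies outside the declared instrument bounds."""


class ConfigurationError(ValueError):
    """Unsupported estimator configuration (family/link pair, ...)."""


@dataclass
class FitResult:
    """A fitted mapping plus its diagnostics.

    ``aic`` is present only for estimators with a defined likelihood
    (OLS, fractional logit, GLM, multinomial response maps); CLAD has
    none. ``predictor`` maps a design matrix to utilities on the
    original scale and is what the selection procedure consumes.
    """

    model: MappingModel
    n_used: int
    aic: Optional[float] = None
    converged: bool = True
    iterations: int = 0
    stderr: Optional[np.ndarray] = None
    notes: str = ""
    predictor: Optional[object] = None  # fitted estimator object


def _validate_Xy(X, y) -> Tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError(f"incompatible shapes X{X.shape}, y{y.shape}")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("X and y must be finite")
    return X, y


def _check_full_rank(Xc: np.ndarray) -> None:
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise SingularDesignError(
            f"design matrix is rank deficient ({Xc.shape[1]} columns, "
            f"rank {np.linalg.matrix_rank(Xc)})"
        )


class OLSRegressor(RegressorMixin, BaseEstimator):
    """Ordinary least squares with Gaussian-likelihood AIC.

    Attributes after fit: ``coef_``, ``intercept_``, ``aic_``,
    ``stderr_`` (constant first), ``loglik_``, ``n_features_in_``.
    """

    def __init__(self, clip: Optional[Tuple[float, float]] = None):
        self.clip = clip

    def fit(self, X, y):
        X, y = _validate_Xy(X, y)
        Xc = sm.add_constant(X, has_constant="add")
        _check_full_rank(Xc)
        res = sm.OLS(y, Xc).fit()
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.stderr_ = np.asarray(res.bse, dtype=float)
        self.loglik_ = float(res.llf)
        # 2k - 2 loglik with k = all coefficients including the constant
        self.aic_ = 2 * Xc.shape[1] - 2 * self.loglik_
        self.converged_ = True
        self.n_features_in_ = X.shape[1]
        self._n_obs = X.shape[0]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        out = self.intercept_ + X @ self.coef_
        if self.clip is not None:
            out = np.clip(out, self.clip[0], self.clip[1])
        return out


def _lad_fit(Xc: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Median regression (LAD) coefficients, constant first."""
    res = sm.QuantReg(y, Xc).fit(q=0.5, max_iter=5000, p_tol=1e-10)
    return np.asarray(res.params, dtype=float)


class CLADRegressor(RegressorMixin, BaseEstimator):
    """Censored least absolute deviations for an upper-censored response.

    Iterative trimming: fit LAD on the current subsample, recompute
    fitted values on the full sample, retain observations whose fitted
    value is strictly below ``censor_upper``, and repeat until the
    retained set stabilises (or ``max_iter``). Oscillation between two
    retained sets terminates with ``converged_ = False`` and both sets
    recorded in ``notes_``.

    Predictions are *not* clipped at the censoring point by default —
    a fitted linear index above 1 is informative about proximity to
    full health — but ``clip=(lo, hi)`` truncates if requested.
    Standard errors, when requested, come from a seeded nonparametric
    bootstrap.

    Parameters
    ----------
    censor_upper : float, default 1.0
        Upper censoring point of the response (full health).
    max_iter : int, default 100
        Cap on trimming iterations.
    compute_stderr : bool, default False
        Run the bootstrap for standard errors after the point fit.
    n_bootstrap : int, default 1000
        Bootstrap replicates when ``compute_stderr`` is on.
    seed : int, default 0
        Seed for the bootstrap resampling.
    """

    def __init__(
        self,
        censor_upper: float = 1.0,
        max_iter: int = 100,
        compute_stderr: bool = False,
        n_bootstrap: int = 1000,
        seed: int = 0,
        clip: Optional[Tuple[float, float]] = None,
    ):
        self.censor_upper = censor_upper
        self.max_iter = max_iter
        self.compute_stderr = compute_stderr
        self.n_bootstrap = n_bootstrap
        self.seed = seed
        self.clip = clip

    def _trimmed_lad(self, Xc, y):
        """One full CLAD pass; returns (params, n_iter, converged, notes)."""
        n = Xc.shape[0]
        active = np.ones(n, dtype=bool)
        prev: Optional[np.ndarray] = None
        notes = ""
        converged = False
        params = None
        for it in range(1, self.max_iter + 1):
            params = _lad_fit(Xc[active], y[active])
            fitted = Xc @ params
            new_active = fitted < self.censor_upper
            if not new_active.any():
                # pathological trim-out; keep last fit, flag non-convergence
                notes = "all fitted values at or above the censoring point"
                return params, it, False, notes
            if np.array_equal(new_active, active):
                converged = True
                return params, it, True, notes
            if prev is not None and np.array_equal(new_active, prev):
                notes = (
                    "retained-set oscillation between sizes "
                    f"{int(prev.sum())} and {int(active.sum())}"
                )
                return params, it, False, notes
            prev = active
            active = new_active
        return params, self.max_iter, converged, "max_iter reached"

    def fit(self, X, y):
        X, y = _validate_Xy(X, y)
        if np.all(y >= self.censor_upper):
            raise DegenerateCensoringError(
                f"all responses at or above censor_upper={self.censor_upper}"
            )
        Xc = sm.add_constant(X, has_constant="add")
        _check_full_rank(Xc)
        params, n_iter, converged, notes = self._trimmed_lad(Xc, y)
        self.intercept_ = float(params[0])
        self.coef_ = np.asarray(params[1:], dtype=float)
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.notes_ = notes
        self.stderr_ = None
        if self.compute_stderr:
            self.stderr_ = self._bootstrap_se(Xc, y)
        self.n_features_in_ = X.shape[1]
        return self

    def _bootstrap_se(self, Xc, y) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        n = Xc.shape[0]
        draws = []
        for _ in range(self.n_bootstrap):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if np.all(yb >= self.censor_upper):
                continue  # degenerate resample carries no information
            params, *_ = self._trimmed_lad(Xc[idx], yb)
            draws.append(params)
        return np.std(np.asarray(draws), axis=0, ddof=1)

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        out = self.intercept_ + X @ self.coef_
        if self.clip is not None:
            out = np.clip(out, self.clip[0], self.clip[1])
        return out


class FractionalLogitRegressor(RegressorMixin, BaseEstimator):
    """Fractional logit for a bounded response.

    The response is affinely transformed onto [0, 1] using the declared
    instrument bounds, fitted as a binomial-family logit-link GLM
    (quasi-likelihood, valid for fractional outcomes), and predictions
    are back-transformed to the original utility scale — so fitted
    utilities can never leave the instrument range.
    """

    def __init__(self, bounds: Tuple[float, float] = (-0.594, 1.0)):
        self.bounds = bounds

    def transform_response(self, y):
        lo, hi = self.bounds
        return (np.asarray(y, dtype=float) - lo) / (hi - lo)

    def inverse_transform_response(self, y01):
        lo, hi = self.bounds
        return lo + (hi - lo) * np.asarray(y01, dtype=float)

    def fit(self, X, y):
        X, y = _validate_Xy(X, y)
        lo, hi = self.bounds
        if y.min() < lo or y.max() > hi:
            raise BoundsError(
                f"responses outside declared bounds ({lo}, {hi}): "
                f"observed range ({y.min():.4g}, {y.max():.4g})"
            )
        Xc = sm.add_constant(X, has_constant="add")
        _check_full_rank(Xc)
        y01 = self.transform_response(y)
        res = sm.GLM(y01, Xc, family=sm.families.Binomial()).fit()
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.stderr_ = np.asarray(res.bse, dtype=float)
        self.loglik_ = float(res.llf)
        self.aic_ = 2 * Xc.shape[1] - 2 * self.loglik_
        self.converged_ = bool(res.converged)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        eta = self.intercept_ + X @ self.coef_
        p = 1.0 / (1.0 + np.exp(-eta))
        return self.inverse_transform_response(p)


_FAMILIES = {
    ("gaussian", "identity"),
    ("gaussian", "log"),
    ("binomial", "logit"),
    ("gamma", "identity"),
    ("gamma", "log"),
}


def _sm_family(family: str, link: str):
    links = sm.families.links
    link_obj = {"identity": links.Identity, "log": links.Log, "logit": links.Logit}[link]()
    fam = {"gaussian": sm.families.Gaussian,
           "binomial": sm.families.Binomial,
           "gamma": sm.families.Gamma}[family]
    return fam(link=link_obj)


class GLMRegressor(RegressorMixin, BaseEstimator):
    """Generalised linear model over a configurable family/link pair.

    Gamma-family fits require a strictly positive response; utilities
    (which reach −0.594) are affinely shifted by ``shift`` before the
    fit and the shift is inverted at prediction. ``shift="auto"``
    picks the smallest shift putting the minimum response at 0.05.
    Non-convergence (common for Gamma-identity on utility data) is
    reported via ``converged_ = False`` and ``notes_``, never raised.
    """

    def __init__(self, family: str = "gaussian", link: str = "identity",
                 shift: float | str = "auto",
                 clip: Optional[Tuple[float, float]] = None):
        self.family = family
        self.link = link
        self.shift = shift
        self.clip = clip

    def fit(self, X, y):
        if (self.family, self.link) not in _FAMILIES:
            raise ConfigurationError(
                f"unsupported family/link pair ({self.family}, {self.link})"
            )
        X, y = _validate_Xy(X, y)
        Xc = sm.add_constant(X, has_constant="add")
        _check_full_rank(Xc)
        self.shift_ = 0.0
        if self.family == "gamma":
            if self.shift == "auto":
                self.shift_ = max(0.0, 0.05 - float(y.min()))
            else:
                self.shift_ = float(self.shift)
        ys = y + self.shift_
        self.notes_ = ""
        if self.family == "gamma" and ys.min() <= 0:
            self._mark_failed(Xc, "nonpositive shifted response in Gamma family")
            return self
        try:
            res = sm.GLM(ys, Xc, family=_sm_family(self.family, self.link)).fit()
            bad = not np.isfinite(res.params).all()
            if self.family == "gamma" and not bad:
                bad = bool((res.fittedvalues <= 0).any())
            if bad:
                self._mark_failed(Xc, "fit produced invalid fitted values")
                return self
        except Exception as exc:  # statsmodels raises on domain violations
            self._mark_failed(Xc, f"GLM fit failed: {exc}")
            return self
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.stderr_ = np.asarray(res.bse, dtype=float)
        self.loglik_ = float(res.llf)
        self.aic_ = 2 * Xc.shape[1] - 2 * self.loglik_
        self.converged_ = bool(res.converged)
        if not self.converged_:
            self.notes_ = "IRLS did not converge"
        self.n_features_in_ = Xc.shape[1] - 1
        return self

    def _mark_failed(self, Xc, reason: str) -> None:
        self.intercept_ = np.nan
        self.coef_ = np.full(Xc.shape[1] - 1, np.nan)
        self.stderr_ = None
        self.loglik_ = np.nan
        self.aic_ = np.nan
        self.converged_ = False
        self.notes_ = reason
        self.n_features_in_ = Xc.shape[1] - 1

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        eta = self.intercept_ + X @ self.coef_
        if self.link == "identity":
            mu = eta
        elif self.link == "log":
            mu = np.exp(eta)
        else:  # logit
            mu = 1.0 / (1.0 + np.exp(-eta))
        out = mu - self.shift_
        if self.clip is not None:
            out = np.clip(out, self.clip[0], self.clip[1])
        return out


# ---------------------------------------------------------------------------
# thin functional wrappers returning FitResult


def _to_result(est, X, terms: Optional[Sequence[str]], *, name: str,
               estimator: str, aic=None, stderr=None,
               iterations: int = 0, notes: str = "",
               bounds=None, censor_upper=None,
               glm_family=None, glm_link=None, glm_shift=None) -> FitResult:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    term_names = list(terms) if terms is not None else [
        f"x{i}" for i in range(X.shape[1])
    ]
    coef = getattr(est, "coef_", np.full(X.shape[1], np.nan))
    model = MappingModel(
        name=name,
        estimator=estimator,
        terms=list(zip(term_names, [float(c) for c in coef])),
        constant=float(getattr(est, "intercept_", np.nan)),
        bounds=bounds,
        censor_upper=censor_upper,
        glm_family=glm_family,
        glm_link=glm_link,
        glm_shift=glm_shift,
        provenance="fitted in-session",
    )
    return FitResult(
        model=model,
        n_used=X.shape[0],
        aic=aic,
        converged=bool(getattr(est, "converged_", True)),
        iterations=iterations,
        stderr=stderr,
        notes=notes or getattr(est, "notes_", ""),
        predictor=est,
    )


def fit_ols(X, y, terms=None, name="ols") -> FitResult:
    est = OLSRegressor().fit(X, y)
    return _to_result(est, X, terms, name=name, estimator="ols",
                      aic=est.aic_, stderr=est.stderr_)


def fit_clad(X, y, censor_upper: float = 1.0, terms=None, name="clad",
             max_iter: int = 100, compute_stderr: bool = False,
             n_bootstrap: int = 1000, seed: int = 0) -> FitResult:
    est = CLADRegressor(
        censor_upper=censor_upper, max_iter=max_iter,
        compute_stderr=compute_stderr, n_bootstrap=n_bootstrap, seed=seed,
    ).fit(X, y)
    return _to_result(est, X, terms, name=name, estimator="clad",
                      aic=None, stderr=est.stderr_,
                      iterations=est.n_iter_, censor_upper=censor_upper)


def fit_flogit(X, y, bounds: Tuple[float, float] = (-0.594, 1.0),
               terms=None, name="flogit") -> FitResult:
    est = FractionalLogitRegressor(bounds=bounds).fit(X, y)
    return _to_result(est, X, terms, name=name, estimator="flogit",
                      aic=est.aic_, stderr=est.stderr_, bounds=bounds)


def fit_glm(X, y, family: str = "gaussian", link: str = "identity",
            shift: float | str = "auto", terms=None, name="glm") -> FitResult:
    est = GLMRegressor(family=family, link=link, shift=shift).fit(X, y)
    aic = None if not est.converged_ and np.isnan(est.aic_) else est.aic_
    return _to_result(est, X, terms, name=name, estimator="glm",
                      aic=aic, stderr=est.stderr_,
                      glm_family=family, glm_link=link, glm_shift=est.shift_)
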