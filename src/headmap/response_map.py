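"""Response mapping: predict SF-6D dimension levels, then expected utility.

Instead of regressing the summary utility on the headache scores
directly, response mapping fits one multinomial logit per SF-6D
dimension on the covariates, predicts a probability over that
dimension's levels for each respondent, and converts the six
probability vectors to an expected utility under the additive tariff.

With an additive tariff the expectation decomposes per dimension:

    E[u] = constant − Σ_d Σ_l P_d(l) · decrement(d, l) − extra terms,

where the cross-dimension extra terms ("any dimension beyond level 1",
"any dimension at its worst level") are evaluated under independence of
dimensions given covariates: P(any beyond 1) = 1 − Π_d P_d(1), and
likewise for the worst-level term.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .tariffs import Tariff

__all__ = [
    "MultinomialResponseMapper",
    "fit_response_map",
    "predict_response_map",
    "expected_utility_from_probs",
    "DegenerateDimensionError",
]


class DegenerateDimensionError(ValueError):
    """A dimension shows a single observed level; its logit is unidentified."""


def expected_utility_from_probs(
    probs: Sequence[np.ndarray],
    levels: Sequence[np.ndarray],
    tariff: Tariff,
) -> np.ndarray:
    """Expected tariff utility from per-dimension level probabilities.

    ``probs[d]`` is an (n, K_d) matrix over the level values
    ``levels[d]``; dimensions are treated as independent, which is what
    makes the cross-dimension extra terms tractable in closed form.
    """
    n = probs[0].shape[0]
    eu = np.full(n, tariff.constant, dtype=float)
    p_all_level1 = np.ones(n)
    p_none_worst = np.ones(n)
    for d, (dim, nlev) in enumerate(zip(tariff.dimensions, tariff.levels)):
        P = np.asarray(probs[d], dtype=float)
        lv = np.asarray(levels[d])
        dec = np.array([tariff.decrement(dim, int(l)) for l in lv])
        eu -= P @ dec
        p1 = P[:, lv == 1].sum(axis=1) if (lv == 1).any() else np.zeros(n)
        pw = P[:, lv == nlev].sum(axis=1) if (lv == nlev).any() else np.zeros(n)
        p_all_level1 *= p1
        p_none_worst *= 1.0 - pw
    eu -= tariff.extra_terms.get("any_beyond_level1", 0.0) * (1.0 - p_all_level1)
    eu -= tariff.extra_terms.get("any_at_worst", 0.0) * (1.0 - p_none_worst)
    return eu


class MultinomialResponseMapper(BaseEstimator):
    """Per-dimension multinomial logits over SF-6D levels.

    ``fit(X, states)`` takes the covariate matrix and an (n, 6) array of
    observed dimension levels (1-based). Each dimension gets its own
    multinomial logit on the observed levels; levels never observed in
    the fitting sample receive probability zero at prediction time.

    Fitted attributes: ``results_`` (statsmodels fits per dimension),
    ``levels_`` (observed level values per dimension), ``aics_`` and
    ``aic_`` (per-dimension and summed), ``converged_``.
    """

    def __init__(self, tariff: Optional[Tariff] = None):
        self.tariff = tariff

    def fit(self, X, states):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        S = np.asarray(states, dtype=int)
        if S.ndim != 2 or S.shape[0] != X.shape[0]:
            raise ValueError(f"states shape {S.shape} incompatible with X {X.shape}")
        Xc = sm.add_constant(X, has_constant="add")
        self.results_, self.levels_, self.aics_ = [], [], []
        self.converged_ = True
        for d in range(S.shape[1]):
            obs = np.unique(S[:, d])
            if obs.size < 2:
                raise DegenerateDimensionError(
                    f"dimension {d} has a single observed level ({obs[0]})"
                )
            # recode observed levels to 0..K-1 for the multinomial fit
            codes = np.searchsorted(obs, S[:, d])
            res = sm.MNLogit(codes, Xc).fit(disp=0, maxiter=500)
            k = Xc.shape[1] * (obs.size - 1)
            self.results_.append(res)
            self.levels_.append(obs)
            self.aics_.append(2 * k - 2 * float(res.llf))
            self.converged_ &= bool(res.mle_retvals.get("converged", True))
        self.aic_ = float(np.sum(self.aics_))
        self.n_dimensions_ = S.shape[1]
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> List[np.ndarray]:
        """Per-dimension (n, K_d) level probabilities (observed levels only)."""
        check_is_fitted(self, "results_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        Xc = sm.add_constant(X, has_constant="add")
        return [np.asarray(res.predict(Xc)) for res in self.results_]

    def expected_utility(self, X, tariff: Optional[Tariff] = None) -> np.ndarray:
        """Expected tariff utility per row, dimensions independent given X."""
        t = tariff if tariff is not None else self.tariff
        if t is None:
            raise ValueError("a tariff is required to compute expected utilities")
        if len(t.dimensions) != self.n_dimensions_:
            raise ValueError(
                f"tariff has {len(t.dimensions)} dimensions, "
                f"mapper fitted on {self.n_dimensions_}"
            )
        return expected_utility_from_probs(
            self.predict_proba(X), self.levels_, t)

    def predict(self, X):
        return self.expected_utility(X)


def fit_response_map(X, sf6d_states, tariff: Optional[Tariff] = None):
    """Fit per-dimension multinomial logits; returns the fitted mapper."""
    return MultinomialResponseMapper(tariff=tariff).fit(X, sf6d_states)


def predict_response_map(mapper: MultinomialResponseMapper, X,
                         tariff: Tariff) -> np.ndarray:
    """Expected SF-6D utilities for each covariate row."""
    return mapper.expected_utility(X, tariff)
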