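"""Mapping models: named coefficient vectors applied to respondent data.

A :class:`MappingModel` is the portable artefact of this toolkit — an
ordered list of (term, coefficient) pairs plus a constant and enough
metadata (estimator kind, bounds, censoring, GLM family/link/shift) to
reproduce the prediction rule exactly. Applying a model is deliberately
mundane: build each required variable, multiply by its coefficient, add
the constant, then pass through the estimator's response transform
(identity for OLS/CLAD, inverse logit re-scaled to the instrument range
for fractional logit, the inverse link minus the recorded shift for GLM).

Four ready-to-apply published algorithms are bundled, one per
(source instrument, target utility) pair, selected by the multi-stage
procedure in :mod:`headmap.selection`:

========================  =================================================
``hit6_eq5d_clad1``       HIT-6 → EQ-5D (CLAD, scores only)
``chqlq_eq5d_clad3``      CH-QLQ → EQ-5D (CLAD, full interaction set)
``hit6_sf6d_clad2``       HIT-6 → SF-6D (CLAD, scores + age + sex)
``chqlq_sf6d_ols2``       CH-QLQ → SF-6D (OLS, scores + age + sex)
========================  =================================================

Coefficients are stored exactly as published, to four decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .design import term_value
from .respondent import Respondent

__all__ = [
    "MappingModel",
    "PUBLISHED_MODELS",
    "load_published_model",
    "load_model_file",
    "save_model_file",
    "predict_utilities",
    "UnknownModelError",
]

PUBLISHED_MODELS = (
    "hit6_eq5d_clad1",
    "chqlq_eq5d_clad3",
    "hit6_sf6d_clad2",
    "chqlq_sf6d_ols2",
)

#: theoretical target ranges used by the clip option
TARGET_RANGES = {"eq5d": (-0.594, 1.0), "sf6d": (0.345, 1.0)}


class UnknownModelError(KeyError):
    """Requested published model name is not in the registry."""


@dataclass
class MappingModel:
    name: str
    estimator: str  # ols | clad | flogit | glm | response_map
    terms: List[Tuple[str, float]]
    constant: float
    source: Optional[str] = None
    target: Optional[str] = None
    covariate_set: Optional[int] = None
    bounds: Optional[Tuple[float, float]] = None
    censor_upper: Optional[float] = None
    glm_family: Optional[str] = None
    glm_link: Optional[str] = None
    glm_shift: Optional[float] = None
    provenance: str = ""

    def linear_predictor(self, r: Respondent) -> Optional[float]:
        """Constant + Σ coef·term(r); None if any ingredient is missing."""
        total = self.constant
        for term, coef in self.terms:
            v = term_value(term, r)
            if v is None:
                return None
            total += coef * v
        return total

    def response(self, eta: float) -> float:
        """Apply the estimator's response transform to a linear predictor."""
        if self.estimator in ("ols", "clad"):
            return eta
        if self.estimator == "flogit":
            lo, hi = self.bounds if self.bounds else (0.0, 1.0)
            return lo + (hi - lo) / (1.0 + np.exp(-eta))
        if self.estimator == "glm":
            link = self.glm_link or "identity"
            if link == "identity":
                mu = eta
            elif link == "log":
                mu = float(np.exp(eta))
            else:
                mu = 1.0 / (1.0 + np.exp(-eta))
            return mu - (self.glm_shift or 0.0)
        raise ValueError(f"cannot evaluate estimator kind {self.estimator!r}")


def predict_utilities(
    model: MappingModel,
    cohort: Sequence[Respondent],
    clip: bool = False,
) -> Tuple[np.ndarray, List[str], List[str]]:
    """Apply a mapping model to a cohort.

    Returns (utilities, kept_ids, dropped_ids). Rows missing any term
    ingredient are dropped and reported — never silently imputed.
    With ``clip`` on, predictions are truncated to the target's
    theoretical range (CLAD models can otherwise exceed 1 at the
    mild end of the severity range, by design).
    """
    utilities, kept, dropped = [], [], []
    for r in cohort:
        eta = model.linear_predictor(r)
        if eta is None:
            dropped.append(r.id)
            continue
        u = model.response(eta)
        kept.append(r.id)
        utilities.append(u)
    out = np.asarray(utilities, dtype=float)
    if clip and model.target in TARGET_RANGES:
        lo, hi = TARGET_RANGES[model.target]
        out = np.clip(out, lo, hi)
    return out, kept, dropped


# ---------------------------------------------------------------------------
# plain-text model files (YAML)


def _model_to_dict(m: MappingModel) -> dict:
    d = {
        "name": m.name,
        "estimator": m.estimator,
        "terms": [[t, float(c)] for t, c in m.terms],
        "constant": float(m.constant),
        "provenance": m.provenance,
    }
    for k in ("source", "target", "covariate_set", "censor_upper",
              "glm_family", "glm_link", "glm_shift"):
        v = getattr(m, k)
        if v is not None:
            d[k] = v
    if m.bounds is not None:
        d["bounds"] = [float(m.bounds[0]), float(m.bounds[1])]
    return d


def save_model_file(model: MappingModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_model_to_dict(model), fh, sort_keys=False)


def _model_from_dict(d: dict) -> MappingModel:
    return MappingModel(
        name=d["name"],
        estimator=d["estimator"],
        terms=[(t, float(c)) for t, c in d["terms"]],
        constant=float(d["constant"]),
        source=d.get("source"),
        target=d.get("target"),
        covariate_set=d.get("covariate_set"),
        bounds=tuple(d["bounds"]) if d.get("bounds") else None,
        censor_upper=d.get("censor_upper"),
        glm_family=d.get("glm_family"),
        glm_link=d.get("glm_link"),
        glm_shift=d.get("glm_shift"),
        provenance=d.get("provenance", ""),
    )


def load_model_file(path) -> MappingModel:
    with open(path) as fh:
        return _model_from_dict(yaml.safe_load(fh))


def load_published_model(name: str) -> MappingModel:
    """Load one of the four bundled published mapping algorithms by name."""
    if name not in PUBLISHED_MODELS:
        raise UnknownModelError(
            f"unknown model {name!r}; available: {', '.join(PUBLISHED_MODELS)}"
        )
    path = resources.files("headmap.data.models").joinpath(f"{name}.yaml")
    with path.open() as fh:
        return _model_from_dict(yaml.safe_load(fh))
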