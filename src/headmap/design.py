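"""Covariate sets and design-matrix construction.

Three nested covariate sets are used throughout:

* set 1 — the headache scores alone (HIT-6 total, or the three CH-QLQ
  subscales);
* set 2 — set 1 plus age and a female indicator;
* set 3 — set 2 plus squared score terms, pairwise score interactions
  (CH-QLQ only), score×age interactions, and age squared.

Rows are complete-case: a respondent missing any required ingredient
(including ``sex = other_unknown`` whenever the female indicator is in
the term list) is dropped and reported via the kept-id list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np

from .respondent import FEMALE, MALE, Respondent

__all__ = ["DesignSpec", "build_design", "term_inventory", "EmptyDesignError"]


class EmptyDesignError(ValueError):
    """No complete-case rows remain for the requested covariate set."""


_SOURCES = ("hit6", "chqlq")
_TARGETS = ("eq5d", "sf6d")

_SCORE_TERMS = {"hit6": ["hit6"], "chqlq": ["chqrr", "chqrp", "chqef"]}


def term_inventory(source: str, covariate_set: int) -> List[str]:
    """Ordered term names for a (source, covariate set) pair.

    Set-3 order follows the published coefficient-table layout: scores,
    score squares, pairwise score interactions, score×age interactions,
    age, age squared, female indicator.
    """
    scores = _SCORE_TERMS[source]
    if covariate_set == 1:
        return list(scores)
    if covariate_set == 2:
        return scores + ["age", "female"]
    if covariate_set == 3:
        terms = list(scores)
        terms += [f"{s}_sq" for s in scores]
        for i in range(len(scores)):
            for j in range(i + 1, len(scores)):
                terms.append(f"{scores[i]}_x_{scores[j]}")
        terms += [f"{s}_x_age" for s in scores]
        terms += ["age", "age_sq", "female"]
        return terms
    raise ValueError(f"covariate_set must be 1, 2 or 3, got {covariate_set}")


@dataclass(frozen=True)
class DesignSpec:
    """Which scores predict which utility, with which covariate set."""

    source: str
    target: str
    covariate_set: int

    def __post_init__(self):
        if self.source not in _SOURCES:
            raise ValueError(f"source must be one of {_SOURCES}")
        if self.target not in _TARGETS:
            raise ValueError(f"target must be one of {_TARGETS}")
        if self.covariate_set not in (1, 2, 3):
            raise ValueError("covariate_set must be 1, 2 or 3")

    @property
    def term_list(self) -> List[str]:
        return term_inventory(self.source, self.covariate_set)


def term_value(term: str, r: Respondent) -> float | None:
    """Evaluate one named term for a respondent; None when an ingredient is missing."""
    base: Dict[str, object] = {
        "hit6": r.hit6,
        "chqrr": r.chq_rr,
        "chqrp": r.chq_rp,
        "chqef": r.chq_ef,
        "age": r.age,
    }
    if term in base:
        v = base[term]
        return None if v is None else float(v)
    if term == "female":
        if r.sex == FEMALE:
            return 1.0
        if r.sex == MALE:
            return 0.0
        return None  # other_unknown / missing -> complete-case drop
    if term.endswith("_sq"):
        v = term_value(term[:-3], r)
        return None if v is None else v * v
    if "_x_" in term:
        a, b = term.split("_x_", 1)
        va, vb = term_value(a, r), term_value(b, r)
        if va is None or vb is None:
            return None
        return va * vb
    raise KeyError(f"unknown term {term!r}")


def _response_value(target: str, r: Respondent) -> float | None:
    u = r.eq5d_utility if target == "eq5d" else r.sf6d_utility
    return None if u is None else float(u)


def build_design(
    cohort: Sequence[Respondent],
    spec: DesignSpec,
    require_response: bool = True,
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Build (X, y, kept_ids) for a cohort under a design spec.

    X has one column per term in ``spec.term_list`` (no intercept column;
    estimators add their own constant). Rows are complete cases only.
    With ``require_response=False`` the response may be missing (useful
    when applying a fitted model), and y carries NaN for those rows.
    """
    if len(cohort) == 0:
        raise EmptyDesignError("cohort is empty")
    terms = spec.term_list
    rows, ys, kept = [], [], []
    for r in cohort:
        vals = [term_value(t, r) for t in terms]
        if any(v is None for v in vals):
            continue
        y = _response_value(spec.target, r)
        if require_response and y is None:
            continue
        rows.append(vals)
        ys.append(np.nan if y is None else y)
        kept.append(r.id)
    if not rows:
        raise EmptyDesignError(
            f"no complete-case rows for terms {terms} "
            f"(target {spec.target!r}, n={len(cohort)})"
        )
    return np.asarray(rows, dtype=float), np.asarray(ys, dtype=float), kept
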