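"""Multi-stage model selection across estimator families.

For one (source instrument, target utility) pair, each estimator family
(OLS, FLOGIT, GLM, CLAD, response mapping) is fitted under covariate
sets 1–3, and the candidates are winnowed in three steps:

* Step 1 — within each family where the AIC is defined, keep the
  covariate set with the lowest AIC; families without an AIC (CLAD,
  response mapping, as treated here) advance all three sets.
* Step 2 — for families that advanced more than one candidate, keep
  the candidate with the lowest MSE (estimation sample by default).
* Step 3 — rank the per-family survivors by total MSE in the
  validation sample; the lowest wins. The error-by-range table of each
  survivor is attached so the final judgement call about tail
  performance stays inspectable.

The full trace — who was eliminated at which step and why — is
returned; the procedure is deterministic given the fits and samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .design import DesignSpec, build_design
from .estimators import FitResult
from .metrics import RangeBin, errors_by_range
from .respondent import Respondent

__all__ = ["aic", "select_models", "SelectionTrace", "StepRecord",
           "AICUndefinedError", "IncompleteFamilyError"]


class AICUndefinedError(ValueError):
    """AIC requested for an estimator without a defined likelihood."""


class IncompleteFamilyError(ValueError):
    """A family is missing one of the three covariate sets."""


def aic(fit: FitResult) -> float:
    """The Akaike information criterion of a fit: 2k − 2·log-likelihood.

    k counts every estimated coefficient including the constant.
    Raises for fits without a defined likelihood (CLAD).
    """
    if fit.aic is None:
        raise AICUndefinedError(
            f"AIC is undefined for estimator {fit.model.estimator!r}"
        )
    return float(fit.aic)


@dataclass
class StepRecord:
    step: int
    family: str
    covariate_set: int
    action: str          # "kept" | "eliminated" | "advanced"
    reason: str
    value: Optional[float] = None  # the AIC or MSE that drove the action


@dataclass
class SelectionTrace:
    records: List[StepRecord] = field(default_factory=list)
    winner_family: Optional[str] = None
    winner_covariate_set: Optional[int] = None
    winner: Optional[FitResult] = None
    validation_mse: Dict[str, float] = field(default_factory=dict)
    range_tables: Dict[str, List[RangeBin]] = field(default_factory=dict)

    def log(self, *a, **kw):
        self.records.append(StepRecord(*a, **kw))

    def format(self) -> str:
        lines = []
        for r in self.records:
            v = "" if r.value is None else f" ({r.value:.6g})"
            lines.append(
                f"step {r.step}: {r.family} set {r.covariate_set} "
                f"{r.action} — {r.reason}{v}"
            )
        if self.winner_family:
            lines.append(
                f"winner: {self.winner_family} covariate set "
                f"{self.winner_covariate_set}"
            )
        return "\n".join(lines)


def _mse_on(fit: FitResult, cohort: Sequence[Respondent]) -> float:
    m = fit.model
    spec = DesignSpec(m.source, m.target, m.covariate_set)
    X, y, _ = build_design(cohort, spec, require_response=True)
    pred = fit.predictor.predict(X)
    return float(np.mean((np.asarray(pred) - y) ** 2))


def select_models(
    fits: Mapping[str, Mapping[int, FitResult]],
    estimation_sample: Sequence[Respondent],
    validation_sample: Sequence[Respondent],
    step2_sample: str = "estimation",
) -> SelectionTrace:
    """Run the three-step selection over families of fitted candidates.

    ``fits`` maps family name → {covariate set (1, 2, 3) → FitResult};
    every FitResult.model must carry source/target/covariate_set so that
    design matrices can be rebuilt on the evaluation samples.
    ``step2_sample`` selects which sample Step 2's MSE uses
    ("estimation" or "validation").
    """
    trace = SelectionTrace()
    for family, by_set in fits.items():
        missing = {1, 2, 3} - set(by_set)
        if missing:
            raise IncompleteFamilyError(
                f"family {family!r} missing covariate set(s) {sorted(missing)}"
            )

    step2_cohort = (
        estimation_sample if step2_sample == "estimation" else validation_sample
    )

    # Step 1: AIC within family, where defined
    survivors: Dict[str, Dict[int, FitResult]] = {}
    for family, by_set in fits.items():
        if all(f.aic is not None for f in by_set.values()):
            best = min(sorted(by_set), key=lambda s: by_set[s].aic)
            for s in sorted(by_set):
                if s == best:
                    trace.log(1, family, s, "kept", "lowest AIC in family",
                              value=by_set[s].aic)
                else:
                    trace.log(1, family, s, "eliminated",
                              f"AIC above set {best}", value=by_set[s].aic)
            survivors[family] = {best: by_set[best]}
        else:
            for s in sorted(by_set):
                trace.log(1, family, s, "advanced",
                          "AIC unavailable for family; all sets advance")
            survivors[family] = dict(by_set)

    # Step 2: MSE within families that still carry several candidates
    finalists: Dict[str, Tuple[int, FitResult]] = {}
    for family, by_set in survivors.items():
        if len(by_set) == 1:
            ((s, f),) = by_set.items()
            finalists[family] = (s, f)
            continue
        mses = {s: _mse_on(f, step2_cohort) for s, f in sorted(by_set.items())}
        best = min(sorted(mses), key=lambda s: mses[s])
        for s in sorted(mses):
            action = "kept" if s == best else "eliminated"
            trace.log(2, family, s, action,
                      f"MSE in {step2_sample} sample", value=mses[s])
        finalists[family] = (best, by_set[best])

    # Step 3: validation-sample MSE across family finalists + range tables
    for family, (s, f) in sorted(finalists.items()):
        mse = _mse_on(f, validation_sample)
        trace.validation_mse[family] = mse
        m = f.model
        spec = DesignSpec(m.source, m.target, m.covariate_set)
        X, y, _ = build_design(validation_sample, spec, require_response=True)
        pred = np.asarray(f.predictor.predict(X))
        trace.range_tables[family] = errors_by_range(y, pred, target=m.target)
        trace.log(3, family, s, "ranked", "validation-sample MSE", value=mse)

    winner_family = min(sorted(trace.validation_mse),
                        key=lambda fam: trace.validation_mse[fam])
    s, f = finalists[winner_family]
    trace.winner_family = winner_family
    trace.winner_covariate_set = s
    trace.winner = f
    trace.log(3, winner_family, s, "kept", "lowest validation MSE",
              value=trace.validation_mse[winner_family])
    return trace
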