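"""Synthetic chronic-headache cohorts.

No public dataset carries both headache instruments and both utility
measures, so the toolkit ships a seeded generator that emulates the
joint structure mapping relies on: a single latent severity ``z`` (one
standard-normal factor) drives every instrument, with independent
per-instrument noise. Higher severity raises the HIT-6 total, lowers
the CH-QLQ subscales, and pushes the EQ-5D / SF-6D dimension levels
toward worse categories through per-dimension ordinal thresholds on a
correlated latent. EQ-5D utilities then come from applying the bundled
UK 3L tariff to the generated states — the characteristic bimodal,
negatively skewed utility distribution emerges from the mass at full
health plus the tariff's large worst-level decrement, not from any
hand-placed mixture.

Default calibration constants live in ``data/cohort_defaults.yaml``,
tuned to the published test-sample summary statistics.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .respondent import FEMALE, MALE, Respondent
from .tariffs import (EQ5D_DIMENSIONS, SF6D_DIMENSIONS, Tariff,
                      sf6d_tariff, uk_eq5d3l_tariff)
from .design import term_value

__all__ = ["CohortSpec", "default_spec", "simulate_cohort",
           "simulate_true_mapping", "TrueMapping"]


@dataclass
class CohortSpec:
    """Generator configuration: sample size, seed, calibration constants.

    ``config`` mirrors the packaged defaults YAML; ``age_effect`` is an
    optional genuine linear age effect (utility units per year, applied
    around the mean age) used by selection-procedure experiments and
    zero by default.
    """

    n: int = 349
    seed: int = 0
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        defaults = _load_defaults()
        merged = copy.deepcopy(defaults)
        _deep_update(merged, self.config or {})
        self.config = merged
        demo = self.config["demographics"]
        if not (0.0 <= demo["female_proportion"] <= 1.0):
            raise ValueError("female_proportion must lie in [0, 1]")
        if demo["age_min"] < 18:
            raise ValueError("age_min below adult minimum 18")


def _load_defaults() -> dict:
    path = resources.files("headmap.data").joinpath("cohort_defaults.yaml")
    with path.open() as fh:
        return yaml.safe_load(fh)


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def default_spec(n: int = 349, seed: int = 0, **overrides) -> CohortSpec:
    return CohortSpec(n=n, seed=seed, config=overrides)


def _ordinal_levels(z: np.ndarray, loading: float, thresholds: Sequence[float],
                    rng: np.random.Generator) -> np.ndarray:
    """Threshold a correlated latent into 1-based ordinal levels."""
    noise = math.sqrt(max(0.0, 1.0 - loading ** 2))
    zd = loading * z + noise * rng.standard_normal(z.size)
    levels = np.ones(z.size, dtype=int)
    for t in thresholds:
        levels += (zd > t).astype(int)
    return levels


def simulate_cohort(
    spec: CohortSpec,
    eq5d_tariff_obj: Optional[Tariff] = None,
    sf6d_tariff_obj: Optional[Tariff] = None,
) -> List[Respondent]:
    """Draw a seeded cohort of respondents with scores, states and utilities."""
    cfg = spec.config
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    t_eq = eq5d_tariff_obj if eq5d_tariff_obj is not None else uk_eq5d3l_tariff()
    t_sf = sf6d_tariff_obj if sf6d_tariff_obj is not None else sf6d_tariff()

    z = rng.standard_normal(n)

    demo = cfg["demographics"]
    female = rng.random(n) < demo["female_proportion"]
    age = np.clip(
        np.round(demo["age_mean"] + demo["age_sd"] * rng.standard_normal(n)),
        demo["age_min"], demo["age_max"],
    ).astype(int)

    inst = cfg["instruments"]

    def score(name, lo, hi, integer=False):
        p = inst[name]
        raw = p["mean"] + p["loading"] * z + p["noise"] * rng.standard_normal(n)
        if integer:
            raw = np.round(raw)
        return np.clip(raw, lo, hi)

    hit6 = score("hit6", 36, 78, integer=True).astype(int)
    chq_rr = score("chq_rr", 0.0, 100.0)
    chq_rp = score("chq_rp", 0.0, 100.0)
    chq_ef = score("chq_ef", 0.0, 100.0)

    eq_cfg = cfg["eq5d"]
    eq_levels = np.column_stack([
        _ordinal_levels(z, eq_cfg["dim_loading"], eq_cfg["thresholds"][d], rng)
        for d in EQ5D_DIMENSIONS
    ])
    sf_cfg = cfg["sf6d"]
    sf_levels = np.column_stack([
        _ordinal_levels(z, sf_cfg["dim_loading"], sf_cfg["thresholds"][d], rng)
        for d in SF6D_DIMENSIONS
    ])

    age_effect = float(cfg.get("age_effect", 0.0))
    age_centered = age - demo["age_mean"]

    cohort: List[Respondent] = []
    for i in range(n):
        eq_state = tuple(int(v) for v in eq_levels[i])
        sf_state = tuple(int(v) for v in sf_levels[i])
        u_eq = t_eq.utility(eq_state)
        u_sf = t_sf.utility(sf_state)
        if age_effect:
            u_eq = float(np.clip(u_eq + age_effect * age_centered[i],
                                 t_eq.floor, 1.0))
            u_sf = float(np.clip(u_sf + age_effect * age_centered[i],
                                 t_sf.floor, 1.0))
        cohort.append(Respondent(
            id=f"sim{i:05d}",
            hit6=int(hit6[i]),
            chq_rr=float(chq_rr[i]),
            chq_rp=float(chq_rp[i]),
            chq_ef=float(chq_ef[i]),
            age=int(age[i]),
            sex=FEMALE if female[i] else MALE,
            # 3L levels embed into the 5L descriptive system at the odd levels
            eq5d5l_state=tuple(2 * lv - 1 for lv in eq_state),
            sf6d_state=sf_state,
            eq5d_utility=u_eq,
            sf6d_utility=u_sf,
        ))
    return cohort


@dataclass
class TrueMapping:
    """A cohort whose target utilities follow a known linear model."""

    cohort: List[Respondent]
    beta: Dict[str, float]
    constant: float
    noise: str
    noise_scale: float
    censor_upper: float
    target: str


def simulate_true_mapping(
    spec: CohortSpec,
    beta: Dict[str, float],
    constant: float,
    noise: str = "laplace",
    noise_scale: float = 0.1,
    censor_upper: float = 1.0,
    target: str = "eq5d",
) -> TrueMapping:
    """Overwrite a cohort's target utility with a known censored linear model.

    ``beta`` maps design-term names (e.g. ``hit6``, ``age``, ``female``)
    to generating coefficients; the observed utility is
    ``min(censor_upper, constant + Xβ + ε)`` with Gaussian or Laplace ε.
    The generating parameters ride along for parameter-recovery tests.
    """
    if noise not in ("gaussian", "laplace"):
        raise ValueError(f"noise must be gaussian or laplace, got {noise!r}")
    cohort = simulate_cohort(spec)
    rng = np.random.default_rng(spec.seed + 1_000_003)
    n = len(cohort)
    if noise == "gaussian":
        eps = noise_scale * rng.standard_normal(n)
    else:
        eps = rng.laplace(0.0, noise_scale, size=n)
    for i, r in enumerate(cohort):
        lp = constant + sum(c * term_value(t, r) for t, c in beta.items())
        y = lp + eps[i]
        if censor_upper is not None and math.isfinite(censor_upper):
            y = min(censor_upper, y)
        if target == "eq5d":
            r.eq5d_utility = float(y)
        else:
            r.sf6d_utility = float(y)
    return TrueMapping(cohort=cohort, beta=dict(beta), constant=constant,
                       noise=noise, noise_scale=noise_scale,
                       censor_upper=censor_upper, target=target)
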