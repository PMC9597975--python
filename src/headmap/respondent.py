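"""Respondent records and instrument-range validation.

The toolkit works on respondent-level rows carrying the headache-specific
scores (HIT-6 total; the three CH-QLQ subscales), demographics, and —
when observed — EQ-5D / SF-6D descriptive-system states and utilities.
Item-level scoring of the instruments is out of scope: scores arrive
pre-summarised and are only checked against instrument ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

__all__ = [
    "Respondent",
    "validate_respondent",
    "HIT6_RANGE",
    "CHQLQ_RANGE",
    "EQ5D_UTILITY_RANGE",
    "SF6D_UTILITY_RANGE",
]

#: theoretical instrument bounds
HIT6_RANGE = (36, 78)
CHQLQ_RANGE = (0.0, 100.0)
EQ5D_UTILITY_RANGE = (-0.594, 1.0)
SF6D_UTILITY_RANGE = (0.345, 1.0)

FEMALE = "female"
MALE = "male"
OTHER_UNKNOWN = "other_unknown"
_SEX_VALUES = frozenset({FEMALE, MALE, OTHER_UNKNOWN})


@dataclass
class Respondent:
    """One survey respondent.

    Optional fields stay ``None`` when the instrument was not completed;
    complete-case handling happens downstream in design construction.
    """

    id: str
    hit6: Optional[int] = None
    chq_rr: Optional[float] = None
    chq_rp: Optional[float] = None
    chq_ef: Optional[float] = None
    age: Optional[int] = None
    sex: Optional[str] = None
    eq5d5l_state: Optional[Tuple[int, int, int, int, int]] = None
    sf6d_state: Optional[Tuple[int, ...]] = None
    eq5d_utility: Optional[float] = None
    sf6d_utility: Optional[float] = None


_EPS = 1e-9  # absorb float error at tariff floors (e.g. -0.594 - 1e-16)


def _check_range(name: str, value, lo, hi, out: list) -> None:
    if value is not None and not (lo - _EPS <= value <= hi + _EPS):
        out.append(f"{name}={value!r} outside [{lo}, {hi}]")


def validate_respondent(r: Respondent) -> list[str]:
    """Return a list of invariant violations (empty when the record is valid).

    Validation never raises: each violation is a human-readable string
    naming the offending field and the bound it breaks.
    """
    violations: list[str] = []
    _check_range("hit6", r.hit6, *HIT6_RANGE, violations)
    for name in ("chq_rr", "chq_rp", "chq_ef"):
        _check_range(name, getattr(r, name), *CHQLQ_RANGE, violations)
    _check_range("eq5d_utility", r.eq5d_utility, *EQ5D_UTILITY_RANGE, violations)
    _check_range("sf6d_utility", r.sf6d_utility, *SF6D_UTILITY_RANGE, violations)
    if r.age is not None and r.age < 18:
        violations.append(f"age={r.age!r} below adult minimum 18")
    if r.sex is not None and r.sex not in _SEX_VALUES:
        violations.append(
            f"sex={r.sex!r} not one of {sorted(_SEX_VALUES)}"
        )
    if r.eq5d5l_state is not None:
        if len(r.eq5d5l_state) != 5 or any(
            not (1 <= lv <= 5) for lv in r.eq5d5l_state
        ):
            violations.append(
                f"eq5d5l_state={r.eq5d5l_state!r} must be five levels in 1..5"
            )
    return violations


def normalize_sex(raw: str) -> str:
    """Map free-form sex labels onto the internal categories.

    Accepts f/m/female/male/other/unknown case-insensitively; anything
    unrecognised becomes ``other_unknown`` rather than raising.
    """
    token = str(raw).strip().lower()
    if token in ("f", "female"):
        return FEMALE
    if token in ("m", "male"):
        return MALE
    return OTHER_UNKNOWN
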