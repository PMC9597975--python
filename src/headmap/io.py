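"""Reading and writing respondent-level delimited files."""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .respondent import Respondent, normalize_sex, validate_respondent

__all__ = ["read_cohort_csv", "write_cohort_csv", "SchemaError",
           "COHORT_COLUMNS"]

log = logging.getLogger("headmap")

#: canonical column names written by the simulator / accepted by readers
COHORT_COLUMNS = [
    "id", "hit6", "chq_rr", "chq_rp", "chq_ef", "age", "sex",
    "eq5d5l_state", "sf6d_state", "eq5d_utility", "sf6d_utility",
]

_OPTIONAL_FLOATS = ("chq_rr", "chq_rp", "chq_ef", "eq5d_utility", "sf6d_utility")


class SchemaError(ValueError):
    """Input file is missing a required column or is empty."""


def _parse_state(raw) -> Optional[tuple]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return None
    return tuple(int(p) for p in str(raw).split("-"))


def _fmt_state(state) -> str:
    return "" if state is None else "-".join(str(int(v)) for v in state)


def read_cohort_csv(
    path,
    column_map: Optional[Dict[str, str]] = None,
    required: Sequence[str] = ("id",),
) -> Tuple[List[Respondent], List[Tuple[int, str]]]:
    """Load respondents from a delimited file.

    ``column_map`` renames file columns onto the canonical names (e.g.
    ``{"HIT6_total": "hit6"}``). Rows failing instrument validation are
    excluded and returned as (row number, reason) pairs rather than
    raising; a missing *required* column is a schema error.
    """
    try:
        df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    if column_map:
        df = df.rename(columns=column_map)
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")

    def get(row, col):
        v = row.get(col)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return v

    cohort: List[Respondent] = []
    rejected: List[Tuple[int, str]] = []
    for i, row in enumerate(df.to_dict("records")):
        ident = str(get(row, "id") if get(row, "id") is not None else i)
        hit6 = get(row, "hit6")
        age = get(row, "age")
        sex = get(row, "sex")
        r = Respondent(
            id=ident,
            hit6=None if hit6 is None else int(hit6),
            age=None if age is None else int(age),
            sex=None if sex is None else normalize_sex(sex),
            eq5d5l_state=_parse_state(get(row, "eq5d5l_state")),
            sf6d_state=_parse_state(get(row, "sf6d_state")),
            **{k: (None if get(row, k) is None else float(get(row, k)))
               for k in _OPTIONAL_FLOATS},
        )
        problems = validate_respondent(r)
        if problems:
            # +2: header line plus 1-based row numbering
            rejected.append((i + 2, "; ".join(problems)))
            log.warning("row %d excluded: %s", i + 2, "; ".join(problems))
            continue
        cohort.append(r)
    return cohort, rejected


def write_cohort_csv(cohort: Sequence[Respondent], path) -> None:
    rows = []
    for r in cohort:
        rows.append({
            "id": r.id, "hit6": r.hit6,
            "chq_rr": r.chq_rr, "chq_rp": r.chq_rp, "chq_ef": r.chq_ef,
            "age": r.age, "sex": r.sex,
            "eq5d5l_state": _fmt_state(r.eq5d5l_state),
            "sf6d_state": _fmt_state(r.sf6d_state),
            "eq5d_utility": r.eq5d_utility, "sf6d_utility": r.sf6d_utility,
        })
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)
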