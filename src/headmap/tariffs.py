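"""Preference-based value sets (tariffs) and the 5L→3L crosswalk.

A tariff converts a descriptive-system health state (a tuple of dimension
levels) into a utility on the scale anchored at 1 = full health, 0 = dead.
Both bundled tariffs are additive: start from the full-health constant,
subtract a decrement per dimension level, then subtract any extra terms
triggered by state-wide predicates (e.g. "any dimension beyond level 1").

Because no accepted UK tariff exists for the EQ-5D-5L descriptive system,
5L responses are first cross-walked to the EQ-5D-3L tariff via an exact
3125-state lookup table. The official crosswalk is loaded from file when
available; :func:`synthetic_crosswalk` builds a clearly-labelled stand-in
by interpolating the 3L tariff over fractional levels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

__all__ = [
    "Tariff",
    "CrosswalkTable",
    "load_tariff",
    "uk_eq5d3l_tariff",
    "sf6d_tariff",
    "eq5d3l_utility",
    "sf6d_utility",
    "crosswalk_5l_to_3l_utility",
    "synthetic_crosswalk",
    "load_crosswalk",
    "enumerate_eq5d3l_states",
    "InvalidStateError",
    "CorruptTableError",
]

EQ5D_DIMENSIONS = ("MO", "SC", "UA", "PD", "AD")
SF6D_DIMENSIONS = ("PF", "RL", "SF", "PAIN", "MH", "VIT")
SF6D_LEVELS = (3, 4, 5, 5, 5, 5)


class InvalidStateError(ValueError):
    """A health state has a level outside its dimension's range."""


class CorruptTableError(ValueError):
    """A crosswalk table is incomplete or malformed."""


@dataclass(frozen=True)
class Tariff:
    """Additive value set: constant minus per-level decrements minus extra terms.

    ``extra_terms`` maps a predicate name to a decrement; supported
    predicates are ``any_beyond_level1`` (some dimension above level 1)
    and ``any_at_worst`` (some dimension at its worst level).
    """

    name: str
    constant: float
    decrements: Mapping[Tuple[str, int], float]
    extra_terms: Mapping[str, float] = field(default_factory=dict)
    dimensions: Tuple[str, ...] = EQ5D_DIMENSIONS
    levels: Tuple[int, ...] = (3, 3, 3, 3, 3)
    provenance: str = ""

    def decrement(self, dim: str, level: int) -> float:
        if level == 1:
            return 0.0
        return self.decrements.get((dim, level), 0.0)

    def utility(self, state: Sequence[int]) -> float:
        """Evaluate the tariff at an integer-level state."""
        if len(state) != len(self.dimensions):
            raise InvalidStateError(
                f"state {tuple(state)} has {len(state)} levels, "
                f"tariff {self.name!r} expects {len(self.dimensions)}"
            )
        for dim, lv, nlev in zip(self.dimensions, state, self.levels):
            if not (1 <= lv <= nlev):
                raise InvalidStateError(
                    f"level {lv} invalid for dimension {dim} (1..{nlev})"
                )
        u = self.constant
        for dim, lv in zip(self.dimensions, state):
            u -= self.decrement(dim, int(lv))
        if any(lv > 1 for lv in state):
            u -= self.extra_terms.get("any_beyond_level1", 0.0)
        if any(lv == nlev for lv, nlev in zip(state, self.levels)):
            u -= self.extra_terms.get("any_at_worst", 0.0)
        return u

    @property
    def floor(self) -> float:
        """Utility of the worst state (every dimension at its worst level)."""
        return self.utility(self.levels)


def load_tariff(path, name: str | None = None,
                dimensions: Tuple[str, ...] | None = None) -> Tariff:
    """Read a tariff from the delimited fixture format.

    Rows: ``constant <v>``, ``extra <predicate> <v>``,
    ``decrement <dim> <level> <v>``; ``#`` lines are comments.
    Dimension order and per-dimension level counts are inferred from the
    decrement rows (first appearance order) unless ``dimensions`` is given.
    """
    constant = 1.0
    extras: Dict[str, float] = {}
    decs: Dict[Tuple[str, int], float] = {}
    order: List[str] = []
    provenance_lines: List[str] = []
    text = Path(path).read_text()
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "provenance:" in line:
                provenance_lines.append(line.lstrip("# ").strip())
            continue
        parts = line.split("\t")
        kind = parts[0]
        if kind == "constant":
            constant = float(parts[1])
        elif kind == "extra":
            extras[parts[1]] = float(parts[2])
        elif kind == "decrement":
            dim, lv, val = parts[1], int(parts[2]), float(parts[3])
            decs[(dim, lv)] = val
            if dim not in order:
                order.append(dim)
        else:
            raise ValueError(f"unrecognised tariff row: {raw!r}")
    dims = dimensions if dimensions is not None else tuple(order)
    levels = tuple(
        max(lv for (d, lv) in decs if d == dim) for dim in dims
    )
    return Tariff(
        name=name or Path(path).stem,
        constant=constant,
        decrements=decs,
        extra_terms=extras,
        dimensions=dims,
        levels=levels,
        provenance="; ".join(provenance_lines),
    )


def _data_path(fname: str):
    return resources.files("headmap.data").joinpath(fname)


def uk_eq5d3l_tariff() -> Tariff:
    """The bundled UK EQ-5D-3L time-trade-off value set (range −0.594 to 1)."""
    return load_tariff(_data_path("eq5d3l_uk.tsv"), name="eq5d3l_uk")


def sf6d_tariff() -> Tariff:
    """The bundled SF-6D (SF-12) tariff fixture — synthetic, floor 0.345."""
    return load_tariff(_data_path("sf6d_sf12_synthetic.tsv"), name="sf6d_sf12")


def eq5d3l_utility(state: Sequence[int], tariff: Tariff | None = None) -> float:
    """Utility of an EQ-5D-3L state under an additive tariff (default: UK TTO)."""
    t = tariff if tariff is not None else uk_eq5d3l_tariff()
    return t.utility(state)


def sf6d_utility(state: Sequence[int], tariff: Tariff | None = None) -> float:
    """Utility of an SF-6D state (levels 3/4/5/5/5/5 by default)."""
    t = tariff if tariff is not None else sf6d_tariff()
    return t.utility(state)


def enumerate_eq5d3l_states() -> List[Tuple[int, int, int, int, int]]:
    """All 243 EQ-5D-3L health states in lexicographic order."""
    return list(itertools.product((1, 2, 3), repeat=5))


# ---------------------------------------------------------------------------
# 5L -> 3L crosswalk


@dataclass(frozen=True)
class CrosswalkTable:
    """Exact lookup from each of the 3125 EQ-5D-5L states to a 3L-tariff utility."""

    entries: Mapping[Tuple[int, int, int, int, int], float]
    provenance: str = ""

    def __post_init__(self):
        if len(self.entries) != 5 ** 5:
            raise CorruptTableError(
                f"crosswalk has {len(self.entries)} entries, expected 3125"
            )

    def utility(self, state: Sequence[int]) -> float:
        for lv in state:
            if not (1 <= lv <= 5):
                raise InvalidStateError(f"5L level {lv} outside 1..5")
        key = tuple(int(lv) for lv in state)
        if len(key) != 5:
            raise InvalidStateError(f"5L state needs 5 levels, got {key}")
        try:
            return self.entries[key]
        except KeyError:
            raise CorruptTableError(f"crosswalk missing state {key}") from None


def crosswalk_5l_to_3l_utility(state: Sequence[int], xw: CrosswalkTable) -> float:
    """Pure lookup: the cross-walked 3L-tariff utility of a 5L state."""
    return xw.utility(state)


def _interp_decrement(tariff: Tariff, dim: str, v: float) -> float:
    # piecewise-linear between the integer-level decrements d(1)=0, d(2), d(3)
    lo = int(v)
    if lo >= 3:
        return tariff.decrement(dim, 3)
    frac = v - lo
    d_lo = tariff.decrement(dim, lo)
    d_hi = tariff.decrement(dim, lo + 1)
    return d_lo + frac * (d_hi - d_lo)


def synthetic_crosswalk(tariff: Tariff | None = None) -> CrosswalkTable:
    """A synthetic stand-in for the official 5L→3L crosswalk.

    Each 5L level maps to a fractional 3L level (1, 1.5, 2, 2.5, 3); the
    3L tariff's decrements and extra terms are interpolated linearly in
    that fractional level. States whose 5L levels are all odd coincide
    with genuine 3L states and reproduce the 3L tariff exactly, so the
    table spans the full −0.594..1 range, is monotone in every dimension,
    and keeps full health at 1.
    """
    t = tariff if tariff is not None else uk_eq5d3l_tariff()
    entries: Dict[Tuple[int, int, int, int, int], float] = {}
    beyond = t.extra_terms.get("any_beyond_level1", 0.0)
    worst = t.extra_terms.get("any_at_worst", 0.0)
    for state in itertools.product(range(1, 6), repeat=5):
        v = [1.0 + (lv - 1) / 2.0 for lv in state]
        u = t.constant
        for dim, vv in zip(t.dimensions, v):
            u -= _interp_decrement(t, dim, vv)
        # soft indicator weights so integer states reduce to the 3L predicates
        u -= beyond * max(min(vv - 1.0, 1.0) for vv in v)
        u -= worst * max(max(vv - 2.0, 0.0) for vv in v)
        entries[state] = u
    return CrosswalkTable(entries=entries, provenance="synthetic (interpolated 3L tariff)")


def load_crosswalk(path) -> CrosswalkTable:
    """Load a crosswalk from a 6-column delimited file (5 levels + utility)."""
    entries: Dict[Tuple[int, int, int, int, int], float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) != 6:
            raise CorruptTableError(f"crosswalk row needs 6 columns: {raw!r}")
        key = tuple(int(p) for p in parts[:5])
        entries[key] = float(parts[5])
    return CrosswalkTable(entries=entries, provenance=str(path))


def write_crosswalk(xw: CrosswalkTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("# five 5L levels (MO SC UA PD AD) then 3L-tariff utility\n")
        for state in sorted(xw.entries):
            u = xw.entries[state]
            fh.write("\t".join(str(s) for s in state) + f"\t{u:.6f}\n")
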