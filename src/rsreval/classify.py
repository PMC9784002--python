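"""WHO comprehensive-evaluation types and policy categories.

The WHO model cross-classifies a region's health-service *needs*,
*utilization* and *resource input* levels into eight types A-H that
describe the match between demand, use and supply.  With two levels per
axis the mapping is the classic 2x2x2 table; the Chinese basic-public-
health extension grades each axis Low/Medium/High and assigns one of the
same eight types to each of the 27 grade triples.

Types group into five policy categories:

    relative balance   A, H, F      demand, use and supply in step
    low input          B            use outpaces resource investment
    resource shortage  D            high need, little use, little supply
    overutilization    E            use high relative to need
    resource waste     C, G         supply high relative to use

The 27-cell map ships as packaged JSON (``data/who_map_3level.json``) so a
corrected reading of the source table can be swapped in without touching
code; it was validated by exact reproduction of the published 2009 and 2019
per-province types and category counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "GradeTriple", "ClassificationResult", "TransitionResult",
    "who_type_2level", "who_type_3level", "categorize", "classify_all",
    "transitions", "load_type_map", "WHO_TYPES", "POLICY_CATEGORIES",
    "CATEGORY_OF_TYPE",
]

WHO_TYPES = ("A", "B", "C", "D", "E", "F", "G", "H")

#: categories in reporting order
POLICY_CATEGORIES = (
    "relative_balance", "low_input", "resource_shortage",
    "overutilization", "resource_waste",
)

CATEGORY_OF_TYPE = {
    "A": "relative_balance", "H": "relative_balance", "F": "relative_balance",
    "B": "low_input", "D": "resource_shortage", "E": "overutilization",
    "C": "resource_waste", "G": "resource_waste",
}

# 2x2x2 table: (needs, utilization, resources) with High/Low levels
_MAP_2LEVEL = {
    ("High", "High", "High"): "A", ("High", "High", "Low"): "B",
    ("High", "Low", "High"): "C", ("High", "Low", "Low"): "D",
    ("Low", "High", "High"): "E", ("Low", "High", "Low"): "F",
    ("Low", "Low", "High"): "G", ("Low", "Low", "Low"): "H",
}

_LEVELS_2 = ("Low", "High")
_LEVELS_3 = ("Low", "Medium", "High")


class GradeTriple(NamedTuple):
    """Grades of one unit on the three dimensions."""

    needs: str
    utilization: str
    resources: str


def load_type_map(path: str | Path | None = None) -> dict:
    """Load the 27-cell three-level map.

    The JSON maps utilization grade -> "needs,resources" -> type.  Returns
    a flat dict keyed by (needs, utilization, resources).  A custom *path*
    may supply an alternative table in the same JSON layout.
    """
    if path is None:
        raw = resources.files("rsreval.data").joinpath(
            "who_map_3level.json").read_text()
    else:
        raw = Path(path).read_text()
    nested = json.loads(raw)
    flat = {}
    for util, cells in nested.items():
        for key, who_type in cells.items():
            needs, res = key.split(",")
            flat[(needs, util, res)] = who_type
    expected = {(n, u, r) for n in _LEVELS_3 for u in _LEVELS_3 for r in _LEVELS_3}
    if set(flat) != expected:
        raise ValueError("three-level type map must cover all 27 grade triples")
    bad = sorted(set(flat.values()) - set(WHO_TYPES))
    if bad:
        raise ValueError(f"type map contains unknown types {bad}")
    return flat


_MAP_3LEVEL_CACHE: dict | None = None


def _map_3level() -> dict:
    global _MAP_3LEVEL_CACHE
    if _MAP_3LEVEL_CACHE is None:
        _MAP_3LEVEL_CACHE = load_type_map()
    return _MAP_3LEVEL_CACHE


def who_type_2level(triple: GradeTriple) -> str:
    """Type A-H from a two-level (Low/High) grade triple."""
    triple = GradeTriple(*triple)
    for g in triple:
        if g not in _LEVELS_2:
            raise ValueError(
                f"two-level mode accepts grades {_LEVELS_2}, got {g!r}")
    return _MAP_2LEVEL[triple]


def who_type_3level(triple: GradeTriple, type_map: dict | None = None) -> str:
    """Type A-H from a three-level (Low/Medium/High) grade triple."""
    triple = GradeTriple(*triple)
    for g in triple:
        if g not in _LEVELS_3:
            raise ValueError(
                f"three-level mode accepts grades {_LEVELS_3}, got {g!r}")
    return (type_map or _map_3level())[triple]


def categorize(who_type: str) -> str:
    """Policy category of a WHO type."""
    try:
        return CATEGORY_OF_TYPE[who_type]
    except KeyError:
        raise ValueError(f"unknown WHO type {who_type!r}") from None


@dataclass
class ClassificationResult:
    """Per-unit grade triples, WHO types and policy categories."""

    units: list[str]
    triples: list[GradeTriple]
    who_types: list[str]
    categories: list[str]
    counts: dict
    year: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "unit": self.units,
            "needs_grade": [t.needs for t in self.triples],
            "utilization_grade": [t.utilization for t in self.triples],
            "resources_grade": [t.resources for t in self.triples],
            "who_type": self.who_types,
            "category": self.categories,
        })

    def units_in(self, category: str) -> list[str]:
        return [u for u, c in zip(self.units, self.categories) if c == category]


def classify_all(schemes: dict, year: int | None = None,
                 type_map: dict | None = None) -> ClassificationResult:
    """Classify every unit from per-dimension grading schemes.

    *schemes* maps dimension name ("needs", "utilization", "resources") to
    a :class:`~rsreval.grading.GradingScheme`; the three must cover the
    identical unit set.
    """
    missing = [d for d in ("needs", "utilization", "resources") if d not in schemes]
    if missing:
        raise ValueError(f"missing grading schemes for dimensions {missing}")
    units = list(schemes["needs"].units)
    for dim in ("utilization", "resources"):
        if list(schemes[dim].units) != units:
            raise ValueError(
                f"unit set of {dim!r} scheme differs from needs scheme")
    grade_of = {dim: dict(zip(schemes[dim].units, schemes[dim].grade))
                for dim in ("needs", "utilization", "resources")}
    triples = [GradeTriple(grade_of["needs"][u], grade_of["utilization"][u],
                           grade_of["resources"][u]) for u in units]
    types = [who_type_3level(t, type_map) for t in triples]
    cats = [categorize(t) for t in types]
    counts = {c: cats.count(c) for c in POLICY_CATEGORIES}
    return ClassificationResult(units=units, triples=triples, who_types=types,
                                categories=cats, counts=counts, year=year)


@dataclass
class TransitionResult:
    """Category movements between two classifications of the same units."""

    matrix: pd.DataFrame           # rows = earlier category, cols = later
    moves: list                    # (unit, earlier_category, later_category), changed only
    n_changed: int

    def moved_into(self, category: str) -> list[str]:
        """Units that entered *category* from any other category."""
        return [u for u, frm, to in self.moves if to == category]


def transitions(earlier: ClassificationResult,
                later: ClassificationResult) -> TransitionResult:
    """5x5 category-transition counts plus the per-unit change list.

    No ordering or "improvement" scoring is applied to category changes;
    movements are reported descriptively.
    """
    if set(earlier.units) != set(later.units):
        raise ValueError("the two classifications cover different unit sets")
    later_cat = dict(zip(later.units, later.categories))
    mat = pd.DataFrame(0, index=list(POLICY_CATEGORIES),
                       columns=list(POLICY_CATEGORIES))
    moves = []
    for unit, frm in zip(earlier.units, earlier.categories):
        to = later_cat[unit]
        mat.loc[frm, to] += 1
        if frm != to:
            moves.append((unit, frm, to))
    return TransitionResult(matrix=mat, moves=moves, n_changed=len(moves))
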