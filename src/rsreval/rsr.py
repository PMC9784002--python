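"""Non-integer rank transformation and rank-sum-ratio (RSR) scores.

Classical RSR replaces each indicator value by its integer rank among the n
units and averages ranks within a dimension.  The non-integer variant used
here interpolates the rank linearly between 1 and n from the value's
position within the column range, so quantitative spacing between units is
retained:

    high quality:  R = 1 + (n - 1) (X - X_min) / (X_max - X_min)
    low  quality:  R = 1 + (n - 1) (X_max - X) / (X_max - X_min)

Both map into [1, n], with rank n for the best unit and 1 for the worst.
The dimension score is the rank sum ratio

    RSR_i = (sum_j R_ij) / (m n),   in [1/n, 1],

with all m indicators of a dimension weighted equally.  Dimensions are
always scored separately; no cross-dimension aggregate is formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io import DIMENSIONS, IndicatorSpec, IndicatorTable, RSRTable

__all__ = ["RankMatrix", "noninteger_rank", "compute_rsr", "evaluate_dimensions"]


@dataclass
class RankMatrix:
    """Non-integer ranks for the indicators of one dimension: an (n, m)
    array with every entry in [1, n]."""

    units: list[str]
    specs: list[IndicatorSpec]
    ranks: np.ndarray

    def __post_init__(self):
        self.units = list(self.units)
        self.specs = list(self.specs)
        self.ranks = np.asarray(self.ranks, dtype=float)
        n, m = len(self.units), len(self.specs)
        if self.ranks.shape != (n, m):
            raise ValueError(f"ranks shape {self.ranks.shape} != ({n}, {m})")
        if np.any(self.ranks < 1 - 1e-9) or np.any(self.ranks > n + 1e-9):
            raise ValueError(f"ranks outside [1, {n}]")
        dims = {s.dimension for s in self.specs}
        if len(dims) > 1:
            raise ValueError(f"rank matrix mixes dimensions {sorted(dims)}")

    @property
    def dimension(self) -> str:
        return self.specs[0].dimension


def noninteger_rank(values, orientation: str) -> np.ndarray:
    """Linearly interpolated ranks in [1, n] for one indicator column.

    A constant column carries no ordering information; every unit then
    receives the midpoint rank (1 + n)/2 (the only orientation-symmetric
    choice) and a warning is emitted.
    """
    if orientation not in ("high_quality", "low_quality"):
        raise ValueError(f"unknown orientation {orientation!r}")
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be a 1-d vector")
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 values, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn(
            "constant indicator column: assigning midpoint rank (1+n)/2 to "
            "every unit", stacklevel=2,
        )
        return np.full(n, (1.0 + n) / 2.0)
    if orientation == "high_quality":
        return 1.0 + (n - 1.0) * (x - lo) / (hi - lo)
    return 1.0 + (n - 1.0) * (hi - x) / (hi - lo)


def compute_rsr(ranks: RankMatrix) -> RSRTable:
    """Rank sum ratio per unit from a dimension's rank matrix.

    ``rank_of_rsr`` in the result is the descending tie-averaged rank of
    the scores (1 = best).
    """
    n, m = ranks.ranks.shape
    if m < 1:
        raise ValueError("dimension has no indicators")
    rsr = ranks.ranks.sum(axis=1) / (m * n)
    desc = n + 1 - rankdata(rsr, method="average")
    return RSRTable(units=ranks.units, dimension=ranks.dimension,
                    rsr=rsr, rank_of_rsr=desc, m=m)


def rank_indicators(table: IndicatorTable, dimension: str) -> RankMatrix:
    """Apply :func:`noninteger_rank` to every indicator of one dimension,
    each per its own orientation."""
    specs = table.dimension_specs(dimension)
    if not specs:
        raise ValueError(f"dimension {dimension!r} has no indicators")
    values = table.dimension_values(dimension)
    cols = [noninteger_rank(values[:, j], s.orientation)
            for j, s in enumerate(specs)]
    return RankMatrix(units=table.units, specs=specs, ranks=np.column_stack(cols))


def evaluate_dimensions(table: IndicatorTable) -> dict[str, RSRTable]:
    """Score every dimension of an indicator table: orientation-aware
    non-integer ranks, then equal-weight RSR per dimension."""
    present = {s.dimension for s in table.specs}
    missing = [d for d in DIMENSIONS if d not in present]
    if missing:
        raise ValueError(f"table has no indicators for dimensions {missing}")
    return {dim: compute_rsr(rank_indicators(table, dim)) for dim in DIMENSIONS}
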