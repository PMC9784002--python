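"""Indicator tables, RSR-level tables, and the packaged reference panel.

The central input is a units x indicators table of raw values.  Each
indicator belongs to one of three dimensions of a health-service system --
*needs*, *utilization* and *resources* (resource allocation) -- and has an
orientation: *high_quality* indicators are better when larger (e.g. hospital
delivery rate), *low_quality* indicators are better when smaller (e.g.
maternal mortality rate).

The module also ships, as packaged CSV/JSON data, the published per-province
results of the 2009/2019 maternal-services evaluation of China's 31
provinces (RSR scores and ranks, cumulative-frequency/probit distributions,
fitted values and grades, regression summaries).  Those fixtures make the
whole downstream pipeline runnable and testable without access to the raw
statistical-yearbook indicators, which were never published.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

DIMENSIONS = ("needs", "utilization", "resources")
ORIENTATIONS = ("high_quality", "low_quality")
FIXTURE_YEARS = (2009, 2019)

#: slack allowed below the theoretical RSR lower bound 1/n, to accommodate
#: values printed at 3 decimals (1/31 = 0.0322.. prints as 0.032)
_PRINT_TOL = 1e-3


@dataclass(frozen=True)
class IndicatorSpec:
    """One indicator: short id, display name, dimension and orientation."""

    id: str
    name: str
    dimension: str
    orientation: str

    def __post_init__(self):
        if self.dimension not in DIMENSIONS:
            raise ValueError(
                f"indicator {self.id!r}: unknown dimension {self.dimension!r}, "
                f"expected one of {DIMENSIONS}"
            )
        if self.orientation not in ORIENTATIONS:
            raise ValueError(
                f"indicator {self.id!r}: unknown orientation {self.orientation!r}, "
                f"expected one of {ORIENTATIONS}"
            )


@dataclass
class IndicatorTable:
    """Raw units x indicators matrix with per-indicator metadata.

    Parameters
    ----------
    units
        Unique unit identifiers (n >= 2).  Units that share a romanized
        display name (the two Chinese provinces both romanized "Shanxi")
        must carry distinct ids, e.g. ``Shanxi`` / ``Shaanxi``.
    specs
        One :class:`IndicatorSpec` per column.
    values
        ``(n, m)`` array of finite raw values, columns aligned with *specs*.
    """

    units: list[str]
    specs: list[IndicatorSpec]
    values: np.ndarray

    def __post_init__(self):
        self.units = list(self.units)
        self.specs = list(self.specs)
        self.values = np.asarray(self.values, dtype=float)
        n, m = len(self.units), len(self.specs)
        if n < 2:
            raise ValueError(f"need at least 2 units, got {n}")
        if len(set(self.units)) != n:
            dupes = sorted({u for u in self.units if self.units.count(u) > 1})
            raise ValueError(f"duplicate unit ids: {dupes}")
        if self.values.shape != (n, m):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n} units x {m} indicators"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value for unit {self.units[i]!r}, "
                f"indicator {self.specs[j].id!r}"
            )
        ids = [s.id for s in self.specs]
        if len(set(ids)) != m:
            raise ValueError("duplicate indicator ids in specs")

    @property
    def n_units(self) -> int:
        return len(self.units)

    def dimension_specs(self, dimension: str) -> list[IndicatorSpec]:
        return [s for s in self.specs if s.dimension == dimension]

    def dimension_values(self, dimension: str) -> np.ndarray:
        cols = [j for j, s in enumerate(self.specs) if s.dimension == dimension]
        return self.values[:, cols]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.units, name="unit"),
            columns=[s.id for s in self.specs],
        )


@dataclass
class RSRTable:
    """Per-unit rank-sum-ratio scores for one dimension.

    ``rank_of_rsr`` is the descending competition-style rank (1 = largest
    RSR), tie-averaged when computed fresh; the packaged fixtures carry the
    published ranks verbatim, including the documented tie quirks.
    """

    units: list[str]
    dimension: str
    rsr: np.ndarray
    rank_of_rsr: np.ndarray
    m: int

    def __post_init__(self):
        self.units = list(self.units)
        self.rsr = np.asarray(self.rsr, dtype=float)
        self.rank_of_rsr = np.asarray(self.rank_of_rsr, dtype=float)
        n = len(self.units)
        if self.rsr.shape != (n,) or self.rank_of_rsr.shape != (n,):
            raise ValueError("rsr and rank_of_rsr must be length-n vectors")
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {self.dimension!r}")
        lo, hi = 1.0 / n - _PRINT_TOL, 1.0 + _PRINT_TOL
        if np.any(self.rsr < lo) or np.any(self.rsr > hi):
            raise ValueError(f"RSR values outside [1/n, 1] for n={n}")
        if np.any(self.rank_of_rsr < 1) or np.any(self.rank_of_rsr > n):
            raise ValueError("ranks outside [1, n]")

    @property
    def n_units(self) -> int:
        return len(self.units)

    def ascending_rank(self) -> np.ndarray:
        """Ascending rank (1 = smallest RSR), derived from ``rank_of_rsr``."""
        return len(self.units) + 1 - self.rank_of_rsr

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rsr": self.rsr, "rank": self.rank_of_rsr},
            index=pd.Index(self.units, name="unit"),
        )


# ---------------------------------------------------------------------------
# reading and writing indicator tables

def read_indicator_specs(spec_path: str | Path) -> list[IndicatorSpec]:
    """Read indicator metadata from a CSV (id,name,dimension,orientation
    columns) or a JSON list of objects with those keys."""
    spec_path = Path(spec_path)
    if spec_path.suffix.lower() == ".json":
        records = json.loads(spec_path.read_text())
    else:
        records = pd.read_csv(spec_path, dtype=str).to_dict("records")
    specs = []
    for rec in records:
        try:
            specs.append(IndicatorSpec(
                id=str(rec["id"]), name=str(rec.get("name", rec["id"])),
                dimension=str(rec["dimension"]), orientation=str(rec["orientation"]),
            ))
        except KeyError as exc:
            raise ValueError(f"{spec_path}: spec record missing field {exc}") from None
    return specs


def read_indicator_table(path: str | Path, spec_path: str | Path) -> IndicatorTable:
    """Read a raw indicator CSV (first column = unit id, one column per
    indicator id) together with its spec file.

    Missing cells, unknown indicator columns and duplicate unit ids are
    rejected with the offending row/column named.
    """
    path = Path(path)
    specs = read_indicator_specs(spec_path)
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    known = {s.id for s in specs}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValueError(f"{path}: unknown indicator columns {unknown}")
    missing_ids = [s.id for s in specs if s.id not in df.columns]
    if missing_ids:
        raise ValueError(f"{path}: missing indicator columns {missing_ids}")
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"{path}: duplicate unit ids {dupes}")
    df = df[[s.id for s in specs]]
    if df.isna().any().any():
        unit = df.index[df.isna().any(axis=1)][0]
        col = df.columns[df.isna().any(axis=0)][0]
        raise ValueError(f"{path}: missing value at unit {unit!r}, indicator {col!r}")
    return IndicatorTable(units=list(df.index), specs=specs, values=df.to_numpy())


def write_indicator_table(table: IndicatorTable, path: str | Path,
                          spec_path: str | Path | None = None) -> None:
    """Write the raw values as CSV (shortest round-tripping float repr)
    and, optionally, the indicator specs as CSV or JSON next to them."""
    table.to_frame().to_csv(path)
    if spec_path is not None:
        spec_path = Path(spec_path)
        records = [vars(s) for s in table.specs]
        if spec_path.suffix.lower() == ".json":
            spec_path.write_text(json.dumps(records, indent=1))
        else:
            pd.DataFrame(records).to_csv(spec_path, index=False)


def default_panel() -> list[IndicatorSpec]:
    """The 12-indicator maternal-services panel: 3 needs, 5 utilization,
    4 resource-allocation indicators; maternal mortality rate is the single
    low-quality indicator."""
    mk = IndicatorSpec
    return [
        mk("X1", "maternal mortality rate (1/100,000)", "needs", "low_quality"),
        mk("X2", "obstetric hemorrhage share of maternal deaths (%)", "needs", "high_quality"),
        mk("X3", "pregnancy-induced hypertension share of maternal deaths (%)", "needs", "high_quality"),
        mk("X4", "maternal registration rate (%)", "utilization", "high_quality"),
        mk("X5", "maternal system management rate (%)", "utilization", "high_quality"),
        mk("X6", "prenatal checkup rate (%)", "utilization", "high_quality"),
        mk("X7", "postpartum visit rate (%)", "utilization", "high_quality"),
        mk("X8", "hospital delivery rate (%)", "utilization", "high_quality"),
        mk("X9", "medical institutions (1/100,000)", "resources", "high_quality"),
        mk("X10", "practicing (assistant) physicians (1/1,000)", "resources", "high_quality"),
        mk("X11", "registered nurses (1/1,000)", "resources", "high_quality"),
        mk("X12", "obstetrics and gynecology beds (1/100,000)", "resources", "high_quality"),
    ]


# ---------------------------------------------------------------------------
# packaged fixtures (published 2009/2019 per-province results)

def _data_path(name: str):
    return resources.files("rsreval.data").joinpath(name)


def _fixture_frame(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as p:
        return pd.read_csv(p)


def paper_regions() -> list[str]:
    """The 31 province-level units, in publication (yearbook) order."""
    df = _fixture_frame("paper_rsr.csv")
    sub = df[(df["year"] == 2009) & (df["dimension"] == "needs")]
    return list(sub["region"])


def load_paper_fixture(year: int, table: str):
    """Load a published per-province table.

    Parameters
    ----------
    year
        2009 or 2019.
    table
        ``"rsr"`` -> dict mapping dimension to :class:`RSRTable` (scores and
        ranks as printed); ``"probit"`` -> dict mapping dimension to
        :class:`~rsreval.grading.ProbitDistribution` (downward cumulative
        frequency P and probit as printed).
    """
    if year not in FIXTURE_YEARS:
        raise ValueError(f"no fixture for year {year}; have {FIXTURE_YEARS}")
    if table not in ("rsr", "probit"):
        raise ValueError(f"unknown fixture table {table!r}; use 'rsr' or 'probit'")
    regions = paper_regions()
    out = {}
    if table == "rsr":
        df = _fixture_frame("paper_rsr.csv")
        m_by_dim = {"needs": 3, "utilization": 5, "resources": 4}
        for dim in DIMENSIONS:
            sub = (df[(df["year"] == year) & (df["dimension"] == dim)]
                   .set_index("region").loc[regions])
            out[dim] = RSRTable(
                units=regions, dimension=dim,
                rsr=sub["rsr"].to_numpy(), rank_of_rsr=sub["rank"].to_numpy(),
                m=m_by_dim[dim],
            )
        return out
    from .grading import ProbitDistribution  # avoid import cycle at module load

    df = _fixture_frame("paper_probit.csv")
    rsr_tables = load_paper_fixture(year, "rsr")
    n = len(regions)
    for dim in DIMENSIONS:
        sub = (df[(df["year"] == year) & (df["dimension"] == dim)]
               .set_index("region").loc[regions])
        p = sub["p"].to_numpy()
        out[dim] = ProbitDistribution(
            units=regions, rsr=rsr_tables[dim].rsr,
            avg_rank=np.round(p * n / 100).astype(float),
            p_percent=p, probit=sub["probit"].to_numpy(),
        )
    return out


def load_paper_grading(year: int) -> pd.DataFrame:
    """Published fitted RSR values and Low/Medium/High grades, as a frame
    with columns region, dimension, fitted_rsr, grade."""
    if year not in FIXTURE_YEARS:
        raise ValueError(f"no fixture for year {year}; have {FIXTURE_YEARS}")
    df = _fixture_frame("paper_grading.csv")
    return df[df["year"] == year].drop(columns="year").reset_index(drop=True)


def paper_summary() -> dict:
    """Published regression coefficients, grade cut-offs, ANOVA F values,
    category counts, and the list of tie cells whose published cumulative
    frequencies conflict with the published ranks."""
    return json.loads(_data_path("paper_summary.json").read_text())
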