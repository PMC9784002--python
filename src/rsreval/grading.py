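"""Probit distribution fitting and three-level grading of RSR scores.

The RSR vector of a dimension is assumed approximately normal.  Each unit's
*downward cumulative frequency* is

    P = (ascending average rank) / n * 100%,

with the top value's P = 100% replaced by 100 (1 - 1/(4n)) so that its
normal quantile is finite (for n = 31 the corrected maximum prints as
99.2%).  P is converted to the classical probit

    probit = Phi^-1(P / 100) + 5,

so P = 50% maps to probit 5.  An ordinary least-squares line

    RSR_hat = a + b probit

is then fitted and the standard three-level grading applies the probit
cut-offs 4 and 6 (one probit unit below/above the centre): Low if
probit <= 4, High if probit >= 6, Medium otherwise.  Substituting the
cut-offs into the line yields critical RSR values usable directly on the
RSR scale.  The grading is validated with one-way ANOVA of the fitted
values across grades, a homogeneity-of-variance test, and Student-Newman-
Keuls (SNK-q) pairwise comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import ndtri

__all__ = [
    "ProbitDistribution", "LineFit", "GradingScheme", "GradeValidation",
    "rank_probit", "fit_line", "grade", "validate_grades",
    "DEFAULT_CUTS", "GRADE_LABELS",
]

DEFAULT_CUTS = (4.0, 6.0)
GRADE_LABELS = ("Low", "Medium", "High")
PROBIT_OFFSET = 5.0


@dataclass
class ProbitDistribution:
    """Downward cumulative frequencies and probits of one RSR vector."""

    units: list[str]
    rsr: np.ndarray
    avg_rank: np.ndarray          # ascending, tie-averaged
    p_percent: np.ndarray         # in (0, 100)
    probit: np.ndarray

    def __post_init__(self):
        self.units = list(self.units)
        for name in ("rsr", "avg_rank", "p_percent", "probit"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.units)
        for name in ("rsr", "avg_rank", "p_percent", "probit"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must be a length-{n} vector")
        if np.any(self.p_percent <= 0) or np.any(self.p_percent >= 100):
            raise ValueError("P must lie strictly inside (0, 100) percent")

    @property
    def n_units(self) -> int:
        return len(self.units)


def rank_probit(rsr, units=None, tie_break=None) -> ProbitDistribution:
    """Convert an RSR vector to downward cumulative frequencies and probits.

    Parameters
    ----------
    rsr
        Length-n score vector, n >= 2.
    units
        Optional unit identifiers (defaults to stringified indices).
    tie_break
        Optional length-n vector used only to order exact ties in *rsr*
        (larger tie_break = larger underlying value).  Supply it when an
        external source (e.g. published ranks computed from unrounded
        scores) fixes the order of values that tie at printed precision;
        the result then has strict integer ranks.  Without it, ties receive
        average ranks and hence equal P and probit.
    """
    x = np.asarray(rsr, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("rsr must be a 1-d vector with n >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("rsr must be finite")
    n = x.size
    if units is None:
        units = [str(i) for i in range(n)]
    if tie_break is None:
        avg_rank = stats.rankdata(x, method="average")
    else:
        tb = np.asarray(tie_break, dtype=float)
        if tb.shape != (n,):
            raise ValueError("tie_break must match rsr in length")
        order = np.lexsort((tb, x))          # sort by rsr, then tie_break
        avg_rank = np.empty(n)
        avg_rank[order] = np.arange(1, n + 1)
    p = avg_rank / n * 100.0
    p = np.where(p >= 100.0, 100.0 * (1.0 - 1.0 / (4.0 * n)), p)
    probit = ndtri(p / 100.0) + PROBIT_OFFSET
    return ProbitDistribution(units=list(units), rsr=x, avg_rank=avg_rank,
                              p_percent=p, probit=probit)


@dataclass(frozen=True)
class LineFit:
    """OLS fit of RSR on probit: RSR_hat = a + b probit.

    ``pearson_r`` is the plain correlation of the two vectors; ``adj_r2``
    is the adjusted coefficient of determination, the goodness-of-fit
    number conventionally reported alongside these grading equations.
    """

    a: float
    b: float
    pearson_r: float
    adj_r2: float
    p_value: float


def fit_line(dist: ProbitDistribution) -> LineFit:
    """Least-squares line of RSR on probit, with correlation and the
    regression F-test p-value (equivalent to the slope t-test here)."""
    if np.ptp(dist.probit) == 0:
        raise ValueError("probit vector is constant; cannot fit a line")
    res = stats.linregress(dist.probit, dist.rsr)
    n = dist.n_units
    adj = 1.0 - (1.0 - res.rvalue**2) * (n - 1) / (n - 2)
    return LineFit(a=float(res.intercept), b=float(res.slope),
                   pearson_r=float(res.rvalue), adj_r2=float(adj),
                   p_value=float(res.pvalue))


@dataclass
class GradingScheme:
    """A fitted grading: line coefficients, critical RSR values at the
    probit cut-offs, per-unit fitted RSR and Low/Medium/High grade."""

    units: list[str]
    a: float
    b: float
    pearson_r: float
    adj_r2: float
    probit_cuts: tuple[float, ...]
    critical_rsr: tuple[float, ...]
    probit: np.ndarray
    fitted_rsr: np.ndarray
    grade: list[str]
    rsr: np.ndarray = field(default=None)

    def group_sizes(self) -> dict[str, int]:
        return {g: self.grade.count(g) for g in GRADE_LABELS}


def grade(dist: ProbitDistribution, fit: LineFit,
          cuts: tuple[float, float] = DEFAULT_CUTS) -> GradingScheme:
    """Assign three-level grades at the given probit cut-offs.

    Low iff probit <= cuts[0]; High iff probit >= cuts[1]; else Medium.
    Critical RSR values are the fitted line evaluated at the cut-offs,
    always from full-precision coefficients (rounded published coefficients
    can shift the third decimal).
    """
    cuts = tuple(float(c) for c in cuts)
    if len(cuts) != 2 or not cuts[0] < cuts[1]:
        raise ValueError(f"cuts must be strictly increasing, got {cuts}")
    lo, hi = cuts
    fitted = fit.a + fit.b * dist.probit
    labels = np.where(dist.probit <= lo, "Low",
                      np.where(dist.probit >= hi, "High", "Medium"))
    return GradingScheme(
        units=dist.units, a=fit.a, b=fit.b, pearson_r=fit.pearson_r,
        adj_r2=fit.adj_r2, probit_cuts=cuts,
        critical_rsr=tuple(fit.a + fit.b * c for c in cuts),
        probit=dist.probit, fitted_rsr=fitted, grade=list(labels),
        rsr=dist.rsr,
    )


@dataclass
class GradeValidation:
    """ANOVA + homogeneity + SNK-q summary of a grading."""

    anova_F: float
    anova_p: float
    levene_stat: float
    levene_p: float
    snk_pairs: dict  # (grade_i, grade_j) -> {"q": .., "q_crit": .., "significant": ..}
    group_sizes: dict

    def all_pairs_significant(self) -> bool:
        return bool(self.snk_pairs) and all(
            r["significant"] for r in self.snk_pairs.values())


def _snk_pairs(means, sizes, labels, ms_within, df_within, alpha):
    """Stepwise Student-Newman-Keuls comparisons on sorted group means.

    q = (m_j - m_i) / sqrt(MSw/2 (1/n_i + 1/n_j)); the critical value uses
    the studentized range at the span (number of ordered means covered).
    A pair inside a non-significant span is declared non-significant
    without testing (the stepwise protection rule).
    """
    order = np.argsort(means)
    means, sizes = np.asarray(means)[order], np.asarray(sizes)[order]
    labels = [labels[i] for i in order]
    k = len(means)
    results = {}
    blocked: list[tuple[int, int]] = []
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            key = (labels[i], labels[j])
            if any(i >= a and j <= b for a, b in blocked):
                results[key] = {"q": np.nan, "q_crit": np.nan, "significant": False}
                continue
            se = np.sqrt(ms_within / 2.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            q = (means[j] - means[i]) / se
            q_crit = stats.studentized_range.ppf(1 - alpha, span, df_within)
            sig = bool(q > q_crit)
            results[key] = {"q": float(q), "q_crit": float(q_crit),
                            "significant": sig}
            if not sig:
                blocked.append((i, j))
    return results


def validate_grades(scheme: GradingScheme, alpha: float = 0.05) -> GradeValidation:
    """One-way ANOVA of fitted RSR across grade groups, Levene homogeneity
    test, and SNK-q pairwise comparisons at the given alpha.

    Groups with fewer than 2 members still enter the ANOVA but are dropped
    from the SNK step (with a warning), since a within-group variance
    contribution requires at least two observations.
    """
    fitted = np.asarray(scheme.fitted_rsr, dtype=float)
    grades = np.asarray(scheme.grade)
    groups = {g: fitted[grades == g] for g in GRADE_LABELS if np.any(grades == g)}
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty grade groups")
    arrays = list(groups.values())
    if np.ptp(fitted) == 0:
        # no variance at all: no between-group signal
        anova_F, anova_p = 0.0, 1.0
    else:
        anova = stats.f_oneway(*arrays)
        anova_F, anova_p = float(anova.statistic), float(anova.pvalue)
    big = [a for a in arrays if a.size >= 2]
    if len(big) >= 2:
        levene = stats.levene(*big)
        levene_stat, levene_p = float(levene.statistic), float(levene.pvalue)
    else:
        levene_stat, levene_p = np.nan, np.nan
    snk_groups = {g: a for g, a in groups.items() if a.size >= 2}
    if len(snk_groups) < len(groups):
        warnings.warn(
            "grade group(s) with < 2 members excluded from SNK-q "
            f"comparisons: {sorted(set(groups) - set(snk_groups))}",
            stacklevel=2,
        )
    snk = {}
    if len(snk_groups) >= 2:
        arrs = list(snk_groups.values())
        df_within = sum(a.size for a in arrs) - len(arrs)
        ms_within = sum(((a - a.mean()) ** 2).sum() for a in arrs) / df_within
        if ms_within == 0:
            # constant within every group: any mean difference is trivially real
            names = list(snk_groups.keys())
            snk = {
                (names[i], names[j]): {
                    "q": np.inf, "q_crit": np.nan,
                    "significant": bool(arrs[i][0] != arrs[j][0]),
                }
                for i in range(len(arrs)) for j in range(i + 1, len(arrs))
            }
        else:
            snk = _snk_pairs(
                [a.mean() for a in arrs], [a.size for a in arrs],
                list(snk_groups.keys()), ms_within, df_within, alpha,
            )
    return GradeValidation(
        anova_F=anova_F, anova_p=anova_p,
        levene_stat=levene_stat, levene_p=levene_p, snk_pairs=snk,
        group_sizes={g: int(a.size) for g, a in groups.items()},
    )
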