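"""Rank statistics for comparing centrality across age levels.

Pen sizes are small and centrality distributions are skewed and
zero-inflated, so all comparisons are rank-based: a Kruskal-Wallis test
across the three age levels per measure (with compact significance
letters from pairwise two-group rank tests), Spearman correlations among
the measures within a level, and Spearman correlations of each measure
between consecutive age levels for animals tracked through both.

The H statistic uses mid-ranks with the standard tie correction

    H = [12 / (N (N+1)) * sum n_i Rbar_i^2 - 3 (N+1)] / (1 - sum(t^3 - t) / (N^3 - N))

and a chi-square upper tail with k-1 degrees of freedom.  Spearman's rho
is the Pearson correlation of mid-ranks, with the t approximation on n-2
degrees of freedom for its p-value.  Degenerate inputs (all values
identical, zero rank variance, fewer than 3 paired observations) yield
flagged results rather than exceptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .centrality import MEASURE_COLUMNS
from .events import AGE_ORDER, AnimalTrajectory

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass
class KWResult:
    """Kruskal-Wallis comparison of one measure across groups."""

    measure: str
    H: float
    df: int
    p_value: float
    #: group label -> (n, median, min, max)
    summaries: Mapping[str, tuple[int, float, float, float]] = field(default_factory=dict)
    #: group label -> significance letter string (shared letter = not distinguishable)
    letters: Mapping[str, str] = field(default_factory=dict)

    @property
    def p_formatted(self) -> str:
        return format_p(self.p_value)


@dataclass
class CorrelationResult:
    """Spearman rank correlation between two variables."""

    var_x: str
    var_y: str
    rho: float
    p_value: float
    n: int
    context: str = ""
    flagged: bool = False
    note: str = ""

    @property
    def significant(self) -> bool:
        return (not self.flagged) and self.p_value < 0.05


def format_p(p: float) -> str:
    """Report p-values with a printed floor of 0.0001."""
    if np.isnan(p):
        return "NA"
    if p < 0.0001:
        return "<0.0001"
    return f"{p:.4f}"


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    measure: str = "",
) -> KWResult:
    """Tie-corrected Kruskal-Wallis H test across two or more groups.

    All-identical data give H = 0, p = 1 (no evidence of any difference).
    An empty group is an error.
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, arr in enumerate(arrays):
        if arr.size == 0:
            raise ValueError(f"group {i} has zero observations")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = np.array([a.size for a in arrays])
    ends = np.cumsum(sizes)
    starts = ends - sizes
    rank_means = np.array([ranks[s:e].mean() for s, e in zip(starts, ends)])
    h_raw = 12.0 / (N * (N + 1)) * float(np.sum(sizes * rank_means**2)) - 3.0 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_correction = 1.0 - float(np.sum(counts**3 - counts)) / (N**3 - N)
    df = len(arrays) - 1
    if tie_correction == 0.0:  # every observation identical
        h = 0.0
        p = 1.0
    else:
        h = max(h_raw / tie_correction, 0.0)
        p = float(sps.chi2.sf(h, df))
    summaries = {
        lab: (int(a.size), float(np.median(a)), float(a.min()), float(a.max()))
        for lab, a in zip(labels, arrays)
    }
    return KWResult(measure=measure, H=h, df=df, p_value=p, summaries=summaries)


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    var_x: str = "x",
    var_y: str = "y",
    context: str = "",
) -> CorrelationResult:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Zero variance in either rank vector makes rho undefined (flagged);
    fewer than 3 paired observations make the p-value undefined (flagged).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-d sequences of equal length")
    n = xa.size
    if n < 2:
        return CorrelationResult(var_x, var_y, np.nan, np.nan, n, context, True, "n < 2")
    rx = sps.rankdata(xa)
    ry = sps.rankdata(ya)
    sx = rx.std()
    sy = ry.std()
    if sx == 0.0 or sy == 0.0:
        return CorrelationResult(
            var_x, var_y, np.nan, np.nan, n, context, True, "zero rank variance"
        )
    rho = float(np.clip(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy), -1.0, 1.0))
    if n < 3:
        return CorrelationResult(var_x, var_y, rho, np.nan, n, context, True, "n < 3")
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    if n == 3:  # p-value exists but carries almost no information
        return CorrelationResult(var_x, var_y, rho, p, n, context, True, "low n")
    return CorrelationResult(var_x, var_y, rho, p, n, context)


def assign_letters(
    groups: Sequence[Sequence[float]],
    pairwise_alpha: float = 0.05,
    labels: Sequence[str] | None = None,
    global_result: KWResult | None = None,
    bonferroni: bool = False,
) -> dict[str, str]:
    """Compact letter display from pairwise two-group rank tests.

    Two groups share a letter iff their pairwise Kruskal-Wallis test
    (equivalent to a rank-sum test) is non-significant at
    ``pairwise_alpha``; intransitive patterns yield multi-letter labels
    such as ``"ab"``.  If the global test is non-significant every group
    gets ``"a"``.  ``bonferroni`` divides the pairwise alpha by the number
    of pairs.
    """
    k = len(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    if global_result is None:
        global_result = kruskal_wallis(groups, labels=labels)
    if global_result.p_value >= pairwise_alpha or k == 1:
        return {lab: "a" for lab in labels}
    alpha = pairwise_alpha / len(list(combinations(range(k), 2))) if bonferroni else pairwise_alpha
    similar = [[True] * k for _ in range(k)]
    for i, j in combinations(range(k), 2):
        p = kruskal_wallis([groups[i], groups[j]]).p_value
        similar[i][j] = similar[j][i] = p >= alpha
    # maximal cliques of the "not distinguishable" graph (k is tiny)
    cliques: list[tuple[int, ...]] = []
    for size in range(k, 0, -1):
        for combo in combinations(range(k), size):
            if any(set(combo) <= set(c) for c in cliques):
                continue
            if all(similar[i][j] for i, j in combinations(combo, 2)):
                cliques.append(combo)
    cliques.sort(key=lambda c: (min(c), -len(c)))
    letter_of = {clique: _LETTERS[idx] for idx, clique in enumerate(cliques)}
    out = {}
    for i, lab in enumerate(labels):
        out[lab] = "".join(sorted(letter_of[c] for c in cliques if i in c))
    return out


def level_comparison_table(
    records: pd.DataFrame,
    measures: Sequence[str] = tuple(MEASURE_COLUMNS),
    alpha: float = 0.05,
    pen_median: bool = False,
    bonferroni: bool = False,
) -> tuple[pd.DataFrame, dict[str, KWResult]]:
    """Median (range) per age level with significance letters, per measure.

    ``pen_median`` switches the observational unit from individual animals
    (pooled across pens, the default) to pen medians, avoiding
    pseudo-replication at the cost of power.
    """
    levels = [lv.value for lv in AGE_ORDER if lv.value in set(records["age_level"])]
    results: dict[str, KWResult] = {}
    rows = []
    for measure in measures:
        groups = []
        for lv in levels:
            sub = records.loc[records["age_level"] == lv, measure]
            if pen_median:
                sub = sub.groupby(records.loc[records["age_level"] == lv, "pen_id"]).median()
            groups.append(sub.to_numpy())
        res = kruskal_wallis(groups, labels=levels, measure=measure)
        res.letters = assign_letters(
            groups, pairwise_alpha=alpha, labels=levels, global_result=res,
            bonferroni=bonferroni,
        )
        results[measure] = res
        for lv in levels:
            n, med, lo, hi = res.summaries[lv]
            rows.append(
                {
                    "measure": measure,
                    "age_level": lv,
                    "n": n,
                    "median": med,
                    "min": lo,
                    "max": hi,
                    "letter": res.letters[lv],
                    "H": res.H,
                    "df": res.df,
                    "p_value": res.p_value,
                    "p_formatted": res.p_formatted,
                }
            )
    return pd.DataFrame(rows), results


#: measure pairs reported within a level: binary-vs-weighted per measure,
#: then the documented pairs among the binary measures
_BASE_MEASURES = (
    "degree",
    "in_degree",
    "out_degree",
    "betweenness",
    "closeness",
    "in_closeness",
    "out_closeness",
)
_BINARY_PAIRS = (
    ("in_degree", "out_degree"),
    ("degree", "betweenness"),
    ("in_degree", "betweenness"),
    ("out_degree", "betweenness"),
    ("degree", "closeness"),
    ("degree", "in_closeness"),
    ("degree", "out_closeness"),
    ("in_degree", "in_closeness"),
    ("out_degree", "out_closeness"),
)


def within_level_correlations(records: pd.DataFrame, level: str) -> list[CorrelationResult]:
    """Spearman correlations among centrality measures within one age level.

    Animals from all pens of the level are pooled.  Reported pairs:
    unweighted vs weighted for each of the 7 measures, and the documented
    pairs among the unweighted measures (in vs out degree, degree family
    vs betweenness, degree family vs closeness family).
    """
    sub = records[records["age_level"] == level]
    out: list[CorrelationResult] = []
    for m in _BASE_MEASURES:
        out.append(
            spearman(
                sub[f"{m}_binary"], sub[f"{m}_weighted"],
                f"{m}_binary", f"{m}_weighted", context=level,
            )
        )
    for a, b in _BINARY_PAIRS:
        out.append(
            spearman(
                sub[f"{a}_binary"], sub[f"{b}_binary"],
                f"{a}_binary", f"{b}_binary", context=level,
            )
        )
    return out


def cross_level_correlations(
    records: pd.DataFrame,
    trajectories: Iterable[AnimalTrajectory],
    measures: Sequence[str] = tuple(MEASURE_COLUMNS),
) -> list[CorrelationResult]:
    """Spearman correlation of each measure between consecutive age levels.

    Only animals with pen placements at both levels of a consecutive pair
    (weaned-growing, growing-gilt) enter; pairing is by animal identity.
    Non-consecutive pairings are deliberately not produced.
    """
    by_level = {
        lv.value: records[records["age_level"] == lv.value].set_index("animal_id")
        for lv in AGE_ORDER
    }
    out: list[CorrelationResult] = []
    for first, second in zip(AGE_ORDER, AGE_ORDER[1:]):
        shared = sorted(
            t.animal_id
            for t in trajectories
            if t.pen_at(first) is not None
            and t.pen_at(second) is not None
            and t.animal_id in by_level[first.value].index
            and t.animal_id in by_level[second.value].index
        )
        context = f"{first.value}-{second.value}"
        for measure in measures:
            x = by_level[first.value].loc[shared, measure]
            y = by_level[second.value].loc[shared, measure]
            out.append(spearman(x, y, measure, measure, context=context))
    return out


def correlations_to_frame(results: Iterable[CorrelationResult]) -> pd.DataFrame:
    """Long-format correlation table (context, var_x, var_y, rho, p, n, flags)."""
    return pd.DataFrame(
        [
            {
                "context": r.context,
                "var_x": r.var_x,
                "var_y": r.var_y,
                "rho": r.rho,
                "p_value": r.p_value,
                "p_formatted": format_p(r.p_value) if not np.isnan(r.p_value) else "NA",
                "n": r.n,
                "flagged": r.flagged,
                "note": r.note,
            }
            for r in results
        ]
    )
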