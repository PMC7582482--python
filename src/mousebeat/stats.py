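"""Statistical layer: normality-gated two-group tests and frequency tests.

Group comparisons follow the classic gate: Shapiro-Wilk on both groups,
a two-sample t test when both pass, otherwise a Mann-Whitney U test.
At the tiny group sizes typical of telemetry cohorts (n = 4 per
genotype) the Mann-Whitney p is computed by exact enumeration of all
rank assignments in rational arithmetic; the tie-corrected normal
approximation is reported alongside, labelled, because commercial
packages often print only the asymptotic value. Event-type frequencies
use the Pearson chi-square test. All descriptive output is mean +/- SE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "FrequencyTest",
    "shapiro_wilk",
    "mann_whitney_exact",
    "mann_whitney_asymptotic",
    "two_group_compare",
    "chi_square_frequencies",
    "mean_se",
    "render_group_table",
]


def shapiro_wilk(x: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p. Valid for 3 <= n <= 50; constant input flags."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 50:
        raise ValueError(f"Shapiro-Wilk gate defined for 3 <= n <= 50, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _u_statistic(ranks_x: np.ndarray, n1: int, n2: int) -> float:
    return float(ranks_x.sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_exact(x: np.ndarray, y: np.ndarray,
                       max_combinations: int = 500_000) -> tuple[float, Fraction]:
    """Exact two-sided Mann-Whitney by full enumeration of rank assignments.

    Midranks handle ties. The two-sided p is the exact probability, under
    random assignment of the pooled (mid)ranks, of a U statistic at least
    as far from its null mean n1*n2/2 as observed — returned as a
    :class:`fractions.Fraction` over C(n1+n2, n1). The returned U is
    min(U1, U2), the convention small-sample tables print.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    total = comb(n1 + n2, n1)
    if total > max_combinations:
        raise ValueError(f"{total} assignments exceed enumeration limit; "
                         "use the asymptotic test")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = _u_statistic(ranks[:n1], n1, n2)
    mu = n1 * n2 / 2.0
    obs_dev = abs(u1 - mu)
    hits = 0
    idx = range(n1 + n2)
    for cx in combinations(idx, n1):
        u = _u_statistic(ranks[list(cx)], n1, n2)
        if abs(u - mu) >= obs_dev - 1e-12:
            hits += 1
    return min(u1, n1 * n2 - u1), Fraction(hits, total)


def mann_whitney_asymptotic(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-corrected normal approximation with continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = _u_statistic(ranks[:n1], n1, n2)
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return min(u1, n1 * n2 - u1), 1.0
    z = (abs(u1 - mu) - 0.5) / np.sqrt(var)
    return min(u1, n1 * n2 - u1), float(2 * sps.norm.sf(max(z, 0.0)))


@dataclass
class GroupComparison:
    variable: str
    n: tuple[int, int]
    means: tuple[float, float]
    ses: tuple[float, float]
    test_used: str  # "t" or "mann_whitney"
    statistic: float
    p_value: float
    normality: dict = field(default_factory=dict)  # per-group (W, p)
    extras: dict = field(default_factory=dict)  # labelled alternative p values


def mean_se(x: np.ndarray) -> tuple[float, float]:
    """Mean and standard error (sd/sqrt(n)); SE is NaN for n < 2."""
    x = np.asarray(x, dtype=float)
    m = float(np.mean(x)) if x.size else np.nan
    se = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan
    return m, se


def two_group_compare(
    x: np.ndarray,
    y: np.ndarray,
    variable: str = "",
    alpha: float = 0.05,
    t_variant: str = "pooled",
    exact_max_n: int = 8,
) -> GroupComparison:
    """Normality-gated two-group comparison with mean +/- SE reporting.

    Both groups passing Shapiro-Wilk at ``alpha`` selects the two-sample
    t test (pooled-variance default, Welch via ``t_variant="welch"``);
    otherwise the Mann-Whitney U — exact enumeration when
    ``min(n1, n2) <= exact_max_n``, tie-corrected normal approximation
    above that. The non-selected Mann-Whitney variant is always attached
    under ``extras`` for audit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    normality: dict = {}
    gate_normal = False
    if min(x.size, y.size) >= 3:
        try:
            wx = shapiro_wilk(x)
            wy = shapiro_wilk(y)
            normality = {"x": wx, "y": wy}
            gate_normal = wx[1] > alpha and wy[1] > alpha
        except ValueError as exc:
            normality = {"warning": str(exc)}

    mx, sx = mean_se(x)
    my, sy = mean_se(y)
    extras: dict = {}
    if gate_normal:
        res = sps.ttest_ind(x, y, equal_var=(t_variant == "pooled"))
        used, stat, p = "t", float(res.statistic), float(res.pvalue)
    else:
        if min(x.size, y.size) <= exact_max_n:
            u, p_frac = mann_whitney_exact(x, y)
            used, stat, p = "mann_whitney", u, float(p_frac)
            extras["exact_p_fraction"] = p_frac
            extras["asymptotic_p"] = mann_whitney_asymptotic(x, y)[1]
        else:
            u, p = mann_whitney_asymptotic(x, y)
            used, stat = "mann_whitney", u
            extras["asymptotic_p"] = p
    return GroupComparison(variable, (x.size, y.size), (mx, my), (sx, sy),
                           used, stat, p, normality, extras)


@dataclass
class FrequencyTest:
    table: np.ndarray
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    low_expected_cells: int  # cells with expected count < 5, flagged


def chi_square_frequencies(table: np.ndarray) -> FrequencyTest:
    """Pearson chi-square on an r x k contingency table of counts.

    The statistic is sum((O-E)^2/E) with expectations from the margins;
    df = (r-1)(k-1). Cells with expected counts below 5 are counted and
    flagged, not dropped. Zero row/column margins are an error.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be 2-D")
    if np.any(obs < 0) or not np.allclose(obs, np.rint(obs)):
        raise ValueError("table must hold non-negative integer counts")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero margin in contingency table")
    expected = np.outer(rows, cols) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return FrequencyTest(obs, stat, df, p, expected, int((expected < 5).sum()))


def render_group_table(rows: list[GroupComparison],
                       group_names: tuple[str, str] = ("WT", "MFS")) -> pd.DataFrame:
    """Mean +/- SE table, one comparison per row; dashes for undefined SE."""
    def fmt(m: float, s: float) -> str:
        if not np.isfinite(m):
            return "-"
        return f"{m:.2f} ± {s:.2f}" if np.isfinite(s) else f"{m:.2f} ± -"
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            group_names[0]: [fmt(r.means[0], r.ses[0]) for r in rows],
            group_names[1]: [fmt(r.means[1], r.ses[1]) for r in rows],
            "test": [r.test_used for r in rows],
            "p": [r.p_value for r in rows],
        }
    )
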