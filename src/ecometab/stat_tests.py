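"""Inferential statistics for diversity comparisons.

Covers the parametric layer applied to per-sample diversity values:
Lilliefors normality (Kolmogorov-Smirnov with estimated mean/SD and a
Monte-Carlo null), one-way ANOVA, Tukey HSD with a compact letter
display, and Pearson correlation with the coefficient of determination
reported as a percentage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# Lilliefors
# ---------------------------------------------------------------------------

def _lilliefors_stat(x: np.ndarray) -> float:
    n = x.size
    xs = np.sort(x)
    m, s = xs.mean(), xs.std(ddof=1)
    if s == 0:
        raise ValueError("constant sample: Lilliefors statistic undefined")
    F = stats.norm.cdf((xs - m) / s)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - F)
    d_minus = np.max(F - (i - 1) / n)
    return float(max(d_plus, d_minus))


def lilliefors(
    sample: Sequence[float],
    method: str = "mc",
    n_mc: int = 10_000,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Lilliefors normality test: (D, p).

    ``method="mc"`` builds the null distribution of D by simulating
    ``n_mc`` standard-normal samples of the same size (add-one-corrected
    p, seeded).  ``method="approx"`` delegates to the statsmodels table
    approximation for speed.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError("Lilliefors test needs n >= 4")
    D = _lilliefors_stat(x)
    if method == "approx":
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

        _, p = sm_lilliefors(x, dist="norm", pvalmethod="table")
        return D, float(p)
    if method != "mc":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    n = x.size
    sims = rng.standard_normal((n_mc, n))
    sims.sort(axis=1)
    m = sims.mean(axis=1, keepdims=True)
    s = sims.std(axis=1, ddof=1, keepdims=True)
    F = stats.norm.cdf((sims - m) / s)
    i = np.arange(1, n + 1)
    d_null = np.maximum((i / n - F).max(axis=1), (F - (i - 1) / n).max(axis=1))
    p = (np.count_nonzero(d_null >= D) + 1) / (n_mc + 1)
    return D, float(p)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]


def anova_oneway(
    groups: Sequence[Sequence[float]] | dict[str, Sequence[float]]
) -> AnovaResult:
    """Classical one-way ANOVA between/within decomposition."""
    if isinstance(groups, dict):
        names = list(groups)
        arrays = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        names = [f"group{i+1}" for i in range(len(arrays))]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs >= 2 observations")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    df_b, df_w = k - 1, n_total - k
    if np.concatenate(arrays).std() == 0:
        return AnovaResult(
            F=0.0, df_between=df_b, df_within=df_w, p=1.0,
            group_means={nm: float(a.mean()) for nm, a in zip(names, arrays)},
        )
    F, p = stats.f_oneway(*arrays)
    return AnovaResult(
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p=float(p),
        group_means={nm: float(a.mean()) for nm, a in zip(names, arrays)},
    )


# ---------------------------------------------------------------------------
# Tukey HSD + compact letter display
# ---------------------------------------------------------------------------

@dataclass
class TukeyResult:
    table: pd.DataFrame              # pairwise mean diff, CI, adjusted p
    letters: dict[str, str]          # group -> letter string
    alpha: float


def _compact_letters(names: list[str], nonsig: set[frozenset]) -> dict[str, str]:
    """Letter display: groups sharing a letter are not significantly different.

    Letters are the maximal cliques of the non-significance graph
    (enumerated directly; the number of groups is small).
    """
    cliques: list[frozenset] = []
    for size in range(len(names), 0, -1):
        for combo in itertools.combinations(names, size):
            cs = frozenset(combo)
            if any(cs <= c for c in cliques):
                continue
            if all(frozenset(p) in nonsig for p in itertools.combinations(combo, 2)):
                cliques.append(cs)
    cliques.sort(key=lambda c: min(names.index(g) for g in c))
    letters = {nm: "" for nm in names}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in clique:
            letters[g] += letter
    return {nm: "".join(sorted(v)) for nm, v in letters.items()}


def tukey_hsd(
    groups: dict[str, Sequence[float]] | Sequence[Sequence[float]],
    alpha: float = 0.05,
) -> TukeyResult:
    """Tukey honestly-significant-difference pairwise comparisons.

    Studentized-range adjusted p-values and simultaneous confidence
    intervals per pair, plus the compact letter display used for
    box-plot annotation.
    """
    if not isinstance(groups, dict):
        groups = {f"group{i+1}": g for i, g in enumerate(groups)}
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(arrays) < 2:
        raise ValueError("Tukey HSD needs >= 2 groups")
    res = stats.tukey_hsd(*arrays)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    rows = []
    nonsig: set[frozenset] = set()
    for i, j in itertools.combinations(range(len(names)), 2):
        p = float(res.pvalue[i, j])
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                "ci_low": float(ci.low[i, j]),
                "ci_high": float(ci.high[i, j]),
                "p_adj": p,
            }
        )
        if p > alpha:
            nonsig.add(frozenset((names[i], names[j])))
    letters = _compact_letters(names, nonsig)
    return TukeyResult(table=pd.DataFrame(rows), letters=letters, alpha=alpha)


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    r: float
    R2: float          # percent
    p: float
    slope: float
    intercept: float
    n: int


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with R^2 (%) and the least-squares line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    lr = stats.linregress(x, y)
    return CorrelationResult(
        r=float(r),
        R2=float(100.0 * r**2),
        p=float(p),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        n=int(x.size),
    )
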