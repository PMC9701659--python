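"""Alpha diversity, richness estimation and accumulation curves.

The feature table is read as a community: features are species, samples
(or pooled treatment x time cells) are sampling units.  This module
computes the classical alpha-diversity indices (Shannon H' in nats,
inverse Simpson, Pielou evenness), sample-based species accumulation
curves by random permutation of unit order, the analytic rarefaction
expectation (Mao's tau), the incidence-based Chao and first/second-order
jackknife asymptotic richness estimators, and percentile-bootstrap
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .feature_io import FeatureMatrix, IncidenceMatrix


# ---------------------------------------------------------------------------
# Indices
# ---------------------------------------------------------------------------

def _proportions(p: Sequence[float]) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = p[p > 0]
    return p / total


def shannon(p: Sequence[float]) -> float:
    """Shannon-Wiener H' in nats; zeros are skipped, input is normalized."""
    q = _proportions(p)
    return float(-(q * np.log(q)).sum())


def inverse_simpson(p: Sequence[float]) -> float:
    """Inverse Simpson concentration 1 / sum p_i^2 (effective species)."""
    q = _proportions(p)
    return float(1.0 / (q**2).sum())


def pielou(p: Sequence[float]) -> float:
    """Pielou evenness J' = H' / ln S over species with positive abundance."""
    q = _proportions(p)
    S = q.size
    if S < 2:
        raise ValueError("Pielou evenness undefined for a single species")
    return float(shannon(q) / np.log(S))


@dataclass
class DiversityIndices:
    S: int
    H: float
    DSi: float
    J: float | None
    ci: dict[str, tuple[float, float]] | None = None


def indices(p: Sequence[float]) -> DiversityIndices:
    """All alpha indices of one abundance vector."""
    q = _proportions(p)
    S = int(q.size)
    return DiversityIndices(
        S=S,
        H=shannon(q),
        DSi=inverse_simpson(q),
        J=pielou(q) if S > 1 else None,
    )


def sample_indices(fm: FeatureMatrix) -> pd.DataFrame:
    """Per-sample richness/H'/DSi/J' table, merged with sample metadata."""
    rows = []
    for sid in fm.abundance.index:
        ix = indices(fm.abundance.loc[sid].values)
        rows.append({"sample_id": sid, "S": ix.S, "H": ix.H, "DSi": ix.DSi, "J": ix.J})
    out = pd.DataFrame(rows).set_index("sample_id")
    return out.join(fm.meta)


# ---------------------------------------------------------------------------
# Richness estimators (incidence-based)
# ---------------------------------------------------------------------------

def richness_estimators(im: IncidenceMatrix) -> dict[str, float]:
    """Chao (incidence form), jackknife-1 and jackknife-2 estimators.

    Driven by Q1/Q2, the number of species seen in exactly one / two
    units.  The Chao estimator uses the bias-corrected form when Q2 = 0.
    All three are bounded below by the observed richness S.
    """
    n = im.n_units
    if n < 2:
        raise ValueError("richness estimators need >= 2 units")
    counts = im.incidence_counts.values
    S = int((counts > 0).sum())
    Q1 = int((counts == 1).sum())
    Q2 = int((counts == 2).sum())
    if Q2 > 0:
        chao = S + ((n - 1) / n) * Q1**2 / (2 * Q2)
    else:
        chao = S + ((n - 1) / n) * Q1 * (Q1 - 1) / 2
    jack1 = S + Q1 * (n - 1) / n
    jack2 = S + Q1 * (2 * n - 3) / n - Q2 * (n - 2) ** 2 / (n * (n - 1))
    return {"S": S, "Q1": Q1, "Q2": Q2, "chao": chao, "jack1": jack1, "jack2": jack2}


def chao1_abundance(counts: Sequence[float]) -> float:
    """Abundance-based Chao1 from singleton/doubleton counts."""
    x = np.asarray(counts)
    S = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f2 > 0:
        return S + f1**2 / (2 * f2)
    return S + f1 * (f1 - 1) / 2


# ---------------------------------------------------------------------------
# Accumulation / rarefaction
# ---------------------------------------------------------------------------

@dataclass
class SACResult:
    k: np.ndarray
    mean_richness: np.ndarray
    sd: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    Q1: int
    Q2: int
    estimators: dict[str, float]
    n_perm: int
    seed: int | None


def species_accumulation(
    im: IncidenceMatrix, n_perm: int = 100, seed: int | None = 0
) -> SACResult:
    """Sample-based species accumulation curve, "random" method.

    For each permutation of unit order the cumulative number of distinct
    species after 1..n units is recorded; the curve reports mean and SD
    over ``n_perm`` permutations with a normal-approximation 95% CI.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    presence = im.presence.values.astype(bool)
    n, S_cols = presence.shape
    if n == 0 or S_cols == 0:
        raise ValueError("empty incidence matrix")
    rng = np.random.default_rng(seed)
    curves = np.empty((n_perm, n), dtype=np.int64)
    for b in range(n_perm):
        order = rng.permutation(n)
        cum = np.maximum.accumulate(presence[order], axis=0)
        curves[b] = cum.sum(axis=1)
    mean = curves.mean(axis=0)
    sd = curves.std(axis=0, ddof=1) if n_perm > 1 else np.zeros(n)
    return SACResult(
        k=np.arange(1, n + 1),
        mean_richness=mean,
        sd=sd,
        ci_low=mean - 1.96 * sd,
        ci_high=mean + 1.96 * sd,
        Q1=int((im.incidence_counts.values == 1).sum()),
        Q2=int((im.incidence_counts.values == 2).sum()),
        estimators=richness_estimators(im) if n >= 2 else {},
        n_perm=n_perm,
        seed=seed,
    )


def sac_table(res: SACResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "k": res.k,
            "mean_richness": res.mean_richness,
            "sd": res.sd,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
        }
    )


def _log_choose(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(
        np.asarray(n) - np.asarray(k) + 1
    )


def rarefaction(im: IncidenceMatrix, k: int) -> float:
    """Analytic expected richness in k random units (Mao's tau).

    E[S_k] = S - sum_j C(n - n_j, k) / C(n, k) over species j with
    incidence count n_j.
    """
    n = im.n_units
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside 1..{n}")
    counts = im.incidence_counts.values
    counts = counts[counts > 0]
    S = counts.size
    keep = (n - counts) >= k
    terms = np.zeros(S)
    if keep.any():
        terms[keep] = np.exp(_log_choose(n - counts[keep], k) - _log_choose(n, k))
    return float(S - terms.sum())


def rarefaction_curve(im: IncidenceMatrix) -> pd.DataFrame:
    ks = np.arange(1, im.n_units + 1)
    return pd.DataFrame(
        {"k": ks, "expected_richness": [rarefaction(im, int(k)) for k in ks]}
    )


# ---------------------------------------------------------------------------
# Bootstrap CI
# ---------------------------------------------------------------------------

def bootstrap_ci(
    statistic: Callable[[np.ndarray], float],
    data: np.ndarray,
    B: int = 100,
    level: float = 0.95,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI over unit resamples (rows of ``data``).

    B >= 50 resamples are required; the default of 100 keeps Monte-Carlo
    noise on a 95% interval modest while staying cheap.
    """
    if B < 50:
        raise ValueError("use at least 50 bootstrap resamples")
    data = np.asarray(data)
    n = data.shape[0]
    if n < 2:
        raise ValueError("bootstrap needs >= 2 units")
    rng = np.random.default_rng(seed)
    stats_b = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        stats_b[b] = statistic(data[idx])
    lo = (1 - level) / 2
    return (
        float(np.quantile(stats_b, lo)),
        float(np.quantile(stats_b, 1 - lo)),
    )


def indices_with_ci(
    p: Sequence[float] | np.ndarray,
    B: int = 100,
    level: float = 0.95,
    seed: int | None = 0,
) -> DiversityIndices:
    """Indices of a replicate x feature block with bootstrap CIs.

    ``p`` may be a matrix (replicates x features); indices are computed
    on the column sums and CIs by resampling replicates.
    """
    arr = np.atleast_2d(np.asarray(p, dtype=float))
    point = indices(arr.sum(axis=0))
    if arr.shape[0] < 2:
        return point
    ci = {
        "H": bootstrap_ci(lambda d: shannon(d.sum(axis=0)), arr, B, level, seed),
        "DSi": bootstrap_ci(lambda d: inverse_simpson(d.sum(axis=0)), arr, B, level, seed),
    }
    point.ci = ci
    return point
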