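"""Chemometric screening: normalization, PCA, correlation, clustering.

Normalization follows common metabolomics practice: an optional
variance-stabilising transform (cube root) applied elementwise, then a
per-feature scaling — autoscale (unit variance), range scaling, or
Pareto scaling (divide by the square root of the SD).  PCA is a
centered singular-value decomposition with a deterministic sign
convention and an elbow rule for choosing how many components to keep.
Correlation matrices (feature-feature or sample-sample) and hierarchical
clustering supply the data behind heatmaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .feature_io import FeatureMatrix

logger = logging.getLogger(__name__)

TRANSFORMS = ("none", "cube_root")
SCALINGS = ("none", "autoscale", "range", "pareto")


@dataclass(frozen=True)
class NormalizationSpec:
    """Transform + per-feature scaling, recorded in downstream provenance."""

    transform: str = "none"
    scaling: str = "autoscale"

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.scaling not in SCALINGS:
            raise ValueError(f"unknown scaling {self.scaling!r}")


#: The two mode-specific specifications used for the published-style runs.
ESI_POS_SPEC = NormalizationSpec(transform="none", scaling="autoscale")
ESI_NEG_SPEC = NormalizationSpec(transform="cube_root", scaling="range")


def normalize(fm: FeatureMatrix, spec: NormalizationSpec) -> FeatureMatrix:
    """Apply the transform and per-feature scaling of ``spec``.

    Features whose scale denominator is zero (constant columns) carry no
    discriminating signal and are dropped with a warning.
    """
    X = fm.abundance.astype(float)
    if spec.transform == "cube_root":
        X = np.cbrt(X)

    if spec.scaling != "none":
        if spec.scaling == "range":
            denom = X.max(axis=0) - X.min(axis=0)
        else:
            sd = X.std(axis=0, ddof=1)
            denom = sd if spec.scaling == "autoscale" else np.sqrt(sd)
        bad = denom[denom == 0].index
        if len(bad):
            logger.warning(
                "%d zero-variance features dropped under %s scaling",
                len(bad), spec.scaling,
            )
            X = X.drop(columns=bad)
            denom = denom.drop(bad)
        X = (X - X.mean(axis=0)) / denom
    return FeatureMatrix(abundance=X, meta=fm.meta.copy(), allow_negative=True)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame        # samples x kept components
    loadings: pd.DataFrame      # features x kept components
    var_explained: np.ndarray   # % per component, all components
    eigenvalues: np.ndarray
    n_components: int


def _elbow(eigenvalues: np.ndarray) -> int:
    """Largest component index whose drop to the next exceeds the mean drop."""
    if eigenvalues.size < 2:
        return eigenvalues.size
    drops = eigenvalues[:-1] - eigenvalues[1:]
    mean_drop = drops.mean()
    above = np.nonzero(drops > mean_drop)[0]
    return int(above[-1] + 1) if above.size else 1


def pca(
    fm: FeatureMatrix | pd.DataFrame, n_components: int | str = "elbow"
) -> PCAResult:
    """Centered-SVD principal component analysis.

    No rescaling is applied here beyond centring — scaling is the
    explicit, separately recorded normalization step.  Sign convention:
    the largest-magnitude loading of each component is positive, which
    makes scores reproducible across platforms.
    """
    X = fm.abundance if isinstance(fm, FeatureMatrix) else fm
    if X.shape[0] < 2:
        raise ValueError("PCA needs more than one sample")
    vals = X.values.astype(float)
    if not np.isfinite(vals).all():
        raise ValueError("non-finite values in PCA input")
    centered = vals - vals.mean(axis=0)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    eig = s**2 / (X.shape[0] - 1)
    total = eig.sum()
    var_explained = 100.0 * eig / total if total > 0 else np.zeros_like(eig)

    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]

    if n_components == "elbow":
        k = _elbow(eig)
    else:
        k = int(n_components)
        if not (1 <= k <= eig.size):
            raise ValueError(f"n_components {k} outside 1..{eig.size}")
    comp_names = [f"PC{i+1}" for i in range(k)]
    scores = pd.DataFrame((U * s)[:, :k], index=X.index, columns=comp_names)
    loadings = pd.DataFrame(Vt[:k].T, index=X.columns, columns=comp_names)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        var_explained=var_explained,
        eigenvalues=eig,
        n_components=k,
    )


def pairwise_scores(result: PCAResult) -> list[tuple[str, str]]:
    """Component pairs for pairwise score plots, (PC1,PC2), (PC1,PC3), ..."""
    names = list(result.scores.columns)
    return [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]


# ---------------------------------------------------------------------------
# Correlation and clustering
# ---------------------------------------------------------------------------

def correlation_matrix(
    fm: FeatureMatrix | pd.DataFrame, axis: str = "features"
) -> pd.DataFrame:
    """Pearson correlation between features (columns) or samples (rows).

    Constant vectors have undefined correlation; their entries are NaN
    (the diagonal stays 1).
    """
    X = fm.abundance if isinstance(fm, FeatureMatrix) else fm
    if axis == "samples":
        X = X.T
    elif axis != "features":
        raise ValueError("axis must be 'features' or 'samples'")
    if X.shape[0] < 3:
        raise ValueError("correlation needs >= 3 observations per vector")
    corr = X.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass
class ClusteringResult:
    linkage_matrix: np.ndarray
    leaf_order: list[str]
    labels: list[str]
    distance: str
    linkage: str


def hierarchical_cluster(
    matrix: pd.DataFrame,
    distance: str = "correlation",
    linkage: str = "average",
) -> ClusteringResult:
    """Agglomerative clustering of the rows of ``matrix``.

    Returns the merge tree and leaf order needed to render a heatmap;
    no figure is produced here.
    """
    if matrix.shape[0] < 2:
        raise ValueError("clustering needs >= 2 items")
    vals = matrix.values.astype(float)
    if not np.isfinite(vals).all():
        raise ValueError("non-finite values in clustering input")
    if distance not in ("euclidean", "correlation"):
        raise ValueError(f"unknown distance {distance!r}")
    if linkage not in ("ward", "average", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    dvec = pdist(vals, metric=distance)
    # correlation distance of constant rows is NaN; treat as maximally distant
    dvec = np.nan_to_num(dvec, nan=2.0)
    Z = hierarchy.linkage(dvec, method=linkage)
    order = hierarchy.leaves_list(Z)
    labels = list(matrix.index.astype(str))
    return ClusteringResult(
        linkage_matrix=Z,
        leaf_order=[labels[i] for i in order],
        labels=labels,
        distance=distance,
        linkage=linkage,
    )


def abundance_filter(fm: FeatureMatrix, threshold: float = 2.0) -> FeatureMatrix:
    """Keep features whose (normalized) abundance reaches ``threshold`` somewhere.

    Used ahead of heatmap rendering to separate easily detectable
    species from background: a feature survives if any sample value is
    >= the threshold.
    """
    keep = (fm.abundance >= threshold).any(axis=0)
    return FeatureMatrix(
        abundance=fm.abundance.loc[:, keep],
        meta=fm.meta.copy(),
        allow_negative=fm.allow_negative,
    )
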