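"""Waveform PCA of the gait-vector pool and variance accounting.

The pooled gait vectors (one row per cycle, 4848 columns) are mean-centered
and decomposed into principal components.  Components are retained down to
a numerical floor relative to the leading score variance, which on generic
data reproduces the rank N-1 of N mean-centered vectors.

Person-stability of a component is quantified by the intra-subject
variance — the per-subject sample variance of its scores averaged with
equal weight over subjects — and by the ratio of that quantity to the
component's explained (total) variance.  A small ratio marks a feature that
varies between people but is reproducible within a person; reordering
components by ascending ratio prioritises such features for verification.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "GaitPCAModel",
    "VarianceProfile",
    "fit_gait_pca",
    "components_for_variance",
    "intra_subject_variance",
    "variance_ratio",
    "reorder_components_by_ratio",
    "reconstruct_pc_motion",
    "correlate_with_parameters",
]

#: components with score variance below this fraction of the leading
#: variance are treated as numerical noise
VARIANCE_FLOOR = 1e-12


class FeatureError(ValueError):
    """Raised for invalid feature-stage inputs."""


@dataclass
class GaitPCAModel:
    """PCA of a pool of gait vectors.

    Attributes
    ----------
    mean_vector:
        ``(D,)`` mean gait vector.
    loadings:
        ``(D, M)`` orthonormal columns ordered by explained variance.
    explained_variance:
        ``(M,)`` score variances (denominator N-1), non-increasing.
    scores:
        ``(N, M)`` coordinates of each input vector in the loading basis.
    subject_labels:
        ``(N,)`` subject identity per row (may be empty strings).
    """

    mean_vector: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    scores: np.ndarray
    subject_labels: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        """Project new gait vectors onto the loading basis."""
        return (np.asarray(vectors, dtype=float) - self.mean_vector) @ self.loadings

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        """Map scores back to gait-vector space."""
        return self.mean_vector + np.asarray(scores, dtype=float) @ self.loadings.T


@dataclass
class VarianceProfile:
    """Per-component explained variance, intra-subject variance, and ratio."""

    explained: np.ndarray
    intra: np.ndarray
    ratio: np.ndarray        # intra / explained; NaN where explained == 0
    valid: np.ndarray        # False where explained == 0 (ratio undefined)


def fit_gait_pca(
    vectors: np.ndarray,
    subject_labels=None,
    variance_floor: float = VARIANCE_FLOOR,
) -> GaitPCAModel:
    """Mean-centered PCA of the gait-vector pool.

    All components with score variance above ``variance_floor`` times the
    leading variance are retained, ordered by variance.  A pool of N
    vectors in general position yields N-1 components.

    Raises
    ------
    FeatureError
        For fewer than 2 vectors.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise FeatureError("need at least 2 gait vectors of equal length")
    if subject_labels is None:
        labels = np.full(X.shape[0], "", dtype=object)
    else:
        labels = np.asarray(subject_labels)
        if labels.shape != (X.shape[0],):
            raise FeatureError("subject_labels must have one entry per vector")

    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(X)
    ev = pca.explained_variance_

    # treat a numerically-zero leading variance (all vectors identical) as rank 0
    scale = float(np.mean(X * X)) or 1.0
    if ev.size == 0 or ev[0] <= 1e-26 * scale:
        M = 0
    else:
        M = int(np.sum(ev > variance_floor * ev[0]))
    return GaitPCAModel(
        mean_vector=pca.mean_.copy(),
        loadings=pca.components_[:M].T.copy(),
        explained_variance=ev[:M].copy(),
        scores=scores[:, :M].copy(),
        subject_labels=labels,
    )


def components_for_variance(model: GaitPCAModel, fraction: float) -> int:
    """Smallest k whose cumulative explained variance reaches ``fraction``.

    ``fraction`` must lie in (0, 1]; 1.0 returns all retained components.
    """
    if not 0.0 < fraction <= 1.0:
        raise FeatureError(f"fraction must be in (0, 1], got {fraction}")
    total = float(np.sum(model.explained_variance))
    if total <= 0:
        return 0
    cum = np.cumsum(model.explained_variance) / total
    return int(np.searchsorted(cum, fraction - 1e-12) + 1)


def intra_subject_variance(scores: np.ndarray, subject_labels) -> np.ndarray:
    """Average within-subject score variance per component.

    Per component: the sample variance (denominator n-1) of each subject's
    scores, averaged with equal weight over subjects.

    Raises
    ------
    FeatureError
        If any subject has fewer than 2 observations.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(subject_labels)
    if scores.ndim != 2 or labels.shape != (scores.shape[0],):
        raise FeatureError("scores must be (N, M) with one label per row")
    df = pd.DataFrame(scores)
    grouped = df.groupby(labels, sort=False)
    counts = grouped.size()
    if (counts < 2).any():
        few = counts[counts < 2].index.tolist()
        raise FeatureError(f"subjects with < 2 observations: {few}")
    return grouped.var(ddof=1).mean(axis=0).to_numpy()


def variance_ratio(explained: np.ndarray, intra: np.ndarray) -> VarianceProfile:
    """Elementwise intra-subject / explained variance ratio.

    Components with zero explained variance are flagged (``valid=False``)
    rather than divided.
    """
    explained = np.asarray(explained, dtype=float)
    intra = np.asarray(intra, dtype=float)
    if explained.shape != intra.shape:
        raise FeatureError("explained and intra must have equal length")
    if np.any(intra < 0) or np.any(explained < 0):
        raise FeatureError("variances must be non-negative")
    valid = explained > 0
    ratio = np.full_like(explained, np.nan)
    np.divide(intra, explained, out=ratio, where=valid)
    return VarianceProfile(explained=explained, intra=intra, ratio=ratio, valid=valid)


def reorder_components_by_ratio(profile: VarianceProfile) -> np.ndarray:
    """Permutation of component indices by ascending variance ratio.

    Stable: ties keep the original (explained-variance) order.  Components
    with undefined ratio sort last.  Indices are 0-based.
    """
    key = np.where(profile.valid, profile.ratio, np.inf)
    return np.argsort(key, kind="stable")


def reconstruct_pc_motion(
    model: GaitPCAModel, component: int, scale: float
) -> np.ndarray:
    """Gait vector of the mean gait displaced along one principal component.

    ``mean_vector + scale * loading_column``; visualising the +scale and
    -scale reconstructions shows the motion a component encodes.
    """
    if not 0 <= component < model.n_components:
        raise FeatureError(
            f"component {component} out of range [0, {model.n_components})")
    return model.mean_vector + scale * model.loadings[:, component]


def correlate_with_parameters(scores: np.ndarray, params: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each component's scores with each gait parameter.

    Returns an ``M x P`` table (components x parameters).  Entries where
    either column has zero variance are NaN.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 3:
        raise FeatureError("need (N, M) scores with N >= 3")
    if len(params) != scores.shape[0]:
        raise FeatureError("params must have one row per score row")
    if params.isna().any().any():
        raise FeatureError("params table contains missing values")
    P = params.to_numpy(dtype=float)
    sc = scores - scores.mean(axis=0)
    pc = P - P.mean(axis=0)
    s_sd = sc.std(axis=0, ddof=1)
    p_sd = pc.std(axis=0, ddof=1)
    n = scores.shape[0]
    cov = sc.T @ pc / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(s_sd, p_sd)
    corr[:, p_sd == 0] = np.nan
    corr[s_sd == 0, :] = np.nan
    return pd.DataFrame(corr, columns=list(params.columns))
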