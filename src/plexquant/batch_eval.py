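"""Batch-effect versus biological-grouping metrics on quantification matrices.

Multi-plex isobaric experiments are prone to batch effects aligned with plex
membership.  To quantify how strongly a 2-D embedding of the samples groups
by a given labeling (plex or biology), this module provides:

* a deterministic PCA embedding of the samples,
* MANOVA via Wilks' lambda ``det(W) / det(W + B)`` on the 2-D coordinates,
  with Bartlett's chi-square approximation for the p-value, and
* the ``-log10`` one-way ANOVA p-value of a grouping on the first principal
  component.

Nonlinear embedders (t-SNE, UMAP) are accepted as externally computed
coordinates through the same :class:`Embedding` container.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .quant import QuantMatrix

__all__ = [
    "Embedding",
    "GroupingResult",
    "pca_embed",
    "wilks_lambda",
    "pc1_anova_score",
]

#: -log10(p) reported when the ANOVA p-value underflows to zero
PC1_SCORE_CAP = 320.0


@dataclass
class Embedding:
    """Samples x 2 coordinates with sample names."""

    coordinates: np.ndarray
    sample_names: list[str]
    method: Literal["pca", "external"] = "pca"

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise ValueError("embedding coordinates must be (n_samples, 2)")
        if self.coordinates.shape[0] != len(self.sample_names):
            raise ValueError("coordinate rows and sample names disagree")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite embedding coordinates")


@dataclass
class GroupingResult:
    """MANOVA summary for one grouping of the embedded samples."""

    grouping: str
    wilks_lambda: float
    p_value: float
    n_groups: int
    n_samples: int
    ridged: bool = False

    def to_dict(self) -> dict:
        return {
            "grouping": self.grouping,
            "wilks_lambda": self.wilks_lambda,
            "p_value": self.p_value,
            "n_groups": self.n_groups,
            "n_samples": self.n_samples,
            "ridged": self.ridged,
        }


def pca_embed(
    matrix: QuantMatrix | pd.DataFrame,
    log_transform: bool = True,
    missing: Literal["complete"] = "complete",
) -> Embedding:
    """Project samples onto the first two principal components.

    The input is a protein-groups x samples matrix; proteins with any missing
    value are dropped (complete-rows policy).  Values are optionally
    log-transformed, each protein is centered across samples, and the top-2
    right singular directions give the coordinates.  The sign of each
    component is fixed so that its largest-magnitude loading is positive,
    making the embedding deterministic.
    """
    values = matrix.values if isinstance(matrix, QuantMatrix) else matrix
    if missing != "complete":
        raise ValueError("only the complete-rows missing-value policy is implemented")
    if values.shape[1] < 3:
        raise ValueError("PCA embedding needs at least 3 samples")
    complete = values.dropna(axis=0, how="any")
    if log_transform:
        if (complete <= 0).any().any():
            raise ValueError("log transform requires strictly positive values")
        complete = np.log2(complete)
    if complete.shape[0] < 3:
        raise ValueError(f"only {complete.shape[0]} complete protein rows; need at least 3")
    X = complete.to_numpy().T  # samples x proteins
    X = X - X.mean(axis=0, keepdims=True)
    # thin SVD: right singular vectors are the principal axes (loadings)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    coords = U[:, :2] * s[:2]
    for k in range(2):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            coords[:, k] = -coords[:, k]
    return Embedding(coordinates=coords, sample_names=list(values.columns), method="pca")


def _scatter_matrices(coords: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pooled within-group (W) and between-group (B) scatter of 2-D points."""
    grand = coords.mean(axis=0)
    W = np.zeros((2, 2))
    B = np.zeros((2, 2))
    for g in np.unique(labels):
        pts = coords[labels == g]
        mu = pts.mean(axis=0)
        d = pts - mu
        W += d.T @ d
        dm = (mu - grand)[:, None]
        B += len(pts) * (dm @ dm.T)
    return W, B


def wilks_lambda(emb: Embedding, groups: Sequence, grouping_name: str = "group") -> GroupingResult:
    """Wilks' lambda MANOVA of a grouping on 2-D embedding coordinates.

    Lambda = det(W) / det(W + B) with W the pooled within-group and B the
    between-group scatter.  The p-value uses Bartlett's chi-square
    approximation: ``-(N - 1 - (d + g)/2) * ln(Lambda)`` is chi-square with
    ``d * (g - 1)`` degrees of freedom (d = 2 dimensions, g groups,
    N samples).  A singular W is regularized with a ridge of
    ``1e-12 * trace(W + B)`` and flagged.
    """
    labels = np.asarray(groups)
    if labels.shape[0] != emb.coordinates.shape[0]:
        raise ValueError("one group label per embedded sample required")
    uniq = np.unique(labels)
    g = uniq.size
    N = labels.shape[0]
    if g < 2:
        raise ValueError("need at least 2 groups")
    if N <= g + 2:
        raise ValueError("need more samples than groups + 2")
    W, B = _scatter_matrices(emb.coordinates, labels)
    T = W + B
    det_W = float(np.linalg.det(W))
    det_T = float(np.linalg.det(T))
    ridged = False
    if det_W <= 0 or det_T <= 0:
        ridge = 1e-12 * max(np.trace(T), 1.0) * np.eye(2)
        W = W + ridge
        T = T + ridge
        det_W = float(np.linalg.det(W))
        det_T = float(np.linalg.det(T))
        ridged = True
    lam = det_W / det_T
    lam = min(max(lam, np.finfo(float).tiny), 1.0)
    d = 2
    stat = -(N - 1 - (d + g) / 2.0) * np.log(lam)
    dof = d * (g - 1)
    p = float(scipy.stats.chi2.sf(stat, dof))
    return GroupingResult(
        grouping=grouping_name,
        wilks_lambda=float(lam),
        p_value=p,
        n_groups=int(g),
        n_samples=int(N),
        ridged=ridged,
    )


def pc1_anova_score(emb: Embedding, groups: Sequence) -> float:
    """-log10 of the one-way ANOVA p-value of the grouping on PC1.

    Large scores mean the first embedding axis separates the groups.  When
    the p-value underflows to zero the score is capped at
    :data:`PC1_SCORE_CAP`.
    """
    labels = np.asarray(groups)
    if labels.shape[0] != emb.coordinates.shape[0]:
        raise ValueError("one group label per embedded sample required")
    pc1 = emb.coordinates[:, 0]
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    parts = [pc1[labels == g] for g in uniq]
    if any(len(p) < 2 for p in parts):
        raise ValueError("every group needs at least 2 samples")
    stat, p = scipy.stats.f_oneway(*parts)
    if not np.isfinite(p) or p <= 0.0:
        return PC1_SCORE_CAP
    return float(min(-np.log10(p), PC1_SCORE_CAP))
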