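"""PCA of DMR-window RPKM across samples, and projection of new cohorts.

The feature matrix is samples x DMR windows of RPKM read depth.  Windows
are mean-centred but not variance-scaled (the depth itself is the signal);
an optional log2(RPKM + 1) transform is available.  External samples are
projected with the stored centre and loadings, never refit, so systematic
cohort offsets remain visible -- which is the point of the projection
check.  Separation is quantified as the mean silhouette coefficient on the
first two principal components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import silhouette_score

__all__ = ["PcaModel", "fit_pca", "project_external", "separation_score"]


@dataclass
class PcaModel:
    window_ids: list[str]
    center_vector: np.ndarray
    loadings: np.ndarray  # (n_windows, n_components), orthonormal columns
    explained_variance: np.ndarray
    sample_scores: dict[str, np.ndarray]
    log_transform: bool = False

    def scores_matrix(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = list(sample_ids) if sample_ids is not None else list(self.sample_scores)
        return np.vstack([self.sample_scores[s] for s in ids])


def _prepare(X: np.ndarray, log_transform: bool) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.log2(X + 1.0) if log_transform else X


def fit_pca(
    rpkm_values: np.ndarray,
    sample_ids: Sequence[str],
    window_ids: Sequence[str],
    n_components: int | None = None,
    log_transform: bool = False,
) -> PcaModel:
    """SVD-based PCA of a samples x windows RPKM matrix.

    Columns are mean-centred; no scaling.  Raises on a constant matrix
    (nothing to decompose).
    """
    X = _prepare(np.asarray(rpkm_values, dtype=float), log_transform)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 windows")
    center = X.mean(axis=0)
    Xc = X - center
    if np.allclose(Xc, 0.0):
        raise ValueError("constant matrix: no variance to decompose")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = n_components or min(X.shape[0] - 1, X.shape[1])
    k = min(k, len(s))
    loadings = Vt[:k].T
    scores = Xc @ loadings
    expl = (s[:k] ** 2) / (X.shape[0] - 1)
    return PcaModel(
        window_ids=list(window_ids),
        center_vector=center,
        loadings=loadings,
        explained_variance=expl,
        sample_scores={sid: scores[i] for i, sid in enumerate(sample_ids)},
        log_transform=log_transform,
    )


def project_external(
    model: PcaModel,
    external_values: np.ndarray,
    sample_ids: Sequence[str],
    window_ids: Sequence[str],
) -> dict[str, np.ndarray]:
    """Project external samples into a fitted space (no refit).

    The external matrix must provide every window of the model; windows
    are reordered to the model's order and missing ones are an error.
    """
    idx = {w: j for j, w in enumerate(window_ids)}
    missing = [w for w in model.window_ids if w not in idx]
    if missing:
        raise ValueError(f"external matrix missing model windows: {missing[:10]}")
    order = [idx[w] for w in model.window_ids]
    X = _prepare(np.asarray(external_values, dtype=float)[:, order], model.log_transform)
    scores = (X - model.center_vector) @ model.loadings
    return {sid: scores[i] for i, sid in enumerate(sample_ids)}


def separation_score(
    scores: Mapping[str, np.ndarray], labels: Mapping[str, object]
) -> float:
    """Mean silhouette coefficient of the labels on the first two PCs."""
    ids = list(scores)
    lab = [labels[s] for s in ids]
    if len(set(map(str, lab))) < 2:
        raise ValueError("need at least 2 distinct labels")
    X = np.vstack([np.asarray(scores[s])[:2] for s in ids])
    return float(silhouette_score(X, [str(l) for l in lab]))
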