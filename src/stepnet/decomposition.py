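"""Infomax ICA and k-means clustering of component feature vectors.

The unmixing matrix is learned with the Bell-Sejnowski natural-gradient
infomax rule (logistic nonlinearity) on PCA-whitened data, with EEGLAB-style
annealing of the learning rate. Components carry a quality score in [0, 1]
measuring the spatial smoothness of their scalp projection — a head-model-
free analog of the usual "equivalent dipole explains >= 85% of the scalp
map" retention criterion: genuine cortical projections are spatially smooth
across the scalp, while noise components are not.

Component clustering mirrors the usual group-level workflow: per-component
feature vectors (source coordinates, scalp topography, log spectrum) are
standardized per block, weighted, concatenated, and clustered with k-means;
clusters drawing on too few subjects are flagged as not retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .recording import Recording

__all__ = [
    "ICADecomposition",
    "ClusterSet",
    "infomax_ica",
    "cluster_components",
    "amari_index",
    "topography_quality",
]


@dataclass
class ICADecomposition:
    """Result of infomax ICA on a Recording."""

    unmixing: np.ndarray        # W, (n_components, n_channels)
    mixing: np.ndarray          # pseudo-inverse of W, (n_channels, n_components)
    activations: np.ndarray     # (n_components, n_samples)
    channel_mean: np.ndarray    # per-channel mean removed before unmixing
    quality: np.ndarray         # per-component quality score in [0, 1]
    excluded: np.ndarray        # True where quality < threshold
    converged: bool
    n_iter: int
    final_lrate: float
    final_wchange: float
    fs: float = 0.0
    channel_labels: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def retained(self) -> np.ndarray:
        """Indices of components passing the quality threshold."""
        return np.flatnonzero(~self.excluded)


def _whiten(X: np.ndarray, n_components: int):
    cov = X @ X.T / X.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_components]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.maximum(evals, 1e-12)
    sphere = (evecs / np.sqrt(evals)).T  # (n_comp, n_ch)
    return sphere


def infomax_ica(rec_or_data, n_components: Optional[int] = None,
                max_iter: int = 500, seed=None, tol: float = 1e-6,
                quality_threshold: float = 0.85,
                l_rate: Optional[float] = None) -> ICADecomposition:
    """Bell-Sejnowski natural-gradient infomax ICA.

    Accepts a :class:`Recording` or a raw (channels x samples) array. Data
    are mean-centered per channel and PCA-whitened to ``n_components``
    before the logistic-infomax rotation is learned in mini-blocks; the
    learning rate anneals when the update direction turns sharply and the
    iteration stops when the weight change drops below ``tol`` (or flags
    non-convergence after ``max_iter`` passes and returns the partial
    result).
    """
    if isinstance(rec_or_data, Recording):
        data = rec_or_data.data
        fs = rec_or_data.fs
        labels = list(rec_or_data.channel_labels)
        positions = rec_or_data.channel_positions
    else:
        data = np.asarray(rec_or_data, float)
        fs, labels, positions = 0.0, [], None
    n_ch, n_samp = data.shape
    if n_components is None:
        n_components = n_ch
    if not 1 <= n_components <= n_ch:
        raise ValueError("n_components must be in [1, n_channels]")
    rng = np.random.default_rng(seed)
    mean = data.mean(axis=1)
    X = data - mean[:, None]
    sphere = _whiten(X, n_components)
    Xw = sphere @ X

    n = n_components
    W = np.eye(n)
    block = int(np.ceil(min(5 * np.log(n_samp), 0.3 * n_samp)))
    lrate = l_rate if l_rate is not None else 0.00065 / max(np.log(n), 1.0)
    wchange = np.inf
    oldW = W.copy()
    old_delta = None
    n_iter = 0
    converged = False
    I = np.eye(n)
    for n_iter in range(1, max_iter + 1):
        perm = rng.permutation(n_samp)
        blowup = False
        for start in range(0, n_samp - block + 1, block):
            u = W @ Xw[:, perm[start:start + block]]
            y = 1.0 / (1.0 + np.exp(-u))
            W = W + lrate * ((block * I + (1.0 - 2.0 * y) @ u.T) @ W) / block
            if np.max(np.abs(W)) > 1e8:
                blowup = True
                break
        if blowup:  # restart smaller
            lrate *= 0.5
            W = np.eye(n)
            oldW = W.copy()
            old_delta = None
            continue
        delta = W - oldW
        wchange = float((delta ** 2).sum())
        if old_delta is not None:
            denom = np.sqrt((delta ** 2).sum() * (old_delta ** 2).sum())
            if denom > 0:
                cosang = (delta * old_delta).sum() / denom
                if cosang < 0.5:  # direction turned > 60 degrees: anneal
                    lrate *= 0.9
        old_delta = delta
        oldW = W.copy()
        if wchange < tol:
            converged = True
            break

    unmixing = W @ sphere                 # (n_comp, n_ch)
    mixing = np.linalg.pinv(unmixing)     # (n_ch, n_comp)
    activations = unmixing @ X

    # order components by back-projected variance, largest first
    power = (mixing ** 2).sum(axis=0) * activations.var(axis=1)
    order = np.argsort(power)[::-1]
    unmixing, mixing = unmixing[order], mixing[:, order]
    activations = activations[order]

    quality = topography_quality(mixing, positions)
    return ICADecomposition(
        unmixing=unmixing, mixing=mixing, activations=activations,
        channel_mean=mean, quality=quality,
        excluded=quality < quality_threshold, converged=converged,
        n_iter=n_iter, final_lrate=lrate, final_wchange=wchange,
        fs=fs, channel_labels=labels)


def topography_quality(mixing: np.ndarray,
                       positions: Optional[np.ndarray]) -> np.ndarray:
    """Spatial-smoothness quality score per component, in [0, 1].

    Each scalp map (mixing column) is reconstructed by Gaussian-kernel ridge
    smoothing over the channel positions; the score is the R-squared of that
    rank-reduced reconstruction. Smooth, source-like maps score near 1,
    spatially incoherent (noise) maps near 0. Without channel positions the
    score defaults to 1 (no spatial information to judge by).
    """
    n_comp = mixing.shape[1]
    if positions is None or mixing.shape[0] < 8:
        return np.ones(n_comp)
    d2 = ((positions[:, None, :] - positions[None, :, :]) ** 2).sum(-1)
    nn = np.sqrt(np.partition(np.where(d2 > 0, d2, np.inf), 0, axis=1)[:, 0])
    ell = 2.0 * np.median(nn)
    K = np.exp(-d2 / (2 * ell ** 2))
    lam = 1e-2
    S = K @ np.linalg.inv(K + lam * np.eye(K.shape[0]))
    q = np.empty(n_comp)
    for j in range(n_comp):
        a = mixing[:, j]
        resid = a - S @ a
        denom = ((a - a.mean()) ** 2).sum()
        q[j] = 0.0 if denom == 0 else max(0.0, 1.0 - (resid ** 2).sum() / denom)
    return np.clip(q, 0.0, 1.0)


def amari_index(P: np.ndarray) -> float:
    """Permutation/scale-invariant separation error of P = W @ M_true.

    0 for a scaled permutation matrix; values below ~0.05 indicate good
    separation. Normalized to lie in [0, 1].
    """
    P = np.abs(np.asarray(P, float))
    n = P.shape[0]
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * n * (n - 1)))


# ---------------------------------------------------------------------------
# component clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterSet:
    """k-means partition of component feature vectors."""

    assignments: np.ndarray      # (n_components,) cluster index
    features: np.ndarray         # standardized, weighted, concatenated
    subject_ids: np.ndarray      # (n_components,)
    k: int
    min_subjects: int
    inertia: float

    @property
    def rosters(self) -> list:
        """Per-cluster set of contributing subjects."""
        return [set(self.subject_ids[self.assignments == c])
                for c in range(self.k)]

    @property
    def retained(self) -> np.ndarray:
        """True for clusters with at least ``min_subjects`` subjects."""
        return np.array([len(r) >= self.min_subjects for r in self.rosters])

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == cluster)


def cluster_components(blocks: Dict[str, np.ndarray],
                       subject_ids: Sequence, k: int,
                       min_subjects: int = 5, seed=None,
                       weights: Optional[Dict[str, float]] = None,
                       n_init: int = 10) -> ClusterSet:
    """Cluster components on standardized, block-weighted feature vectors.

    ``blocks`` maps block names (e.g. ``coords``, ``topography``,
    ``spectrum``) to (n_components, n_features) arrays. Each block is
    z-scored per feature and scaled by weight / sqrt(n_features) so equal
    weights give each block equal influence regardless of its width.
    """
    names = sorted(blocks)
    if not names:
        raise ValueError("no feature blocks given")
    n_comp = next(iter(blocks.values())).shape[0]
    subject_ids = np.asarray(list(subject_ids), object)
    if subject_ids.size != n_comp:
        raise ValueError("subject_ids length must match component count")
    if not 1 <= k <= n_comp:
        raise ValueError(f"k={k} outside [1, {n_comp}]")
    weights = weights or {}
    parts = []
    for name in names:
        B = np.asarray(blocks[name], float)
        if B.ndim != 2 or B.shape[0] != n_comp:
            raise ValueError(f"block {name!r} must be (n_components, d)")
        if not np.all(np.isfinite(B)):
            raise ValueError(f"block {name!r} has non-finite entries")
        sd = B.std(axis=0)
        Z = (B - B.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        parts.append(Z * (weights.get(name, 1.0) / np.sqrt(B.shape[1])))
    F = np.hstack(parts)
    km = KMeans(n_clusters=k, n_init=n_init,
                random_state=None if seed is None else int(seed) % (2 ** 32))
    labels = km.fit_predict(F)
    return ClusterSet(assignments=labels, features=F, subject_ids=subject_ids,
                      k=k, min_subjects=min_subjects,
                      inertia=float(km.inertia_))
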