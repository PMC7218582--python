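"""Beta-diversity machinery: Bray-Curtis distances, principal coordinate
analysis, permutational MANOVA and complete-linkage clustering.

PCoA and PERMANOVA are implemented directly (Gower double-centering and the
classical pseudo-F sum-of-squares partition with a seeded permutation
estimator); hierarchical clustering delegates to scipy's complete-linkage
agglomeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .io import ProportionTable

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "bray_curtis",
    "distance_matrix",
    "PCoAResult",
    "pcoa",
    "permanova",
    "complete_linkage",
    "cut",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        v = self.values
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge sequence (scipy linkage encoding) plus leaf ids."""

    leaf_ids: tuple[str, ...]
    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def bray_curtis(
    x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray
) -> float:
    """BC = Σ|x_i − y_i| / Σ(x_i + y_i); in [0, 1] for non-negative input."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("Bray-Curtis requires non-negative vectors")
    denom = (a + b).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(a - b).sum() / denom)


def distance_matrix(p: ProportionTable, warn_on_counts: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis distances between sample columns."""
    mat = p.data.to_numpy(dtype=float)
    if warn_on_counts and mat.size and mat.max() > 1 + 1e-9:
        warnings.warn(
            "input looks like counts, not proportions; Bray-Curtis is "
            "intended for compositional data",
            stacklevel=2,
        )
    n = mat.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(mat[:, i : i + 1] - mat[:, i + 1 :]).sum(axis=0)
        tot = (mat[:, i : i + 1] + mat[:, i + 1 :]).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(tot > 0, diff / tot, 0.0)
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return DistanceMatrix(tuple(p.sample_ids), d)


@dataclass(frozen=True)
class PCoAResult:
    sample_ids: tuple[str, ...]
    coordinates: np.ndarray  # n x k
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    negative_eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(d: DistanceMatrix, k: int | None = None) -> PCoAResult:
    """Classical (metric) multidimensional scaling via Gower centering.

    B = −½·J·D²·J; coordinates are eigenvectors scaled by sqrt of positive
    eigenvalues, descending. Axes with negative eigenvalues are dropped
    (their magnitudes reported) and per-axis proportion of variance is
    λ_i / Σ positive λ.
    """
    n = d.n
    if k is None:
        k = n - 1
    if k > n - 1:
        raise ValueError("k must be at most n−1")
    d2 = d.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-9 * max(abs(evals).max(), 1.0)
    pos = evals > tol
    neg = evals < -tol
    if neg.any():
        warnings.warn(
            f"dropping {int(neg.sum())} negative PCoA eigenvalue(s); "
            f"largest magnitude {abs(evals[neg]).max():.3g}",
            stacklevel=2,
        )
    lam = evals[pos]
    coords = evecs[:, pos] * np.sqrt(lam)
    k_eff = min(k, coords.shape[1])
    return PCoAResult(
        sample_ids=d.sample_ids,
        coordinates=coords[:, :k_eff],
        eigenvalues=lam[:k_eff],
        negative_eigenvalues=evals[neg],
        proportion_explained=(lam / lam.sum())[:k_eff] if lam.size else lam,
    )


def _permanova_f(d2: np.ndarray, labels: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    a = n_groups
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    d: DistanceMatrix,
    groups: Sequence[str] | Mapping[str, str],
    n_perm: int = 1000,
    seed: int | None = 0,
) -> tuple[float, float]:
    """One-factor PERMANOVA on a distance matrix.

    pseudo-F partitions Σ d²/n; the p-value is the permutation estimator
    (1 + #{F_perm >= F_obs}) / (1 + n_perm) under seeded label shuffles, so
    it can never be exactly zero.
    """
    if isinstance(groups, Mapping):
        labels_raw = [groups[s] for s in d.sample_ids]
    else:
        labels_raw = list(groups)
    if len(labels_raw) != d.n:
        raise ValueError("group labels must align with samples")
    uniq = sorted(set(labels_raw))
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    code = {lab: i for i, lab in enumerate(uniq)}
    labels = np.array([code[lab] for lab in labels_raw])
    d2 = d.values**2
    f_obs = _permanova_f(d2, labels, len(uniq))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _permanova_f(d2, perm, len(uniq)) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(f_obs), float(p)


def complete_linkage(d: DistanceMatrix) -> Dendrogram:
    """Agglomerative clustering with max-distance (furthest neighbour)
    linkage; merge heights are non-decreasing."""
    if d.n < 2:
        raise ValueError("clustering needs at least two samples")
    condensed = d.values[np.triu_indices(d.n, 1)]
    z = hierarchy.linkage(condensed, method="complete")
    return Dendrogram(d.sample_ids, z)


def cut(dend: Dendrogram, height: float) -> dict[str, int]:
    """Partition induced by removing merges above ``height``.

    Returns sample_id -> cluster label (1-based, scipy convention).
    """
    labels = hierarchy.fcluster(dend.linkage, t=height, criterion="distance")
    return {sid: int(lab) for sid, lab in zip(dend.leaf_ids, labels)}
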