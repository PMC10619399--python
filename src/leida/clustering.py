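"""Recurrent PL-state detection: k-means over pooled leading eigenvectors.

The pooled eigenvectors are unit-norm directional objects, so the default
distance is the cosine distance ``1 - x . c / |c|`` and the fitting loop is
a spherical k-means (Lloyd iterations with k-means++ seeding, centroid =
mean direction of the assigned vectors).  A Euclidean option delegates to
scikit-learn's KMeans.  One partition model is fitted per k in a sweep
(k = 2..20 by default, 19 models); each model is the best of
``n_replicates`` seeded restarts by inertia.

A validation cohort is labelled with `assign_to_centroids`: a single
assignment pass against fixed centroids ("single-iteration k-means"), so
the discovery and validation arms share identical PL-state definitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .phase import EigenvectorPool

DISTANCES = ("cosine", "euclidean")


class _EmptyCluster(Exception):
    pass


@dataclass
class PartitionModel:
    """One k-means solution: k centroids and per-frame state assignments."""

    k: int
    centroids: np.ndarray  # (k, n_regions)
    assignments: np.ndarray  # 1-based labels over the fitting pool
    inertia: float
    distance: str = "cosine"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.assignments = np.asarray(self.assignments, dtype=int)
        if not np.isfinite(self.centroids).all():
            raise ValueError("centroids must be finite")
        if self.centroids.shape[0] != self.k:
            raise ValueError("centroid count must equal k")
        present = np.unique(self.assignments)
        if present.min() < 1 or present.max() > self.k:
            raise ValueError("assignments must lie in [1, k]")

    def state_label(self, state: int) -> str:
        """Name a state the conventional way, e.g. ``k18c10``."""
        return f"k{self.k}c{state}"

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "k": self.k,
                    "distance": self.distance,
                    "seed": self.seed,
                    "inertia": self.inertia,
                    "centroids": self.centroids.tolist(),
                }
            )
        )
        return path


def _as_vectors(pool: EigenvectorPool | np.ndarray) -> np.ndarray:
    vectors = pool.vectors if isinstance(pool, EigenvectorPool) else np.asarray(pool)
    return np.asarray(vectors, dtype=float)


def _kmeanspp_cosine(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding under cosine distance (rows of x are unit norm)."""
    n = x.shape[0]
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    dist = np.maximum(1.0 - x @ centers[0], 0.0)
    for j in range(1, k):
        total = dist.sum()
        if total <= 0:
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=dist / total)
        centers[j] = x[idx]
        dist = np.minimum(dist, np.maximum(1.0 - x @ centers[j], 0.0))
    return centers


def _lloyd_cosine(
    x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, float]:
    """Spherical k-means; raises _EmptyCluster if a cluster empties."""
    n = x.shape[0]
    centers = _kmeanspp_cosine(x, k, rng)
    labels = None
    for _ in range(max_iter):
        sims = x @ centers.T
        new_labels = sims.argmax(axis=1)
        counts = np.bincount(new_labels, minlength=k)
        if (counts == 0).any():
            raise _EmptyCluster
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        onehot = np.zeros((n, k))
        onehot[np.arange(n), labels] = 1.0
        centers = (onehot.T @ x) / counts[:, None]
        norms = np.linalg.norm(centers, axis=1, keepdims=True)
        centers = centers / np.where(norms > 0, norms, 1.0)
    sims = x @ centers.T
    labels = sims.argmax(axis=1)
    inertia = float(np.sum(1.0 - sims[np.arange(n), labels]))
    return labels, centers, inertia


def _fit_single_cosine(
    x: np.ndarray, k: int, seed_seq: np.random.SeedSequence, max_retries: int = 20
) -> tuple[np.ndarray, np.ndarray, float]:
    # empty-cluster events during fitting re-seed the replicate
    for child in seed_seq.spawn(max_retries):
        try:
            return _lloyd_cosine(x, k, np.random.default_rng(child))
        except _EmptyCluster:
            continue
    raise RuntimeError(
        f"k-means with k={k} kept producing empty clusters after "
        f"{max_retries} re-seeds"
    )


def fit_partitions(
    pool: EigenvectorPool | np.ndarray,
    k_min: int = 2,
    k_max: int = 20,
    n_replicates: int = 50,
    seed: int | None = None,
    distance: str = "cosine",
) -> list[PartitionModel]:
    """Fit one partition model per k in [k_min, k_max].

    Each model is the best of ``n_replicates`` restarts by inertia;
    restarts draw sub-seeds from ``seed`` so the sweep is fully
    deterministic.  With the default k = 2..20 the sweep yields 19 models.
    """
    x = _as_vectors(pool)
    if k_min < 2 or k_max < k_min:
        raise ValueError("need 2 <= k_min <= k_max")
    if k_max > x.shape[0]:
        raise ValueError(f"k_max={k_max} exceeds the {x.shape[0]} pooled vectors")
    if distance not in DISTANCES:
        raise ValueError(f"distance must be one of {DISTANCES}")

    root = np.random.SeedSequence(seed)
    models = []
    for k, k_seq in zip(range(k_min, k_max + 1), root.spawn(k_max - k_min + 1)):
        if distance == "cosine":
            best = None
            for rep_seq in k_seq.spawn(n_replicates):
                labels, centers, inertia = _fit_single_cosine(x, k, rep_seq)
                if best is None or inertia < best[2]:
                    best = (labels, centers, inertia)
            labels, centers, inertia = best
        else:
            km = KMeans(
                n_clusters=k,
                n_init=n_replicates,
                random_state=int(k_seq.generate_state(1)[0] % (2**31)),
            ).fit(x)
            labels, centers, inertia = km.labels_, km.cluster_centers_, km.inertia_
        models.append(
            PartitionModel(
                k=k,
                centroids=centers,
                assignments=labels + 1,
                inertia=float(inertia),
                distance=distance,
                seed=seed,
            )
        )
    return models


def assign_to_centroids(
    pool: EigenvectorPool | np.ndarray,
    centroids: np.ndarray,
    distance: str = "cosine",
) -> np.ndarray:
    """Label each pooled vector with its nearest fixed centroid (1-based).

    Centroids are not updated; empty states are allowed (occupancy 0).
    This is the fixed-centroid ("single-iteration") assignment used to
    carry discovery-arm PL-state definitions onto a validation cohort.
    """
    x = _as_vectors(pool)
    centroids = np.asarray(centroids, dtype=float)
    if centroids.ndim != 2 or centroids.shape[1] != x.shape[1]:
        raise ValueError(
            f"centroid dimension {centroids.shape} does not match "
            f"pool dimension {x.shape[1]}"
        )
    if distance not in DISTANCES:
        raise ValueError(f"distance must be one of {DISTANCES}")
    if distance == "cosine":
        norms = np.linalg.norm(centroids, axis=1, keepdims=True)
        sims = x @ (centroids / np.where(norms > 0, norms, 1.0)).T
        return sims.argmax(axis=1) + 1
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1) + 1
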