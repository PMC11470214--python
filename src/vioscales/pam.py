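"""Partitioning Around Medoids (PAM) on a precomputed dissimilarity matrix.

The classical BUILD + SWAP algorithm: BUILD greedily seeds the medoids by
maximal cost reduction; SWAP repeatedly applies the single best-improvement
medoid/non-medoid exchange until no exchange lowers the total cost.  The
procedure is fully deterministic given the input order — all ties are broken
toward the lowest candidate index — which makes resampled consensus runs
reproducible without any randomness inside the clusterer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .gower import DissimilarityMatrix

__all__ = ["PAM", "ClusteringResult", "pam"]


@dataclass
class ClusteringResult:
    """A medoid partition: ids, labels, medoids and the summed cost."""

    k: int
    ids: np.ndarray
    medoid_ids: np.ndarray
    labels: np.ndarray
    total_cost: float

    @property
    def labels_by_id(self) -> dict:
        return dict(zip(self.ids.tolist(), self.labels.tolist()))


class PAM(BaseEstimator, ClusterMixin):
    """K-medoids clustering via BUILD + SWAP on precomputed dissimilarities.

    Parameters
    ----------
    n_clusters:
        Number of medoids k, ``1 <= k <= n``.
    max_iter:
        Safety cap on SWAP exchanges.

    Attributes
    ----------
    medoid_indices_ : ndarray of shape (k,)
        Row indices of the medoids, ascending.
    labels_ : ndarray of shape (n,)
        Cluster index of every point (position of its medoid in
        ``medoid_indices_``).
    inertia_ : float
        Sum of dissimilarities of points to their medoids.
    n_iter_ : int
        Number of SWAP exchanges performed.

    Notes
    -----
    The estimator is deterministic; there is no random initialization.
    """

    def __init__(self, n_clusters: int = 5, max_iter: int = 300):
        self.n_clusters = n_clusters
        self.max_iter = max_iter

    def fit(self, X, y=None):
        d = np.asarray(X, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("X must be a square precomputed dissimilarity matrix")
        if not np.all(np.isfinite(d)):
            raise ValueError("dissimilarity matrix contains non-finite entries")
        n = d.shape[0]
        k = int(self.n_clusters)
        if not 1 <= k <= n:
            raise ValueError(f"n_clusters={k} must lie in [1, {n}]")

        medoids = self._build(d, k)
        medoids, n_swaps = self._swap(d, medoids)
        medoids = np.sort(medoids)
        labels = np.argmin(d[:, medoids], axis=1)
        labels[medoids] = np.arange(k)  # each medoid anchors its own cluster
        self.medoid_indices_ = medoids
        self.labels_ = labels
        self.inertia_ = float(d[np.arange(n), medoids[labels]].sum())
        self.n_iter_ = n_swaps
        return self

    @staticmethod
    def _build(d: np.ndarray, k: int) -> np.ndarray:
        n = d.shape[0]
        first = int(np.argmin(d.sum(axis=0)))
        medoids = [first]
        dnear = d[:, first].copy()
        for _ in range(1, k):
            gains = np.maximum(dnear[:, None] - d, 0.0).sum(axis=0)
            gains[medoids] = -np.inf
            c = int(np.argmax(gains))  # ties -> lowest index
            medoids.append(c)
            np.minimum(dnear, d[:, c], out=dnear)
        return np.array(sorted(medoids))

    def _swap(self, d: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, int]:
        # Best-improvement exchanges; additionally, a bounded number of
        # cost-neutral exchanges (cycle-protected, lowest index first) lets
        # the search cross plateaus created by tied dissimilarities, which
        # strict descent cannot leave.
        n = d.shape[0]
        k = len(medoids)
        medoids = np.sort(medoids)
        n_swaps = 0
        neutral_budget = 2 * k
        visited = {tuple(medoids)}
        tol = 1e-12
        while n_swaps < self.max_iter:
            sub = d[:, medoids]
            nearest = np.argmin(sub, axis=1)
            d1 = sub[np.arange(n), nearest]
            if k > 1:
                part = np.partition(sub, 1, axis=1)
                d2 = part[:, 1]
            else:
                d2 = np.full(n, np.inf)
            total = d1.sum()
            is_medoid = np.zeros(n, dtype=bool)
            is_medoid[medoids] = True

            deltas = np.empty((k, n))
            for i in range(k):
                ref = np.where(nearest == i, d2, d1)
                cand_cost = np.minimum(d, ref[:, None]).sum(axis=0)
                cand_cost[is_medoid] = np.inf
                deltas[i] = cand_cost - total

            flat = int(np.argmin(deltas))  # row-major: lowest (i, h) wins ties
            i, h = divmod(flat, n)
            if deltas[i, h] < -tol:
                medoids = np.sort(np.concatenate([np.delete(medoids, i), [h]]))
                visited.add(tuple(medoids))
                n_swaps += 1
                continue
            moved = False
            if neutral_budget > 0:
                neutral = np.argwhere(np.abs(deltas) <= tol)
                for i, h in neutral:  # argwhere is row-major: lowest index first
                    candidate = np.sort(np.concatenate([np.delete(medoids, i), [h]]))
                    key = tuple(candidate)
                    if key not in visited:
                        medoids = candidate
                        visited.add(key)
                        neutral_budget -= 1
                        n_swaps += 1
                        moved = True
                        break
            if not moved:
                break
        return medoids, n_swaps

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def pam(dissim: DissimilarityMatrix | np.ndarray, k: int, seed: int | None = None) -> ClusteringResult:
    """Functional wrapper around :class:`PAM`.

    ``seed`` is accepted for interface symmetry with the resampling stages
    but has no effect: BUILD + SWAP is deterministic.
    """
    if isinstance(dissim, DissimilarityMatrix):
        values, ids = dissim.values, dissim.ids
    else:
        values = np.asarray(dissim, dtype=float)
        ids = np.arange(values.shape[0])
    est = PAM(n_clusters=k).fit(values)
    return ClusteringResult(
        k=k,
        ids=ids,
        medoid_ids=ids[est.medoid_indices_],
        labels=est.labels_,
        total_cost=est.inertia_,
    )
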