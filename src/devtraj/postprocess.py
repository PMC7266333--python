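"""Consensus post-processing of MCMC allocation traces.

Because the mixture posterior is invariant to relabelling of components (and
the sampler deliberately mixes over labels), a single partition cannot be
read off the chains by majority label.  Instead, the posterior similarity
matrix (PSM) records for each pair of observations the proportion of pooled
post-burn-in iterations in which they share a component — a label-free
summary.  Partitioning around medoids (PAM) on the dissimilarity ``1 - PSM``
then yields candidate partitions for k = 2..20, compared by the average
silhouette width.  Convergence across chains is monitored with the
Gelman-Rubin potential scale reduction factor applied to the occupied-cluster
count K and the concentration parameter alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

__all__ = [
    "ClusteringResult",
    "psm",
    "pam",
    "avg_silhouette",
    "select_clustering",
    "gelman_rubin",
]


@dataclass(frozen=True)
class ClusteringResult:
    """Consensus partition: medoids, assignments and silhouette score."""

    k: int
    medoids: np.ndarray  # (k,) indices into the observations
    assignment: np.ndarray  # (n,) values in 0..k-1
    silhouette: float
    objective: float = np.nan  # total dissimilarity to assigned medoids
    silhouette_by_k: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        med = np.asarray(self.medoids, dtype=int)
        assign = np.asarray(self.assignment, dtype=int)
        object.__setattr__(self, "medoids", med)
        object.__setattr__(self, "assignment", assign)
        for j, m in enumerate(med):
            if assign[m] != j:
                raise ValueError("each medoid must belong to its own cluster")


def _pooled_allocations(traces, burn_in_fraction: float) -> np.ndarray:
    chunks = []
    for t in traces:
        alloc = np.asarray(t.allocations if hasattr(t, "allocations") else t)
        if alloc.ndim != 2:
            raise ValueError("each trace must be an (iterations, n) allocation array")
        start = int(np.floor(burn_in_fraction * len(alloc)))
        kept = alloc[start:]
        if len(kept) == 0:
            raise ValueError("no iterations remain after burn-in")
        chunks.append(kept)
    n_cols = {c.shape[1] for c in chunks}
    if len(n_cols) != 1:
        raise ValueError("traces cover different numbers of observations")
    return np.concatenate(chunks, axis=0)


def psm(traces, burn_in_fraction: float = 0.5) -> np.ndarray:
    """Posterior similarity matrix pooled across chains.

    ``S[i, j]`` is the proportion of post-burn-in iterations (pooled over
    all chains) in which observations i and j carry the same label.  The
    matrix is symmetric with unit diagonal; ``1 - S`` is the consensus
    dissimilarity.
    """
    if not (0.0 <= burn_in_fraction < 1.0):
        raise ValueError("burn_in_fraction must lie in [0, 1)")
    trace_list = [traces] if isinstance(traces, np.ndarray) else list(traces)
    Z = _pooled_allocations(trace_list, burn_in_fraction)
    m, n = Z.shape
    S = np.zeros((n, n))
    step = max(1, 2_000_000 // (n * n))  # bound the chunk workspace
    for s in range(0, m, step):
        blk = Z[s : s + step]
        S += (blk[:, :, None] == blk[:, None, :]).sum(axis=0)
    S /= m
    np.fill_diagonal(S, 1.0)
    return S


# ---------------------------------------------------------------------------
# Partitioning around medoids


def _check_dissimilarity(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("D must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("D must have a zero diagonal")
    return D


def pam(D: np.ndarray, k: int) -> ClusteringResult:
    """Partitioning around medoids: BUILD then SWAP to a local optimum.

    BUILD greedily seeds k medoids; SWAP repeatedly applies the single
    (medoid, non-medoid) exchange that most reduces the total dissimilarity
    of points to their nearest medoid, until no exchange improves it.  The
    objective never increases across SWAP steps.
    """
    D = _check_dissimilarity(D)
    n = len(D)
    if not (2 <= k < n):
        raise ValueError(f"k must satisfy 2 <= k < n = {n}, got {k}")

    # BUILD: first medoid minimises total dissimilarity; subsequent medoids
    # maximise the decrease in the objective.
    medoids = [int(np.argmin(D.sum(axis=0)))]
    nearest = D[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))
        medoids.append(best)
        nearest = np.minimum(nearest, D[:, best])

    medoids = np.asarray(medoids, dtype=int)
    objective = _pam_objective(D, medoids)
    while True:
        improved = False
        best_delta, best_swap = -1e-12, None
        non_medoids = np.setdiff1d(np.arange(n), medoids)
        Dm = D[:, medoids]  # (n, k)
        order = np.argsort(Dm, axis=1)
        d1 = Dm[np.arange(n), order[:, 0]]  # nearest-medoid distance
        d2 = Dm[np.arange(n), order[:, 1]]  # second nearest
        which = order[:, 0]
        for j in range(k):
            loss = np.where(which == j, d2, d1)  # nearest if medoid j removed
            for h in non_medoids:
                new_obj = np.minimum(loss, D[:, h]).sum()
                delta = objective - new_obj
                if delta > best_delta:
                    best_delta, best_swap = delta, (j, h)
        if best_swap is not None and best_delta > 1e-12:
            j, h = best_swap
            medoids[j] = h
            new_objective = _pam_objective(D, medoids)
            assert new_objective <= objective + 1e-9, "PAM objective increased"
            objective = new_objective
            improved = True
        if not improved:
            break

    assignment = np.argmin(D[:, medoids], axis=1)
    assignment[medoids] = np.arange(k)  # medoids belong to their own cluster
    return ClusteringResult(
        k=k,
        medoids=medoids,
        assignment=assignment,
        silhouette=np.nan,
        objective=float(objective),
    )


def _pam_objective(D: np.ndarray, medoids: np.ndarray) -> float:
    return float(D[:, medoids].min(axis=1).sum())


def avg_silhouette(D: np.ndarray, assignment: np.ndarray) -> float:
    """Average silhouette width on a precomputed dissimilarity matrix.

    ``s_i = (b_i - a_i) / max(a_i, b_i)`` with ``a_i`` the mean dissimilarity
    to the own cluster and ``b_i`` the smallest mean dissimilarity to another
    cluster; observations in singleton clusters contribute 0.
    """
    D = _check_dissimilarity(D)
    assignment = np.asarray(assignment)
    labels, counts = np.unique(assignment, return_counts=True)
    if len(labels) < 2:
        raise ValueError("average silhouette needs at least two clusters")
    return float(silhouette_score(D, assignment, metric="precomputed"))


def select_clustering(S: np.ndarray, k_min: int = 2, k_max: int = 20) -> ClusteringResult:
    """PAM on ``1 - S`` for each k in [k_min, k_max]; keep the k with the
    largest average silhouette width (ties broken toward smaller k)."""
    S = np.asarray(S, dtype=float)
    n = len(S)
    if n <= k_min:
        raise ValueError(f"need more than k_min = {k_min} observations, have {n}")
    k_max = min(k_max, n - 1)
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)  # guard against asymmetric rounding

    best: ClusteringResult | None = None
    sil_by_k: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        res = pam(D, k)
        sil = avg_silhouette(D, res.assignment)
        sil_by_k[k] = sil
        if best is None or sil > best.silhouette + 1e-12:
            best = ClusteringResult(
                k=k,
                medoids=res.medoids,
                assignment=res.assignment,
                silhouette=sil,
                objective=res.objective,
            )
    return ClusteringResult(
        k=best.k,
        medoids=best.medoids,
        assignment=best.assignment,
        silhouette=best.silhouette,
        objective=best.objective,
        silhouette_by_k=sil_by_k,
    )


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor over >= 2 equal-length scalar chains.

    ``sqrt((((n-1)/n) W + B/n) / W)`` with W the mean within-chain variance
    and B the between-chain variance times n.  Chains that are identical
    constants return 1 by convention.
    """
    arrs = [np.asarray(c, dtype=float).ravel() for c in chains]
    if len(arrs) < 2:
        raise ValueError("need at least two chains")
    lengths = {len(a) for a in arrs}
    if len(lengths) != 1:
        raise ValueError("chains must have equal lengths")
    n = lengths.pop()
    if n < 2:
        raise ValueError("chains must have at least two iterations")
    X = np.vstack(arrs)
    W = X.var(axis=1, ddof=1).mean()
    B = n * X.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return 1.0 if B == 0.0 else np.inf
    V = (n - 1) / n * W + B / n
    return float(np.sqrt(V / W))
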