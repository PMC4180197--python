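"""Partitioning Around Medoids (PAM) on a precomputed distance matrix.

The classical Kaufman-Rousseeuw two-phase algorithm: BUILD greedily seeds k
medoids (first the object minimizing total distance to all others, then
the object giving the largest cost decrease, repeatedly); SWAP repeatedly
applies the single (medoid, non-medoid) exchange with the largest decrease
of the configuration cost

    E = sum_clusters sum_{o in C_i} dist(o, m_i)

until no exchange improves it.  Every tie breaks toward the lowest object
index, so a run is bit-reproducible; a ``random`` initialization is kept
behind a flag for robustness checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gower import DistanceMatrix

__all__ = ["Clustering", "pam_build", "pam_swap", "pam"]


@dataclass(frozen=True)
class Clustering:
    """Result of a PAM run: sorted medoid indices, per-object cluster ids
    (position of the nearest medoid in ``medoids``), exact cost E and the
    number of accepted swap iterations."""

    medoids: tuple[int, ...]
    assignment: np.ndarray
    cost: float
    iterations: int
    k: int

    def __post_init__(self) -> None:
        if len(set(self.medoids)) != self.k:
            raise ValueError("medoids must be distinct")


def _as_array(D) -> np.ndarray:
    if isinstance(D, DistanceMatrix):
        return D.values
    return np.asarray(D, dtype=float)


def _assign(d: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    """Nearest-medoid assignment (ties -> lowest medoid index, medoids
    sorted ascending) and the exact configuration cost."""
    sub = d[:, medoids]  # medoids already sorted ascending
    assignment = np.argmin(sub, axis=1)
    cost = float(sub[np.arange(len(d)), assignment].sum())
    return assignment, cost


def pam_build(D, k: int) -> tuple[int, ...]:
    """Greedy BUILD initialization; deterministic, ties -> lowest index."""
    d = _as_array(D)
    n = len(d)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    first = int(np.argmin(d.sum(axis=1)))
    medoids = [first]
    nearest = d[:, first].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        nxt = int(np.argmax(gains))
        medoids.append(nxt)
        nearest = np.minimum(nearest, d[:, nxt])
    return tuple(sorted(medoids))


def pam_swap(D, medoids, max_iter_factor: int = 10) -> Clustering:
    """Best-improvement SWAP phase from a given medoid set."""
    d = _as_array(D)
    n = len(d)
    med = np.array(sorted(set(int(m) for m in medoids)), dtype=np.int64)
    if len(med) != len(tuple(medoids)):
        raise ValueError("medoids must be distinct")
    k = len(med)
    assignment, cost = _assign(d, med)
    iterations = 0
    max_iter = max_iter_factor * n
    while True:
        if iterations >= max_iter:
            warnings.warn(
                f"PAM swap hit the iteration cap ({max_iter})", stacklevel=2
            )
            break
        is_medoid = np.zeros(n, dtype=bool)
        is_medoid[med] = True
        candidates = np.flatnonzero(~is_medoid)
        if len(candidates) == 0:
            break
        sub = d[:, med]
        order = np.argsort(sub, axis=1, kind="stable")
        d1 = sub[np.arange(n), order[:, 0]]
        nearest_pos = order[:, 0]
        d2 = sub[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        best = None  # (new_cost, medoid_pos, candidate)
        for pos in range(k):
            base = np.where(nearest_pos == pos, d2, d1)
            if k == 1:
                base = np.full(n, np.inf)
            new_costs = np.minimum(base[None, :], d[candidates, :]).sum(axis=1)
            c = int(np.argmin(new_costs))
            cand_cost = float(new_costs[c])
            if best is None or cand_cost < best[0] - 1e-12:
                best = (cand_cost, pos, int(candidates[c]))
        if best is None or best[0] >= cost - 1e-12:
            break
        cost_new, pos, obj = best
        med[pos] = obj
        med = np.sort(med)
        assignment, cost = _assign(d, med)
        iterations += 1
    return Clustering(
        medoids=tuple(int(m) for m in med),
        assignment=assignment,
        cost=cost,
        iterations=iterations,
        k=k,
    )


def pam(D, k: int, init: str = "build", seed: int | None = None) -> Clustering:
    """BUILD (default) or seeded-random initialization followed by SWAP."""
    d = _as_array(D)
    n = len(d)
    if init == "build":
        medoids = pam_build(d, k)
    elif init == "random":
        if seed is None:
            raise ValueError("random initialization requires a seed")
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        rng = np.random.default_rng(seed)
        medoids = tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))
    else:
        raise ValueError(f"unknown init {init!r}; use 'build' or 'random'")
    return pam_swap(d, medoids)
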