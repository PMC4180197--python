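"""External validation of a clustering against ground-truth classes.

Purity is the fraction of objects lying in their cluster's majority class:

    purity(C, W) = (1/N) * sum_clusters max_class |cluster ∩ class|

It ranges over [0, 1], is invariant to relabeling of clusters and classes,
and inflates toward 1 as the number of clusters grows (k = N singletons
always score 1), so it is meaningful mainly when k is known a priori.
Counts are kept as exact integers; the ratio is converted to float only
for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = ["ContingencyTable", "PurityReport", "contingency", "purity"]


@dataclass(frozen=True)
class ContingencyTable:
    """Cluster x class integer counts with margins."""

    counts: np.ndarray  # clusters x classes, int
    cluster_ids: tuple
    class_names: tuple

    def __post_init__(self) -> None:
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def cluster_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def class_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class PurityReport:
    """Purity value plus each cluster's majority class and count."""

    value: float
    exact: Fraction
    majority_classes: tuple
    majority_counts: tuple
    table: ContingencyTable


def contingency(assignment, labels) -> ContingencyTable:
    """Cluster-by-class counts; clusters ordered by id, classes by first
    appearance in ``labels``."""
    assignment = np.asarray(assignment)
    labels = np.asarray(labels, dtype=object)
    if len(assignment) != len(labels):
        raise ValueError(
            f"length mismatch: {len(assignment)} assignments vs {len(labels)} labels"
        )
    if len(assignment) == 0:
        raise ValueError("empty clustering")
    cluster_ids = tuple(sorted(set(assignment.tolist())))
    class_names: tuple = tuple(dict.fromkeys(labels.tolist()))
    ci = {c: i for i, c in enumerate(cluster_ids)}
    cj = {c: j for j, c in enumerate(class_names)}
    counts = np.zeros((len(cluster_ids), len(class_names)), dtype=np.int64)
    for a, l in zip(assignment, labels):
        counts[ci[a], cj[l]] += 1
    return ContingencyTable(counts=counts, cluster_ids=cluster_ids,
                            class_names=class_names)


def purity(ct: ContingencyTable) -> PurityReport:
    """Exact purity of a contingency table (empty clusters contribute 0)."""
    if ct.n < 1:
        raise ValueError("purity needs at least one object")
    maj_counts = []
    maj_classes = []
    for row in ct.counts:
        m = int(row.max()) if len(row) else 0
        maj_counts.append(m)
        # report the alphabetically first class among tied majorities
        tied = [ct.class_names[j] for j in np.flatnonzero(row == m)]
        maj_classes.append(min(tied, key=str) if tied else None)
    exact = Fraction(int(sum(maj_counts)), ct.n)
    return PurityReport(
        value=float(exact),
        exact=exact,
        majority_classes=tuple(maj_classes),
        majority_counts=tuple(maj_counts),
        table=ct,
    )
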