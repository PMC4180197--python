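"""Gower similarity and distance for mixed numeric/categorical rows.

Gower's coefficient averages per-feature similarities over the features
comparable for a pair of rows:

    S_ij = [ sum_h (1 - |x_ih - x_jh| / G_h) + a + alpha ] / [ p1 + (p2 - d) + p3 ]

with G_h the observed range of quantitative feature h, alpha the number of
matches on qualitative features, and, on asymmetric (presence/absence)
binary features, a the number of joint presences while the d joint absences
are dropped from the denominator.  A feature missing in either row is
skipped for that pair.  The printed relation d^2 = 1 - S gives the default
distance transform ``sqrt``; the common ``one-minus-s`` alternative is also
offered because PAM sums raw distances, so the choice can move medoids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import FeatureSchema, MixedDataset

__all__ = [
    "RangeTable",
    "DistanceMatrix",
    "GowerParts",
    "compute_ranges",
    "gower_similarity",
    "gower_distance",
    "gower_parts",
    "gower_matrix",
]

TRANSFORMS = ("sqrt", "one-minus-s")


class UndefinedSimilarityError(ValueError):
    """A pair of rows shares no comparable feature."""


@dataclass(frozen=True)
class RangeTable:
    """Observed max - min per numeric feature, ignoring missing cells."""

    ranges: dict[str, float]

    def __post_init__(self) -> None:
        for name, g in self.ranges.items():
            if not (g >= 0):
                raise ValueError(f"negative range for {name!r}")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric n x n matrix in [0, 1] with zero diagonal, plus the
    features and transform that produced it."""

    values: np.ndarray
    features: tuple[str, ...]
    transform: str

    def __post_init__(self) -> None:
        d = self.values
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(d)).max() > 1e-12:
            raise ValueError("distance matrix diagonal must be zero")
        if d.min() < -1e-12 or d.max() > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def compute_ranges(ds: MixedDataset) -> RangeTable:
    ranges: dict[str, float] = {}
    for name in ds.schema.numeric:
        col = ds.values[name].to_numpy(dtype=float)
        col = col[~np.isnan(col)]
        ranges[name] = float(col.max() - col.min()) if len(col) else 0.0
    return RangeTable(ranges)


def _feature_pair_terms(
    kind: str, xi, xj, g: float
) -> tuple[float, float] | None:
    """(similarity contribution, denominator contribution) for one feature
    of one row pair, or None if the feature is skipped for this pair."""
    if kind == "numeric":
        if np.isnan(xi) or np.isnan(xj):
            return None
        if g == 0.0:
            return 1.0, 1.0  # constant feature: both values necessarily equal
        return 1.0 - abs(xi - xj) / g, 1.0
    if xi is None or xj is None:
        return None
    if kind == "categorical":
        return (1.0 if xi == xj else 0.0), 1.0
    if kind == "asymmetric_binary":
        pi, pj = xi not in ("0", 0, 0.0), xj not in ("0", 0, 0.0)
        if not pi and not pj:
            return None  # joint absence: excluded from the denominator
        return (1.0 if (pi and pj) else 0.0), 1.0
    raise ValueError(f"unknown feature kind {kind!r}")


def gower_similarity(row_i, row_j, schema: FeatureSchema, ranges: RangeTable) -> float:
    """Similarity of two rows (dicts or Series keyed by feature name)."""
    num = den = 0.0
    for name in schema.names:
        kind = schema.kinds[name]
        g = ranges.ranges.get(name, 0.0)
        terms = _feature_pair_terms(kind, row_i[name], row_j[name], g)
        if terms is None:
            continue
        num += terms[0]
        den += terms[1]
    if den == 0.0:
        raise UndefinedSimilarityError("rows share no comparable feature")
    return num / den


def gower_distance(s: float, transform: str = "sqrt") -> float:
    """Distance from a similarity: sqrt(1 - S) by default, or 1 - S."""
    if not (-1e-12 <= s <= 1 + 1e-12):
        raise ValueError(f"similarity {s} outside [0, 1]")
    s = min(max(s, 0.0), 1.0)
    if transform == "sqrt":
        return float(np.sqrt(1.0 - s))
    if transform == "one-minus-s":
        return 1.0 - s
    raise ValueError(f"unknown transform {transform!r}; use one of {TRANSFORMS}")


@dataclass(frozen=True)
class GowerParts:
    """Per-feature numerator/denominator stacks of the Gower sum.

    ``numer[f]`` and ``denom[f]`` are n x n arrays holding feature f's
    contribution to the similarity numerator and to the count of comparable
    features.  Summing any subset of features and dividing yields that
    subset's similarity matrix — which makes ranked-subset sweeps cheap.
    """

    numer: np.ndarray  # p x n x n
    denom: np.ndarray  # p x n x n
    features: tuple[str, ...]

    def similarity(self, feature_idx) -> np.ndarray:
        num = self.numer[feature_idx].sum(axis=0)
        den = self.denom[feature_idx].sum(axis=0)
        if (den == 0).any():
            i, j = np.argwhere(den == 0)[0]
            raise UndefinedSimilarityError(
                f"rows {i} and {j} share no comparable feature"
            )
        return num / den

    def distance_matrix(self, feature_names, transform: str = "sqrt") -> DistanceMatrix:
        index = {f: k for k, f in enumerate(self.features)}
        idx = [index[f] for f in feature_names]
        s = self.similarity(idx)
        s = np.clip(s, 0.0, 1.0)
        if transform == "sqrt":
            d = np.sqrt(1.0 - s)
        elif transform == "one-minus-s":
            d = 1.0 - s
        else:
            raise ValueError(f"unknown transform {transform!r}")
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2.0  # exact symmetry against float noise
        return DistanceMatrix(
            values=d, features=tuple(feature_names), transform=transform
        )


def gower_parts(ds: MixedDataset) -> GowerParts:
    """Vectorized per-feature Gower contributions for all row pairs."""
    n, p = ds.n, ds.p
    numer = np.zeros((p, n, n))
    denom = np.zeros((p, n, n))
    ranges = compute_ranges(ds)
    for j, name in enumerate(ds.schema.names):
        kind = ds.schema.kinds[name]
        if kind == "numeric":
            col = ds.values[name].to_numpy(dtype=float)
            present = ~np.isnan(col)
            both = np.outer(present, present)
            g = ranges.ranges[name]
            if g == 0.0:
                warnings.warn(
                    f"numeric feature {name!r} is constant; it contributes "
                    "similarity 1 to every pair — consider dropping it",
                    stacklevel=2,
                )
                sim = np.ones((n, n))
            else:
                filled = np.where(present, col, 0.0)
                sim = 1.0 - np.abs(filled[:, None] - filled[None, :]) / g
            numer[j] = np.where(both, sim, 0.0)
            denom[j] = both.astype(float)
        else:
            vals = ds.values[name].to_numpy(dtype=object)
            present = np.array([v is not None for v in vals])
            codes = np.array(
                [-1 if v is None else hash(v) for v in vals], dtype=np.int64
            )
            both = np.outer(present, present)
            eq = codes[:, None] == codes[None, :]
            if kind == "categorical":
                numer[j] = np.where(both & eq, 1.0, 0.0)
                denom[j] = both.astype(float)
            else:  # asymmetric_binary
                pres1 = present & np.array(
                    [v not in ("0", 0, 0.0, None) for v in vals]
                )
                joint_presence = np.outer(pres1, pres1)
                joint_absence = np.outer(present & ~pres1, present & ~pres1)
                numer[j] = np.where(joint_presence, 1.0, 0.0)
                denom[j] = np.where(both & ~joint_absence, 1.0, 0.0)
    return GowerParts(numer=numer, denom=denom, features=ds.schema.names)


def gower_matrix(ds: MixedDataset, transform: str = "sqrt") -> DistanceMatrix:
    """Pairwise Gower distances over all rows; the class column is not part
    of the feature table, so it can never enter the computation."""
    if ds.p < 2:
        raise ValueError("distance computation requires at least 2 features")
    parts = gower_parts(ds)
    return parts.distance_matrix(ds.schema.names, transform=transform)
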