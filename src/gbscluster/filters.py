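"""Filter feature-selection criteria for mixed clinical data.

Five classical filters are provided, all supervised and independent of any
downstream clusterer:

* information gain, symmetrical uncertainty and chi-squared — univariate
  rankers over the feature-value x class contingency table;
* CFS — a subset selector maximizing the merit
  ``M_S = k * r_cf / sqrt(k + k(k-1) * r_ff)`` where both correlations are
  symmetrical-uncertainty values, searched with best-first forward search;
* consistency — the smallest subset whose inconsistency rate does not
  exceed that of the full feature set.

All of them require discrete features, so numeric columns are first cut by
recursive entropy minimization with the MDL stopping rule (Fayyad-Irani).
Logarithms are base 2 throughout; a feature left with a single interval
scores 0 on every ranker.
"""

from __future__ import annotations

import heapq
import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import FeatureRanking, FeatureSubset, MixedDataset

__all__ = [
    "DiscretizedDataset",
    "ProbTables",
    "discretize_mdl",
    "entropy",
    "info_gain_scores",
    "symmetrical_uncertainty",
    "su_scores",
    "chi_squared_scores",
    "cfs_merit",
    "cfs_select",
    "inconsistency_rate",
    "consistency_select",
]

MISSING = -1  # code reserved for missing cells


# ---------------------------------------------------------------------------
# Entropy and probability tables
# ---------------------------------------------------------------------------

def _entropy_counts(counts: np.ndarray) -> float:
    """Shannon entropy in bits from nonnegative counts."""
    total = counts.sum()
    if total == 0:
        raise ValueError("entropy of an empty sample is undefined")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _as_codes(values) -> np.ndarray:
    """Map an arbitrary symbol vector to integer codes, missing -> -1."""
    arr = np.asarray(values, dtype=object)
    out = np.empty(len(arr), dtype=np.int64)
    table: dict[object, int] = {}
    for i, v in enumerate(arr):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            out[i] = MISSING
        else:
            out[i] = table.setdefault(v, len(table))
    return out


def entropy(values) -> float:
    """Entropy (bits) of a symbol vector; missing entries are excluded."""
    codes = _as_codes(values)
    codes = codes[codes != MISSING]
    if len(codes) == 0:
        raise ValueError("no observed values after removing missing entries")
    return _entropy_counts(np.bincount(codes))


@dataclass(frozen=True)
class ProbTables:
    """Joint and marginal frequencies of one feature against the class."""

    joint: np.ndarray  # values x classes, sums to 1
    p_feature: np.ndarray
    p_class: np.ndarray
    n: int

    @classmethod
    def from_codes(cls, f: np.ndarray, c: np.ndarray) -> "ProbTables":
        """Build tables from two code vectors, dropping rows missing in
        either."""
        keep = (f != MISSING) & (c != MISSING)
        f, c = f[keep], c[keep]
        n = len(f)
        if n == 0:
            raise ValueError("no complete (feature, class) pairs")
        nf, nc = int(f.max()) + 1, int(c.max()) + 1
        counts = np.bincount(f * nc + c, minlength=nf * nc).reshape(nf, nc)
        joint = counts / n
        return cls(joint=joint, p_feature=joint.sum(1), p_class=joint.sum(0), n=n)


def _mutual_information(pt: ProbTables) -> float:
    """MI in bits; zero-probability cells contribute 0 (limit convention)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        outer = np.outer(pt.p_feature, pt.p_class)
        ratio = np.where(pt.joint > 0, pt.joint / np.where(outer > 0, outer, 1.0), 1.0)
        terms = np.where(pt.joint > 0, pt.joint * np.log2(ratio), 0.0)
    return float(terms.sum())


# ---------------------------------------------------------------------------
# Supervised discretization (recursive entropy minimization, MDL stop)
# ---------------------------------------------------------------------------

@dataclass
class DiscretizedDataset:
    """All-symbolic view of a MixedDataset: numeric columns replaced by
    interval codes, categorical columns factorized unchanged."""

    codes: np.ndarray  # n x p int, MISSING == -1
    feature_names: tuple[str, ...]
    symbols: dict[str, tuple[str, ...]]
    cut_points: dict[str, tuple[float, ...]]
    label_codes: np.ndarray
    label_symbols: tuple[str, ...]
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {name: j for j, name in enumerate(self.feature_names)}

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def p(self) -> int:
        return self.codes.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.codes[:, self._index[name]]

    def n_values(self, name: str) -> int:
        return len(self.symbols[name])


def _class_counts(labels: np.ndarray, k: int) -> np.ndarray:
    return np.bincount(labels, minlength=k)


def _mdl_cut_points(x: np.ndarray, y: np.ndarray, n_classes: int) -> list[float]:
    """Recursive binary splitting of sorted numeric values by class entropy,
    accepting each cut only if it passes the MDL criterion."""
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    cuts: list[float] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2:
            return
        xs, ys = x[lo:hi], y[lo:hi]
        total = _class_counts(ys, n_classes)
        ent_s = _entropy_counts(total)
        if ent_s == 0.0:
            return
        # candidate cuts between adjacent distinct values; prefix class counts
        prefix = np.zeros((n + 1, n_classes), dtype=np.int64)
        for i in range(n):
            prefix[i + 1] = prefix[i]
            prefix[i + 1, ys[i]] += 1
        best = None  # (weighted entropy, index)
        for i in range(1, n):
            if xs[i] == xs[i - 1]:
                continue
            left = prefix[i]
            right = total - left
            w = (i * _entropy_counts(left) + (n - i) * _entropy_counts(right)) / n
            if best is None or w < best[0] - 1e-12:
                best = (w, i)
        if best is None:
            return
        w_ent, i = best
        gain = ent_s - w_ent
        left = prefix[i]
        right = total - left
        k = int((total > 0).sum())
        k1 = int((left > 0).sum())
        k2 = int((right > 0).sum())
        ent1 = _entropy_counts(left)
        ent2 = _entropy_counts(right)
        delta = math.log2(3**k - 2) - (k * ent_s - k1 * ent1 - k2 * ent2)
        threshold = (math.log2(n - 1) + delta) / n
        if gain <= threshold:
            return
        cuts.append((xs[i - 1] + xs[i]) / 2.0)
        recurse(lo, lo + i)
        recurse(lo + i, hi)

    recurse(0, len(x))
    return sorted(cuts)


def discretize_mdl(ds: MixedDataset) -> DiscretizedDataset:
    """Discretize every numeric feature against the class labels.

    Features where the MDL rule accepts no cut collapse to a single
    interval (and will score 0 on every ranker).  Categorical and
    asymmetric-binary features pass through unchanged (factorized).
    """
    label_symbols = ds.classes
    label_index = {c: i for i, c in enumerate(label_symbols)}
    label_codes = np.array([label_index[v] for v in ds.labels], dtype=np.int64)
    n_classes = len(label_symbols)

    n, p = ds.n, ds.p
    codes = np.full((n, p), MISSING, dtype=np.int64)
    symbols: dict[str, tuple[str, ...]] = {}
    cut_points: dict[str, tuple[float, ...]] = {}
    numeric = set(ds.schema.numeric)

    for j, name in enumerate(ds.schema.names):
        col = ds.values[name].to_numpy()
        if name in numeric:
            col = col.astype(float)
            present = ~np.isnan(col)
            if not present.any():
                warnings.warn(
                    f"numeric feature {name!r} is all-missing; "
                    "treated as a single interval",
                    stacklevel=2,
                )
                cuts: list[float] = []
            else:
                cuts = _mdl_cut_points(col[present], label_codes[present], n_classes)
            cut_points[name] = tuple(cuts)
            edges = [-math.inf] + cuts + [math.inf]
            labels_ = tuple(
                f"({edges[i]:g},{edges[i + 1]:g}]" for i in range(len(edges) - 1)
            )
            symbols[name] = labels_
            codes[present, j] = np.searchsorted(np.array(cuts), col[present], side="left")
        else:
            vals = ds.values[name].to_numpy(dtype=object)
            table: dict[str, int] = {}
            for i, v in enumerate(vals):
                if v is None:
                    continue
                codes[i, j] = table.setdefault(v, len(table))
            symbols[name] = tuple(table)

    return DiscretizedDataset(
        codes=codes,
        feature_names=ds.schema.names,
        symbols=symbols,
        cut_points=cut_points,
        label_codes=label_codes,
        label_symbols=label_symbols,
    )


# ---------------------------------------------------------------------------
# Rankers
# ---------------------------------------------------------------------------

def _make_ranking(dd: DiscretizedDataset, scores: list[float], method: str) -> FeatureRanking:
    order = sorted(range(dd.p), key=lambda j: (-scores[j], j))
    entries = tuple((dd.feature_names[j], float(scores[j])) for j in order)
    return FeatureRanking(entries=entries, method=method)


def _feature_class_tables(dd: DiscretizedDataset, j: int) -> ProbTables | None:
    f = dd.codes[:, j]
    keep = f != MISSING
    if not keep.any():
        return None
    return ProbTables.from_codes(f, dd.label_codes)


def info_gain_scores(dd: DiscretizedDataset) -> FeatureRanking:
    """Mutual information of each feature with the class, in bits."""
    scores = []
    for j in range(dd.p):
        pt = _feature_class_tables(dd, j)
        scores.append(0.0 if pt is None else _mutual_information(pt))
    return _make_ranking(dd, scores, "info_gain")


def symmetrical_uncertainty(a, b) -> float:
    """``2 MI(A,B) / (H(A) + H(B))`` in [0, 1]; 0 if both entropies vanish.

    Accepts arbitrary symbol vectors; rows missing in either are dropped.
    """
    a = np.asarray(a, dtype=object)
    b = np.asarray(b, dtype=object)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return _su_codes(_as_codes(a), _as_codes(b))


def _su_codes(ca: np.ndarray, cb: np.ndarray) -> float:
    keep = (ca != MISSING) & (cb != MISSING)
    ca, cb = ca[keep], cb[keep]
    if len(ca) == 0:
        return 0.0
    ha = _entropy_counts(np.bincount(ca))
    hb = _entropy_counts(np.bincount(cb))
    if ha + hb == 0.0:
        return 0.0
    pt = ProbTables.from_codes(ca, cb)
    return 2.0 * _mutual_information(pt) / (ha + hb)


def su_scores(dd: DiscretizedDataset) -> FeatureRanking:
    """Symmetrical uncertainty of each feature with the class."""
    scores = [_su_codes(dd.codes[:, j], dd.label_codes) for j in range(dd.p)]
    return _make_ranking(dd, scores, "sym_uncertainty")


def chi_squared_scores(dd: DiscretizedDataset) -> FeatureRanking:
    """Contingency chi-square of each feature against the class.

    The two-valued feature/class form generalizes to the full
    feature-value x class table: ``sum (O - E)^2 / E`` with expected counts
    from the margins; cells with expected count 0 contribute 0.
    """
    scores = []
    for j in range(dd.p):
        pt = _feature_class_tables(dd, j)
        if pt is None:
            scores.append(0.0)
            continue
        observed = pt.joint * pt.n
        expected = np.outer(pt.p_feature, pt.p_class) * pt.n
        with np.errstate(divide="ignore", invalid="ignore"):
            cells = np.where(expected > 0, (observed - expected) ** 2 / np.where(expected > 0, expected, 1.0), 0.0)
        scores.append(float(cells.sum()))
    return _make_ranking(dd, scores, "chi2")


# ---------------------------------------------------------------------------
# CFS
# ---------------------------------------------------------------------------

class _SUCache:
    """Lazily computed symmetrical-uncertainty correlations on a
    DiscretizedDataset (feature-class and feature-feature)."""

    def __init__(self, dd: DiscretizedDataset) -> None:
        self.dd = dd
        self._fc: dict[int, float] = {}
        self._ff: dict[tuple[int, int], float] = {}

    def feature_class(self, j: int) -> float:
        if j not in self._fc:
            self._fc[j] = _su_codes(self.dd.codes[:, j], self.dd.label_codes)
        return self._fc[j]

    def feature_feature(self, i: int, j: int) -> float:
        key = (i, j) if i < j else (j, i)
        if key not in self._ff:
            self._ff[key] = _su_codes(self.dd.codes[:, key[0]], self.dd.codes[:, key[1]])
        return self._ff[key]


def _merit_from_sums(k: int, sum_cf: float, sum_ff: float) -> float:
    if k == 0:
        return 0.0
    denom = math.sqrt(k + 2.0 * sum_ff)  # k + k(k-1)*mean_ff, pairs counted once
    return sum_cf / denom if denom > 0 else 0.0


def cfs_merit(dd: DiscretizedDataset, subset) -> float:
    """CFS merit ``k r_cf / sqrt(k + k(k-1) r_ff)`` of a feature subset.

    Correlations are symmetrical-uncertainty values; for a singleton the
    merit reduces to the feature-class correlation.
    """
    names = list(subset)
    if not names:
        raise ValueError("subset must be non-empty")
    idx = [dd._index[name] for name in names]
    cache = _SUCache(dd)
    sum_cf = sum(cache.feature_class(j) for j in idx)
    sum_ff = sum(
        cache.feature_feature(a, b) for a, b in itertools.combinations(idx, 2)
    )
    return _merit_from_sums(len(idx), sum_cf, sum_ff)


def cfs_select(dd: DiscretizedDataset, stale_limit: int = 5) -> FeatureSubset:
    """Best-first forward search for the subset maximizing CFS merit.

    Expands the open node of highest merit, adding one feature at a time;
    terminates after ``stale_limit`` consecutive expansions that fail to
    improve the best merit found.
    """
    cache = _SUCache(dd)
    p = dd.p

    # node: (neg merit, tie counter, frozenset of indices, sum_cf, sum_ff)
    counter = itertools.count()
    start = (0.0, next(counter), frozenset(), 0.0, 0.0)
    open_heap = [start]
    visited: set[frozenset] = {frozenset()}
    best_merit = -math.inf
    best_set: frozenset = frozenset()
    stale = 0

    while open_heap and stale < stale_limit:
        neg_merit, _, node, sum_cf, sum_ff = heapq.heappop(open_heap)
        improved = False
        for j in range(p):
            if j in node:
                continue
            child = node | {j}
            if child in visited:
                continue
            visited.add(child)
            c_cf = sum_cf + cache.feature_class(j)
            c_ff = sum_ff + sum(cache.feature_feature(i, j) for i in node)
            merit = _merit_from_sums(len(child), c_cf, c_ff)
            heapq.heappush(open_heap, (-merit, next(counter), child, c_cf, c_ff))
            if merit > best_merit + 1e-12:
                best_merit = merit
                best_set = child
                improved = True
        stale = 0 if improved else stale + 1

    if not best_set:  # all merits were 0; fall back to the single best feature
        j = max(range(p), key=lambda j: (cache.feature_class(j), -j))
        best_set = frozenset({j})
        best_merit = cache.feature_class(j)
    names = frozenset(dd.feature_names[j] for j in best_set)
    return FeatureSubset(features=names, method="cfs", quality=float(best_merit))


# ---------------------------------------------------------------------------
# Consistency
# ---------------------------------------------------------------------------

def inconsistency_rate(dd: DiscretizedDataset, subset, denominator: str = "instances") -> float:
    """Fraction of instances not explained by the majority class of their
    identical feature pattern.

    For each distinct value pattern of ``subset``, the inconsistency count
    is (occurrences − occurrences in the majority class); the rate sums
    these counts and divides by the number of instances (or by the number
    of distinct patterns with ``denominator="patterns"``).  A missing cell
    is a pattern symbol of its own: patterns must match exactly.
    """
    names = list(subset)
    if not names:
        raise ValueError("subset must be non-empty")
    idx = [dd._index[name] for name in names]
    return _inconsistency_idx(dd, idx, denominator)


def _inconsistency_idx(dd: DiscretizedDataset, idx, denominator: str = "instances") -> float:
    sub = dd.codes[:, idx]
    groups: dict[bytes, np.ndarray] = {}
    keys = [row.tobytes() for row in sub]
    pattern_counts: dict[bytes, np.ndarray] = {}
    n_classes = len(dd.label_symbols)
    for key, c in zip(keys, dd.label_codes):
        if key not in pattern_counts:
            pattern_counts[key] = np.zeros(n_classes, dtype=np.int64)
        pattern_counts[key][c] += 1
    total = sum(int(v.sum() - v.max()) for v in pattern_counts.values())
    if denominator == "instances":
        return total / dd.n
    elif denominator == "patterns":
        return total / len(pattern_counts)
    raise ValueError(f"unknown denominator {denominator!r}")


def consistency_select(
    dd: DiscretizedDataset,
    exhaustive_limit: int = 15,
    stale_limit: int = 5,
    denominator: str = "instances",
) -> FeatureSubset:
    """Smallest subset whose inconsistency rate is at most the full-set rate.

    Exhaustive size-ordered enumeration for p <= ``exhaustive_limit``;
    best-first forward search otherwise.  Ties at equal size break on lower
    inconsistency, then lexicographic feature order.
    """
    p = dd.p
    full_rate = _inconsistency_idx(dd, list(range(p)), denominator)
    tol = 1e-12

    def lex_key(idx_tuple):
        return tuple(dd.feature_names[j] for j in sorted(idx_tuple))

    if p <= exhaustive_limit:
        for size in range(1, p + 1):
            qualifying = []
            for combo in itertools.combinations(range(p), size):
                rate = _inconsistency_idx(dd, list(combo), denominator)
                if rate <= full_rate + tol:
                    qualifying.append((rate, lex_key(combo), combo))
            if qualifying:
                rate, _, combo = min(qualifying)
                names = frozenset(dd.feature_names[j] for j in combo)
                return FeatureSubset(
                    features=names, method="consistency", quality=1.0 - rate
                )
        combo = tuple(range(p))
        return FeatureSubset(
            features=frozenset(dd.feature_names), method="consistency",
            quality=1.0 - full_rate,
        )

    # best-first forward search on inconsistency rate
    counter = itertools.count()
    heap = [(1.0, 0, next(counter), frozenset())]
    visited: set[frozenset] = {frozenset()}
    best: tuple[int, float, tuple, frozenset] | None = None  # (size, rate, lex, set)
    stale = 0
    while heap and stale < stale_limit:
        rate0, _, _, node = heapq.heappop(heap)
        improved = False
        for j in range(p):
            if j in node:
                continue
            child = node | {j}
            if child in visited:
                continue
            visited.add(child)
            rate = _inconsistency_idx(dd, sorted(child), denominator)
            if rate <= full_rate + tol:
                cand = (len(child), rate, lex_key(child), child)
                if best is None or cand[:3] < best[:3]:
                    best = cand
                    improved = True
                continue  # no need to expand below a qualifying node
            if best is None or len(child) < best[0]:
                heapq.heappush(heap, (rate, len(child), next(counter), child))
                if rate < rate0 - tol:
                    improved = True
        stale = 0 if improved else stale + 1

    if best is None:
        combo = frozenset(range(p))
        best = (p, full_rate, lex_key(combo), combo)
    names = frozenset(dd.feature_names[j] for j in best[3])
    return FeatureSubset(
        features=names, method="consistency", quality=1.0 - best[1]
    )
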