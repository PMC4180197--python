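"""Experimental protocols: baseline, ranker sweep, method comparison,
pairwise subtype clustering, and the k-sweep.

Every protocol follows the same discipline: filters see the class labels
(they are supervised), the Gower/PAM stage never does (labels live outside
the feature table), and purity uses the labels again as ground truth.
Rankers (chi-squared, information gain, symmetrical uncertainty) are
evaluated by sweeping the top-s ranked features for every s from 2 to p
and keeping the smallest s that attains the maximum purity; subset
selectors (CFS, consistency) are evaluated on the subset they return.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .data_model import FeatureRanking, MixedDataset, subset_by_classes
from .evaluation import PurityReport, contingency, purity
from .filters import (
    DiscretizedDataset,
    cfs_select,
    chi_squared_scores,
    consistency_select,
    discretize_mdl,
    info_gain_scores,
    su_scores,
)
from .gower import GowerParts, gower_parts
from .pam import Clustering, pam

__all__ = [
    "RANKER_METHODS",
    "SUBSET_METHODS",
    "ALL_METHODS",
    "RecoveryOutcome",
    "recovery_replicate",
    "SweepCurve",
    "MethodResult",
    "PairwiseReport",
    "KSweepReport",
    "baseline_purity",
    "ranker_sweep",
    "run_method",
    "pairwise_experiment",
    "k_sweep",
]

RANKER_METHODS = {
    "chi2": chi_squared_scores,
    "ig": info_gain_scores,
    "su": su_scores,
}
SUBSET_METHODS = {"cfs": cfs_select, "consistency": consistency_select}
ALL_METHODS = ("ig", "su", "cfs", "consistency", "chi2")


@dataclass(frozen=True)
class SweepCurve:
    """Purity of the top-s ranked features for each subset size s."""

    points: tuple[tuple[int, float], ...]  # (size, purity)
    feature_order: tuple[str, ...]  # features in rank order
    best_size: int
    best_purity: float
    method: str
    k: int
    transform: str

    @property
    def best_features(self) -> tuple[str, ...]:
        return self.feature_order[: self.best_size]


@dataclass(frozen=True)
class MethodResult:
    """One comparison-table row: method, subset size, purity.

    ``purity`` is None when the method selected a single feature, for
    which no distance matrix (hence no clustering) can be computed.
    """

    method: str
    n_features: int
    features: tuple[str, ...]
    purity: float | None
    quality: float | None = None  # selector's own score (CFS merit etc.)


@dataclass(frozen=True)
class PairwiseReport:
    """Per class pair x method purities at k = 2, plus per-pair all-feature
    baselines."""

    pairs: tuple[tuple[str, str], ...]
    results: dict[tuple[str, str], dict[str, MethodResult]]
    baselines: dict[tuple[str, str], float]
    transform: str


@dataclass(frozen=True)
class KSweepReport:
    """Purity grid over k values x methods, plus per-k all-feature
    baselines."""

    k_values: tuple[int, ...]
    results: dict[int, dict[str, MethodResult]]
    baselines: dict[int, float]
    transform: str


def _purity_of(cl: Clustering, labels) -> PurityReport:
    return purity(contingency(cl.assignment, labels))


def _distance_from_sums(num: np.ndarray, den: np.ndarray, transform: str) -> np.ndarray:
    if (den == 0).any():
        i, j = np.argwhere(den == 0)[0]
        raise ValueError(f"rows {i} and {j} share no comparable feature")
    s = np.clip(num / den, 0.0, 1.0)
    d = np.sqrt(1.0 - s) if transform == "sqrt" else 1.0 - s
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def baseline_purity(
    ds: MixedDataset, k: int, transform: str = "sqrt", parts: GowerParts | None = None
) -> PurityReport:
    """Purity of PAM(k) on Gower distances over every feature."""
    if parts is None:
        parts = gower_parts(ds)
    d = parts.distance_matrix(ds.schema.names, transform=transform)
    return _purity_of(pam(d, k), ds.labels)


def ranker_sweep(
    ds: MixedDataset,
    ranking: FeatureRanking,
    k: int,
    transform: str = "sqrt",
    parts: GowerParts | None = None,
) -> SweepCurve:
    """Cluster the top-s ranked features for every s in 2..p.

    The per-feature Gower contributions are accumulated incrementally, so
    the whole sweep costs one full distance matrix plus one PAM run per
    size.  The best subset is the smallest s attaining the maximum purity.
    """
    if set(ranking.features) != set(ds.schema.names):
        raise ValueError("ranking must cover exactly the dataset's features")
    if parts is None:
        parts = gower_parts(ds)
    index = {f: i for i, f in enumerate(parts.features)}
    order = [index[f] for f in ranking.features]

    num = parts.numer[order[0]].copy()
    den = parts.denom[order[0]].copy()
    points: list[tuple[int, float]] = []
    for s in range(2, ds.p + 1):
        j = order[s - 1]
        num += parts.numer[j]
        den += parts.denom[j]
        d = _distance_from_sums(num, den, transform)
        points.append((s, _purity_of(pam(d, k), ds.labels).value))

    best_size, best_purity = min(points, key=lambda t: (-t[1], t[0]))
    return SweepCurve(
        points=tuple(points),
        feature_order=ranking.features,
        best_size=best_size,
        best_purity=best_purity,
        method=ranking.method,
        k=k,
        transform=transform,
    )


def _subset_purity(
    ds: MixedDataset, features, k: int, transform: str, parts: GowerParts
) -> float | None:
    if len(features) < 2:
        return None  # single feature: distance matrix undefined
    d = parts.distance_matrix(
        tuple(f for f in ds.schema.names if f in set(features)), transform=transform
    )
    return _purity_of(pam(d, k), ds.labels).value


def run_method(
    ds: MixedDataset,
    method: str,
    k: int,
    transform: str = "sqrt",
    dd: DiscretizedDataset | None = None,
    parts: GowerParts | None = None,
) -> MethodResult:
    """Apply one filter method end to end and report its purity at k."""
    if method not in RANKER_METHODS and method not in SUBSET_METHODS:
        raise KeyError(f"unknown method {method!r}; use one of {ALL_METHODS}")
    if dd is None:
        dd = discretize_mdl(ds)
    if parts is None:
        parts = gower_parts(ds)
    if method in RANKER_METHODS:
        ranking = RANKER_METHODS[method](dd)
        curve = ranker_sweep(ds, ranking, k, transform=transform, parts=parts)
        return MethodResult(
            method=method,
            n_features=curve.best_size,
            features=curve.best_features,
            purity=curve.best_purity,
        )
    subset = SUBSET_METHODS[method](dd)
    feats = tuple(f for f in ds.schema.names if f in subset.features)
    return MethodResult(
        method=method,
        n_features=len(feats),
        features=feats,
        purity=_subset_purity(ds, feats, k, transform, parts),
        quality=subset.quality,
    )


def pairwise_experiment(
    ds: MixedDataset, methods=ALL_METHODS, k: int = 2, transform: str = "sqrt"
) -> PairwiseReport:
    """Cluster every unordered pair of subtypes at k = 2, with per-pair
    feature re-selection and an all-features baseline."""
    classes = ds.classes
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    pairs = tuple(itertools.combinations(classes, 2))
    results: dict[tuple[str, str], dict[str, MethodResult]] = {}
    baselines: dict[tuple[str, str], float] = {}
    for pair in pairs:
        sub = subset_by_classes(ds, pair)
        dd = discretize_mdl(sub)
        parts = gower_parts(sub)
        baselines[pair] = baseline_purity(sub, k, transform, parts=parts).value
        results[pair] = {
            m: run_method(sub, m, k, transform=transform, dd=dd, parts=parts)
            for m in methods
        }
    return PairwiseReport(
        pairs=pairs, results=results, baselines=baselines, transform=transform
    )


def k_sweep(
    ds: MixedDataset,
    methods=ALL_METHODS,
    k_values=(2, 3, 4, 5, 6, 10, 20),
    transform: str = "sqrt",
) -> KSweepReport:
    """Purity across cluster counts.

    Ranker subsets are re-selected per k (their sweep optimizes purity at
    that k); CFS and consistency subsets depend only on the labels, so
    they are selected once and reused for every k.
    """
    k_values = tuple(int(k) for k in k_values)
    if any(not 1 <= k <= ds.n for k in k_values):
        raise ValueError(f"k values must lie in [1, {ds.n}]")
    dd = discretize_mdl(ds)
    parts = gower_parts(ds)
    fixed: dict[str, tuple[tuple[str, ...], float]] = {}
    for m in methods:
        if m in SUBSET_METHODS:
            subset = SUBSET_METHODS[m](dd)
            feats = tuple(f for f in ds.schema.names if f in subset.features)
            fixed[m] = (feats, subset.quality)
    rankings = {m: RANKER_METHODS[m](dd) for m in methods if m in RANKER_METHODS}

    results: dict[int, dict[str, MethodResult]] = {}
    baselines: dict[int, float] = {}
    for k in k_values:
        baselines[k] = baseline_purity(ds, k, transform, parts=parts).value
        row: dict[str, MethodResult] = {}
        for m in methods:
            if m in fixed:
                feats, quality = fixed[m]
                row[m] = MethodResult(
                    method=m,
                    n_features=len(feats),
                    features=feats,
                    purity=_subset_purity(ds, feats, k, transform, parts),
                    quality=quality,
                )
            else:
                curve = ranker_sweep(ds, rankings[m], k, transform=transform, parts=parts)
                row[m] = MethodResult(
                    method=m,
                    n_features=curve.best_size,
                    features=curve.best_features,
                    purity=curve.best_purity,
                )
        results[k] = row
    return KSweepReport(
        k_values=k_values, results=results, baselines=baselines, transform=transform
    )


# ---------------------------------------------------------------------------
# Parameter recovery on planted data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryOutcome:
    """Scorecard of one planted-data replicate: did the pipeline recover
    what the generator planted?

    ``pairwise_wins`` holds one flag per subtype pair (best method purity at
    k=2 at least the pair's all-features baseline); single-feature
    selections are excluded from bests and means, as their purity is not
    computed.
    """

    seed: int
    informative_in_top: dict[str, bool]  # per ranker
    baseline: float
    sweep_best: float
    sweep_beats_baseline: bool
    pairwise_wins: tuple[bool, ...]
    mean_purity_low_k: float
    mean_purity_high_k: float
    k_ascending: bool


def recovery_replicate(
    seed: int,
    top_m: int = 12,
    k: int = 4,
    k_span: tuple[int, int] = (2, 20),
    delta: float | None = None,
    methods=ALL_METHODS,
) -> RecoveryOutcome:
    """Run the full study once on a fresh draw from the default generator.

    Checks, per replicate: the rankers place every planted informative
    numeric feature within the top ``top_m``; the sweep-selected subset
    beats the all-features baseline at the true k; each subtype pair's best
    filtered purity reaches its baseline at k = 2; and mean purity over
    methods rises from the low to the high end of ``k_span``.
    """
    from .synthetic import SyntheticConfig, generate

    cfg = SyntheticConfig(seed=seed) if delta is None else SyntheticConfig(
        seed=seed, delta=delta)
    ds, truth = generate(cfg)
    dd = discretize_mdl(ds)
    parts = gower_parts(ds)

    planted = truth.informative_numeric
    in_top: dict[str, bool] = {}
    curves: dict[str, SweepCurve] = {}
    for m in ("ig", "su"):
        ranking = RANKER_METHODS[m](dd)
        in_top[m] = planted <= set(ranking.top(top_m))
        curves[m] = ranker_sweep(ds, ranking, k, parts=parts)

    base = baseline_purity(ds, k, parts=parts).value
    sweep_best = max(c.best_purity for c in curves.values())

    pw = pairwise_experiment(ds, methods=methods, k=2)
    wins = []
    for pair in pw.pairs:
        vals = [r.purity for r in pw.results[pair].values() if r.purity is not None]
        wins.append(bool(vals) and max(vals) >= pw.baselines[pair])

    ks = k_sweep(ds, methods=methods, k_values=k_span)
    def mean_at(kv: int) -> float:
        vals = [r.purity for r in ks.results[kv].values() if r.purity is not None]
        return float(np.mean(vals))
    lo, hi = mean_at(k_span[0]), mean_at(k_span[1])

    return RecoveryOutcome(
        seed=seed,
        informative_in_top=in_top,
        baseline=base,
        sweep_best=sweep_best,
        sweep_beats_baseline=sweep_best > base,
        pairwise_wins=tuple(wins),
        mean_purity_low_k=lo,
        mean_purity_high_k=hi,
        k_ascending=hi >= lo,
    )
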