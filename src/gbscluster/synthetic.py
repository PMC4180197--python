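"""Synthetic mixed-type datasets with planted subtype structure.

The generator emulates the statistical shape of a four-subtype
Guillain-Barre cohort: 129 cases split 20/37/59/13 across AIDP, AMAN,
AMSAN and Miller-Fisher, described by 156 features (128 numeric — nerve
conduction and CSF measurements — and 28 categorical clinical findings).
A small planted set of numeric features separates the subtypes
(class-conditional Gaussians with means spaced ``delta`` within-class
standard deviations apart, class order randomized per feature); a few
categorical features are tilted toward a class-specific symbol; some
features are noisy copies of informative ones (redundancy); the rest are
pure noise.  Ground truth (labels, informative set, redundancy map) is
returned alongside so parameter-recovery experiments can score
themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import FeatureSchema, MixedDataset

__all__ = ["SyntheticConfig", "GroundTruth", "generate", "make_worked_example"]

DEFAULT_CLASS_NAMES = ("AIDP", "AMAN", "AMSAN", "MF")


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the planted-cluster generator; defaults mirror the cohort
    the pipeline is designed around (129 x 156, unbalanced subtypes)."""

    class_sizes: tuple[int, ...] = (20, 37, 59, 13)
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
    n_informative_numeric: int = 7
    n_redundant: int = 9
    n_noise_numeric: int = 112
    n_categorical: int = 28
    n_informative_categorical: int = 3
    delta: float = 2.0  # between-class mean separation, within-class SD units
    categorical_tilt: float = 0.6  # P(class-specific symbol | class)
    redundant_correlation: float = 0.9
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.class_sizes):
            raise ValueError("class sizes must be positive")
        if len(self.class_sizes) != len(self.class_names):
            raise ValueError("class_sizes and class_names lengths differ")
        if min(self.n_informative_numeric, self.n_redundant,
               self.n_noise_numeric) < 0 or self.n_categorical < 0:
            raise ValueError("feature counts must be nonnegative")
        if self.n_informative_categorical > self.n_categorical:
            raise ValueError("more informative categoricals than categoricals")
        if self.n_redundant > 0 and self.n_informative_numeric == 0:
            raise ValueError("redundant copies need informative sources")
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must be in [0, 1)")
        if not 0 < self.redundant_correlation < 1:
            raise ValueError("redundant correlation must be in (0, 1)")

    @property
    def n(self) -> int:
        return sum(self.class_sizes)

    @property
    def n_numeric(self) -> int:
        return self.n_informative_numeric + self.n_redundant + self.n_noise_numeric

    @property
    def p(self) -> int:
        return self.n_numeric + self.n_categorical


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: labels, the informative feature names, and which
    feature each redundant copy was derived from."""

    labels: tuple[str, ...]
    informative_numeric: frozenset[str]
    informative_categorical: frozenset[str]
    redundancy_map: dict[str, str] = field(default_factory=dict)

    @property
    def informative(self) -> frozenset[str]:
        return self.informative_numeric | self.informative_categorical


def generate(cfg: SyntheticConfig) -> tuple[MixedDataset, GroundTruth]:
    """Draw one dataset from the planted-cluster model (reproducible from
    ``cfg.seed``)."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    n_classes = len(cfg.class_sizes)
    labels = np.repeat(np.array(cfg.class_names, dtype=object),
                       np.array(cfg.class_sizes))
    class_idx = np.repeat(np.arange(n_classes), np.array(cfg.class_sizes))

    columns: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    groups: dict[str, str | None] = {}
    names: list[str] = []

    def add(name: str, kind: str, group: str, col: np.ndarray) -> None:
        names.append(name)
        kinds[name] = kind
        groups[name] = group
        columns[name] = col

    # informative numerics: class-specific means, unit within-class SD;
    # modelled on nerve conduction measurements (all-NCT in spirit)
    informative_numeric: list[str] = []
    for i in range(cfg.n_informative_numeric):
        name = f"nct_sig{i + 1:02d}"
        means = cfg.delta * rng.permutation(n_classes)
        col = means[class_idx] + rng.standard_normal(n)
        add(name, "numeric", "nct", col)
        informative_numeric.append(name)

    # redundant copies: source + Gaussian perturbation tuned for the target
    # correlation on the source's empirical variance
    redundancy_map: dict[str, str] = {}
    for i in range(cfg.n_redundant):
        src = informative_numeric[i % cfg.n_informative_numeric]
        name = f"nct_red{i + 1:02d}"
        src_col = columns[src]
        sd = float(np.std(src_col))
        eps_sd = sd * np.sqrt(1.0 / cfg.redundant_correlation**2 - 1.0)
        add(name, "numeric", "nct", src_col + eps_sd * rng.standard_normal(n))
        redundancy_map[name] = src

    # noise numerics: one shared distribution, no class information;
    # split across nerve-conduction, CSF and clinical groups
    n_csf = min(4, cfg.n_noise_numeric)
    n_clin_num = min(3, max(cfg.n_noise_numeric - n_csf, 0))
    for i in range(cfg.n_noise_numeric):
        if i < n_csf:
            name, group = f"csf{i + 1}", "csf"
        elif i < n_csf + n_clin_num:
            name, group = f"clin_num{i - n_csf + 1}", "clinical"
        else:
            name, group = f"nct_noise{i - n_csf - n_clin_num + 1:03d}", "nct"
        loc, scale = rng.normal(0, 3), rng.uniform(0.5, 3.0)
        add(name, "numeric", group, loc + scale * rng.standard_normal(n))

    # categoricals: informative ones tilt toward a class-specific symbol
    informative_categorical: list[str] = []
    for i in range(cfg.n_categorical):
        informative = i < cfg.n_informative_categorical
        name = f"clin_cat{i + 1:02d}"
        if informative:
            n_symbols = n_classes
            symbol_of_class = rng.permutation(n_symbols)
            probs = np.full((n_classes, n_symbols),
                            (1.0 - cfg.categorical_tilt) / (n_symbols - 1))
            probs[np.arange(n_classes), symbol_of_class] = cfg.categorical_tilt
            col = np.array(
                [f"L{rng.choice(n_symbols, p=probs[c])}" for c in class_idx],
                dtype=object,
            )
            informative_categorical.append(name)
        else:
            n_symbols = int(rng.integers(2, 6))
            col = np.array(
                [f"L{s}" for s in rng.integers(0, n_symbols, size=n)],
                dtype=object,
            )
        add(name, "categorical", "clinical", col)

    if cfg.missing_rate > 0:
        for name in names:
            mask = rng.random(n) < cfg.missing_rate
            if kinds[name] == "numeric":
                col = columns[name].astype(float)
                col[mask] = np.nan
                columns[name] = col
            else:
                col = columns[name].astype(object)
                col[mask] = None
                columns[name] = col

    schema = FeatureSchema(
        names=tuple(names), kinds=kinds, class_column="subtype", groups=groups
    )
    values = pd.DataFrame(columns, columns=names)
    ds = MixedDataset(values=values, labels=labels, schema=schema)
    truth = GroundTruth(
        labels=tuple(labels.tolist()),
        informative_numeric=frozenset(informative_numeric),
        informative_categorical=frozenset(informative_categorical),
        redundancy_map=redundancy_map,
    )
    return ds, truth


def make_worked_example() -> tuple[np.ndarray, np.ndarray]:
    """The fixed 51-object, 3-cluster, 3-class purity illustration.

    Cluster sizes 15/11/25, class totals 12/17/22, cell counts
    (0,14,1 / 9,2,0 / 3,1,21); its purity is (9+14+21)/51 = 44/51.
    """
    cells = {
        (1, "A"): 0, (1, "B"): 14, (1, "C"): 1,
        (2, "A"): 9, (2, "B"): 2, (2, "C"): 0,
        (3, "A"): 3, (3, "B"): 1, (3, "C"): 21,
    }
    assignment: list[int] = []
    labels: list[str] = []
    for (cluster, cls), count in cells.items():
        assignment.extend([cluster] * count)
        labels.extend([cls] * count)
    return np.array(assignment), np.array(labels, dtype=object)
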