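"""Mixed-type clinical dataset container, schema, and CSV/sidecar I/O.

The pipeline operates on tables that mix numeric measurements (nerve
conduction amplitudes, latencies, CSF counts ...) with categorical clinical
findings.  A :class:`FeatureSchema` declares, per column, how each feature
is to be treated downstream — as a quantitative variable, a symmetric
categorical one, or an asymmetric (presence/absence) binary one — and names
the class column holding the diagnostic subtype.  Class labels are kept
outside the feature table so no clustering step can accidentally see them.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureKind",
    "FeatureSchema",
    "MixedDataset",
    "FeatureRanking",
    "FeatureSubset",
    "SchemaError",
    "ParseError",
    "load_dataset",
    "write_dataset",
    "select_features",
    "subset_by_classes",
]

#: tokens interpreted as a missing cell when reading CSV data
MISSING_TOKENS = {"", "NA"}

VALID_KINDS = ("numeric", "categorical", "asymmetric_binary")
VALID_GROUPS = (None, "clinical", "nct", "csf")


class SchemaError(ValueError):
    """Schema and data disagree (missing/extra/duplicated columns, bad kind)."""


class ParseError(ValueError):
    """A cell could not be parsed according to its declared kind."""


@dataclass(frozen=True)
class FeatureSchema:
    """Per-feature typing information plus the name of the class column.

    ``kinds`` maps feature name -> one of ``numeric``, ``categorical``,
    ``asymmetric_binary``; ``groups`` optionally tags features as
    ``clinical``, ``nct`` (nerve conduction test) or ``csf``.
    """

    names: tuple[str, ...]
    kinds: dict[str, str]
    class_column: str
    groups: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise SchemaError("duplicate feature names in schema")
        if self.class_column in self.names:
            raise SchemaError(
                f"class column {self.class_column!r} also declared as a feature"
            )
        for name in self.names:
            kind = self.kinds.get(name)
            if kind not in VALID_KINDS:
                raise SchemaError(f"feature {name!r} has invalid kind {kind!r}")
            if self.groups.get(name) not in VALID_GROUPS:
                raise SchemaError(
                    f"feature {name!r} has invalid group {self.groups.get(name)!r}"
                )
        # normalize so schemas compare equal regardless of how groups were given
        object.__setattr__(
            self, "groups", {n: self.groups.get(n) for n in self.names}
        )

    @property
    def numeric(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if self.kinds[n] == "numeric")

    @property
    def categorical(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if self.kinds[n] == "categorical")

    @property
    def asymmetric_binary(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if self.kinds[n] == "asymmetric_binary")

    def restrict(self, names: Iterable[str]) -> "FeatureSchema":
        """Schema for a column-projected dataset, preserving original order."""
        keep = set(names)
        unknown = keep - set(self.names)
        if unknown:
            raise KeyError(f"unknown feature(s): {sorted(unknown)}")
        sub = tuple(n for n in self.names if n in keep)
        return FeatureSchema(
            names=sub,
            kinds={n: self.kinds[n] for n in sub},
            class_column=self.class_column,
            groups={n: self.groups.get(n) for n in sub},
        )


@dataclass
class MixedDataset:
    """An n x p mixed-type table with class labels and a schema.

    ``values`` is a pandas DataFrame whose numeric columns are float64 (NaN
    marks missing) and whose categorical / asymmetric-binary columns are
    object dtype holding strings (None marks missing).  ``labels`` is the
    length-n vector of class symbols, stored separately from the features.
    """

    values: pd.DataFrame
    labels: np.ndarray
    schema: FeatureSchema

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.n < 2:
            raise ValueError(f"need at least 2 rows, got {self.n}")
        if self.p < 1:
            raise ValueError("need at least 1 feature")
        if len(self.labels) != self.n:
            raise ValueError(
                f"labels length {len(self.labels)} != number of rows {self.n}"
            )
        if tuple(self.values.columns) != self.schema.names:
            raise SchemaError("dataset columns do not match schema names")
        for name in self.schema.numeric:
            col = self.values[name].to_numpy()
            finite = np.isfinite(col[~np.isnan(col)])
            if not finite.all():
                raise ValueError(f"non-finite value in numeric column {name!r}")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> tuple[str, ...]:
        """Distinct class symbols in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return tuple(seen)

    def class_counts(self) -> dict[str, int]:
        return {c: int((self.labels == c).sum()) for c in self.classes}


@dataclass(frozen=True)
class FeatureRanking:
    """Ordered (feature, score) list from a ranking filter.

    Scores are non-increasing; ties keep the original column order so runs
    are deterministic.
    """

    entries: tuple[tuple[str, float], ...]
    method: str

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(a < b - 1e-12 for a, b in zip(scores, scores[1:])):
            raise ValueError("ranking scores must be non-increasing")

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(f for f, _ in self.entries)

    def top(self, s: int) -> tuple[str, ...]:
        return self.features[:s]


@dataclass(frozen=True)
class FeatureSubset:
    """Unordered selected feature set with the quality its selector reports.

    For CFS ``quality`` is the merit M_S; for the consistency method it is
    the consistency value 1 − inconsistency rate.
    """

    features: frozenset[str]
    method: str
    quality: float

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("feature subset must be non-empty")


# ---------------------------------------------------------------------------
# I/O: CSV + plain-text schema sidecar
# ---------------------------------------------------------------------------

def read_schema(schema_path: str) -> FeatureSchema:
    """Parse a sidecar: one `name kind [group]` line per feature plus
    `class: <name>`."""
    names: list[str] = []
    kinds: dict[str, str] = {}
    groups: dict[str, str | None] = {}
    class_column: str | None = None
    with open(schema_path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("class:"):
                class_column = line.split(":", 1)[1].strip()
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise SchemaError(f"{schema_path}:{lineno}: malformed line {line!r}")
            names.append(parts[0])
            kinds[parts[0]] = parts[1]
            groups[parts[0]] = parts[2] if len(parts) == 3 else None
    if class_column is None:
        raise SchemaError(f"{schema_path}: no `class:` line")
    return FeatureSchema(tuple(names), kinds, class_column, groups)


def write_schema(schema: FeatureSchema, schema_path: str) -> None:
    with open(schema_path, "w", encoding="utf-8") as fh:
        fh.write(f"class: {schema.class_column}\n")
        for name in schema.names:
            group = schema.groups.get(name)
            if group:
                fh.write(f"{name} {schema.kinds[name]} {group}\n")
            else:
                fh.write(f"{name} {schema.kinds[name]}\n")


def _parse_columns(raw: pd.DataFrame, schema: FeatureSchema) -> pd.DataFrame:
    cols: dict[str, object] = {}
    for name in schema.names:
        col = raw[name].astype(object)
        is_missing = col.isna() | col.astype(str).str.strip().isin(MISSING_TOKENS)
        if schema.kinds[name] == "numeric":
            parsed = np.full(len(col), np.nan)
            for i, (miss, cell) in enumerate(zip(is_missing, col)):
                if miss:
                    continue
                try:
                    parsed[i] = float(cell)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"row {i}, column {name!r}: cannot parse {cell!r} as numeric"
                    ) from None
            cols[name] = parsed
        else:
            sym = np.array(
                [None if miss else str(c) for miss, c in zip(is_missing, col)],
                dtype=object,
            )
            cols[name] = sym
    return pd.DataFrame(cols, columns=list(schema.names))


def load_dataset(data_path: str, schema_path: str) -> MixedDataset:
    """Read a CSV (header row) plus its schema sidecar into a MixedDataset."""
    schema = read_schema(schema_path)
    raw = pd.read_csv(data_path, dtype=object, keep_default_na=False)
    expected = set(schema.names) | {schema.class_column}
    got = set(raw.columns)
    if expected != got:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        raise SchemaError(
            f"schema mismatch: missing columns {missing}, extra columns {extra}"
        )
    labels = raw[schema.class_column].astype(str).to_numpy(dtype=object)
    values = _parse_columns(raw, schema)
    return MixedDataset(values=values, labels=labels, schema=schema)


def write_dataset(ds: MixedDataset, data_path: str, schema_path: str) -> None:
    """Write CSV + sidecar in the same form load_dataset reads (round-trips)."""
    write_schema(ds.schema, schema_path)
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(list(ds.schema.names) + [ds.schema.class_column])
    numeric = set(ds.schema.numeric)
    columns = {name: ds.values[name].to_numpy() for name in ds.schema.names}
    for i in range(ds.n):
        row: list[str] = []
        for name in ds.schema.names:
            cell = columns[name][i]
            if name in numeric:
                row.append("NA" if np.isnan(cell) else repr(float(cell)))
            else:
                row.append("NA" if cell is None else str(cell))
        row.append(str(ds.labels[i]))
        writer.writerow(row)
    with open(data_path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Subsetting
# ---------------------------------------------------------------------------

def select_features(ds: MixedDataset, names: Iterable[str]) -> MixedDataset:
    """Column-project a dataset onto ``names`` (labels and n unchanged).

    Distance computation needs at least two features, so fewer than two
    names is rejected.
    """
    names = set(names)
    if ds.schema.class_column in names:
        raise KeyError(
            f"class column {ds.schema.class_column!r} is not a feature"
        )
    unknown = names - set(ds.schema.names)
    if unknown:
        raise KeyError(f"unknown feature(s): {sorted(unknown)}")
    if len(names) < 2:
        raise ValueError(
            f"need at least 2 features for distance computation, got {len(names)}"
        )
    schema = ds.schema.restrict(names)
    return MixedDataset(
        values=ds.values[list(schema.names)].copy(),
        labels=ds.labels.copy(),
        schema=schema,
    )


def subset_by_classes(ds: MixedDataset, classes: Sequence[str]) -> MixedDataset:
    """Rows restricted to a pair of distinct classes (pairwise experiments)."""
    if len(classes) != 2 or classes[0] == classes[1]:
        raise KeyError(f"need two distinct classes, got {tuple(classes)}")
    present = set(ds.classes)
    for c in classes:
        if c not in present:
            raise KeyError(f"unknown class {c!r}; dataset has {sorted(present)}")
    mask = np.isin(ds.labels, list(classes))
    return MixedDataset(
        values=ds.values.loc[mask].reset_index(drop=True),
        labels=ds.labels[mask],
        schema=ds.schema,
    )
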