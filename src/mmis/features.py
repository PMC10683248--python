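"""Model-ready feature matrices: selection, KNN imputation, normalization.

Annotated variants become a variants x features numeric matrix (booleans as
0/1, integers as floats, missing as NaN). Missing cells are filled by
k-nearest-neighbour imputation and features are min-max scaled to [0,1],
with all state fitted on training rows only so that held-out data can be
transformed without leakage.

Imputation convention: the distance between two partially observed rows is
the Euclidean distance over mutually observed features, rescaled by
sqrt(n_features / n_mutually_observed) (the standard incomplete-data KNN
distance). A missing cell is replaced by the unweighted mean of that feature
over the k nearest donor rows that observe it; donors tied with the k-th
distance are all included, so the result never depends on row order.
Imputation precedes normalization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotatedVariant, AnnotationSchema, MISSING_TOKEN


class FeatureError(ValueError):
    """Configuration or contract violation in the feature pipeline."""


@dataclass(frozen=True)
class FeatureSpec:
    """Ordered feature selection drawn from an annotation schema.

    ``variant`` tags whether this is the full feature set or the subset
    with mitochondria-specific fields removed.
    """

    feature_names: tuple[str, ...]
    variant: str = "full"

    def __post_init__(self) -> None:
        if len(set(self.feature_names)) != len(self.feature_names):
            raise FeatureError("duplicate feature names in spec")
        if self.variant not in ("full", "no_mito_specific"):
            raise FeatureError(f"unknown spec variant {self.variant!r}")

    def __len__(self) -> int:
        return len(self.feature_names)

    @classmethod
    def from_schema(cls, schema: AnnotationSchema, drop_category: str | None = None):
        if drop_category is None:
            return cls(schema.field_names, "full")
        dropped = set(schema.names_in_category(drop_category))
        names = tuple(n for n in schema.field_names if n not in dropped)
        tag = "no_mito_specific" if drop_category == "mito_specific" else "full"
        return cls(names, tag)


class FeatureMatrix:
    """Numeric matrix with explicit missingness (NaN) and optional labels."""

    def __init__(
        self,
        ids: Sequence[str],
        feature_names: Sequence[str],
        values: np.ndarray,
        labels: np.ndarray | None = None,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape != (len(ids), len(feature_names)):
            raise FeatureError(
                f"values shape {values.shape} inconsistent with "
                f"{len(ids)} rows x {len(feature_names)} features"
            )
        self.ids = list(ids)
        self.feature_names = tuple(feature_names)
        self.values = values
        if labels is not None:
            labels = np.asarray(labels)
            if labels.shape != (len(self.ids),):
                raise FeatureError("labels must align with rows")
            if not np.isin(labels, (0, 1)).all():
                raise FeatureError("labels must be binary 0/1")
            labels = labels.astype(int)
        self.labels = labels

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            list(self.ids),
            self.feature_names,
            self.values.copy(),
            None if self.labels is None else self.labels.copy(),
        )

    def select_columns(self, names: Sequence[str]) -> "FeatureMatrix":
        missing = [n for n in names if n not in self.feature_names]
        if missing:
            raise FeatureError(f"features absent from matrix: {missing}")
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            list(self.ids), list(names), self.values[:, idx], self.labels
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.feature_names)
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        return df

    def to_tsv(self, path) -> None:
        """TSV with '.' as missing marker; label column first when present."""
        df = self.to_frame().copy()
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("\t".join(["id"] + list(df.columns)) + "\n")
            for rid, row in df.iterrows():
                cells = [str(rid)]
                for col, v in row.items():
                    if col == "label":
                        cells.append(str(int(v)))
                    elif isinstance(v, float) and math.isnan(v):
                        cells.append(MISSING_TOKEN)
                    else:
                        cells.append(repr(float(v)))
                fh.write("\t".join(cells) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="id", na_values=[MISSING_TOKEN])
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").to_numpy(dtype=int)
        return cls(
            [str(i) for i in df.index],
            list(df.columns),
            df.to_numpy(dtype=float),
            labels,
        )


def build_feature_matrix(
    variants: Iterable[AnnotatedVariant],
    spec: FeatureSpec,
    labels: Sequence[int] | None = None,
) -> FeatureMatrix:
    """One row per variant, columns in spec order; booleans become 0/1."""
    variants = list(variants)
    ids = []
    rows = []
    for av in variants:
        absent = [n for n in spec.feature_names if n not in av.values]
        if absent:
            raise FeatureError(
                f"spec features absent from annotated variant {av.key}: {absent}"
            )
        row = []
        for name in spec.feature_names:
            v = av.values[name]
            if v is None:
                row.append(np.nan)
            elif isinstance(v, bool):
                row.append(1.0 if v else 0.0)
            else:
                try:
                    row.append(float(v))
                except (TypeError, ValueError):
                    row.append(np.nan)
        ids.append(str(av.key))
        rows.append(row)
    values = (
        np.asarray(rows, dtype=float)
        if rows
        else np.empty((0, len(spec.feature_names)))
    )
    lab = None if labels is None else np.asarray(labels)
    return FeatureMatrix(ids, spec.feature_names, values, lab)


def subset_features(
    matrix: FeatureMatrix, schema: AnnotationSchema, drop_category: str
) -> FeatureMatrix:
    """Remove columns whose schema category equals ``drop_category``."""
    dropped = set(schema.names_in_category(drop_category))
    keep = [n for n in matrix.feature_names if n not in dropped]
    return matrix.select_columns(keep)


# ---------------------------------------------------------------------------
# KNN imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputerState:
    """Fitted KNN-imputer state: k and the completed training matrix."""

    k: int
    reference_rows: np.ndarray  # complete after fit
    feature_names: tuple[str, ...]
    distance: str = "nan_euclidean"

    def __post_init__(self) -> None:
        self.reference_rows = np.asarray(self.reference_rows, dtype=float)
        if self.k < 1 or self.k > len(self.reference_rows):
            raise FeatureError(
                f"k={self.k} outside [1, {len(self.reference_rows)}]"
            )
        if np.isnan(self.reference_rows).any():
            raise FeatureError("reference rows must be complete after fit")

    def to_json(self) -> dict:
        return {
            "k": self.k,
            "reference_rows": self.reference_rows.tolist(),
            "feature_names": list(self.feature_names),
            "distance": self.distance,
        }

    @classmethod
    def from_json(cls, payload: dict) -> "ImputerState":
        return cls(
            k=payload["k"],
            reference_rows=np.asarray(payload["reference_rows"], dtype=float),
            feature_names=tuple(payload["feature_names"]),
            distance=payload.get("distance", "nan_euclidean"),
        )


def _masked_distance(a: np.ndarray, b: np.ndarray) -> float:
    """nan-Euclidean distance scaled by total/observed feature count."""
    both = ~np.isnan(a) & ~np.isnan(b)
    n_both = int(both.sum())
    if n_both == 0:
        return math.inf
    diff = a[both] - b[both]
    return math.sqrt(len(a) / n_both * float(diff @ diff))


def _donor_mean(
    target: np.ndarray,
    donors: np.ndarray,
    donor_values: np.ndarray,
    k: int,
) -> float:
    """Mean of ``donor_values`` over the k nearest donors (ties expanded)."""
    dists = np.array([_masked_distance(target, d) for d in donors])
    finite = np.isfinite(dists)
    if not finite.any():
        # no donor shares any observed feature with the target; fall back to
        # the plain feature mean over all donors
        return float(np.mean(donor_values))
    dists = dists[finite]
    vals = donor_values[finite]
    kk = min(k, len(dists))
    kth = np.partition(dists, kk - 1)[kk - 1]
    chosen = dists <= kth
    return float(np.mean(vals[chosen]))


def fit_impute(matrix: FeatureMatrix, k: int = 5) -> tuple[ImputerState, FeatureMatrix]:
    """Fit the KNN imputer on training rows and return the completed matrix.

    Requires at least k+1 rows and no fully missing column. For each missing
    cell the donors are the *other* rows observing that feature; the cell
    becomes the unweighted mean of the feature over the k nearest donors
    (all donors at the k-th distance included).
    """
    X = matrix.values
    n, p = X.shape
    if n < k + 1:
        raise FeatureError(f"need at least k+1={k + 1} rows, got {n}")
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        bad = [matrix.feature_names[j] for j in np.flatnonzero(all_missing)]
        raise FeatureError(f"columns entirely missing: {bad}")
    completed = X.copy()
    for i in range(n):
        miss_cols = np.flatnonzero(np.isnan(X[i]))
        for j in miss_cols:
            donor_idx = np.flatnonzero(~np.isnan(X[:, j]))
            donor_idx = donor_idx[donor_idx != i]
            completed[i, j] = _donor_mean(X[i], X[donor_idx], X[donor_idx, j], k)
    state = ImputerState(
        k=k, reference_rows=completed, feature_names=matrix.feature_names
    )
    out = FeatureMatrix(matrix.ids, matrix.feature_names, completed, matrix.labels)
    return state, out


def transform_impute(state: ImputerState, matrix: FeatureMatrix) -> FeatureMatrix:
    """Impute new rows against the fitted (complete) reference rows."""
    if matrix.feature_names != state.feature_names:
        raise FeatureError(
            "feature names differ from fitted state: "
            f"{set(matrix.feature_names) ^ set(state.feature_names)}"
        )
    X = matrix.values.copy()
    ref = state.reference_rows
    for i in range(len(X)):
        miss_cols = np.flatnonzero(np.isnan(X[i]))
        if miss_cols.size == 0:
            continue
        for j in miss_cols:
            X[i, j] = _donor_mean(matrix.values[i], ref, ref[:, j], state.k)
    return FeatureMatrix(matrix.ids, matrix.feature_names, X, matrix.labels)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizerState:
    """Per-feature min-max parameters fitted on training data.

    Constant features get scale 1 (and are flagged) so they map to 0.
    """

    mins: np.ndarray
    scales: np.ndarray  # max - min, or 1 for constant features
    constant: np.ndarray  # bool flags
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        self.constant = np.asarray(self.constant, dtype=bool)
        if (self.scales <= 0).any():
            raise FeatureError("normalizer scales must be positive")

    def to_json(self) -> dict:
        return {
            "mins": self.mins.tolist(),
            "scales": self.scales.tolist(),
            "constant": self.constant.tolist(),
            "feature_names": list(self.feature_names),
        }

    @classmethod
    def from_json(cls, payload: dict) -> "NormalizerState":
        return cls(
            mins=np.asarray(payload["mins"], dtype=float),
            scales=np.asarray(payload["scales"], dtype=float),
            constant=np.asarray(payload["constant"], dtype=bool),
            feature_names=tuple(payload["feature_names"]),
        )


def fit_normalize(matrix: FeatureMatrix) -> tuple[NormalizerState, FeatureMatrix]:
    """Min-max scale each feature to [0,1] on the training matrix.

    Imputation must already have run: missing values are a contract
    violation here. Transforming new data with the stored parameters may
    legitimately fall outside [0,1].
    """
    if matrix.n_missing:
        raise FeatureError(
            "fit_normalize requires a complete matrix (impute first); "
            f"{matrix.n_missing} missing cells found"
        )
    X = matrix.values
    mins = X.min(axis=0)
    maxs = X.max(axis=0)
    scales = maxs - mins
    constant = scales == 0
    scales = np.where(constant, 1.0, scales)
    state = NormalizerState(
        mins=mins, scales=scales, constant=constant,
        feature_names=matrix.feature_names,
    )
    return state, transform_normalize(state, matrix)


def transform_normalize(state: NormalizerState, matrix: FeatureMatrix) -> FeatureMatrix:
    if matrix.feature_names != state.feature_names:
        raise FeatureError(
            "feature names differ from fitted state: "
            f"{set(matrix.feature_names) ^ set(state.feature_names)}"
        )
    if matrix.n_missing:
        raise FeatureError("transform_normalize requires a complete matrix")
    X = (matrix.values - state.mins) / state.scales
    X[:, state.constant] = 0.0
    return FeatureMatrix(matrix.ids, matrix.feature_names, X, matrix.labels)


def save_states(path, imputer: ImputerState, normalizer: NormalizerState) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(
            {"imputer": imputer.to_json(), "normalizer": normalizer.to_json()},
            fh,
        )


def load_states(path) -> tuple[ImputerState, NormalizerState]:
    with open(path, "rt", encoding="utf-8") as fh:
        payload = json.load(fh)
    return (
        ImputerState.from_json(payload["imputer"]),
        NormalizerState.from_json(payload["normalizer"]),
    )
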