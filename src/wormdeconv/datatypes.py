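"""Core in-memory containers shared across the pipeline.

All tabular data is held in pandas objects with explicit string labels;
the dataclasses below bundle a matrix with the metadata that travels with
it and enforce the structural invariants every stage relies on (unique
ids, finiteness, simplex rows).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MARKER_COLUMNS = ("feature_id", "cell_type", "marker_score")

#: Row-sum tolerance for proportion matrices.
SIMPLEX_ATOL = 1e-6


class ValidationError(ValueError):
    """An input table violates a structural contract."""


def validate_marker_table(markers: pd.DataFrame) -> pd.DataFrame:
    """Check a marker table (feature_id, cell_type, marker_score).

    Returns the table unchanged on success; raises :class:`ValidationError`
    with the offending detail otherwise.
    """
    missing = [c for c in MARKER_COLUMNS if c not in markers.columns]
    if missing:
        raise ValidationError(f"marker table missing columns: {missing}")
    if markers.empty:
        raise ValidationError("marker table is empty")
    dup = markers.duplicated(subset=["feature_id", "cell_type"])
    if dup.any():
        pairs = markers.loc[dup, ["feature_id", "cell_type"]].head(5)
        raise ValidationError(
            f"duplicate (feature_id, cell_type) pairs, e.g.\n{pairs}"
        )
    scores = markers["marker_score"].to_numpy(dtype=float)
    if not np.isfinite(scores).all():
        raise ValidationError("marker_score contains non-finite values")
    if (scores < 0).any():
        raise ValidationError("marker_score contains negative values")
    return markers


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class BulkMatrix:
    """Features x samples measurement matrix with per-sample metadata.

    ``values`` rows are feature ids, columns are sample ids; ``metadata``
    is indexed by sample id and carries at least ``day`` (int),
    ``replicate`` (str) and ``modality`` ('rna' or 'protein').
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "sample ids")
        if not self.values.columns.equals(self.metadata.index):
            if set(self.values.columns) != set(self.metadata.index):
                raise ValidationError(
                    "bulk matrix samples and metadata index disagree"
                )
            self.metadata = self.metadata.loc[self.values.columns]
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("bulk matrix contains non-finite entries")
        if (arr < 0).any():
            raise ValidationError("bulk matrix contains negative entries")
        for col in ("day", "replicate", "modality"):
            if col not in self.metadata.columns:
                raise ValidationError(f"bulk metadata missing column '{col}'")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class SignatureMatrix:
    """Marker-restricted reference expression, features x cell types."""

    values: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "signature feature rows")
        _check_unique(self.values.columns, "signature cell-type columns")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValidationError("signature entries must be finite and >= 0")

    @property
    def cell_types(self) -> pd.Index:
        return self.values.columns

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index


@dataclass
class ProportionMatrix:
    """Samples x cell types proportions; every row lies on the simplex.

    ``day`` is a per-sample integer series aligned with ``values.index``.
    """

    values: pd.DataFrame
    day: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "sample ids")
        _check_unique(self.values.columns, "cell-type columns")
        if not self.values.index.equals(self.day.index):
            if set(self.values.index) != set(self.day.index):
                raise ValidationError("day metadata does not cover all samples")
            self.day = self.day.loc[self.values.index]
        arr = self.values.to_numpy(dtype=float)
        if (arr < -SIMPLEX_ATOL).any():
            raise ValidationError("proportions contain negative entries")
        sums = arr.sum(axis=1)
        bad = np.abs(sums - 1.0) > SIMPLEX_ATOL
        if bad.any():
            offender = self.values.index[bad][0]
            raise ValidationError(
                f"proportion rows must sum to 1 +/- {SIMPLEX_ATOL}; "
                f"sample '{offender}' sums to {sums[bad][0]!r}"
            )

    @property
    def cell_types(self) -> pd.Index:
        return self.values.columns

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index


def validate_ground_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Check a tissue ground-truth table (tissue, nuclei_count, total_cell_volume)."""
    required = ("tissue", "nuclei_count", "total_cell_volume")
    missing = [c for c in required if c not in truth.columns]
    if missing:
        raise ValidationError(f"ground-truth table missing columns: {missing}")
    if truth["tissue"].duplicated().any():
        dups = truth.loc[truth["tissue"].duplicated(), "tissue"].tolist()
        raise ValidationError(f"duplicate tissue labels: {dups}")
    if (truth["nuclei_count"].to_numpy(dtype=float) < 0).any():
        raise ValidationError("nuclei_count must be >= 0")
    if (truth["total_cell_volume"].to_numpy(dtype=float) < 0).any():
        raise ValidationError("total_cell_volume must be >= 0")
    if not (truth["nuclei_count"] > 0).any():
        raise ValidationError("need at least one tissue with positive nuclei_count")
    return truth
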