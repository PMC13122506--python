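"""Marker selection and signature-matrix construction.

The signature matrix is the design matrix of the deconvolution
regression: reference mean expression restricted to marker genes. Marker
eligibility follows two modality presets taken from single-worm omics
practice: RNA mode keeps every cell type (minimum marker count 0) while
proteomics mode, where coverage is shallow, requires at least five
detected markers per cell type; both modes require a minimum specificity
score of 0.08 per marker and use the top 100 markers per cell type.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from .datatypes import SignatureMatrix, ValidationError, validate_marker_table

log = logging.getLogger(__name__)

__all__ = [
    "SignatureConfig",
    "select_top_markers",
    "filter_markers_and_cell_types",
    "build_signature",
    "prepare_markers",
]


@dataclass(frozen=True)
class SignatureConfig:
    """Marker eligibility thresholds.

    top_k: markers retained per cell type (by descending score).
    min_marker_count: minimum surviving markers for a cell type to be
        estimated at all (0 for RNA, 5 for proteomics).
    min_marker_score: minimum specificity score per marker.
    """

    top_k: int = 100
    min_marker_count: int = 0
    min_marker_score: float = 0.08

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.min_marker_count < 0 or self.min_marker_score < 0:
            raise ValueError("thresholds must be >= 0")

    @classmethod
    def rna(cls, **overrides) -> "SignatureConfig":
        return replace(cls(min_marker_count=0), **overrides)

    @classmethod
    def proteomics(cls, **overrides) -> "SignatureConfig":
        return replace(cls(min_marker_count=5), **overrides)


def select_top_markers(markers: pd.DataFrame, top_k: int = 100) -> pd.DataFrame:
    """Keep the ``top_k`` highest-scoring markers of each cell type.

    Ties at the cut are broken by ascending feature_id (stable across
    runs and platforms); cell types with fewer than ``top_k`` markers
    keep them all.
    """
    validate_marker_table(markers)
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    ordered = markers.sort_values(
        ["cell_type", "marker_score", "feature_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return ordered.groupby("cell_type", sort=False).head(top_k).reset_index(drop=True)


def filter_markers_and_cell_types(
    markers: pd.DataFrame,
    available_features,
    config: SignatureConfig,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Apply availability, score and per-cell-type count filters.

    Drops marker records whose feature is not in ``available_features``
    or whose score falls below ``config.min_marker_score``, then drops
    every cell type left with fewer than ``config.min_marker_count``
    markers. Returns the surviving table and an exclusion log mapping
    each dropped cell type to the reason.
    """
    validate_marker_table(markers)
    available = set(available_features)
    if not available:
        raise ValueError("available_features is empty")

    surviving = markers[
        markers["feature_id"].isin(available)
        & (markers["marker_score"] >= config.min_marker_score)
    ]

    excluded: dict[str, str] = {}
    counts = surviving.groupby("cell_type").size()
    for ct in markers["cell_type"].unique():
        n = int(counts.get(ct, 0))
        if n < max(1, config.min_marker_count):
            excluded[ct] = (
                f"{n} surviving markers < required "
                f"{max(1, config.min_marker_count)} "
                f"(min_marker_count={config.min_marker_count}, "
                f"min_marker_score={config.min_marker_score})"
            )
    kept = surviving[~surviving["cell_type"].isin(excluded)].reset_index(drop=True)
    if kept.empty:
        raise ValidationError(
            "every cell type was excluded by the marker filters "
            f"(min_marker_count={config.min_marker_count}, "
            f"min_marker_score={config.min_marker_score})"
        )
    for ct, reason in excluded.items():
        log.info("cell type %s excluded: %s", ct, reason)
    return kept, excluded


def prepare_markers(
    markers: pd.DataFrame,
    available_features,
    config: SignatureConfig,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Full eligibility pipeline: availability -> score -> top-k -> count.

    The count requirement is applied last so that, in proteomics mode, it
    acts on the markers that are actually detectable.
    """
    available = set(available_features)
    if not available:
        raise ValueError("available_features is empty")
    validate_marker_table(markers)
    surviving = markers[
        markers["feature_id"].isin(available)
        & (markers["marker_score"] >= config.min_marker_score)
    ]
    if surviving.empty:
        raise ValidationError(
            "no marker survived the availability/score filters"
        )
    topped = select_top_markers(surviving, config.top_k)
    return filter_markers_and_cell_types(
        topped, available, replace(config, min_marker_score=0.0)
    )


def build_signature(
    reference_profiles: pd.DataFrame, markers: pd.DataFrame
) -> SignatureMatrix:
    """Assemble the features x cell-types signature from retained markers.

    Rows are the union of all marker features (a feature marking several
    cell types appears once); columns are the retained cell types; entries
    are the reference mean expression. Rows and columns are sorted for
    deterministic output.
    """
    validate_marker_table(markers)
    missing_feat = sorted(
        set(markers["feature_id"]) - set(reference_profiles.index)
    )
    if missing_feat:
        raise ValidationError(
            f"marker features absent from the reference: {missing_feat[:10]}"
            + (" ..." if len(missing_feat) > 10 else "")
        )
    missing_ct = sorted(
        set(markers["cell_type"]) - set(reference_profiles.columns)
    )
    if missing_ct:
        raise ValidationError(
            f"marker cell types absent from the reference: {missing_ct}"
        )
    features = sorted(set(markers["feature_id"]))
    cell_types = sorted(set(markers["cell_type"]))
    values = reference_profiles.loc[features, cell_types].astype(float)
    counts = markers.groupby("cell_type").size().to_dict()
    return SignatureMatrix(
        values=values,
        provenance={
            "n_marker_records": len(markers),
            "markers_per_cell_type": {k: int(v) for k, v in sorted(counts.items())},
        },
    )
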