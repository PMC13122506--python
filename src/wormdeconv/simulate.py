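"""Synthetic single-worm cohorts with known cell-type composition.

The generator emulates the data model of reference-based deconvolution in
C. elegans: a single-cell reference of per-cell-type mean expression
profiles with scored marker genes, and an aging cohort of bulk samples
(one worm each) whose true tissue proportions drift monotonically with
age — somatic tissues such as the intestine and muscle shrink while the
(somatic) gonad, uterine tissue and neurons expand their relative share
of the transcriptome. A proteomics variant subsamples the feature space
to the ~3,500 proteins a single-worm proteome typically detects.

Every quantity is deterministic given ``SimulationConfig.seed``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import BulkMatrix, ProportionMatrix

__all__ = [
    "SimulationConfig",
    "DEFAULT_TRAJECTORY",
    "simulate_reference",
    "simulate_aging_cohort",
    "simulate_proteome_coverage",
]

#: Default 10-tissue aging trajectory: (day-1 proportion, final-day proportion).
#: Shrinking somatic tissues (intestine, muscle, vulval/epidermis) against an
#: expanding gonadal / uterine / neuronal share, with the remaining mass spread
#: over slowly drifting tissues so each endpoint sums to 1.
DEFAULT_TRAJECTORY: dict[str, tuple[float, float]] = {
    "intestine": (0.193, 0.052),
    "muscle": (0.107, 0.036),
    "vulval_epidermis": (0.079, 0.012),
    "gonadal": (0.072, 0.144),
    "neurons": (0.027, 0.078),
    "uterine": (0.075, 0.233),
    "hypodermis": (0.200, 0.150),
    "pharynx": (0.100, 0.120),
    "germline": (0.100, 0.135),
    "spermatheca": (0.047, 0.040),
}


class ConfigurationError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic cohort generator.

    Parameters
    ----------
    n_cell_types, n_features
        Size of the reference: cell types (columns) and genes/proteins (rows).
    markers_per_type
        Number of marker genes planted per cell type; the marker budget
        ``markers_per_type * n_cell_types`` must fit inside ``n_features``.
    marker_fold_change
        Expression multiplier of a marker in its own cell type relative to
        its mean expression elsewhere (> 1). The resulting specificity
        score is exactly ``1 - 1/marker_fold_change``.
    n_days, replicates_per_day
        Cohort layout: days of adulthood sampled and worms per day.
    trajectory
        Per-cell-type ``(start, end)`` proportion pairs; each endpoint
        vector must sum to 1. ``None`` selects :data:`DEFAULT_TRAJECTORY`
        when ``n_cell_types`` matches it, otherwise seeded Dirichlet
        endpoints.
    noise_cv
        Coefficient of variation of the multiplicative log-normal noise
        applied per feature per sample (0 = noiseless).
    biological_cv
        Between-cell-type variability of non-marker genes in the
        reference (log-normal CV); keeps reference columns from being
        identical outside the marker blocks.
    proteome_n_features
        Feature count retained by the proteomics coverage model; ``None``
        means min(3500, n_features).
    """

    n_cell_types: int = 10
    n_features: int = 10_000
    markers_per_type: int = 100
    marker_fold_change: float = 5.0
    n_days: int = 12
    replicates_per_day: int = 5
    trajectory: dict[str, tuple[float, float]] | None = None
    noise_cv: float = 0.1
    biological_cv: float = 0.5
    proteome_n_features: int | None = None
    seed: int = 0

    #: proteome coverage used when ``proteome_n_features`` is None: the
    #: ~3,500 detected proteins typical of single-worm proteomics, capped
    #: by the feature count of small test configurations.
    DEFAULT_PROTEOME_FEATURES = 3_500

    def __post_init__(self) -> None:
        if min(self.n_cell_types, self.n_features, self.markers_per_type,
               self.n_days, self.replicates_per_day) < 1:
            raise ConfigurationError("all size parameters must be >= 1")
        if self.marker_fold_change <= 1:
            raise ConfigurationError("marker_fold_change must exceed 1")
        if self.noise_cv < 0 or self.biological_cv < 0:
            raise ConfigurationError("coefficients of variation must be >= 0")
        if self.markers_per_type * self.n_cell_types > self.n_features:
            raise ConfigurationError(
                f"marker budget {self.markers_per_type} x {self.n_cell_types} "
                f"exceeds n_features={self.n_features}"
            )
        if self.proteome_n_features is not None and not (
            1 <= self.proteome_n_features <= self.n_features
        ):
            raise ConfigurationError(
                "proteome_n_features must lie in [1, n_features]"
            )
        if self.trajectory is not None:
            self._check_trajectory(self.trajectory)

    def _check_trajectory(self, traj: dict[str, tuple[float, float]]) -> None:
        if len(traj) != self.n_cell_types:
            raise ConfigurationError(
                f"trajectory has {len(traj)} cell types, expected "
                f"{self.n_cell_types}"
            )
        start = np.array([v[0] for v in traj.values()], dtype=float)
        end = np.array([v[1] for v in traj.values()], dtype=float)
        for name, vec in (("start", start), ("end", end)):
            if (vec < 0).any() or (vec > 1).any():
                raise ConfigurationError(f"{name} proportions outside [0, 1]")
            if abs(vec.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"{name} proportions sum to {vec.sum()!r}, expected 1"
                )

    def resolve_trajectory(self) -> dict[str, tuple[float, float]]:
        """Concrete (start, end) pairs for every cell type."""
        if self.trajectory is not None:
            return dict(self.trajectory)
        if self.n_cell_types == len(DEFAULT_TRAJECTORY):
            return dict(DEFAULT_TRAJECTORY)
        # Seeded Dirichlet endpoints for non-default cohort sizes.
        rng = np.random.default_rng([self.seed, 2])
        start = rng.dirichlet(np.full(self.n_cell_types, 5.0))
        end = rng.dirichlet(np.full(self.n_cell_types, 5.0))
        names = [f"ct{i + 1:02d}" for i in range(self.n_cell_types)]
        return {n: (float(s), float(e)) for n, s, e in zip(names, start, end)}

    @property
    def resolved_proteome_n_features(self) -> int:
        if self.proteome_n_features is not None:
            return self.proteome_n_features
        return min(self.DEFAULT_PROTEOME_FEATURES, self.n_features)

    @property
    def cell_types(self) -> list[str]:
        return list(self.resolve_trajectory())

    @property
    def feature_ids(self) -> list[str]:
        width = len(str(self.n_features))
        return [f"g{i + 1:0{width}d}" for i in range(self.n_features)]


def _lognormal_cv(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


def marker_specificity(profiles: pd.DataFrame) -> pd.DataFrame:
    """Specificity score of every (feature, cell type) pair.

    score = (expression in own type - mean expression in the other types)
    divided by the expression in the own type, clamped to [0, 1]. This is
    the convention used throughout the package both to score simulated
    markers and to filter marker tables.
    """
    arr = profiles.to_numpy(dtype=float)
    n = arr.shape[1]
    if n < 2:
        raise ValueError("need >= 2 cell types to score specificity")
    other_mean = (arr.sum(axis=1, keepdims=True) - arr) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(arr > 0, (arr - other_mean) / arr, 0.0)
    return pd.DataFrame(
        np.clip(score, 0.0, 1.0), index=profiles.index, columns=profiles.columns
    )


def simulate_reference(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-cell-type mean expression profiles and a marker table.

    Baseline expression is log-normal per gene (shared across cell types),
    modulated by log-normal between-type biological variation. Each cell
    type receives ``markers_per_type`` disjoint marker genes whose own-type
    expression is pinned to ``marker_fold_change`` times their mean
    expression in the other types, so the specificity score of a planted
    marker is exactly ``1 - 1/marker_fold_change``.

    Returns
    -------
    profiles : DataFrame, features x cell types
    markers : DataFrame with columns feature_id, cell_type, marker_score,
        one row per planted marker.
    """
    rng = np.random.default_rng([config.seed, 0])
    cell_types = config.cell_types
    features = config.feature_ids
    nf, nt = config.n_features, config.n_cell_types

    base = rng.lognormal(3.0, 1.0, nf)
    jitter = _lognormal_cv(rng, config.biological_cv, (nf, nt))
    arr = base[:, None] * jitter

    # Disjoint marker blocks drawn without replacement over all features.
    marker_idx = rng.choice(nf, size=nt * config.markers_per_type, replace=False)
    blocks = marker_idx.reshape(nt, config.markers_per_type)
    for t in range(nt):
        rows = blocks[t]
        others = np.delete(arr[rows], t, axis=1).mean(axis=1)
        arr[rows, t] = config.marker_fold_change * others

    profiles = pd.DataFrame(arr, index=features, columns=cell_types)

    scores = marker_specificity(profiles)
    records = []
    for t, ct in enumerate(cell_types):
        for i in np.sort(blocks[t]):
            records.append(
                (features[i], ct, float(scores.iat[i, t]))
            )
    markers = pd.DataFrame(
        records, columns=["feature_id", "cell_type", "marker_score"]
    )
    return profiles, markers


def day_proportions(config: SimulationConfig) -> pd.DataFrame:
    """True proportions per day: linear interpolation between the
    trajectory endpoints, renormalized to the simplex. Index = day 1..n."""
    traj = config.resolve_trajectory()
    start = np.array([v[0] for v in traj.values()])
    end = np.array([v[1] for v in traj.values()])
    days = np.arange(1, config.n_days + 1)
    if config.n_days == 1:
        frac = np.zeros(1)
    else:
        frac = (days - 1) / (config.n_days - 1)
    props = (1 - frac[:, None]) * start + frac[:, None] * end
    props /= props.sum(axis=1, keepdims=True)
    return pd.DataFrame(props, index=pd.Index(days, name="day"),
                        columns=list(traj))


def simulate_aging_cohort(
    config: SimulationConfig, reference_profiles: pd.DataFrame
) -> tuple[BulkMatrix, ProportionMatrix]:
    """Mix the reference into a day-structured cohort of bulk samples.

    Each sample is ``profiles @ true_proportions`` for its day, times
    mean-one log-normal noise with CV ``config.noise_cv``. Sample ids are
    ``d{day}_r{replicate}``.
    """
    if list(reference_profiles.columns) != config.cell_types:
        raise ValueError(
            "reference profile cell types do not match the configuration"
        )
    if reference_profiles.shape[0] != config.n_features:
        raise ValueError("reference profile feature count mismatch")

    rng = np.random.default_rng([config.seed, 1])
    per_day = day_proportions(config)
    arr = reference_profiles.to_numpy(dtype=float)

    sample_ids, days, reps, cols, truth_rows = [], [], [], [], []
    for day in per_day.index:
        w = per_day.loc[day].to_numpy()
        clean = arr @ w
        for r in range(1, config.replicates_per_day + 1):
            noise = _lognormal_cv(rng, config.noise_cv, config.n_features)
            cols.append(clean * noise)
            sample_ids.append(f"d{day:02d}_r{r}")
            days.append(int(day))
            reps.append(f"r{r}")
            truth_rows.append(w)

    values = pd.DataFrame(
        np.column_stack(cols), index=reference_profiles.index,
        columns=sample_ids,
    )
    metadata = pd.DataFrame(
        {"day": days, "replicate": reps, "modality": "rna"},
        index=pd.Index(sample_ids, name="sample"),
    )
    truth = ProportionMatrix(
        values=pd.DataFrame(truth_rows, index=values.columns,
                            columns=per_day.columns),
        day=metadata["day"],
    )
    return BulkMatrix(values=values, metadata=metadata), truth


def simulate_proteome_coverage(
    bulk: BulkMatrix, proteome_n_features: int, seed: int
) -> BulkMatrix:
    """Restrict a cohort to a random subset of features, emulating the
    limited coverage of single-worm proteomics (~3,500 detected proteins).

    Dropout is uniform without replacement and seeded; sample metadata is
    preserved except that the modality flag becomes 'protein'. Feature
    order of the retained rows is preserved.
    """
    if proteome_n_features > bulk.n_features:
        raise ValueError(
            f"requested {proteome_n_features} features but the cohort has "
            f"only {bulk.n_features}"
        )
    if proteome_n_features < 1:
        raise ValueError("proteome_n_features must be >= 1")
    rng = np.random.default_rng([seed, 3])
    keep = np.sort(
        rng.choice(bulk.n_features, size=proteome_n_features, replace=False)
    )
    values = bulk.values.iloc[keep].copy()
    metadata = bulk.metadata.copy()
    metadata["modality"] = "protein"
    return BulkMatrix(values=values, metadata=metadata)
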