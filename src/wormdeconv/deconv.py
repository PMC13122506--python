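"""Cell-type proportion estimation by linear epsilon-SVR.

Each bulk sample is regressed on the signature columns with a linear
support-vector regression (epsilon-insensitive loss, regularization C),
the convention popularised by the CIBERSORT family. Raw coefficients may
be negative; proportions are obtained by clipping at zero and
renormalising to the simplex.

Scaling convention
------------------
Proportions are only identified up to the relative scale of mixture and
signature, and the epsilon tube is an absolute quantity, so both inputs
are brought onto one fixed expression scale before fitting: the mixture
is scaled so its mean over the shared features equals ``scale``
(default 50), and the signature matrix is multiplied by the single
global factor that gives its entries the same mean. A single factor —
rather than per-column scaling — preserves the relative total signal of
the cell types, which is what the recovered coefficients measure; it
also makes the result exactly invariant to rescaling any one mixture.
On this scale the default tube epsilon = 0.01 is small relative to
signal while the documented search ranges (C in [1e-4, 0.1], epsilon in
[0.001, 0.5]) span underfitting to near-interpolation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .datatypes import BulkMatrix, ProportionMatrix, SignatureMatrix

log = logging.getLogger(__name__)

__all__ = [
    "DeconvolutionConfig",
    "DeconvolutionResult",
    "fit_sample",
    "coefficients_to_proportions",
    "deconvolve",
    "grid_search",
    "mean_proportions_by_day",
    "nnls_proportions",
]


class DeconvolutionError(ValueError):
    """A sample or cohort cannot be deconvolved."""


@dataclass(frozen=True)
class DeconvolutionConfig:
    """SVR hyper-parameters.

    C: regularization strength (default 0.001); epsilon: half-width of
    the insensitive tube (default 0.01). The search ranges are the
    documented bounds for grid_search. ``scale`` is the common mean
    expression both inputs are normalised to before fitting.
    """

    C: float = 0.001
    epsilon: float = 0.01
    C_search_range: tuple[float, float] = (0.0001, 0.1)
    epsilon_search_range: tuple[float, float] = (0.001, 0.5)
    scale: float = 50.0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.epsilon <= 0 or self.scale <= 0:
            raise ValueError("C, epsilon and scale must be positive")
        lo, hi = self.C_search_range
        if not lo <= self.C <= hi:
            raise ValueError(f"C={self.C} outside search range {self.C_search_range}")
        lo, hi = self.epsilon_search_range
        if not lo <= self.epsilon <= hi:
            raise ValueError(
                f"epsilon={self.epsilon} outside search range "
                f"{self.epsilon_search_range}"
            )


def _shared_features(signature: SignatureMatrix, features: pd.Index) -> pd.Index:
    shared = signature.values.index.intersection(features)
    if len(shared) < 2:
        raise DeconvolutionError(
            f"only {len(shared)} features shared between signature and bulk; "
            "need >= 2"
        )
    return shared


def fit_sample(
    signature: SignatureMatrix,
    mixture: pd.Series,
    config: DeconvolutionConfig | None = None,
) -> pd.Series:
    """Raw (unconstrained) SVR coefficients of one bulk sample.

    Restricts to the features shared between signature and mixture,
    applies the common-scale normalisation, and solves a linear
    epsilon-SVR regressing the mixture on the signature columns. The
    returned coefficient vector is indexed by cell type and may contain
    negatives.
    """
    config = config or DeconvolutionConfig()
    if signature.values.shape[1] < 2:
        raise DeconvolutionError("need >= 2 cell types in the signature")
    shared = _shared_features(signature, mixture.index)
    X = signature.values.loc[shared].to_numpy(dtype=float)
    y = mixture.loc[shared].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise DeconvolutionError("mixture contains non-finite values")
    if y.std() == 0:
        raise DeconvolutionError(
            "mixture has zero variance over the shared features"
        )

    y_scaled = y * (config.scale / y.mean())
    X_scaled = X * (config.scale / X.mean())

    model = SVR(kernel="linear", C=config.C, epsilon=config.epsilon)
    model.fit(X_scaled, y_scaled)
    coef = np.asarray(model.coef_).ravel()
    return pd.Series(coef, index=signature.values.columns, name=mixture.name)


def coefficients_to_proportions(raw: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Clip negative coefficients to zero and renormalise to the simplex."""
    values = np.asarray(raw, dtype=float)
    if values.ndim != 1 or values.size < 1:
        raise ValueError("expected a 1-D coefficient vector")
    clipped = np.clip(values, 0.0, None)
    total = clipped.sum()
    if total <= 0:
        raise DeconvolutionError(
            "all coefficients <= 0: sample composition is unidentifiable"
        )
    props = clipped / total
    if isinstance(raw, pd.Series):
        return pd.Series(props, index=raw.index, name=raw.name)
    return props


@dataclass
class DeconvolutionResult:
    """Cohort-level output: proportions plus per-sample diagnostics."""

    proportions: ProportionMatrix
    shared_feature_count: int
    failures: dict[str, str] = field(default_factory=dict)


def deconvolve(
    signature: SignatureMatrix,
    bulk: BulkMatrix,
    config: DeconvolutionConfig | None = None,
) -> DeconvolutionResult:
    """Estimate proportions for every sample of a cohort independently.

    Per-sample failures are recorded and the sample omitted rather than
    aborting the cohort; the run fails only if no sample succeeds.
    """
    config = config or DeconvolutionConfig()
    shared = _shared_features(signature, bulk.feature_ids)
    log.info(
        "deconvolving %d samples over %d shared features (%d cell types)",
        bulk.n_samples, len(shared), signature.values.shape[1],
    )
    rows, ids, failures = [], [], {}
    for sample_id in bulk.sample_ids:
        try:
            raw = fit_sample(signature, bulk.values[sample_id], config)
            rows.append(coefficients_to_proportions(raw))
            ids.append(sample_id)
        except (DeconvolutionError, ValueError) as exc:  # flagged, not fatal
            failures[sample_id] = str(exc)
            log.warning("sample %s failed: %s", sample_id, exc)
    if not rows:
        raise DeconvolutionError(
            f"every sample failed; first error: {next(iter(failures.values()))}"
        )
    values = pd.DataFrame(rows, index=pd.Index(ids, name="sample"))
    proportions = ProportionMatrix(
        values=values, day=bulk.metadata.loc[ids, "day"].astype(int)
    )
    return DeconvolutionResult(
        proportions=proportions,
        shared_feature_count=len(shared),
        failures=failures,
    )


def nnls_proportions(
    signature: SignatureMatrix,
    mixture: pd.Series,
    config: DeconvolutionConfig | None = None,
) -> pd.Series:
    """Non-negative least-squares estimate on the same scaled inputs.

    Independent of the SVR path; used as a cross-check oracle on clean
    mixtures.
    """
    from scipy.optimize import nnls

    config = config or DeconvolutionConfig()
    shared = _shared_features(signature, mixture.index)
    X = signature.values.loc[shared].to_numpy(dtype=float)
    y = mixture.loc[shared].to_numpy(dtype=float)
    coef, _ = nnls(X * (config.scale / X.mean()), y * (config.scale / y.mean()))
    total = coef.sum()
    if total <= 0:
        raise DeconvolutionError("NNLS returned an all-zero solution")
    return pd.Series(coef / total, index=signature.values.columns,
                     name=mixture.name)


def grid_search(
    signature: SignatureMatrix,
    bulk: BulkMatrix,
    truth: ProportionMatrix,
    C_grid,
    epsilon_grid,
    config: DeconvolutionConfig | None = None,
) -> tuple[DeconvolutionConfig, pd.DataFrame]:
    """Exhaustive (C, epsilon) search by mean absolute recovery error.

    Every grid point must lie inside the configured search ranges. Ties
    are broken toward smaller C, then smaller epsilon. Returns the best
    configuration and the full error surface as a tidy DataFrame with
    columns C, epsilon, mae.
    """
    base = config or DeconvolutionConfig()
    C_grid = sorted(float(c) for c in C_grid)
    epsilon_grid = sorted(float(e) for e in epsilon_grid)
    if not C_grid or not epsilon_grid:
        raise ValueError("C and epsilon grids must be non-empty")
    for c in C_grid:
        if not base.C_search_range[0] <= c <= base.C_search_range[1]:
            raise ValueError(f"C={c} outside search range {base.C_search_range}")
    for e in epsilon_grid:
        if not base.epsilon_search_range[0] <= e <= base.epsilon_search_range[1]:
            raise ValueError(
                f"epsilon={e} outside search range {base.epsilon_search_range}"
            )

    truth_aligned = truth.values
    records = []
    for c in C_grid:
        for e in epsilon_grid:
            cand = DeconvolutionConfig(
                C=c, epsilon=e,
                C_search_range=base.C_search_range,
                epsilon_search_range=base.epsilon_search_range,
                scale=base.scale,
            )
            result = deconvolve(signature, bulk, cand)
            est = result.proportions.values
            common = est.index.intersection(truth_aligned.index)
            mae = float(
                np.abs(
                    est.loc[common, truth_aligned.columns].to_numpy()
                    - truth_aligned.loc[common].to_numpy()
                ).mean()
            )
            records.append({"C": c, "epsilon": e, "mae": mae})
    surface = pd.DataFrame(records)
    # argmin with deterministic tie-break toward smaller C then epsilon
    best_row = surface.sort_values(["mae", "C", "epsilon"]).iloc[0]
    best = DeconvolutionConfig(
        C=float(best_row["C"]), epsilon=float(best_row["epsilon"]),
        C_search_range=base.C_search_range,
        epsilon_search_range=base.epsilon_search_range,
        scale=base.scale,
    )
    return best, surface


def mean_proportions_by_day(proportions: ProportionMatrix) -> pd.DataFrame:
    """Arithmetic mean of the per-sample proportion vectors within each
    day; one row per day present, each row on the simplex."""
    df = proportions.values.copy()
    df["day"] = proportions.day
    out = df.groupby("day").mean()
    return out
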