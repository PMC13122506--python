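"""Comparison of deconvolution output against anatomical ground truth.

For young adult C. elegans the number of nuclei and the estimated total
cell volume of each major tissue are known from anatomical work; these
yield two independent notions of tissue "proportion" (nuclei fraction
and volume fraction). Deconvolution estimates are mapped onto the
curated thirteen-tissue scheme, correlated against both fractions, and
screened for outlier tissues whose omics signal departs strongly from
anatomy (classically: neurons, whose nuclei share is ~30% but whose
transcript share is marginal, and the intestine, whose volume exceeds
its nuclei share).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ProportionMatrix, ValidationError, validate_ground_truth

log = logging.getLogger(__name__)

__all__ = [
    "CURATED_TISSUES",
    "DEFAULT_TISSUE_MAPPING",
    "tissue_fractions",
    "aggregate_proportions",
    "correlate_with_truth",
    "TruthComparison",
]

#: The curated thirteen-tissue scheme used for ground-truth comparison.
CURATED_TISSUES = (
    "intestine",
    "hypodermal cells",
    "muscle",
    "gonadal",
    "uterine-vulval",
    "neurons",
    "spermatheca",
    "sp-ut junction",
    "vulval",
    "int-rect valve",
    "glia",
    "distal tip",
    "coelomocytes",
)

#: Default correspondence from the synthetic reference's cell-type labels
#: to the curated tissues. Editable: pipelines may supply their own mapping
#: file (see io.read_mapping / io.write_mapping).
DEFAULT_TISSUE_MAPPING: dict[str, str] = {
    "intestine": "intestine",
    "muscle": "muscle",
    "vulval_epidermis": "vulval",
    "gonadal": "gonadal",
    "neurons": "neurons",
    "uterine": "uterine-vulval",
    "hypodermis": "hypodermal cells",
    "pharynx": "muscle",
    "germline": "gonadal",
    "spermatheca": "spermatheca",
}


def tissue_fractions(truth: pd.DataFrame) -> pd.DataFrame:
    """Normalise nuclei counts and cell volumes into per-tissue fractions.

    Returns a DataFrame indexed by tissue with columns ``nuclei_fraction``
    and ``volume_fraction``; each column sums to 1.
    """
    validate_ground_truth(truth)
    nuclei = truth["nuclei_count"].to_numpy(dtype=float)
    volume = truth["total_cell_volume"].to_numpy(dtype=float)
    if nuclei.sum() <= 0 or volume.sum() <= 0:
        raise ValidationError("nuclei and volume totals must both be positive")
    return pd.DataFrame(
        {
            "nuclei_fraction": nuclei / nuclei.sum(),
            "volume_fraction": volume / volume.sum(),
        },
        index=pd.Index(truth["tissue"], name="tissue"),
    )


def aggregate_proportions(
    proportions: ProportionMatrix,
    mapping: dict[str, str],
    curated: tuple[str, ...] = CURATED_TISSUES,
) -> ProportionMatrix:
    """Sum cell-type proportions into curated tissue groups.

    Every mapping target must belong to ``curated``. Cell types missing
    from the mapping are pooled into an ``unmapped`` residual column with
    a warning, so row sums are preserved exactly.
    """
    bad_targets = sorted(set(mapping.values()) - set(curated))
    if bad_targets:
        raise ValidationError(
            f"mapping targets outside the curated tissue set: {bad_targets}"
        )
    unmapped = [ct for ct in proportions.values.columns if ct not in mapping]
    if unmapped:
        log.warning(
            "cell types without a tissue mapping pooled as 'unmapped': %s",
            unmapped,
        )
    groups: dict[str, list[str]] = {}
    for ct in proportions.values.columns:
        groups.setdefault(mapping.get(ct, "unmapped"), []).append(ct)
    data = {
        tissue: proportions.values[cols].sum(axis=1)
        for tissue, cols in groups.items()
    }
    ordered = [t for t in curated if t in data] + (
        ["unmapped"] if "unmapped" in data else []
    )
    values = pd.DataFrame(data)[ordered]
    return ProportionMatrix(values=values, day=proportions.day)


@dataclass
class TruthComparison:
    """Agreement between predicted tissue proportions and anatomy."""

    method: str
    shared_tissues: list[str]
    excluded_tissues: list[str]
    corr_nuclei: float
    corr_volume: float
    corr_nuclei_volume: float
    residuals: pd.DataFrame  # per tissue: residual + standardized, per truth column
    outliers_nuclei: list[str] = field(default_factory=list)
    outliers_volume: list[str] = field(default_factory=list)


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero-variance input: correlation undefined")
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def _standardized_residuals(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS of y on x; residuals and robust z-scores (1.4826 * MAD scale).

    The robust scale keeps a single displaced tissue from inflating its
    own denominator; zero-MAD degenerate cases fall back to the standard
    deviation, and if that is zero too every residual is exactly zero.
    """
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    # numerically-null residuals (perfect fits) count as exactly zero
    tol = 1e-12 * max(1.0, float(np.abs(y).max()))
    resid = np.where(np.abs(resid) < tol, 0.0, resid)
    mad = np.median(np.abs(resid - np.median(resid)))
    scale = 1.4826 * mad
    if scale == 0:
        scale = resid.std(ddof=0)
    if scale == 0:
        return resid, np.zeros_like(resid)
    with np.errstate(divide="ignore"):
        return resid, resid / scale


def correlate_with_truth(
    predicted: pd.Series,
    truth_fractions: pd.DataFrame,
    method: str = "spearman",
    outlier_threshold: float = 2.0,
) -> TruthComparison:
    """Correlate predicted per-tissue proportions with both ground truths.

    ``predicted`` is a per-tissue series (typically young-adult / day-1
    mean proportions); ``truth_fractions`` is the output of
    :func:`tissue_fractions`. Tissues absent from either side are
    excluded and logged. Outliers are tissues whose absolute standardized
    residual from the least-squares line of predicted on the truth
    fraction exceeds ``outlier_threshold``.
    """
    shared = [t for t in truth_fractions.index if t in predicted.index]
    excluded = sorted(
        set(truth_fractions.index).symmetric_difference(predicted.index)
    )
    if excluded:
        log.info("tissues excluded from the comparison: %s", excluded)
    if len(shared) < 3:
        raise ValidationError(
            f"only {len(shared)} tissues shared between prediction and truth; "
            "need >= 3"
        )
    p = predicted.loc[shared].to_numpy(dtype=float)
    nuc = truth_fractions.loc[shared, "nuclei_fraction"].to_numpy(dtype=float)
    vol = truth_fractions.loc[shared, "volume_fraction"].to_numpy(dtype=float)

    corr_nuc = _corr(nuc, p, method)
    corr_vol = _corr(vol, p, method)
    corr_nv = _corr(nuc, vol, method)

    res_n, z_n = _standardized_residuals(nuc, p)
    res_v, z_v = _standardized_residuals(vol, p)
    residuals = pd.DataFrame(
        {
            "residual_nuclei": res_n,
            "standardized_nuclei": z_n,
            "residual_volume": res_v,
            "standardized_volume": z_v,
        },
        index=pd.Index(shared, name="tissue"),
    )
    out_n = [t for t, z in zip(shared, z_n) if abs(z) > outlier_threshold]
    out_v = [t for t, z in zip(shared, z_v) if abs(z) > outlier_threshold]
    return TruthComparison(
        method=method,
        shared_tissues=list(shared),
        excluded_tissues=excluded,
        corr_nuclei=corr_nuc,
        corr_volume=corr_vol,
        corr_nuclei_volume=corr_nv,
        residuals=residuals,
        outliers_nuclei=out_n,
        outliers_volume=out_v,
    )
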