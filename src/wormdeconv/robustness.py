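"""Replicate-correlation robustness of deconvolution output.

Worms collected on the same day of adulthood are biological replicates;
if deconvolution is reproducible, the proportion vectors of same-day
pairs should correlate far better than randomly chosen pairs from
different days. This module computes every intra-day pairwise
correlation and a large seeded baseline of random cross-day pairs
(default 100,000 draws), for Spearman (default) or Pearson
coefficients.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import ProportionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "CorrelationSummary",
    "intra_day_correlations",
    "random_pair_baseline",
    "summarize_robustness",
]

_METHODS = ("spearman", "pearson")


def _check_method(method: str) -> None:
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")


def _row_transform(values: np.ndarray, method: str) -> np.ndarray:
    """Center (and for Spearman, rank) each row, normalised to unit norm.

    Rows with zero variance come back as all-NaN so that any correlation
    involving them is undefined rather than silently 0 or 1.
    """
    x = values.astype(float)
    if method == "spearman":
        x = rankdata(x, axis=1)
    x = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(x, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norm > 0, x / norm, np.nan)
    return out


def intra_day_correlations(
    proportions: ProportionMatrix, method: str = "spearman"
) -> tuple[dict[int, np.ndarray], int]:
    """Correlation of every unordered same-day sample pair.

    Returns ``(per_day, n_undefined)`` where ``per_day`` maps each day
    with >= 2 samples to the array of its pairwise coefficients and
    ``n_undefined`` counts pairs excluded because one vector had zero
    variance (zero rank variance for Spearman).
    """
    _check_method(method)
    if proportions.values.shape[1] < 3:
        raise ValueError(
            "need >= 3 cell-type columns for an informative correlation"
        )
    z = _row_transform(proportions.values.to_numpy(), method)
    days = proportions.day.to_numpy()
    per_day: dict[int, np.ndarray] = {}
    n_undefined = 0
    for day in np.unique(days):
        idx = np.flatnonzero(days == day)
        if len(idx) < 2:
            continue
        block = z[idx]
        corr = block @ block.T
        iu = np.triu_indices(len(idx), k=1)
        vals = corr[iu]
        bad = np.isnan(vals)
        n_undefined += int(bad.sum())
        per_day[int(day)] = vals[~bad]
    if not per_day:
        raise ValueError("no day has >= 2 samples")
    if n_undefined:
        log.warning("%d intra-day pairs undefined (zero variance)", n_undefined)
    return per_day, n_undefined


def random_pair_baseline(
    proportions: ProportionMatrix,
    method: str = "spearman",
    n_random_pairs: int = 100_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlations of random cross-day sample pairs.

    Draws ``n_random_pairs`` unordered pairs uniformly (with replacement
    across draws) conditioned on the two samples having different day
    labels. Returns ``(coefficients, pairs)`` where ``pairs`` is the
    (n, 2) array of drawn sample positions; undefined coefficients are
    dropped from ``coefficients``.
    """
    _check_method(method)
    days = proportions.day.to_numpy()
    if len(np.unique(days)) < 2:
        raise ValueError("need >= 2 distinct days for a cross-day baseline")
    rng = np.random.default_rng([seed, 4])
    n = len(days)
    pairs = np.empty((0, 2), dtype=np.int64)
    while len(pairs) < n_random_pairs:
        draw = rng.integers(0, n, size=(2 * (n_random_pairs - len(pairs)) + 16, 2))
        ok = days[draw[:, 0]] != days[draw[:, 1]]
        pairs = np.concatenate([pairs, draw[ok]])
    pairs = pairs[:n_random_pairs]
    z = _row_transform(proportions.values.to_numpy(), method)
    vals = np.einsum("ij,ij->i", z[pairs[:, 0]], z[pairs[:, 1]])
    kept = vals[~np.isnan(vals)]
    if len(kept) < len(vals):
        log.warning(
            "%d baseline pairs undefined (zero variance)", len(vals) - len(kept)
        )
    return kept, pairs


@dataclass
class CorrelationSummary:
    """Intra-day vs random-baseline correlation summary."""

    method: str
    per_day: dict[int, np.ndarray]
    baseline: np.ndarray
    per_day_mean: dict[int, float]
    intra_day_mean: float
    baseline_mean: float
    difference: float
    n_random_pairs: int = 100_000
    seed: int = 0
    n_undefined: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Tidy (day, pair_id, method, coefficient, is_baseline) table."""
        rows = []
        for day, vals in sorted(self.per_day.items()):
            for i, v in enumerate(vals):
                rows.append((day, i, self.method, float(v), False))
        for i, v in enumerate(self.baseline):
            rows.append((-1, i, self.method, float(v), True))
        return pd.DataFrame(
            rows, columns=["day", "pair_id", "method", "coefficient",
                           "is_baseline"],
        )


def summarize_robustness(
    intra: dict[int, np.ndarray],
    baseline: np.ndarray,
    method: str = "spearman",
    n_random_pairs: int = 100_000,
    seed: int = 0,
    n_undefined: int = 0,
) -> CorrelationSummary:
    """Pool intra-day and baseline coefficients into a summary.

    The pooled intra-day mean weights every pair equally (pairs pooled
    across days); the headline statistic is the difference between the
    pooled intra-day mean and the baseline mean.
    """
    if not intra or all(len(v) == 0 for v in intra.values()):
        raise ValueError("no defined intra-day coefficients")
    if len(baseline) == 0:
        raise ValueError("no defined baseline coefficients")
    per_day_mean = {d: float(np.mean(v)) for d, v in intra.items() if len(v)}
    pooled = np.concatenate([v for v in intra.values() if len(v)])
    intra_mean = float(pooled.mean())
    base_mean = float(np.mean(baseline))
    return CorrelationSummary(
        method=method,
        per_day=intra,
        baseline=np.asarray(baseline, dtype=float),
        per_day_mean=per_day_mean,
        intra_day_mean=intra_mean,
        baseline_mean=base_mean,
        difference=intra_mean - base_mean,
        n_random_pairs=n_random_pairs,
        seed=seed,
        n_undefined=n_undefined,
    )
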