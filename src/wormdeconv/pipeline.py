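"""End-to-end pipeline: signature -> deconvolution -> robustness
(-> ground truth when a truth table is supplied).

Every intermediate is written to the output directory as TSV with
provenance comments, plus a YAML run manifest recording configuration,
seeds and package version. Re-running an identical configuration yields
byte-identical tables.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .datatypes import ValidationError
from .deconv import DeconvolutionConfig, DeconvolutionResult, deconvolve, \
    mean_proportions_by_day
from .groundtruth import (
    CURATED_TISSUES,
    TruthComparison,
    aggregate_proportions,
    correlate_with_truth,
    tissue_fractions,
)
from .robustness import (
    CorrelationSummary,
    intra_day_correlations,
    random_pair_baseline,
    summarize_robustness,
)
from .signature import SignatureConfig, build_signature, prepare_markers

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class PipelineConfig:
    """File paths and stage settings for one pipeline run."""

    reference_path: str
    markers_path: str
    bulk_path: str
    truth_path: str | None = None
    mapping_path: str | None = None
    modality: str = "rna"
    signature: SignatureConfig | None = None
    deconvolution: DeconvolutionConfig = field(default_factory=DeconvolutionConfig)
    correlation_method: str = "spearman"
    n_random_pairs: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in ("rna", "protein"):
            raise ValidationError("modality must be 'rna' or 'protein'")
        if self.signature is None:
            # proteomics implies the 5-marker count requirement by default
            self.signature = (
                SignatureConfig.proteomics()
                if self.modality == "protein"
                else SignatureConfig.rna()
            )


@dataclass
class PipelineResult:
    signature: "pd.DataFrame"
    excluded_cell_types: dict[str, str]
    deconvolution: DeconvolutionResult
    day_means: "pd.DataFrame"
    robustness: CorrelationSummary
    truth_comparison: TruthComparison | None


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    """Execute the full pipeline and write all artefacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        reference = io.read_matrix(config.reference_path, "feature_id")
        markers = io.read_marker_table(config.markers_path)
        bulk = io.read_bulk(config.bulk_path)
    except Exception as exc:
        raise StageError(f"stage 'load' failed: {exc}") from exc

    sig_conf = config.signature
    try:
        kept, excluded = prepare_markers(markers, bulk.feature_ids, sig_conf)
        signature = build_signature(reference, kept)
    except Exception as exc:
        raise StageError(f"stage 'signature' failed: {exc}") from exc
    io.write_signature(signature, outdir / "signature.tsv")

    try:
        result = deconvolve(signature, bulk, config.deconvolution)
    except Exception as exc:
        raise StageError(f"stage 'deconvolution' failed: {exc}") from exc
    io.write_proportions(
        result.proportions, outdir / "proportions.tsv",
        provenance={
            "C": config.deconvolution.C,
            "epsilon": config.deconvolution.epsilon,
            "shared_features": result.shared_feature_count,
            "failed_samples": len(result.failures),
        },
    )
    day_means = mean_proportions_by_day(result.proportions)
    io.write_matrix(day_means, outdir / "day_means.tsv")

    try:
        intra, n_undef = intra_day_correlations(
            result.proportions, config.correlation_method
        )
        baseline, _ = random_pair_baseline(
            result.proportions, config.correlation_method,
            config.n_random_pairs, config.seed,
        )
        robustness = summarize_robustness(
            intra, baseline, config.correlation_method,
            config.n_random_pairs, config.seed, n_undef,
        )
    except Exception as exc:
        raise StageError(f"stage 'robustness' failed: {exc}") from exc
    robustness.to_frame().to_csv(outdir / "correlations.tsv", sep="\t",
                                 index=False)
    summary = pd.DataFrame(
        [
            {
                "method": robustness.method,
                "intra_day_mean": robustness.intra_day_mean,
                "baseline_mean": robustness.baseline_mean,
                "difference": robustness.difference,
                "n_random_pairs": robustness.n_random_pairs,
                "seed": robustness.seed,
            }
        ]
    )
    summary.to_csv(outdir / "robustness_summary.tsv", sep="\t", index=False)

    comparison = None
    if config.truth_path is not None:
        try:
            truth = io.read_ground_truth(config.truth_path)
            fractions = tissue_fractions(truth)
            mapping = (
                io.read_mapping(config.mapping_path)
                if config.mapping_path
                else {t: t for t in CURATED_TISSUES}
            )
            aggregated = aggregate_proportions(result.proportions, mapping)
            day_means_t = mean_proportions_by_day(aggregated)
            young = day_means_t.iloc[0].drop("unmapped", errors="ignore")
            comparison = correlate_with_truth(
                young, fractions, config.correlation_method
            )
        except Exception as exc:
            raise StageError(f"stage 'groundtruth' failed: {exc}") from exc
        comparison.residuals.to_csv(outdir / "truth_residuals.tsv", sep="\t")
        pd.DataFrame(
            [
                {
                    "method": comparison.method,
                    "corr_nuclei": comparison.corr_nuclei,
                    "corr_volume": comparison.corr_volume,
                    "corr_nuclei_volume": comparison.corr_nuclei_volume,
                    "outliers_nuclei": ";".join(comparison.outliers_nuclei),
                    "outliers_volume": ";".join(comparison.outliers_volume),
                }
            ]
        ).to_csv(outdir / "truth_comparison.tsv", sep="\t", index=False)
    else:
        log.info("no ground-truth table supplied; comparison stage skipped")

    from importlib.metadata import version, PackageNotFoundError

    try:
        pkg_version = version("wormdeconv")
    except PackageNotFoundError:
        pkg_version = "unknown"
    io.write_config(
        {
            "reference": str(config.reference_path),
            "markers": str(config.markers_path),
            "bulk": str(config.bulk_path),
            "truth": None if config.truth_path is None else str(config.truth_path),
            "mapping": None if config.mapping_path is None else str(config.mapping_path),
            "modality": config.modality,
            "signature": {
                "top_k": sig_conf.top_k,
                "min_marker_count": sig_conf.min_marker_count,
                "min_marker_score": sig_conf.min_marker_score,
            },
            "deconvolution": {
                "C": config.deconvolution.C,
                "epsilon": config.deconvolution.epsilon,
                "scale": config.deconvolution.scale,
            },
            "robustness": {
                "method": config.correlation_method,
                "n_random_pairs": config.n_random_pairs,
                "seed": config.seed,
            },
            "excluded_cell_types": excluded,
            "version": pkg_version,
        },
        outdir / "manifest.yaml",
    )
    return PipelineResult(
        signature=signature.values,
        excluded_cell_types=excluded,
        deconvolution=result,
        day_means=day_means,
        robustness=robustness,
        truth_comparison=comparison,
    )
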