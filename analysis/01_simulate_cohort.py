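#!/usr/bin/env python
"""Simulate the study inputs: a single-cell reference with scored
markers and an aging cohort of single-worm bulk samples.

The cohort follows the default 10-tissue trajectory (shrinking
intestine/muscle/vulval-epidermis, expanding gonadal/uterine/neurons)
over 12 days of adulthood with 5 worms per day and 10% multiplicative
noise; a proteome-coverage variant keeps 3,500 of the 10,000 features.
Outputs go to results/data/.
"""
from pathlib import Path

import wormdeconv as wd
from wormdeconv import io

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = wd.SimulationConfig(noise_cv=0.1, seed=SEED)  # 10 x 10,000 defaults
    profiles, markers = wd.simulate_reference(cfg)
    bulk, truth = wd.simulate_aging_cohort(cfg, profiles)
    proteome = wd.simulate_proteome_coverage(
        bulk, cfg.resolved_proteome_n_features, SEED
    )

    prov = {"seed": SEED, "generator": "wormdeconv.simulate"}
    io.write_matrix(profiles, OUT / "reference.tsv", prov)
    io.write_marker_table(markers, OUT / "markers.tsv", prov)
    io.write_bulk(bulk, OUT / "bulk_rna.tsv", prov)
    io.write_bulk(proteome, OUT / "bulk_protein.tsv", prov)
    io.write_proportions(truth, OUT / "truth.tsv", prov)

    print(f"reference: {profiles.shape[0]} features x {profiles.shape[1]} "
          f"cell types, {len(markers)} scored markers")
    print(f"cohort: {bulk.n_samples} samples over "
          f"{bulk.metadata['day'].nunique()} days")
    print(f"proteome variant: {proteome.n_features} features")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
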