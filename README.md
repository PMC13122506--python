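# wormdeconv

Cell-type deconvolution of single-worm omics profiles.

Single-worm RNA sequencing and single-worm proteomics measure one whole
*C. elegans* at a time — organism-level resolution, but still a bulk
mixture of all its cells. `wormdeconv` estimates the relative
contribution of each cell type or tissue to such a profile from a
marker-gene signature derived from single-cell RNA sequencing, so that
cohorts of individually profiled worms can be read as per-tissue
trajectories (e.g. the shrinking intestinal and muscle share and the
expanding gonadal/uterine/neuronal share during aging).

## Model

For a bulk profile `y` and a signature matrix `S` (marker genes ×
cell types, reference mean expression), proportions `w` solve

    y ≈ S w,   w ≥ 0,  Σᵢ wᵢ = 1

fitted per sample by linear ε-support-vector regression
(C = 0.001, ε = 0.01 by default; robust ε-insensitive loss), with
negative coefficients clipped and the rest renormalised to the simplex.
Markers pass a specificity-score filter (≥ 0.08) and a top-100-per-type
cut; in proteomics mode, where only ~3,500 proteins are detected, cell
types with fewer than five detected markers are excluded. Robustness is
quantified by comparing same-day replicate correlations of the
proportion vectors against a 100,000-draw random cross-day baseline,
and predictions can be compared against anatomical ground truth
(per-tissue nuclei counts and cell volumes) on a curated
thirteen-tissue scheme. Details: [docs/methods.md](docs/methods.md).

A fully seeded synthetic-cohort generator (`wormdeconv.simulate`)
produces references with planted markers and aging cohorts with known
mixing proportions, so every stage is testable without external data.

## Worked example

```python
import numpy as np
import wormdeconv as wd

cfg = wd.SimulationConfig(n_cell_types=10, n_features=1000,
                          markers_per_type=20, noise_cv=0.1, seed=11)
profiles, markers = wd.simulate_reference(cfg)
bulk, truth = wd.simulate_aging_cohort(cfg, profiles)

kept, _ = wd.prepare_markers(markers, bulk.feature_ids, wd.SignatureConfig.rna())
signature = wd.build_signature(profiles, kept)
result = wd.deconvolve(signature, bulk)

est = result.proportions.values
mae = np.abs(est.to_numpy()
             - truth.values.loc[est.index, est.columns].to_numpy()).mean()
print(f"recovery MAE: {mae:.4f}")

intra, n_undef = wd.intra_day_correlations(result.proportions)
base, _ = wd.random_pair_baseline(result.proportions, seed=11)
s = wd.summarize_robustness(intra, base)
print(f"intra-day Spearman {s.intra_day_mean:.3f} "
      f"vs cross-day baseline {s.baseline_mean:.3f}")
```

prints

```
recovery MAE: 0.0109
intra-day Spearman 0.890 vs cross-day baseline 0.696
```

— the estimator recovers the known proportions of the 60 noisy samples
to about one percentage point per entry, and same-day replicate worms
correlate far better than random pairs from different days, i.e. the
output tracks age-dependent composition rather than noise.

The same pipeline is available from the shell
(`wormdeconv simulate | build-signature | deconvolve | robustness |
compare-truth | run-all`), and the `analysis/` scripts walk through the
full study on a simulated cohort: `01` simulates reference + cohort +
proteome variant, `02` builds the signature and deconvolves (printing
the recovered day-1 → day-12 trajectory per tissue), `03` computes the
replicate-robustness summary, `04` repeats estimation under proteome
coverage, `05` compares predictions with a synthetic anatomical
ground-truth table. Outputs land in `results/`.

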