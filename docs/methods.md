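# Methods

## The deconvolution model

A bulk measurement of a whole worm is a mixture of the signals of its
cell types. Writing the bulk expression vector as `y` (over genes or
proteins) and the reference signature as `S` (genes × cell types, mean
expression of each marker gene in each cell type), the model is

    y ≈ S w,    w ≥ 0,  Σ w = 1,

and `w` is the vector of cell-type proportions. Following the
CIBERSORT-family convention, `w` is estimated per sample by **linear
ε-support-vector regression**: minimise `½‖w‖² + C Σ max(0, |yᵢ − (Sw)ᵢ| − ε)`
over the shared features, with regularisation strength `C = 0.001` and
tube half-width `ε = 0.01` (defaults; documented search ranges
`C ∈ [1e-4, 0.1]`, `ε ∈ [0.001, 0.5]`). The ε-insensitive L1 loss makes
the fit robust to a minority of aberrant features (unmodelled genes,
contamination), which is the practical reason SVR is preferred over
plain least squares in this family of methods. Raw coefficients may be
negative; proportions are obtained by clipping at zero and renormalising
to the simplex. Samples are fitted independently — no information is
shared across worms.

The estimates are **relative transcriptional (or protein-mass)
contributions**, not absolute cell counts: a tissue with large,
transcriptionally active cells is over-represented relative to its
nuclei count. They are meant for tracing trends (aging trajectories,
perturbation responses), not absolute composition.

### Scaling convention

Two identification issues constrain the preprocessing:

1. the proportions are only defined up to the relative scale of the
   mixture and the signature, so an arbitrary per-sample library size
   must be removed;
2. `ε` and the capacity limit implied by `C` are absolute quantities,
   so the fit is only reproducible if the data arrive on a fixed scale.

Both are solved by bringing mixture and signature onto one common
expression scale: the mixture is scaled so its mean over the shared
features equals `scale` (default 50), and the signature matrix is
multiplied by the **single global factor** that gives its entries the
same mean. Per-column scaling of the signature is deliberately avoided:
it would divide each cell type's coefficient by that column's scale and
thereby bias the recovered proportions by each cell type's total signal
(the bias is visible even with an exact non-negative least-squares
solver). A single global factor preserves relative column masses, makes
the estimate exactly invariant to rescaling any one mixture, and places
the default `(C, ε)` in a regime where the documented search ranges span
underfitting (C at 1e-4 with few hundred markers) to near-interpolation.
Measurements are used in linear space (un-logged); mixing is additive in
linear space.

`fit_sample` requires ≥ 2 shared features and ≥ 2 cell types and rejects
zero-variance mixtures. A sample whose coefficients are all ≤ 0 is
reported as unidentifiable; in cohort mode such failures are flagged and
skipped rather than aborting the run.

## Marker selection and the signature matrix

The reference arrives pre-scored: a table of (feature, cell type,
marker score) records plus per-cell-type mean expression profiles. The
marker **score** is the specificity statistic

    score = (own-type expression − mean expression in the other types)
            / own-type expression,  clamped to [0, 1],

i.e. 0 for a gene no more expressed in its type than elsewhere and
→ 1 for a perfectly exclusive marker. The same statistic is used to
score simulated references and to filter real marker tables.

Eligibility pipeline (in order): drop markers absent from the bulk
dataset ("available" markers), drop markers with score < 0.08, keep the
top 100 markers per cell type (descending score, ties broken by feature
id), then drop cell types with fewer surviving markers than the count
threshold. The count threshold is the modality switch: **0 for RNA**
(every cell type is estimated) and **5 for proteomics**, where shallow
coverage (~3,500 detected proteins) makes estimates from a handful of
markers unreliable. Applying the count filter after the availability
filter means it acts on detectable markers, which is the point of the
proteomics preset. The signature matrix is the union of retained marker
features (each feature once, even when it marks several cell types) by
retained cell types, filled with reference mean expression, rows and
columns sorted.

## Synthetic cohorts

The generator emulates the study design end-to-end so that every stage
is testable against known truth:

* **Reference**: per-gene baseline expression is log-normal
  (`meanlog 3, sdlog 1`, a CPM-like scale with heavy right tail);
  between-cell-type biological variation is multiplicative log-normal
  with CV 0.5 (cell types differ genome-wide, not only at markers).
  Each cell type receives `markers_per_type` disjoint markers whose
  own-type expression is pinned to `fold_change ×` their mean expression
  in the other types, so a planted marker's specificity score is exactly
  `1 − 1/fold_change` (0.8 at the default fold change 5) and the 0.08
  eligibility threshold is met deterministically for any fold change ≥ 2.
* **Aging cohort**: true proportions interpolate linearly (then
  renormalise) between day-1 and final-day endpoint compositions. The
  default 10-tissue trajectory encodes the canonical aging pattern —
  intestine 19.3 % → 5.2 %, muscle 10.7 % → 3.6 %, vulval/epidermis
  7.9 % → 1.2 % shrinking; gonadal 7.2 % → 14.4 %, neurons 2.7 % → 7.8 %,
  uterine 7.5 % → 23.3 % expanding — with the remaining mass over
  hypodermis, pharynx, germline and spermatheca. Defaults: 12 days ×
  5 replicate worms. Each sample is `profiles · w(day)` times
  mean-one multiplicative log-normal noise with CV 0.1 per feature
  (positive-valued omics intensities; noise_cv = 0 reproduces the
  mixture exactly).
* **Proteome coverage**: a seeded uniform subsample of features
  (default min(3500, n_features)), modality flag set to `protein`.
  Uniform dropout is a deliberate simplification — real proteomic
  detection is probably abundance-biased, but no detection model is
  available to calibrate against, and uniform dropout already produces
  the qualitatively correct effect (fewer markers per type, higher
  recovery error, cell types at risk of falling under the 5-marker
  rule).

What the generator does **not** emulate: count noise and zero inflation
of sequencing, abundance-dependent protein detection, batch structure,
cross-subject reference mismatch (the signature used for deconvolution
is the same one that generated the data), and biological deviation from
linear mixing. Passing tests therefore demonstrate correctness of the
estimator and pipeline under the model's own assumptions, not accuracy
on real single-worm data.

## Replicate-correlation robustness

Worms collected the same day are biological replicates. For each day
with ≥ 2 samples, every unordered pair's proportion vectors (over cell
types) are correlated — Spearman by default, Pearson as an alternative —
giving n(n−1)/2 coefficients per day. The baseline draws 100,000 random
unordered pairs conditioned on different day labels (with replacement
across draws, since small cohorts have fewer than 100,000 distinct
cross-day pairs), seeded. Zero-variance vectors make a coefficient
undefined; such pairs are excluded from means and counted in the log
rather than being imputed as 0. The headline statistic is the pooled
intra-day mean minus the baseline mean: positive and large means
replicate worms agree while different ages differ, i.e. the output is
reproducible signal rather than noise. Rank correlation over ~10
proportions is coarse (needs ≥ 3 cell types; granularity 1/(n(n²−1)/6)),
which is why both methods are first-class.

## Anatomical ground truth

Nuclei counts and total cell volumes per tissue give two anatomical
composition measures: `nuclei_fraction = nuclei / Σ nuclei` and
analogously volume. Deconvolution output is aggregated onto the curated
thirteen-tissue scheme (intestine, hypodermal cells, muscle, gonadal,
uterine-vulval, neurons, spermatheca, sp-ut junction, vulval, int-rect
valve, glia, distal tip, coelomocytes) by summing mapped cell-type
proportions; the cell-type → tissue mapping ships as an editable
key-value file because reference-atlas labels differ between atlases.
Unmapped cell types go into an explicit `unmapped` residual column so
row sums stay exact. Comparison uses day-1 mean proportions by default
(the anatomical tables are from young adults) and reports three
correlations (prediction vs nuclei, prediction vs volume, nuclei vs
volume) plus per-tissue residuals from the least-squares line of
prediction on each truth fraction.

**Outlier rule**: a tissue is flagged when its |standardized residual|
exceeds a threshold (default 2.0). The residual is standardized by a
robust scale, 1.4826 × MAD of the residuals (falling back to the
population SD when the MAD is zero, and treating residuals below 1e-12
as exactly zero). A robust scale is the appropriate choice here because
the question is "which single tissues depart from an otherwise
consistent relation" — with a plain sample SD a single strong outlier
inflates its own denominator, and with few tissues (n ≈ 6–13) the
maximum attainable |z| under the sample SD is (n−1)/√n ≈ 2, making a
threshold of 2 unusable by construction.

## Numerical and design notes

* SVR is solved by libsvm's deterministic SMO (scikit-learn `SVR`,
  linear kernel); with identical inputs the fit is bitwise reproducible,
  and all simulation randomness flows from explicit integer seeds
  through `numpy.random.default_rng`.
* The non-negative least-squares estimator (`nnls_proportions`) applies
  the same scaling and serves as an independent oracle on clean
  mixtures; it is never used as the production estimator (no robustness
  to aberrant features).
* Grid search evaluates the full (C, ε) grid against known truth by
  mean absolute recovery error, ties broken toward smaller C then
  smaller ε. On noiseless synthetic data the error surface is nearly
  flat in C above ~1e-3, so the argmin may sit anywhere on the
  low-error plateau; the informative structure is the degradation at
  the underfitting corner (C = 1e-4) and at large ε.
* Top-k marker ties are broken by ascending feature id (platform-stable
  ordering); signature rows/columns are sorted; all writers emit
  full-precision floats so re-runs are byte-identical.
* Problem sizes used in the shipped tests and acceptance script —
  cohorts of 10 cell types × 1,000 features (20 markers/type) for
  recovery checks and 10 × 10,000 (100 markers/type, 10 cohorts) for
  the coverage comparison — were chosen to keep the full suite fast
  while leaving every estimate well inside its tolerance.

## Known limitations

* Proportions are transcript/protein-mass shares, not cell counts; the
  anatomical comparison quantifies exactly this gap (neurons are the
  canonical example: ~30 % of nuclei, marginal transcript share).
* The proteomics mode reuses transcriptome-derived markers; no
  protein-level marker atlas is modelled.
* Uniform proteome dropout understates the loss of low-abundance
  markers relative to real data.
* The robustness statistic compares means only; no significance test
  of intra-day vs baseline distributions is attempted.
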