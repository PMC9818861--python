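# Methods

`msfingerprint` implements the dry-lab half of a non-targeted LC-HRMS
authenticity test for two closely related food classes (the motivating case
is spelt vs common wheat). The wet-lab half — duplicate protein extraction,
digestion and LC-HRMS measurement of a set of cultivars per class — is out
of scope; this package starts at centroided MS1 spectra in mzXML and ends at
calibrated classification scores, precision parameters and Youden plots.

## From spectra to images

Each measurement is an ordered list of MS1 scans; MS2 and higher levels are
discarded on read. A run becomes a 2-D matrix with one row per scan
(retention time) and one column per integer m/z bin: every centroid's
intensity is added to the bin its m/z rounds to (nearest integer, halves
away from zero). Bins run inclusively from `mz_min` to `mz_max`, so the
default 400–1200 Da window yields 801 columns. Summation (rather than a
per-bin maximum) was chosen as the aggregation statistic: it conserves total
ion current, which makes linear in-silico mixing commute with aggregation.
Runs longer than the configured scan count are truncated at the end; shorter
runs are padded with zero rows. No peak alignment, baseline correction or
feature selection is applied — absorbing small m/z and retention-time shifts
is delegated to the convolutional classifier.

Each row is then z-normalized: subtract the row mean, divide by the row's
population SD. Rows with zero variance (including padding) map to all-zero
rows rather than NaN. Normalization is applied once; the API rejects double
normalization because the transform is defined on intensities.

**Artificial mixes.** Processed-food blends are emulated by a weighted
elementwise sum of two *raw* matrices (e.g. 0.9 of a class-A spectrum plus
0.1 of a class-B spectrum), normalized afterwards. Mixing on raw intensities
keeps the operation physically interpretable (ion currents add).

## Synthetic fingerprints

No public raw data accompanies the method, so the package carries a
first-class generator that emulates the calibration design: 2 classes × 11
cultivars × duplicate runs = 44 spectra. The generative model is:

* a dataset-level set of chromatographic peaks, each with an m/z location
  (uniform in the window), a retention-time center, a Gaussian elution
  profile (SD `chrom_width` = 3 scans) and a base amplitude log-uniform in
  10² – 10³ counts;
* `n_shared_peaks` = 60 peaks common to both classes plus
  `n_marker_peaks` = 10 class-specific markers per class, scaled by
  `1 + class_effect` in their own class (default `class_effect` = 2, i.e.
  markers tripled — a strong, cleanly separable signature);
* cultivar-level log-normal intensity multipliers per peak
  (`cultivar_sd` = 0.2 on the log scale), drawn once per cultivar;
* run-level log-normal multipliers (`run_sd` = 0.05) and a whole-scan
  retention-time shift (`rt_jitter_sd` = 1 scan, rounded to an integer)
  drawn per replicate — replicates are measured on different days, so
  between-run variation exceeds pure instrument noise but stays well below
  cultivar-to-cultivar variation;
* per-centroid m/z scatter (SD 0.05 Da, absorbed by integer binning) and
  additive Gaussian intensity noise truncated at zero.

The default scan count is 200. The real measurements are ~7× longer (1375
scans), but every structural property the package's statistics depend on —
counts, fold design, calibration identities, separability — is scan-count
invariant, and 200 scans keeps a full nested cross-validation run on one CPU
core in the ten-minute range. The 1375-scan geometry remains one config key
away (`n_scans: 1375`).

What the generator does **not** emulate: isotope envelopes, charge states,
chimeric/chemical noise structure, nonlinear matrix effects of processed
foods, and class signatures carried by many small correlated differences
rather than discrete marker peaks. Passing tests therefore demonstrate that
the pipeline recovers a planted class signal under realistic hierarchical
noise — not that any particular real commodity pair is separable.

## Classifier

A shallow CNN maps the normalized matrix to a probability: four stacked
(3×3 convolution → ReLU → 2×2 max-pool) stages with 8/16/32/64 filters,
then flatten and a single sigmoid unit. Pooling uses floor semantics (a
200-row image reaches the head at 12 rows). Training minimizes binary
cross-entropy with Adam (learning rate 1e-3, batch size 8) for at most 30
epochs, stopping early once the epoch-mean loss falls below 0.005 — at that
point every training prediction is saturated at the correct label and
further epochs only sharpen saturation. Initialization (He for conv, 1/√n
for the dense head) and shuffling are seeded; runs are reproducible on a
platform, though bit-identity across BLAS builds is not promised.

The network is implemented directly on numpy (im2col and shifted-view
matmul convolutions, analytic backprop verified against finite differences
in the test suite). There is deliberately no hyperparameter search: with
~10⁵ features per image and eleven cultivars per class, tuning invites
overfitting, so the defaults above are the entire tuning surface.

Output probabilities are clipped to [1e-6, 1−1e-6] because the downstream
score is linear in log odds, which diverge at 0 and 1.

## Nested cross-validation

Folds are built at cultivar granularity: both replicates of a cultivar
always travel together. Cultivars are sorted lexicographically within each
class and paired by rank; fold *i* holds out pair *i* for testing and trains
on everything else (40 train / 4 test spectra in the 11-cultivar design). A
seeded random pairing mode exists for robustness checks; the partition —
every cultivar tested exactly once — is identical either way. Per-fold
models are independent, seeded `base + fold_index`.

The held-out probabilities of all 44 calibration spectra are the raw
material for score calibration. External samples are scored by all fold
models; their log odds are averaged. Because the D transform is affine,
averaging log odds then transforming equals averaging per-model D scores —
the package averages on the log-odds/D scale, where the mean is exactly
interpretable (probability-scale averaging would not commute with the
transform).

## D scores, calibration and decisions

For sample *i* with probability *pᵢ*:

    Dᵢ = ln(pᵢ / (1 − pᵢ)) · λ + θ,
    λ = 2 / (μ̄_A − μ̄_B),   θ = 1 − λ · μ̄_A,

where μ̄_A, μ̄_B are the class means of the calibration set's held-out log
odds. By construction the calibrated class means are exactly +1 and −1, to
machine precision, for any input — this exactness is asserted in the tests.
The decision threshold is zero: D > 0 calls class A, D < 0 class B; D = 0 is
reported as "inconclusive" rather than forced into a class. Because the
transform is affine and fitted to the class means, the scores are invariant
to which class the raw CNN probability was oriented toward; orientation is
nonetheless explicit config (`positive_class`).

Performance is summarized by the Matthews correlation coefficient of the
held-out confusion table; a zero denominator factor returns MCC = 0 (the
standard convention), and the implementation is tested against the Pearson
correlation of the truth/prediction indicator vectors, to which MCC is
mathematically identical.

## Precision parameters and risk

Following single-laboratory precision concepts (intermediate precision in
the sense of ISO 5725-3), two SDs are reported per class:

* **classification SD** — sample SD of all individual D scores of the class.
  "Variation within a class" could also be read as variation of cultivar
  means; the all-scores reading is primary because the normal risk model
  treats the class point cloud as one distribution centred at ±1. The
  cultivar-means SD is reported as a secondary column.
* **intermediate SD** — pooled within-cultivar replicate SD,
  √(mean over cultivars of per-cultivar sample variance); for duplicates
  this equals √(mean((d₁−d₂)²/2)).

Misclassification risk assumes D scores are normal within a class: for a
class with mean above the zero threshold it is Φ((0 − mean)/SD), mirrored
for a negative-mean class. A class at +1 with SD 0.393 gives
Φ(−1/0.393) = 0.547% ≈ 0.5%. Normality is not enforced; a skew/kurtosis
diagnostic is logged when reports are built. The analytic tail is tested
against a Monte-Carlo oracle.

## Youden plots and reporting

Each cultivar contributes one point (run-1 D score, run-2 D score).
Quadrant I (both positive) is a concordant class-A call, III a concordant
class-B call, II/IV discordant replicates, with exact zeros reported as
"axis". Quadrant assignment is a pure function of the score signs and is
cross-checked against the decision table. SVG output is byte-stable for
fixed input (fixed hash salt, no timestamps). Spectral-matrix heatmaps use
power-law intensity normalization (default exponent 0.3) for visual
contrast.

`run_pipeline` chains all stages from one YAML/dict config and emits a
bundle: held-out probability table, calibration parameters, D-score table,
precision report (CSV + JSON), Youden plot and a machine-readable
`summary.json` whose MCC is computed by the same `dscore.mcc` used
everywhere else (no parallel computation paths).

## Numerical choices and degenerate inputs

* Population SD in row normalization; SD = 0 rows → zero rows.
* Rounding of m/z: nearest integer, half away from zero.
* Probability clipping ε = 1e-6; log odds at the clip bound ≈ ±13.82.
* Calibration requires distinct class means; equal means raise a
  degenerate-calibration error rather than emitting infinities.
* A class mean exactly on the decision threshold returns risk 0.5 with a
  warning; SD ≤ 0 is an error.
* mzXML peaks are written as 32-bit network-order floats without
  compression (the most interoperable dialect); centroids that collide
  after the float32 round trip are merged on read.
* Profile-mode (non-centroided) input is neither detected nor converted —
  a documented limitation.

## Known limitations

Single-laboratory scope (no between-lab reproducibility), exactly-two-class
designs, centroid-only input, and a synthetic-data generator whose marker
model is simpler than real proteomic fingerprints. The CLI exposes each
stage (`simulate`, `prepare`, `train-ncv`, `predict`, `dscore`, `precision`,
`report`, `run`) but model files are numpy archives specific to this
package, not a standard interchange format.
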