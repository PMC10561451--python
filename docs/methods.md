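# Methods

## The assay being modeled

A cardiomyocyte line stably expressing an EGFP fusion of the 53BP1
focus-forming region reports DNA double-strand breaks (DSBs): in
undamaged cells the reporter is diffuse in the nucleus, after damage it
aggregates into discrete intranuclear foci. Doxorubicin (DOX) induces DSBs
dose- and time-dependently; a compound co-incubated with DOX that reduces
foci formation is a candidate DSB inhibitor. Two readouts quantify a well:
the mean number of detected foci per cell (threshold pipeline), and the
percentage of foci-positive cells among reporter-expressing cells
(classification pipeline). A primary screen compares 315 compounds, each at
50 µM with 0.5 µM DOX for 1 h, in 3 replicates, with control and DOX wells
on every plate.

## Synthetic data generator

The generator is the toolkit's source of ground truth; all accuracy claims
are made against it.

**Foci law.** Per-cell true foci counts are Poisson with mean
`λ(dose, e) = λ0 + (1 − e)·f_dur·Δ(dose)`,
`Δ(dose) = (λmax − λ0)·dose/(dose + EC50)`. This is a deliberately simple
saturating form chosen for three properties the assay exhibits: monotone
dose response, compound rescue `e` that interpolates between the DOX level
(`e = 0`) and the untreated baseline (`e = 1`), and Poisson cell-to-cell
variance. Defaults: `λ0 = 0.5` foci (spontaneous background), `λmax = 12`
(a countable saturating load for ~14 px nuclei), `EC50 = 0.3 µM` (so the
0.5 µM model dose sits past half-saturation and 0.05 µM is still
detectably above baseline), `f_dur = 1.4` for ≥ 24 h treatments.

**Expression heterogeneity.** Reporter lines show strong cell-to-cell
brightness variation and a fraction of cells with no detectable green
signal at all (silenced or below detection). Per-cell green gain is
log-normal (median 1, log-sd 0.5) with a point mass `p_nonsignal = 0.1` at
zero. `p_nonsignal` is a free parameter of the simulation, not an observed
value. Non-signaling cells keep a bookkeeping foci count but render no
green signal.

**Rendering and camera.** Nuclei are non-overlapping discs (rejection
sampling; radius 14 ± 2 px at a 40×-objective-like 0.325 µm/px scale) with
a soft sigmoid rim and per-nucleus nuclear-stain gain uniform on
[0.3, 1.0] — the wide range is the point, it is what defeats single-global-
threshold segmentation. Foci are isotropic Gaussians (σ = 1.5 px) with peak
amplitude 4× the cell's diffuse green level (±20%). The camera applies a
flat background (100 counts), optional low-order gradient (off by
default), Poisson shot noise, Gaussian read noise (sd 5), and 16-bit
quantization. A `touching_pairs` flag plants tangent nucleus pairs to
stress watershed splitting.

**Seeds.** One top-level seed; per-plate/well/field seeds are spawned with
`numpy.random.SeedSequence` (deterministic counter scheme). Identical
(config, treatment, seed) give bit-identical images and truth.

**Fast mode.** `simulate_screen(..., mode="fast")` emits per-well true
cell records directly from the statistical law without rendering pixels,
so whole-screen statistics (315 × 3 wells, ~200 cells/well) run in
seconds. The mode is recorded in provenance. Fast mode exercises the
sampling and statistics layers but not segmentation/detection; the image
mode and the dedicated benchmarks cover those.

**What the generator does not emulate** (and what passing tests therefore
do not show about real data): optical PSF and focus drift, cytoplasmic
autofluorescence, irregular nucleus shapes, spatially correlated plate
effects (edge effects, gradients across wells), foci clustering beyond
Poisson placement, photobleaching, and imaging-device differences between
batches.

## Segmentation

This stage is often done with a trained segmentation network; fociscreen
instead uses a deterministic classical pipeline with the same input/output
contract — fully testable and free of training artifacts.
Steps: Gaussian smoothing (σ = 2 px); robust global background statistics
(median/MAD — nuclei are sparse, so the median is background); an initial
mask at `background + 6` robust SDs of the smoothed noise (low, to catch
dim nuclei); a low-order background re-estimate with foreground replaced
by the median, subtracted, and the threshold re-applied (handles
gradients); hole filling; then a *per-nucleus half-max refinement*: each
detected blob is cut at `core_fraction = 0.5` of its own
background-subtracted 90th-percentile peak. This last step is what makes
the boundary gain-invariant — a nucleus at gain 0.3 and one at gain 1.0
get the same relative cut. Touching nuclei are split by
distance-transform watershed seeded at distance peaks (min distance
0.7 × expected radius); instances outside the area band (disc areas at
radius ± 3 sd, with 0.5×/1.5× slack) are dropped; labels are relabeled
contiguously. Border-touching nuclei are flagged and excluded from crops
by default (their truncated counts would bias per-cell statistics).

Crops are 64 × 64 px, centered on the centroid, padded with the background
level at field edges. Green normalization uses within-crop percentiles
(p1, p99.5): `g' = clip((g − v_low)/(v_high − v_low), 0, 1)` — exactly
invariant to affine intensity maps before camera clipping. A crop whose
anchor spread is < 1e-6 (flat green) is flagged `low_dynamic_range` and
zeroed; the raw green mean and anchors are kept as absolute
signal-presence features.

## Foci detection

Granularity-style threshold counting with parameters derived from the
generator's spot width and exposed in config: focus diameter range
3–9 px, top-hat disk radius ⌈d_max/2⌉ = 5 px, detection threshold
`median + 4 · 1.4826 · MAD` of the top-hat image inside the nucleus,
minimum peak separation 3 px. Median/MAD rather than mean/SD so that
bright foci do not inflate their own threshold. Numerical choices worth
noting:

- Pixels outside the nucleus are filled with the intranuclear median
  before the top-hat, so the mask boundary produces no rim response.
- A clipped focus saturates the normalized channel into a flat plateau;
  peak finding therefore runs on a lightly smoothed top-hat
  (σ = d_min/3), which turns each plateau into a single maximum, while
  thresholding stays on the raw top-hat.
- An absolute prominence floor (0.05 normalized units) guards the
  noise-free limit where the MAD collapses to zero.
- Centers are integer pixel maxima (no sub-pixel fit); ties resolve by
  the deterministic processing order.

Cells flagged `low_dynamic_range` return `not_evaluable` rather than zero
foci: whether a cell belongs in a denominator is the classifier's call.
Per-well means are over evaluable cells only, with `n_evaluable` reported;
a well with none is *missing*, never 0.

## Classification

Truth labeling: expression gain 0 → `non_signaling`; otherwise
`foci_positive` iff the true foci count ≥ 5. The positivity threshold is
the largest genuinely unconstrained choice in the toolkit; it is a config
value carried in provenance, and all reported accuracies are relative to
it.

`feature_baseline` (default): multinomial logistic regression with
balanced class weights on an 11-dimensional fixed-order feature vector —
raw green mean and raw anchor spread (signal presence), normalized-channel
variance and kurtosis in the mask, top-hat energy, threshold-backend foci
count and summed prominence, a 3-scale granularity spectrum (fraction of
masked intensity removed by openings of radius 1, 2, 4), and mask area.
Deterministic, trains in seconds.

`conv_small` (optional): a compact convolutional network in numpy —
inputs are 32 × 32 × 3 tensors (2 × 2 mean-pooled normalized green, the
nucleus mask, and a constant tanh-squashed raw-brightness plane);
architecture conv(8@5×5)/ReLU/maxpool(4)/dense(32)/ReLU/softmax(3);
weighted cross-entropy with Adam, seeded shuffling. Same-seed training is
exactly reproducible (pure numpy, no threading nondeterminism).

Probabilities form a simplex; argmax ties resolve in the fixed class
order `non_signaling < foci_negative < foci_positive`. Macro accuracy is
the unweighted mean of per-class recalls, so rare classes count equally.

## Screen statistics

- `% foci-positive = 100 · n_pos / (n_pos + n_neg)`; non-signaling cells
  are excluded from the denominator; zero signaling cells → missing.
- `RPS_i = 100 · S_i / median(S_all)` per plate and replicate, median over
  compound wells only — control/DOX wells are not compounds and are kept
  out of the normalizer (they are still RPS-scaled by the same plate
  median for QC display). Plate median 0 is an error, not a silent NaN.
- Ranking: mean RPS over available replicates (count recorded), ascending
  rank, ties broken by compound_id (stable mergesort), lowest `n_select`
  (default 12) flagged selected. No multiple-testing correction is applied
  to the ranking — it ranks, it does not test; QC p-values are reported
  unadjusted and labeled.
- 4PL on log-dose: `y = bottom + (top − bottom)/(1 + exp(h·(ln d − ln IC50)))`
  with span ≥ 0 enforced by parameterization (the Hill slope carries
  orientation), multi-start least squares (IC50 starts at log-dose
  quartiles, Hill starts ±1, ±2), zero doses mapped to 0.01× the smallest
  positive dose. Flat data or a collapsed span/slope yields an honest
  non-converged fit with no IC50.
- Mann-Whitney U with midranks; U is reported for the first sample as
  pairs(x > y) + ½ ties, so identical samples give `n1·n2/2` and
  all-x-below-y gives 0. Two-sided p is exact — full enumeration of
  group-label assignments over the pooled midranks, which remains valid
  under ties — when `n1·n2 ≤ 400` and the enumeration is feasible
  (≤ 5·10^5 assignments), using the symmetric tail
  `|U − n1·n2/2| ≥ |u_obs − n1·n2/2|`; otherwise the normal approximation
  with tie and continuity corrections.
- QC: ECDF of mean RPS, fixed 10-RPS-unit histograms of control vs
  selected wells, and the Mann-Whitney comparison between them.

## Pipeline and provenance

The YAML run config rejects unknown keys at any level before any compute.
A 12-hex-digit SHA-256 config hash (excluding the output directory) is
written into a leading comment line of every CSV and into
`provenance.json`. With the `feature_baseline` backend, re-running the
same config and seed reproduces byte-identical CSVs. Stage logs record
counts (cells found, crops kept, cells classified); cell counts are
non-increasing along the pipeline — stages only exclude, never invent.

## Problem sizes used in tests and the acceptance script

Chosen as the smallest sizes at which the checked statistics are stable:
segmentation F1 on 20 default 1024 × 1024 fields (~80 nuclei each, gains
spanning [0.3, 1.0]); foci-count error on 1000 planted single-cell crops
at default SNR (0–10 foci, well separated); classifier on 1500 training /
500 held-out generator-rendered crops; screen recovery on the full
315 × 3 design in fast mode with 12 planted actives at `e = 0.85`; 4PL
Monte Carlo over 200 curves at 5% relative response noise; determinism on
a 4-compound image-mode screen at 320 × 320 px.

## Known limitations

- The classical segmenter assumes roughly convex, non-overlapping nuclei;
  heavily confluent fields or irregular shapes would need a learned
  model, which is out of scope.
- Foci counting reports counts only (no per-focus intensity/area dose
  metrics), does not attempt sub-pixel localization, and merges foci
  closer than the minimum separation — at high damage loads counts
  saturate below the true value.
- The dose law, expression model and noise model are simulation choices;
  parameters estimated from them (e.g., EC50-scale behavior) calibrate
  the machinery, not the biology.
- Fast-mode screen statistics inherit truth labels; they validate the
  normalization/ranking layer, not the imaging layers.
- The hit rule implemented is the 12-lowest-mean-RPS selection; other hit
  definitions (e.g., deviation-based cutoffs yielding different hit
  counts) are not modeled.
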