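# Methods

This note records the modelling assumptions, default parameters, and
numerical choices behind `mrigrade`, in the order the pipeline runs.

## Images and normalization

All operators work on 2-D float arrays in [0, 1] (row-major, origin
top-left). PNG inputs are scaled by the bit-depth maximum; RGB collapses
to luminance with the BT.601 weights (0.2989/0.5870/0.1140 at full
precision, so pure white maps exactly to 1.0). Feature extraction
assumes both dimensions ≥ 8; resizing is bilinear with output clipped to
[0, 1]. Dataset directories are read in lexicographic filename order so
feature matrices are identical across platforms. Stratified splits round
the per-class training count half-up and are driven by a single seed.

## The 90-feature hybrid descriptor

The default budget per extractor family (configurable; the default must
total 90):

| family | n | defaults |
|---|---|---|
| GLCM | 20 | 8 gray levels, offsets (0,1),(−1,1),(−1,0),(−1,−1), symmetric, normalized; 5 statistics per offset |
| LBP | 10 | radius 1, P = 8, uniform rotation-invariant mapping (10 bins) |
| RLBP | 10 | radial means over radii 1..3 before thresholding |
| LTP | 10 | band half-width t = 0.1; upper/lower 10-bin histograms each merged pairwise to 5 bins |
| region metrics | 16 | area, centroid (2), convex area, equivalent diameter, Euler number, extent, major/minor axis, orientation, eccentricity, perimeter, filled area, solidity, bbox height/width |
| BIBS | 8 | 8 rays from the centroid, max-normalized |
| Gabor | 8 | f ∈ {0.1, 0.25} cycles/px × θ ∈ {0, π/4, π/2, 3π/4}, σ = 2, half-width 7 |
| log-energy | 4 | Haar wavelet, 2 levels, ε = 1e−12 |
| PCA filter | 1 | 8×8 tiles, mean |first-PC score| |
| ICA filter | 1 | FastICA (deflation, logcosh, ≤200 iter, tol 1e−4); PCA fallback on non-convergence |
| fractal dimension | 1 | box counting, slope clipped to [0, 2] |
| shape signature | 1 | boundary bbox width/height |

Conventions worth knowing:

- **Quantization** is equal-width binning of [0, 1] with the top bin
  closed (1.0 falls in bin `levels−1`).
- **GLCM statistics** use energy = Σp² (angular second moment), entropy
  in bits with 0·log 0 := 0, homogeneity = Σ p/(1+|i−j|) (the
  inverse-difference form, not the squared-difference variant), and
  correlation defined as 0 when a marginal standard deviation vanishes.
- **LBP-family sampling** places P neighbours counter-clockwise from
  east, bilinearly interpolated; "neighbour ≥ centre" sets the bit, with
  a 1e−12 slack so flat regions deterministically code all-ones; only
  interior pixels (full circle inside the image) are coded. LTP codes a
  neighbour +1/0/−1 against the band centre ± t and splits into upper and
  lower binary maps.
- **Gabor kernels** follow the discrete form with envelope
  exp(−(i²+j²)/2σ) — σ carries squared-pixel units — and the free
  amplitudes are fixed by unit L2 norm. Features are mean magnitudes of
  the even/odd responses under reflect-padded "same" convolution, which
  makes them nonnegative and insensitive to the phase of a texture.
- **Log-energy** cascades the approximation subband, summarises each of
  the four subbands per level by the mean natural-log magnitude of its
  centred 2-D FFT, and sums successive differences across levels; ε
  stabilises the logarithm because Haar detail subbands of flat regions
  are exactly zero. One level therefore yields exactly [0, 0, 0, 0].
- **Segmentation** for the shape families is Otsu thresholding (256
  bins) keeping the largest 8-connected component; the perimeter metric
  counts contour pixels (object pixels with a background 4-neighbour),
  which equals the step count of a simple closed 8-connected border walk
  and is directly oracle-checkable. Euler numbers pair 8-connected
  objects with 4-connected background.
- **Degenerate images**: a constant image has no Otsu object, so the
  pipeline substitutes zeros for the shape block (and for any non-finite
  value anywhere) and logs the substitution; the standalone shape
  functions still raise. This keeps the "90 finite features on any valid
  image" contract without hiding errors in interactive use.

## PCA reduction

Features mix wildly different scales (areas vs histogram masses), so the
reducer z-scores first (zero-variance columns get scale 1), then
eigendecomposes the sample covariance. Loadings are completed to a full
orthonormal basis when n < d so that the k = d transform round-trips
exactly; eigenvalues are clamped at 0; each column's sign is fixed so its
largest-magnitude entry is positive (a deterministic convention, since
eigenvectors are sign-ambiguous). Component selection takes the smallest
k whose normalized cumulative eigenvalue sum reaches the threshold,
default 0.999 — "all of the variance" up to float round-off; the
retained k is data-dependent and intentionally not asserted anywhere.

## Classical classifiers

All six families are sklearn-style estimators (fit/predict/get_params)
and share two tie conventions: equal votes or scores resolve to the
lowest class label, equal distances to the lower training index.

- **Twoing decision tree** — binary axis-aligned splits at midpoints of
  consecutive distinct sorted values, scored by the CART twoing
  criterion (P_L·P_R/4)(Σ|p(c|L)−p(c|R)|)², bounded by 0.25; Gini gain is
  available as an alternative. Growth is best-first (globally highest
  score next) so a `max_splits` cap spends its budget on the strongest
  splits; the default cap of 138 reflects a typical optimized value for
  this problem family. Sample weights are supported for boosting.
- **Correlation KNN** — distance 1 − Pearson r between feature vectors
  (constant vectors are uncorrelatable and get distance 1); default
  k = 12 with the correlation metric. Correlation distance needs ≥ 3
  informative dimensions to discriminate; it is intended for the reduced
  feature space, not for toy 2-D data.
- **Pooled LDA** — shared within-class covariance with a ridge of
  1e−6·trace/d, so collinear features never break the solve; empirical
  priors.
- **Gaussian naive Bayes** — per-class diagonal Gaussians with variances
  floored at 1e−9.
- **Linear SVM** — one-vs-one hinge-loss problems solved to tolerance
  1e−4 (libsvm SMO); per-class decision values are exposed for ROC
  analysis.
- **Ensembles** — Bag (bootstrap + majority vote), AdaBoost in the
  discrete multiclass SAMME form with a configurable learning rate, and
  RUSBoost, which before each boosting round undersamples every class to
  the minority-class count (weight-proportional, without replacement)
  and fits the weak tree on the balanced subsample while computing the
  boosting error and weight update on the full set. The per-round class
  counts are recorded in `resample_counts_` for inspection. Rounds no
  better than chance are skipped; a zero-error round stops boosting.
- **Hyperparameter search** — seeded random search over per-family
  grids (tree: max_splits 1–199 and criterion; KNN: k 1–30 and metric;
  SVM: C on a log grid 1e−3–1e3; ensembles: n_learners 5–99, learning
  rate 1e−3–1, max_splits 1–49; NB/LDA: nothing to tune), scored by
  stratified k-fold misclassification (k = 5, reduced if a class is
  smaller). Ties keep the first candidate, so a fixed seed fixes the
  chosen spec.

## The 20-layer CNN

The architecture is fixed: image input; three blocks of
[conv 3×3 → batch norm → ReLU → max-pool 2×2 stride 2] with 8/16/32
filters; a fourth conv(64) → batch norm → ReLU block without pooling;
dropout 0.5; a dense layer with one unit per class; softmax; and the
cross-entropy classification output — 20 layers with exactly 4
convolutional, 4 normalization, 4 activation and 3 pooling layers.

The network is implemented directly in numpy: im2col convolutions with
same-padding, hand-written backward passes, inverted dropout, batch
normalization with running statistics (momentum 0.9) for inference, and
mini-batch SGD with momentum 0.9, learning rate 0.01, batch size 10. He
initialisation, shuffling and dropout all draw from one seeded
generator, so training is bit-reproducible; training stops early once
training accuracy reaches 1.0 (configurable). The default input is
64×64×1 — the smallest square that survives three poolings with
comfortable margin — which keeps a full 200-image training run in the
tens of seconds on one CPU while retaining enough capacity to memorise
the benchmark (it reaches 100% training accuracy in ~10–25 epochs).

## Evaluation

Confusion rows are true classes, columns predictions. Sensitivity is
row-wise correctness, precision column-wise (prevalence-weighted
sensitivities sum exactly to accuracy); 0/0 rates are reported as 0 with
a warning. ROC curves sweep unique scores descending with ties grouped
and are anchored at (0,0) and (1,1); AUC is the trapezoid area, equal to
the normalized Mann–Whitney U statistic on tie-free scores. Multiclass
AUC is one-vs-rest per class; the headline value of a 4-class report is
the Non-Demented class's AUC, with the macro average reported alongside.

## Synthetic phantoms

Each phantom is a bright ellipse ("parenchyma", 0.85) on a dark
background (0.05) with a mid-gray cortical band (0.55) and a dark
central ventricle ellipse (0.15). Severity 1→4 scales the ventricle
semi-axes through 10/18/28/42% of the brain's and thins the cortical
band through 30/24/18/12% of the semi-minor axis — the two canonical
atrophy markers, and nothing else. Per-image jitter (±5% centre shift,
±10° rotation, ±10% scale) and additive Gaussian noise (default sd 0.05,
clipped to [0, 1]) make classes learnable but not trivially separable:
with the defaults, classical-classifier accuracies on held-out phantoms
fall strictly between chance (0.25) and 1, while the linear SVM and the
CNN can exceed 0.8.

What the phantoms deliberately do **not** emulate: real MRI contrast,
bias fields, skull/scalp anatomy, partial-volume effects, slice
positioning, or inter-subject variability. Passing benchmarks on
phantoms therefore demonstrates that the pipeline is implemented
correctly and can learn morphology of this kind — not that any reported
accuracy transfers to clinical scans.

## Benchmark scale

The repository's end-to-end benchmark uses 200 phantoms (50 per class,
64×64) for both the classical comparison and CNN training, and 5-fold
(or class-limited) cross-validation with small search budgets. These
sizes were chosen so the complete test suite and the benchmark script
each run comfortably on a single CPU core; all of them scale up by
changing one argument.

## Known limitations

- The RLBP radial-mean construction and the LTP 5-bin compression are
  reasonable defaults for descriptors whose published dimensionalities
  vary; alternative binnings change feature counts and must be
  configured consistently with the 90-total registry.
- The one-component ICA patch filter can fail to converge on
  near-Gaussian tiles; the documented fallback to the PCA filter value
  keeps the feature deterministic but makes the two features identical
  on such images.
- The numpy CNN is single-threaded and CPU-bound; it is a faithful,
  reproducible small network, not a performance implementation.
- Box-counting estimates of fractal dimension on small masks are biased
  by the few available scales; values are clipped to the valid [0, 2]
  range rather than extrapolated.
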