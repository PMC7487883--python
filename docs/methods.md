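# Methods

This note documents the models, parameter choices and numerical conventions
behind `ihcloc`, and what the synthetic benchmarks do and do not establish.

## Stain model and unmixing

Brightfield IHC staining is modelled by the Beer–Lambert law: transmitted
intensity `I = I0 · 10^(-OD)` with the optical density at each pixel a
non-negative combination of two unit-norm stain color vectors,
hematoxylin (DNA, purple) and DAB (target protein, brown).  The pixel-to-OD
transform is `OD = -log10((p + 1)/255)`, clipped at 0; the `+1` offset
avoids `log 0` at black pixels and the clip removes the small negative value
the offset would otherwise give at pure white.  Base-10 logarithms follow
the convention of the stain-separation literature.

**LIN** projects each OD vector onto the two basis rows by pseudo-inverse
and clips negative concentrations to zero (concentrations are physical).
The default basis is the standard Ruifrok–Johnston hematoxylin/DAB pair,
overridable by a 2×3 CSV.  A basis whose Gram matrix has condition number
above 1e8 is rejected.

**NMF** fits a per-image rank-2 factorization `OD ≈ W·H` by coordinate
descent (iteration cap 500, tolerance 1e-5; non-convergence returns the best
iterate with a warning).  A rank-2 non-negative factorization is only unique
up to the choice of a cone containing the data, so the solver is initialized
at the extreme angular directions of the stained-pixel OD cloud (pixels with
OD norm > 0.15, projected on their best-fit SVD plane, 1st/99th angle
percentiles).  This pins the fitted cone to the data cone; generic
double-SVD initializations systematically land on a wider cone (fitted rows
~18° off the true stains even on noise-free images) and are kept only as a
fallback for nearly unstained images.  Note the identifiability limit: a
stain direction is recoverable only if some pixels carry that stain alone.
Nuclear-protein images (class i) have no pure-hematoxylin pixels, so their
fitted hematoxylin row is under-determined even though the reconstruction
error stays at the quantization floor.  Fitted rows are matched to a
reference basis by cosine similarity (ties to identity) so channels always
come back in (dna, protein) order.

8-bit quantization bounds any round-trip through PNG pixels at roughly 1e-2
OD; exactness statements (LIN inverts the generator to <1e-6) therefore
refer to the continuous rendering the generator also exposes.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
histology.  Nuclei are random ellipses (axes 12–26 px by default, rejection
sampling caps mutual overlap at 50%); the protein occupies the nuclei
(class i), 8-px annular rings around them (class ii), or both (class iii).
Each stain's OD is its peak strength (defaults 0.7 hematoxylin, 0.9 DAB —
moderate-to-strong staining) times a smooth random texture field in
[0.55, 1], which gives patches non-trivial co-occurrence structure.
Optional Gaussian OD noise (default 0) is added before quantization.
Everything is deterministic given the seed; per-image seeds are derived as
seed + image index.

`synth_dataset` assigns each protein a normal-state class (cycling i, ii,
iii); a chosen fraction of proteins are biomarkers whose cancer-state images
use the next class in the cycle.  Each protein carries its own stain-strength
(±15%) and nucleus-size jitter, drawn once per protein, so images of one
protein are more alike than images of different proteins — this is what
makes the per-protein partition strictly harder than per-image, mirroring
real datasets where staining conditions are protein-specific.

What the generator does **not** emulate: glands, stroma, unstained tissue
regions, multi-label patterns, staining artifacts, JPEG compression.
Passing synthetic benchmarks therefore demonstrates the pipeline's internal
correctness and statistical calibration, not field performance on real
tissue.

## Patch selection

The protein channel is Gaussian-smoothed (σ = size/8 by default) and
candidate windows on a stride grid (stride = size/2) are scored by their
mean smoothed intensity; means rather than sums keep scores comparable
across sizes during grid search.  Selection is greedy by descending score
with a pairwise area-overlap cap (default 25%) and (row, col) tie-breaks,
so results are deterministic.  Defaults are 205 patches of 75 px for
engineered features and 35 patches of 224 px for deep extraction.  A grid
search helper sweeps counts 25–385 (step 20) × sizes 45–225 (step 30) over
a user-supplied evaluation callback, recording failed cells as missing.

## Engineered features (848)

* **DNA block (16).** Otsu masks (mean fallback for unimodal windows) give
  area and overlap ratios; Manders split coefficients use the standard >0
  support masks so perfect colocalization scores exactly 1; Pearson
  correlation is computed over the mask union; intensity-weighted centroid
  distance and eight nearest-neighbor distance statistics (mean/median/
  std/max in both directions, via Euclidean distance transforms) are
  normalized by the window diagonal.  Degenerate cases are imputed, never
  NaN: zero denominators → 0, zero-variance correlation → 0, empty-mask
  distances → the diagonal (i.e. 1 after normalization).
* **Haralick block (576).** 5-level 2-D DWT with periodization (Daubechies
  db1–db10, default db4) yields 16 subbands (deepest approximation +
  LH/HL/HH per level).  Each subband is min–max quantized to 32 gray levels
  (constant subband → all zeros) and 9 statistics — energy, contrast,
  correlation, variance, homogeneity, sum average, entropy, sum entropy,
  difference entropy; logs base 2, 0·log0 := 0 — are computed from
  symmetric, normalized co-occurrence matrices at the four unit-distance
  offsets.  A subband too small to pair pixels (the 1×1 deepest level of a
  2^5-sided window) gets the degenerate single-entry matrix.
* **LBP block (256).** Classic radius-1 8-neighbor codes (bit b set iff
  neighbor ≥ center, neighbors ordered clockwise from top-left), histogram
  normalized to sum 1.  A constant window puts all mass at code 255.

Image-level vectors are the element-wise mean over the image's patch
vectors, matching the aggregation used for deep features.

## Deep features

`gapnet_pl` is built in full: 8 convolutions (widths w,w,2w,2w,4w,4w,8w,8w;
w=32 by default and scalable — the penultimate width is fixed at 256
regardless), a max pool after each conv pair plus one global-average-pool
module (5 pooling layers), global-average-pool taps after conv 4, conv 6 and
the final pool concatenated into the 256-unit penultimate layer, then two
more fully-connected layers; SELU after every learned layer except the
output, no batch normalization, no ReLU, LeCun-normal initialization.

The six ImageNet-named slots (googlenet, resnet18, resnet50, resnet101,
inception_v3, densenet201) emit the canonical 1000-wide penultimate vector.
In this package they are small random-weight convolutional extractors (three
conv/ReLU/pool stages, GAP, linear head) — deterministic random-projection
features that satisfy every dimensional and aggregation contract and keep
extraction fast on a CPU.  Pretrained weights enter only through an optional
plugin hook; requesting them without a plugin is a configuration error, not
a silent substitution.

All layers carry hand-written backward passes (verified against finite
differences in the test suite), so fine-tuning — replace the output layer,
train all parameters with momentum SGD (lr 1e-3, momentum 0.9, batch 32) —
works end to end.  Learning rates an order of magnitude higher destabilize
the SELU trunk on small batches; 1e-3 descends reliably at test scale.

Single-channel protein patches are peak-normalized, resized bilinearly to
the backbone's input side and replicated across the three input channels.
The combined representation is the fixed-order concatenation
[engineered 848 | six 1000-wide slots | gapnet 256] = 7104 columns; missing
or mis-sized blocks raise rather than silently shrinking the contract.

## Feature selection

Stepwise discriminant analysis on Wilks' Λ = det(W)/det(T) (within-class
over total scatter).  F-to-enter/F-to-remove default to 3.84/2.71 (the
χ²(1) conventions); `max_k` defaults to min(200, n/3) to keep scatter
matrices well-conditioned on small runs.  The candidate scan uses bordered-
determinant Schur complements, so each step is O(d·k²) over all d candidates
— this is what makes selection on the 7104-column combined matrix practical.
Singular scatter is ridge-stabilized (λ = 1e-8 · trace) with a warning.
Removals are skipped if they would break the strict decrease of the Λ trace
(a cycling guard).  Ties break to the lower column index, so selection is
deterministic and permutation-equivariant.

## Classification and evaluation

RBF-SVM with one-vs-one pairwise-coupled probability estimates (the LIBSVM
behavior), features min–max scaled to [0,1] on training statistics only.
(c, g) are chosen by inner 5-fold cross-validated accuracy over a grid —
full grid c ∈ 2^{-5..15}, g ∈ 2^{-15..3} in octave-pair steps; a 3×3
reduced grid is the pipeline default at desk scale — with ties to smaller c
then smaller g.  Outer evaluation is stratified 10-fold over images
(per-image) or stratified grouped folds over proteins (per-protein; no
protein spans train and test).  Metrics: accuracy, macro recall, macro
precision, and F1 as the harmonic mean of the macro pair; empty classes are
excluded from macro averages with a warning.  Protein-level location calls
are majority votes over image predictions, ties broken by the largest mean
score.

## Biomarker screen

Each image's 21-dim score vector concatenates the 3-class probability
triples of the seven single classifiers (one per feature route: engineered
+ one backbone's deep block, SDA-reduced, in the fixed backbone order).
Per protein, a two-sided independent two-sample t-test per dimension
(pooled-variance Student by default; Welch behind a flag) compares the m
normal against the n cancer vectors; zero-variance dimensions are imputed
(p = 1 if means agree, else 0).  The protein is flagged iff min(p) < 0.05
with no multiplicity correction — a deliberately liberal rule whose
inflation under correlated nulls the test suite quantifies; Bonferroni/BH
corrections and a Hotelling T² variant are available but off by default.
Score triples within a vector sum to 1, so the 21 dimensions are strongly
dependent; the per-dimension tests are screening devices, not independent
hypotheses.

Controls: (1) a half-split null — t-tests between random halves of a
protein's normal images, where no true translocation can appear; on
same-class synthetic proteins ≥ 85% of these P values exceed 0.05; (2) an
intensity-distance control — 64-bin protein-channel histograms, all
normal×cancer pairwise Euclidean distances pooled by detection flag and
fitted by maximum-likelihood gamma distributions (location fixed at 0);
similar fits for detected vs undetected proteins indicate detection is not
driven by raw intensity shifts.

## Desk-scale benchmark sizes

The synthetic benchmarks (`ihcloc.benchmark`, also exercised by
`scripts/acceptance.py`) run the full pipeline at sizes a single CPU
finishes in minutes, chosen once as part of the study design: 160-px
images with 10 nuclei; 5 patches of 48 px; deep input side 48 with GapNet
width w=4; SDA capped at 30 features; the reduced SVM grid.  The modeling
set is 18 proteins × (3 normal + 2 cancer) images with no translocations;
the screened set is 20 proteins × (4 normal + 12 cancer) with half the
proteins translocating — the m ∈ [3,6], n ∈ [10,29] structure of real
biomarker collections.  The partition-gap experiment runs on feature-level
synthetic data (3 Gaussian classes, per-protein nuisance offsets, 12
proteins × 5 images, 5 folds, 20 seeds), since the leakage effect under
test is a property of the fold structure, not of image processing.

## Known limitations

* The six ImageNet-named feature slots are random-weight extractors unless
  a pretrained plugin is registered; their discriminative power on real
  images is far below actual pretrained networks.
* The engineered feature set matches the published block sizes (16/576/256)
  and their stated semantics, but the exact historical SLF formulas are not
  reproduced byte-for-byte; every choice is config-exposed.
* The min-p decision rule is anti-conservative by design; users screening
  many proteins should enable a correction.
* NMF stain estimation is unidentifiable for purely co-located stains (see
  above); LIN with a measured basis is preferred when a basis is available.
* The synthetic generator omits tissue-level structure, so benchmark
  accuracies do not transfer to real IHC imagery.
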