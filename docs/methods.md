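# Methods

## Data model and normalization

A capture is a triplet of co-registered cubes — tissue `It`, white
reference `Iw`, dark signal `Id` — in `(row, column, band)` layout.
Reflectance is recovered per pixel per band by flat-field correction
`r = (It − Id) / (Iw − Id)`. The dark signal is subtracted from both
numerator and denominator (one dark capture serves both roles). Entries
whose denominator magnitude falls below `eps = 1e-6` are set to zero and
counted; if more than half of all entries are degenerate the white/dark
pair is rejected as a calibration failure. Negative reflectance from noise
is floored at zero by default.

The band count is data-driven rather than fixed. The nominal instrument
range is 420–750 nm at 1 nm steps, but the package's default axis carries
311 bands over 420–730 nm; the phantom generator spans the full window at
any band count (test configurations use 16–40 bands to keep CPU costs
down), and every algorithm reads the band count from its input.

## Spectral low-rank denoising

The optional denoiser matricises the cube to pixels × bands, projects onto
the top-`rank` right-singular vectors of the global SVD, and reconstructs;
a flag additionally smooths the low-rank spatial coefficient maps with a
small Gaussian as a cheap surrogate for nonlocal spatial similarity. This
is a deliberately simple spectral-low-rank denoiser with a swappable
interface — segmentation quality does not hinge on the denoiser, and
pixel-wise schemes are typically run without it. Without smoothing the
operation is an orthogonal projection, hence idempotent; `iterations=0` is
the identity.

## Foreground masking

The capture surface is a dark porous material, so tissue/background
separation starts from 2-means clustering of per-pixel reflectance
summaries (mean and quartiles across bands), taking the brightest cluster
as the tissue seed. Heavily pigmented tumor can be nearly as dark as the
surface, so brightness alone is not sufficient: the background set is
iteratively re-split in two and a sub-cluster is moved to tissue when its
mean spectrum is spectrally closer (smaller SAM angle) to the tissue mean
than to the darkest-background mean. Morphological opening/closing (disk
radius 2) and removal of connected components below 16 px clean the mask.
Degenerate scenes (uniform cube, single cluster) return an all-ones mask
with a warning rather than failing. Background spectra are then zeroed, and
pixel-wise processing uses foreground pixels only — background texture
otherwise dominates both clustering and classifier training.

## Patching, augmentation, stitching

Cubes are tiled into non-overlapping 32×32 patches from origin (0, 0).
Spatial dimensions not divisible by the patch size are mirror-padded up to
the next multiple; stitching crops the padding back off, so the
extract → stitch round trip is exact on the retained footprint. Patches
with no foreground pixels are dropped, and a pluggable per-patch predicate
can drop dye-stained patches (the provided default flags a patch when more
than 25% of its foreground pixels fall within a SAM angle threshold of a
dye reference spectrum — the prevalence cut-off is a package choice, as no
canonical value exists). Augmentation is exactly fourfold: original,
vertical flip, horizontal flip, both; labels flip identically, and
augmented copies are flagged so stitching uses only originals. Dropped
tiles stitch to zero (non-tumor).

## Pixel-wise framework

* **SAM** is the angle between spectra as vectors, scale-invariant, so
  slow illumination amplitude variation cancels.
* **N-Findr** projects signatures to k−1 principal components and seeks the
  k pixels spanning the maximum-volume simplex by seeded random
  initialisation plus full replacement sweeps; three restarts guard against
  local maxima, and on instances with ≤ 12 signatures the result is
  verified against exhaustive search in the tests. Default k = 8.
* **Abundances** default to fully-constrained least squares (FCLS:
  nonnegative, sum-to-one) solved exactly by active-set elimination on the
  KKT system; NNLS and unconstrained modes are provided for comparison.
  The solver choice is a package decision — any of the three supports the
  SVM scheme, and FCLS gives physically interpretable fractions.
* **Kmeans+SAM**: k-means (k = 7, k-means++ with a fixed seed, ten
  initialisations) on foreground spectra; for each cluster the summed
  per-pixel minimum angle to the tumor references is compared against the
  summed angle to the normal references, and the whole cluster takes the
  closer class. Ties go to non-tumor, favouring specificity (false
  positives are the costlier error in a pathology setting). "Similarity"
  is taken as smaller angle = more similar. The per-pixel score
  (normal angle − tumor angle) supports ROC analysis.
* **SVM schemes**: a kernel SVM on raw signatures or abundance vectors.
  Defaults are RBF kernel, box constraint C = 44.184 and kernel scale
  σ = 4.0136 (mapped to `gamma = 1/σ²`). Training uses a deterministic
  equal-interval 10% subsample of the pooled training signatures (stride
  `round(1/fraction)` from index 0), which keeps SVM training tractable at
  full-cube signature counts. Hyperparameter search runs as seeded random
  search over kernel ∈ {linear, rbf} and log-uniform C, σ ∈ [1e-2, 1e3],
  scored by cross-validated accuracy; the default configuration is always
  included as a candidate so tuning never regresses below it, and the
  returned config records the search mode.

Background pixels are forced non-tumor by every segmenter.

## Patch-based framework

All networks map `(batch, H, W, bands)` to per-pixel probabilities via a
sigmoid head, and run on a small numpy layer engine written for this
package (stride-1 "same" convolutions via kernel-offset loops, which
handles the even spectral kernels' asymmetric padding exactly; backward
passes verified against finite differences to 1e-6 in the tests).

* **3D Xception**: per encoder block, two depthwise-separable 3D
  convolutions (depthwise (3, 3, sk) then pointwise 1×1×1) with a pointwise
  residual shortcut, ReLU, ×2 spatial max-pooling and dropout 0.40.
  Spectral kernels default to 10 for the first block and 20 thereafter,
  clipped with a warning when they exceed the band depth; the spectral
  stride is 1 throughout, and the spectral axis survives untouched until a
  max (default) or mean collapse at the bottleneck. The 2D decoder mirrors
  the encoder with nearest ×2 upsampling, skip connections from
  spectrally-collapsed encoder features, and 3×3 convolutions. Default
  filters (64, 128, 256) over three blocks; the four-block (…, 728)
  variant is available and strictly larger in parameters.
* **3D U-Net baseline**: two full 3D convolutions + ReLU per block, same
  collapse and decoder.
* **ResNet adapters**: the spectral axis is treated as 2D channels, a 1×1
  convolution reduces it to 3, then a stem convolution and residual stages
  of basic blocks (two 3×3 convolutions plus identity) in the ResNet-34
  layout (3, 4, 6, 3) with stage widths doubling from a configurable base.
  The "pretrained" variant freezes the body and trains only the reduction
  convolution and decoder head; since no pretrained weight file is
  available offline, the frozen body holds random weights and the model
  metadata flags `pretrained_weights_available: False`. Normalisation
  layers are omitted throughout; activations are ReLU. These internal
  choices (decoder depth, stem, skip wiring) are documented defaults of
  this package, not claims of parity with any particular published graph.

**Losses.** BCE is the pixel mean of `−GT·log PR − (1−GT)·log(1−PR)` with
probabilities clipped to [1e-7, 1−1e-7]; the soft Jaccard loss is
`1 − (ΣPR·GT + s)/(ΣPR + ΣGT − ΣPR·GT + s)` with smoothing `s = 1e-7` (so
two empty masks give 0); BCE+JC is their exact sum. On binary inputs the
Jaccard loss equals 1 − JC/100 of the evaluation metric.

**Training.** Adam or RMSProp (default) with optional per-step exponential
learning-rate decay; batch size 8; dropout active at train time only.
Parameter initialisation, shuffling and dropout all draw from generators
seeded by the network/training seeds, so same-seed runs reproduce
bit-for-bit on a single CPU thread. Per-epoch train/val loss and val JC
are recorded and the best-validation-JC weights are returned; a non-finite
loss aborts with a diagnostic. Recommended learning rates: 1e-5 for the 3D
Xception, 1e-3 for the 3D U-Net, 1e-4 for the ResNet adapters. Test and
acceptance runs use reduced problem sizes (2 blocks, filters (4, 8),
16-band patches, 5 epochs) — chosen as the smallest configurations that
still exercise every code path end-to-end.

## Evaluation protocol

Metrics come from pixel confusion counts: accuracy, sensitivity,
specificity and JC = TP/(TP+FP+FN) as percentages, plus tie-aware ROC AUC
(equal to the normalised Mann–Whitney U statistic). By default metrics are
computed over foreground pixels only — background is trivially correct and
inflates accuracy/specificity — with a flag for whole-image evaluation.
Zero-denominator metrics (e.g. sensitivity with no positive pixels) are
reported as NaN and excluded from aggregates rather than coerced to 0 or
100. LOOCV retrains the segmenter from scratch per fold, tests every
sample exactly once, and aggregates with the unweighted mean and sample
standard deviation (ddof = 1); a fold whose segmenter raises is marked
failed and excluded. Named splits assert train/test disjointness.

## Synthetic phantom generator

The generator emulates the statistical structure the frameworks assume,
not skin optics in the radiative-transfer sense. Chromophore absorbance
curves are analytic stand-ins — exponential-decay melanin (monotonically
decreasing with wavelength), Gaussian-mixture hemoglobin bands
(oxyhemoglobin peaks at 542/577 nm, deoxyhemoglobin at 555 nm), power-law
scattering — and reflectance follows `r(λ) = albedo·exp(−Σ conc·A(λ))`.
Tumor regions carry higher melanin and total-hemoglobin concentrations
than normal tissue (defaults give a tumor/normal mean-spectrum SAM angle
well above 0.05 rad); the tumor margin is a compact-support smoothstep so
border pixels carry mixed signatures while interior pixels are exactly
pure. The scene is an elliptical tissue region on a dark (albedo ≈ 0.02)
surface; the camera model applies a planar illumination gradient (±15% by
default), a constant dark level (0.01) and additive Gaussian noise
(σ = 0.004), with `white = illumination + dark`, so flat-field
normalization of a noiseless phantom recovers the generating reflectance
field exactly — the basis of the inversion checks. Optional dye blobs
insert a flat-red absorber for exercising the dye filter. Everything is
determined by `(config, seed)`.

The default single tumor blob covers ~33% of the tissue area, and the
dataset sampler jitters geometry around that operating point, matching the
tumor-pixel prevalence regime the classifiers are tuned for.

What passing tests on phantoms do **not** show: robustness to real-tissue
spectral variability (the phantom has two base spectra plus a soft
margin), to specular artefacts, staining, shadows, or to approximate
ground truth traced from histology cross-sections. Phantom JC values near
100% indicate a correctly wired pipeline, not expected clinical
performance.

## Numerical choices

* Degenerate flat-field denominators → reflectance 0, logged count.
* SAM of a zero spectrum is an error at the API surface; internally
  (cluster scoring) zero spectra receive the uninformative angle π/2.
* FCLS falls back to least-squares on a singular KKT system; endmember
  Gram condition numbers above 1e10 raise a warning.
* k-means empty clusters are handled by scikit-learn's re-assignment; the
  cluster→class rule skips empty clusters.
* Probability clipping bound 1e-7 for all log terms.
* Max-pool gradients split ties evenly; spectral max-collapse routes the
  gradient to the first arg-max.

## Known limitations

* The denoiser is a global-SVD simplification; an iterative nonlocal
  method can be swapped in behind the same interface.
* The ResNet "pretrained" configuration cannot load ImageNet weights
  offline; it exercises the frozen-body training path with random weights.
* Training determinism is guaranteed for this numpy backend on one thread;
  it is best-effort across BLAS builds.
* Bayesian hyperparameter search is approximated by seeded random search
  (flagged in its output); with generous budgets the distinction is
  immaterial for the two-parameter space involved.
* The CLI's `train` command merges patches across samples and therefore
  does not support stitching predictions back to source frames; use the
  library API (`extract_patches` per cube) when stitched maps are needed.
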