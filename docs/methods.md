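# Methods

`weakcount` implements one supervised and two weakly supervised
approaches to counting cotton bolls (or any bright, roughly convex
organ) in tiled RGB plant imagery, together with the tiling,
annotation-handling, aggregation and evaluation machinery around them.
This note records the models, their assumptions, the numerical choices
made where the design was open, and what the synthetic benchmark does
and does not demonstrate.

## Problem setting

Full-scale plant images are decomposed into fixed-size square tiles
(default 500 px; every model and test here also runs at 64 px) with zero
padding on the bottom/right edges. Tile `(r, c)` owns the half-open
pixel window `[c·T, (c+1)·T) × [r·T, (r+1)·T)`, so point annotations
partition exactly and the plant-level count — the sum of per-tile
counts — conserves the total number of annotated points. Tiles are
non-overlapping; deduplicating organs that straddle tile borders is out
of scope, and boundary points are deterministically assigned to the
higher-index tile.

Supervision always derives from point marks (one per organ): the integer
count is the number of points, the binary class label is
`present ⟺ count > 0`, and counts are binned `0 / [1,5] / [6,10] /
[11,15] / dnc (>15)`. The `[0,10]` interval is the subitizing range:
models are expected to count exactly inside it; beyond it only
lower-bound information is used. Tiles above 15 are flagged `dnc`
("did not count") and excluded from training but never deleted from
files. Class labels are never stored independently — they are recomputed
from counts, keeping a single source of truth.

## Models

All three counters share a small convolutional backbone (`tiny_cnn`:
four conv/batch-norm/ReLU blocks, output stride 8, 64 channels) built on
the package's own NumPy layer engine (`weakcount.nn`: im2col
convolution, batch normalization, pooling, linear layers, SGD/Adam with
manual backward passes; analytic gradients are verified against finite
differences in the test suite). Residual `paper_resnet50/101` backbones
with the standard stage layouts exist behind the same interface for
structural parity, but are not CPU-trainable at realistic sizes.

**S-Count (supervised).** Backbone → 1×1 convolution to *N* response
maps (batch-normalized, ReLU; *N* = 6 by default, the value that
performs best in this family of models) → flatten → linear count
regression, trained with mean squared error on the point-derived counts.
The raw output is unclamped during training (clamping biases gradients
near zero) and clamped at 0, then rounded, at prediction.

**WS-Count (presence/absence supervision only).** Two sub-networks: a
presence-absence classifier (PAC: backbone → global average pool →
logit) and a count regressor with the S-Count head. Each tile is
processed at three scales — whole tile, 2×2 quarters, 4×4 sixteenths; 21
branches in all, sharing one PAC and one counter (resized to a common
16 px input). Training is two-stage: the PAC is fitted first with binary
cross-entropy and then frozen (a flag enables fine-tuning) while the
counter minimizes

    L_WS = L_PAC-C + L_SP-C
    L_PAC-C = (1/21) Σ_b [(1−p_b)·|c_b| + p_b·max(0, margin − c_b)]
    L_SP-C  = |C1−C4| + |C1−C16| + |C4−C16|

with `margin` = 1 boll, `C1` the whole-tile count, `C4`/`C16` the sums
over quarters/sixteenths. These concrete forms are the simplest
functions with the required zero sets: `L_PAC-C = 0` iff every branch is
consistent (p=0 with c=0, or p=1 with c ≥ margin), `L_SP-C = 0` iff the
three scale totals agree. Prediction uses the scale-1 branch by default
(`prediction="scale_mean"` averages the three totals). No count is ever
consumed: the trainer accepts only class labels, rejects numeric labels,
and an access-auditing layer on the training examples lets tests prove
the contract.

**CountSeg (image-level lower-count supervision).** Backbone → 1×1
convolution to 60 shared channels, split half/half: the classification
branch produces a confidence map whose spatial maximum is the presence
score (max pooling chosen for its direct presence semantics; the pooling
function is pluggable), the density branch a rectified map whose sum is
the predicted count. Joint training minimizes the unweighted sum

    L = L_class + L_spatial + L_global

- `L_class`: binary cross-entropy of the pooled score.
- `L_global`: `(Σd − count)²` inside the subitizing range; beyond it the
  hinge `max(0, (subitizing_max+1) − Σd)²`, penalizing only
  under-estimation — the exact count is never used there.
- `L_spatial`: pixel-averaged cross-entropy between the min-max
  normalized density map and a pseudo ground truth: the count-capped
  strongest local maxima of the confidence map under non-maximum
  suppression (radius 3 cells). Capping at the known count is what
  suppresses the classifier's false-positive peaks.

## Numerical choices that mattered

These were found the hard way — naive gradients collapse both weak
models — and are the package's own engineering, kept separate from the
loss *definitions*, which are exactly as written above.

- **Density rectifier with leaky backward** (slope 0.1): a hard ReLU
  silences the global count gradient once the spatial term drives the
  whole map to zero; the leak lets the count revive dead cells while the
  forward map stays nonnegative.
- **Clamped spatial cross-entropy**: min-max normalization always places
  one cell at exactly 1, so an unclamped `−log` term reaches ~690 and
  dominates everything; imperfect cells are clamped into
  `[10⁻⁴, 1−10⁻⁴]` while exactly-correct cells contribute exactly 0.
- **Spatial subgradient preconditioning**: the spatial loss is invariant
  to the map's scale, so its chain factor `1/(max−min)` explodes on
  near-flat maps; the factor is clamped at 1 and the per-cell terms at
  ±8. The spatial term steers *where* density mass sits; the global term
  owns the total.
- **Spatial term on presence tiles only**: an absent tile has no peaks
  to localize and its density is already pulled to zero by `L_global`.
- **Huber-smoothed consistency subgradients** (WS-Count): the exact
  subgradients of the pairwise absolute differences are ±1/±2 signs that
  flicker at scale consensus and drown the 1/21-scaled classifier
  consistency signal, pinning training at the degenerate all-zero
  consensus; training uses `sign(Δ) → clip(Δ, ±1)` (knee at 1 boll).
  Reported loss values are unaffected.
- **PAC crop augmentation**: sub-patches of *absent* tiles are certainly
  absent, so they are added as extra negatives, calibrating the PAC at
  the sixteenth-patch scale it must judge during counting. This uses
  class labels only.
- Batch normalization uses running statistics (momentum 0.1) in
  evaluation mode, making prediction deterministic and batch-context
  independent up to float32 reduction order.

## Synthetic scenes

The generator renders intensity-elevated ellipses ("bolls": radius,
eccentricity, orientation and brightness drawn per blob) with
Gaussian-softened edges on flat, noisy, or foliage-like backgrounds
(low-frequency multiplicative field over a green-dominant base), with
optional offset shadow ellipses and painter's-algorithm occlusion.
Placement is rejection-sampled so every blob keeps ≥ 25% of its area
visible; an occluded blob still contributes its point (the ellipse
center) and its clipped mask — partially visible organs are still
counted. `(config, seed)` determines the output bit-for-bit. Scenes
export as PNG plus VGG-Image-Annotator-style JSON (point and polygon
regions), so the annotation reader round-trips them.

It emulates: brightness-against-foliage contrast, size/shape
variability, occlusion, shadows, count-bin imbalance. It does not
emulate: real boll texture, out-of-focus background plants, illumination
gradients, or 3D structure. Passing the benchmark therefore shows the
*mechanisms* work (supervision contracts, consistency training, density
counting, conservation, evaluation), not that field-image accuracy
transfers.

## The desk-scale benchmark

Fixed study conditions (`weakcount.benchmark`): 64×64 tiles, counts 0–5
with 20% empty tiles, well-separated blobs (radius 4–7 px, no occlusion
or shadows, noisy background), 200 training / 50 held-out tiles, all
seeded. Training settings: S-Count Adam 10⁻³ × 12 epochs; CountSeg SGD
10⁻³ (its canonical optimizer) × 15 epochs; WS-Count Adam 3·10⁻³, 12 PAC
+ 40 counting epochs — the weak objective needs more steps because its
per-branch gradients are 1/21-scaled. Held-out RMSE is computed on
rounded integer predictions (a flag exposes real-valued RMSE). The
expected qualitative outcome is the supervision ordering: supervised
regression ≤ density-map counting ≤ consistency-trained counting, with
the weak models under-counting — they are trained on presence, not
magnitude. Problem sizes were chosen so the whole study (three models,
three seeds) trains in minutes on a single CPU core.

Full-scale configuration defaults mirror the tiled-field setting (500 px
tiles, counts to 15, ResNet-style backbones, WS-Count learning rate
10⁻⁴, CountSeg SGD 10⁻³) and are exposed in the model configs.

## Evaluation protocol

Counting models are trained K times (5 in the full protocol) with
different seeds. Per-tile error uses the median of the K predictions
(lower median for even K); RMSE `√(Σ(gt−pred)²/N)` is reported per count
bin as mean ± sample standard deviation over the K run-level RMSEs (the
across-runs reading of run-to-run variability); the error sign
convention is `gt − pred`, so positive errors mean under-counting. The
report also carries the signed-error histogram, the fraction of median
errors within ±3, an ordinary least-squares fit of predicted on true
counts with R², bubble-plot data (point, multiplicity), and per-plant
totals (tile, predict, sum) with mean ± std across runs. Bins with no
tiles are omitted rather than reported as NaN. `least_squares_fit` and
the local-maxima search are backed by SciPy; the tests hold them to
independent closed-form and brute-force oracles.

## Degenerate inputs and tie-breaks

Empty prediction lists, length mismatches, constant ground truth in the
fit, negative counts, probabilities outside [0,1], non-square tiles for
rotation, points outside the source extent, and `dnc` counts in
training all raise errors naming the offending input. Ties in the
max-pooled class score resolve to the first cell in row-major order;
pseudo-ground-truth peak selection is greedy by descending confidence
with Chebyshev-radius NMS; the even-K median takes the lower value;
rotation uses the fixed convention 90° CCW, `(x, y) → (y, W−1−x)`,
verified against pixel-array rotation.

## Known limitations

- The weak models' accuracy here rides on high foreground/background
  contrast; low-contrast organs would degrade the PAC and hence
  WS-Count first.
- WS-Count's scale-1 prediction systematically under-counts dense tiles
  (multiple organs in one patch still satisfy consistency with count 1
  per occupied patch).
- The NumPy engine is single-threaded and desk-scale by design; the
  `paper_resnet*` backbones are provided for structure, not speed.
- Cross-tile double counting of organs on tile borders is not
  deduplicated (non-overlapping tiles make it rare, not impossible).
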