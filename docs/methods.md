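# Methods

This note records the model, the numerical choices and the limits of what
the synthetic experiments can show. It is the package's own account of its
design; every number quoted here is computed by the test suite or the
acceptance script, not asserted from elsewhere.

## Networks

Both networks map a single-channel region to a two-channel softmax of the
same spatial shape (stride 1 everywhere, symmetric zero-padding of
`(k−1)·d/2` per side, odd kernels only).

**2D.** Five feature blocks of 3×3 convolutions at dilations 1, 2, 4, 8,
16 with layer counts 2, 2, 3, 3, 3, giving the per-axis receptive field
`1 + 2·(2·1 + 2·2 + 3·4 + 3·8 + 3·16) = 181`. The block outputs are
concatenated and classified by a 1×1 convolution ("block 6"). Layer
counts are not free: they are pinned by the requirement that the default
spec reproduce the 181×181 receptive field, which the spec constructors
re-validate at startup.

**3D.** Same block structure with 3×3×3 kernels in blocks 1–2 and 3×3×1
in blocks 3–5. In-plane dilations 1, 2, 3, 4, 5 give
`1 + 2·(2+4+9+12+15) = 85` in-plane; through-plane only the four 3-tap
layers of blocks 1–2 contribute, giving `1 + 2·4 = 9`. Each block output
passes through a 1×1×1 compression convolution (default 16 channels)
before concatenation, which keeps the cached feature tensor small.

Choices the architecture description leaves open, fixed here once:

* nonlinearity: ReLU after every convolution, no normalization layers —
  inference is exactly deterministic;
* channel widths: configurable, default 8 per feature block (a
  deliberately compact desk-scale width; the receptive field is
  width-independent);
* classifier block: a single 1-tap convolution to 2 channels, so
  image-specific fine-tuning is a convex logistic refit on cached
  features;
* initialization: He-scaled Gaussian weights, zero biases, seeded.

The networks are implemented directly on numpy: forward passes are
im2col gathers plus one BLAS matmul per layer, and the input gradient of
a stride-1 same-padded convolution is computed as a convolution with the
spatially flipped, channel-transposed kernel. The backward pass is
verified against central finite differences in float64 (biases nudged off
the ReLU kinks, where the loss is genuinely non-differentiable and no
subgradient check can agree with a two-sided difference).

## Instance preparation

Training converts a K-ary label map into binary crops: instances are
connected components per class (or an explicit instance map), each
binarized against its own label, with the tight box expanded by a margin
drawn uniformly from 0–10 per side (independent per side — the margin is
the only data augmentation). Regions are standardized by their own mean
and standard deviation; a constant region maps to zeros. Crops are resized
isotropically so the minimum side is 96 px (2D) or the maximum side 80
voxels (3D); linear interpolation for intensities and probabilities,
nearest-neighbor for masks, and the inverse mapping pastes predictions
back at the recorded box. Coordinates are 0-based, boxes half-open.

## CRF label update

The pairwise term uses the 4-/6-neighborhood with `d_ij = 1` and operates
on the *normalized* intensities (the published σ = 0.1 is small, which is
consistent with standardized units). Probabilities are clamped to
`[1e−6, 1−1e−6]` before logarithms. Scribble constraints are encoded as
t-links whose "infinite" capacity sits just above a certified upper bound
on any finite cut, so no finite-energy labeling can violate them. Ties at
`p = 0.5` with λ = 0 go to background.

The min-cut is computed with scipy's max-flow, which works on int32
capacities; energies are converted to fixed point with an adaptive scale
chosen so that the worst finite cut plus rounding slack stays below 2³¹
(at 2D working sizes the scale is ~10⁴–10⁶, i.e. rounding is far below
the energy resolution that matters). Exactness is tested by exhaustive
enumeration on hundreds of random ≤12-pixel instances across
λ ∈ {0, 1, 10}.

One algebraic point: as λ grows, the quantity guaranteed to be
non-increasing is the weighted cut sum that λ multiplies; the raw count
of differing neighbor pairs is only monotone when all edge weights are
equal (uniform intensities).

## Uncertainty and the weight map

`U_p` uses strict thresholds `t0 < p < t1` and is recomputed from the
current softmax at every round (a config flag can freeze it at the
initial forward pass). The geodesic metric is the hybrid step cost
`sqrt(‖Δx‖² + γ²·ΔI²)` with γ = 1 on normalized intensities, computed by
Dijkstra on the same pixel graph as the CRF. The published ε = 0.2 is
interpreted in these units with unit pixel spacing; since every step
costs at least 1, the scribble-uncertainty band at ε = 0.2 is then
empty — `U_s` only activates at coarser effective spacing or larger ε,
and the implementation keeps ε configurable. The weight map applies the
case order as precedence: scribbles (ω) beat uncertainty zeros beat the
default 1.

## Fine-tuning loop

Per test image: one full forward pass caches the concatenation features;
then four rounds of (graph-cut label update → weight map → 20 gradient
steps on the classifier at lr 10⁻² → probability refresh from the
cache). The objective of the network update is the *summed* weighted
negative log-likelihood; the descent direction, however, is the per-pixel
mean gradient. With the raw summed gradient, a 10⁻² step over ~10⁴ pixels
saturates the classifier onto the current labeling in a single step and
the alternation degenerates to "CRF then freeze"; normalizing by pixel
count makes the printed step size and step count meaningful at any region
size. Plain gradient descent, momentum off by default.

The classifier is restored to the checkpoint state after each image
(stateless per image), so test images are independent. Exact minimization
in the label update guarantees the energy never increases across a label
update at fixed θ, which the acceptance suite asserts per round on 20
seeded scenes.

## Training

SGD with momentum 0.9, weight decay 5·10⁻⁴, batch size 1 (crops have
heterogeneous shapes), initial lr 10⁻³ halved every 5k iterations, 80k
iterations in the full-scale profile. The desk profile shrinks iterations
(default 2k, halving every quarter of the run) and keeps everything else.
The training loss is the per-pixel mean cross-entropy so crops of
different sizes contribute comparably. Validation loss is logged every
100 iterations.

## Synthetic scenes and the robot user

Scenes emulate the premise that makes zero-shot box segmentation
possible: all object classes are salient and hyper-intense against the
background but differ in geometry. Defaults (chosen once as a plausible
MRI-like regime): 64×64 images, background level 0.35, object intensity
offsets +0.28…+0.35 with per-object texture noise σ ≈ 0.03, global
Gaussian noise σ = 0.04, instances non-overlapping with 1–2 instances
per class and nominal radii 6–13 px. Shape families: ellipse and lobed
blob (seen classes), capsule and bean/crescent (held-out, "unseen"
classes). An optional smooth multiplicative bias field is available but
off by default; no attempt is made to model MRI physics.

The robot user boxes ground-truth instances (tight box plus random 0–10
margin) and, given a prediction, draws scribbles *only inside
mis-segmented areas*: length-capped skeleton runs of the largest
false-negative components (foreground scribbles) and false-positive
components (background scribbles), started at the deepest interior pixel.

What passing the synthetic benchmark does and does not show: it shows the
pipeline's machinery — box cropping, zero-shot transfer across shape
families under a shared saliency premise, exact CRF refinement, and the
benefit ordering initial ≤ unsupervised ≤ supervised — all hold
end-to-end under controlled conditions. It does not show performance on
real anatomy: real MRI has structured background clutter, partial-volume
boundaries, intensity inhomogeneity and inter-subject variation that the
generator deliberately omits.

## Benchmark scale

The zero-shot acceptance run trains the compact 2D network (8 channels)
on 200 instances of the two seen classes for 2,000 iterations and
evaluates 40 held-out-class instances in three modes (initial,
unsupervised, scribble-supervised); the determinism check repeats a small
train→segment→refine pipeline twice and compares outputs bit for bit.
These sizes are the package's desk-scale defaults; the full-scale
training profile remains available via `TrainConfig()`.

## Known limitations

* No multi-class output head; one box segments one instance.
* No automatic bounding-box detection; boxes come from the user or the
  robot user.
* The numpy networks are single-threaded-CPU oriented; widths beyond a
  few dozen channels or large 3D volumes are slow.
* `U_s` is inert at the default ε = 0.2 with unit spacing (see above).
* The 3D path is exercised by unit tests on small volumes; the full
  benchmark machinery is 2D.
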