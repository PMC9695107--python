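# Methods

## Problem and model

Automated glaucoma screening relies on segmenting the optic disc (OD) and
optic cup (OC) in retinal fundus photographs and measuring the vertical
cup-to-disc ratio (CDR).  Segmentation networks trained on one acquisition
setup degrade on another (domain shift), and adversarially adapted networks
often produce anatomically implausible, ragged regions.  This package
implements an unsupervised domain-adaptation framework for joint OD/OC
segmentation whose central component is a *shape-constrained loss*: a
differentiable penalty on the non-circularity of the predicted disc and cup
contours, exploiting the domain-invariant prior that both structures are
close to circles.

The framework has two coupled sub-models:

* **Image translation.**  A shared content encoder `EC` maps source- and
  target-domain images into a common content space; a style encoder `ES`
  extracts a short per-image style code; a shared decoder `G` recombines
  content and style.  Cross-domain translations `G(c_s, s_t)` and
  `G(c_t, s_s)` are judged by two patch discriminators (`D1` on the target
  side, `D2` on the source side).  The translation total is
  `mu1*(image L1 recon) + mu2*(content L1 recon) + mu3*(style L1 recon) +
  mu4*(GAN terms)`.
* **Segmentation.**  A U-Net consumes the content features directly.
  Because content already lives at 1/4 image resolution, the first two
  downsampling stages of a standard U-Net are removed; a convolutional
  triple attention module (CTAM) refines the bottleneck tensor.  Training
  combines per-pixel cross-entropy on the labeled source domain, an
  adversarial output-space alignment term driven by a patch discriminator
  `D` on segmentation probability maps, and the shape-constraint total —
  the circularity loss summed over the segmentations of the source, target
  and both translated images:
  `L_total = L_tra + rho1*(delta1*CE + delta2*L_adv) + rho2*L_shape_total`.

## The circularity loss

For a region contour with points `p_i`, centroid `c = mean(p_i)`, radial
distances `E_i = |p_i - c|` and mean distance `m`, the per-region term is

    L_region = (1/k) * sum_i (E_i - m)^2 / m^2 ,

zero exactly for a circle, dimensionless, invariant to translation and
scale, independent of contour sampling density, and strictly increasing in
ellipse eccentricity.  `L_shape = L_disc + L_cup`.  Two switches expose
variants: `normalization="printed"` drops the `1/k` and one power of `m`
(the raw unnormalized-count form), and `deviation="absolute"` replaces the
squared deviation with `|E_i - m|/m`.  The scale-free squared form is the
default because it makes values comparable across contour resolutions and
image sizes.

**Hard path** (label maps): the region is the largest 8-connected
component, holes filled; the contour is its inner boundary (region pixels
with a non-region 8-neighbour), with pixels clipped by the image frame not
counted as contour.  Cup = class 2, disc = classes 1∪2; each term uses its
own region's centroid.

**Soft path** (probability maps, used in training): the boundary indicator
is `b = p - minpool_3x3(p)` with edge-replicated padding, and centroid,
mean distance and variance are `b`-weighted sums over the pixel grid.  On a
one-hot input `b` is exactly the indicator of the hard boundary pixel set,
so soft and hard losses coincide on hard masks (the agreement test over 50
random phantoms observes relative differences at machine precision).  This
morphological surrogate was chosen over a spatial-gradient-magnitude
indicator precisely for that exact hard-limit reduction.  The function is
piecewise smooth: min-pooling introduces kinks at argmin ties, where only a
subgradient exists; the finite-difference gradient check therefore probes
pixels whose perturbation cannot flip an argmin.

**Degenerate regions.**  A region whose probability mass or boundary mass
is below 1e-6 of the image area (or whose mean radius is zero) contributes
a constant penalty of 10.0 with zero gradient, instead of NaN — early in
training the segmenter routinely predicts no cup at all.

## CTAM

The triple attention operator runs three branches on a `C×H×W` tensor: two
permute the tensor (C↔W and C↔H) so that Z-pool — stacking the max and the
mean over the leading dimension into 2 slices — captures channel↔height and
channel↔width interactions, the third pools channels directly for spatial
attention.  Each branch convolves the 2-slice summary (7×7, padding 3, the
cited triplet-attention default; configurable), batch-normalizes, applies a
sigmoid to obtain weights in (0,1), multiplies them onto the (permuted)
input, and permutes back.  The output is the average of the three branches.
The average is computed in an anchored form `b2 + ((b1-b2)+(b3-b2))/3` —
algebraically identical to `(b1+b2+b3)/3` but bit-exact in the identity
limit where every attention weight is forced to 1 (the naive form loses the
last ulp in IEEE arithmetic).

## Numerical backend

No GPU framework is used: the networks run on a small reverse-mode autodiff
engine over numpy arrays (`odcseg.nn`) providing broadcasting arithmetic,
reductions, slicing/padding, im2col-based convolution, batch norm, the usual
activations and Adam.  Tensors preserve float32/float64 dtype; training runs
in float32 for CPU speed, while verification paths (the shape-loss gradient
check) feed float64 and stay in double precision throughout.  Gradients of
`max`/`min` ties are split evenly (symmetric subgradient) for reductions and
routed to the first argument for elementwise minima.

## Synthetic two-domain phantoms

Phantoms emulate the *structure* of cross-dataset fundus ROIs: a bright
quasi-circular disc with a brighter concentric cup, dark vessel strokes
(quadratic Beziers), and a domain-specific appearance (palette, vessel
density, Gaussian blur, contrast, brightness, noise).  Domain A is
saturated, reddish and sharp; domain B paler, washed-out and blurrier; the
per-channel mean intensity gap exceeds 15/255, so a real appearance shift
exists over identical anatomy.  Geometry: the disc boundary radius is
`R*f(θ)` with `f = 1 + `3 low-order sinusoidal harmonics of total amplitude
equal to the boundary jitter (default 0.06, capped at 0.15 so shapes stay
circular-like); the cup uses the *same* angular profile scaled by the
sampled CDR (default range 0.35–0.65), which makes the rasterized vertical
CDR equal the sampled one up to rasterization error.  What phantoms do NOT
model: camera optics, pathology, peripapillary atrophy, illumination
gradients, non-concentric cups.  Tests passing on phantoms therefore
validate the mechanics and direction of the method, not clinical accuracy.

## Training procedure

Each iteration alternates four Adam updates: (a) image discriminators on
real vs detached translated images; (b) encoders + decoder through the
translation total (non-saturating generator form of the GAN terms);
(c) the segmentation-map discriminator on detached probability maps;
(d) the segmenter and content encoder through the grand total, with the
translation term entering as a constant (it was just optimized in (b)) and
the four shape terms computed on the segmentations of `x_s`, `x_t` and the
two translated images (translated images are re-encoded, then segmented).
Cross-entropy uses the raw pixel *sum* by default: the weight set
`delta = (1, 0.01)`, `rho2 = 1.0` is calibrated against that scale, under
which the data term dominates and the shape constraint acts as a moderate
regularizer.  A per-pixel-mean variant exists (`ce_reduction="mean"`) but
requires re-scaled weights — with the defaults it lets the shape term
overwhelm the data term and suppress the (small) cup class outright.
Default loss weights: `mu = (10, 1, 1, 1)`, `delta = (1, 0.01)`,
`rho1 = 1`, `rho2 = 1.0` — the shape-constraint weight sweep (0.2–2.0,
step 0.2) peaks at 1.0.  Reference full-scale settings are
256×256 images, batch 2, Adam at 1e-4, 400 epochs, fixed seeds.

**Desk-scale settings.**  The test suite and the reproduction script run a
scaled-down analogue chosen to fit a single CPU: 64×64 phantoms,
`base_channels=4` networks, 24 training and 6 test images per domain,
20 epochs at a learning rate of 1e-3 (fewer steps warrant a larger step
size).  At this scale the end-to-end checks are *directional*: the mean
soft shape loss of target-domain predictions must decrease over training,
and cup Dice with the shape constraint must match or exceed the run without
it (median over 3 seeds); absolute metric values at desk scale are not
comparable to full-scale results on real datasets.

## Known limitations

* Architectures other than the U-Net modification are fixed conventional
  choices (MUNIT-style encoders/decoder, 4-layer patch discriminators);
  the framework's behaviour under other backbones is untested here.
* The circularity prior is exactly that — elliptical or free-form priors
  are out of scope.
* Batch norm with batch size 2 makes adversarial training noisy; at desk
  scale run-to-run variation across seeds is substantial.
* The hard-contour path ignores holes and secondary components by design;
  fragmented soft predictions are penalized through all their boundary
  mass, which is the main source of (still small) soft/hard disagreement
  on non-simply-connected inputs.
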