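# Methods

## Cone-beam projection model

A volume is a scalar field on a regular voxel grid with physical spacing,
axes aligned with world x/y/z and (by default) centered at the isocenter.
A view is an `(azimuth, inclination)` pair: the azimuth rotates the source in
the transversal plane (0° along +y), the inclination tilts it out of that
plane.  The source sits at `source_to_isocenter_mm` from the isocenter; the
flat detector is orthogonal to the source-isocenter axis at
`source_to_detector_mm` from the source.  Defaults (600 mm / 1200 mm,
magnification 2, 64–256 px detectors at a few mm pitch) are desk-scale
stand-ins for a clinical C-arm; all are configurable.  The angular origin is
a simulator convention and makes no claim of clinical RAO/LAO semantics.

Each detector pixel receives the line integral of the volume along the
source-to-pixel ray, discretized by midpoint sampling at a fixed step
(default: half the smallest voxel spacing) with trilinear interpolation;
samples outside the grid contribute zero (air).  The scheme is linear in the
volume, converges under step halving, and is validated against an independent
fine-step quadrature of the trilinear interpolant (tests) — near-grazing rays
with tiny chords are excluded from relative-error summaries because their
denominators are noise.  Rays from a source inside the volume support are
rejected.

Trajectories: the *training sphere* distributes n views equiangularly in both
azimuth ([0°, 360°)) and inclination (default [−30°, 30°]) on the smallest
near-square grid with ≥ n cells, enumerated row-major and truncated; the
*test orbit* is a full 360° rotation in the transversal plane.  Both are
deterministic.

## Paired phantoms

Real co-registered MR/X-ray projection data are clinical; the phantom module
emulates the *signal structure* of the task rather than anatomy.  A seeded
material phantom (air / soft tissue / bone / vessel) consists of an
ellipsoidal bone shell around soft tissue with randomly placed inner bone
ellipsoids and vessel capsules; an optional axial truncation blanks end
slices, as incompletely acquired head scans would.  The modality mapping
renders materials into two co-registered volumes:

| material | MR intensity | X-ray attenuation (mm⁻¹) |
|---|---|---|
| air | 0 | 0 |
| soft | 1.0 | 0.019 |
| bone | 0.03 | 0.060 |
| vessel | 1.8 | 0.025 |

enforcing the ambiguity that motivates the problem: bone ≤ 5% of soft-tissue
MR signal (bone and air are indistinguishable by MR intensity) while bone
dominates X-ray attenuation.  Vessels are MR-bright, abstractly emulating
flow-sensitive angiography.  The attenuation values are in the range of soft
tissue/bone at diagnostic energies; the MR values are arbitrary units.  What
the phantoms do **not** model: anatomy, pathology, MR sequence physics,
noise, scatter, or beam hardening — so passing desk-scale tests demonstrates
the method's mechanics and its ablation ordering, not clinical performance.

## Objective

The discriminator is a conditional patch critic on the channel stack of the
MR input and a candidate X-ray projection, outputting a 2D map of scores in
(0, 1).  The adversarial objective is the standard cross-entropy with the
non-saturating generator term (the generator minimizes −log D(I, G)).  The
feature-matching term is the per-layer mean absolute difference of
fixed-extractor activations between label and generated image, summed over
tapped layers; it is a pseudometric and supplies the dense supervisory pull
toward the unique correct solution.  The default extractor is a seeded random
convolutional pyramid (conv3×3 → leaky-ReLU taps, average pooling between
stages): random convolutional features approximately preserve image
distances, require no pretrained weights, and keep every run deterministic.
Any callable returning a list of activation stacks (e.g. a pretrained
perceptual network tapped before each pooling stage) can be plugged in.

Edge weighting: the label's Sobel gradient magnitude (classical 3×3 kernels,
replicate borders) is normalized by its maximum — which is what makes a fixed
threshold on a "0 to 1 data range" meaningful per image — and thresholded at
0.4.  Sub-threshold pixels receive a floor weight (default 0.1) rather than
zero: homogeneous regions are attenuated but still carry gradient; floor 0
reproduces the strict "discard" reading, and a `binarize` flag replaces
surviving magnitudes by 1.  Both unreduced loss maps (patch scores,
per-layer feature differences) are multiplied by the weight map bilinearly
resampled to their resolution (pixel-center alignment, edge clamp) and
broadcast across channels before mean reduction; the same weighting is
applied to the discriminator's objective so both players see the
edge-emphasized game.  The GAN and FM terms enter with configurable
coefficients, default (1, 1).

## Architectures

Both generators are single-channel encoder-decoders: 7×7 stem, stride-2 4×4
convolutions down, nearest-upsample + 3×3 convolutions up, instance
normalization (appropriate at batch size one) and ReLU, residual blocks
(conv-IN-ReLU-conv-IN with identity skip; the last normalization gain is
zero-initialized so fresh blocks are identities), and a linear 7×7 output
head — the data are normalized to zero mean/unit variance, so a bounded
output nonlinearity would clip valid label values.  The *reference* variant
places all residual blocks at the coarsest level with channel widths doubling
per level; the *proposed* variant relocates them to the two finest levels and
halves the fine-level widths relative to the doubling plan.  For a fair
ablation both are instantiated from one parameter budget: the base width of
each variant is chosen so its analytic parameter count is closest to the
budget (default 100k), which lands the two counts within a few percent of
each other while the proposed variant holds roughly an order of magnitude
more parameters at the two finest levels.

## Training and evaluation protocol

MR inputs are zero-centered and scaled to unit standard deviation per
subject (statistics pooled over that subject's training projections and
reused for its held-out views); labels are normalized with statistics pooled
over the whole training split.  Updates alternate one discriminator and one
generator Adam step per pair at batch size one, with moments (0.5, 0.999).
The full-scale defaults are 300 epochs at learning rate 1e-4; desk-scale
runs in the tests, the acceptance script, and the examples use 2 subjects at
64³, 64×64 detectors, ≤ 256 iterations and learning rate 2e-3 — a standard
Adam rate for few-hundred-step schedules, and the problem size that keeps a
six-run ablation within minutes on one CPU.  All randomness (parameter
initialization, epoch shuffling, phantom content) derives from explicit
seeds; with one thread, reruns are bit-identical.  A non-finite loss aborts
with a diagnostic.

Metrics follow the masked protocol: MAE (reported in percent after min-max
scaling both images by the *label's* range — the normalization is a package
convention, stated here because absolute MAE percentages are
convention-dependent) and PSNR (peak = label range) are computed over pixels
that are nonzero in the *raw* label projection, excluding the trivially
correct air background whose inclusion would bias results optimistically;
SSIM uses the standard 11×11 Gaussian window (σ 1.5, K1 0.01, K2 0.03) over
the full image, as no masking convention exists for it.  Per-view metrics are
ordered by azimuth and aggregated as mean ± standard deviation over views
(per-view averaging, not pixel pooling).  The edge-pixel fraction — the
share of pixels above the floor weight under the default threshold — is
reported as a diagnostic of edge sparsity; its value is data-dependent.

## Numerical and design notes

- Projector ray-box clipping uses the slab method; per-view sampling is
  blocked over detector rows to cap the coordinate buffer at ~64 MB.
- Logarithms in the adversarial loss are clipped at 1e-12 (engine) and the
  discriminator output at 1e-8 effective, bounding the loss when the critic
  saturates.
- The autodiff engine is float64 throughout and single-sample (no batch
  axis); convolutions are computed as one GEMM per kernel tap over shifted
  slices.
- Bilinear resampling uses pixel-center alignment with edge clamping;
  resampled weight maps are clipped back into [floor, 1].
- Gradient normalization guards the constant image (max = 0 → all-zero map).
- The instance-normalized discriminator couples every input pixel to every
  patch score through its global statistics; locality-based reasoning about
  the weight map therefore applies exactly only to normalization-free
  critics (the test suite uses a single-layer critic for that probe).

## Known limitations

No tomographic reconstruction, scatter/noise/beam-hardening physics, or
rigid registration of real data; MetaImage/NIfTI volumes are read with
header spacing but rigid header rotations are not applied (inputs are
assumed co-registered and axis-aligned).  Sub-pixel-convolution decoders and
temporal consistency across successive frames are out of scope.  Desk-scale
results quantify the method on phantoms; they do not predict clinical-image
performance.
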