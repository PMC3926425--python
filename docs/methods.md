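# Methods

## Model

`textsnake` refines a user-supplied closed contour against an external
energy composed from edge evidence and an annotation prior:

    energy(x) = − exp(−η·T(x)) · Σ_i δ_i · e_i(x),        e_i ∈ [0, 1]

The energy is nonpositive by construction; its minima sit on strong
edges near the annotation.  The sign convention deserves a note: with
edge terms defined as *nonnegative strengths* and a multiplicative
modulation exp(−η·T) ∈ (0, 1] (1 on/inside the annotation, decaying
away from it), the field simultaneously attracts the contour to object
boundaries and keeps it near the user's rough outline, and it
degenerates to the classic gradient field when η = 0.  Writing the
modulation as a growing factor of T instead would reward drifting away
from the annotation, which contradicts the term's purpose, so the
decaying form is implemented.

The internal energy is the classic tension + rigidity pair with weights
α (continuity) and β (curvature).  Minimization uses the greedy
algorithm: vertices are visited sequentially; each examines the
(2d+1)² integer-offset window, with the continuity term
|d̄ − ‖v_i − v_{i−1}‖| (d̄ = current mean spacing), the curvature term
‖v_{i−1} − 2v_i + v_{i+1}‖², and the energy sampled bilinearly, each
min-max normalized over the window.  Ties go to the smallest offset
magnitude, then row-major window order, so a flat landscape is a fixed
point.  The contour is arc-length resampled every 10 sweeps; iteration
stops when fewer than 5 % of vertices move, or after 200 sweeps.

Consequences of this scheme worth knowing:

* The capture range is set by the spatial extent of the field, not by
  the window size: a vertex will not hop across a flat gap because the
  deformation penalties outweigh a distant gain it cannot see.
  Gradient scales (σ of e₁, the diffusion of e₂) must therefore be
  commensurate with the expected initial-contour error.
* The sequential sweep is order-dependent: rotating the starting vertex
  produces a nearly — not bitwise — identical result.  Rasterized masks
  from rotated starts overlap at ω ≥ 0.9 in tests; given fixed inputs
  the algorithm itself is fully deterministic.

## Texture classification (the e₂ term)

Images are tiled into non-overlapping square blocks (default 37 px).
Each block yields 7 features: mean and population std of raw
intensities, plus contrast, inverse difference moment, correlation,
entropy (natural log) and angular second moment of the gray-level
co-occurrence matrix.  The GLCM uses 32 equal-width bins over [0, 255]
and symmetric pair counting at distance 1 in four directions (0°, 45°,
90°, 135°), with the statistics computed per direction and averaged.
The correlation of a constant block (0/0 in the formula) is defined
as 0.  Features are z-scored with training-set statistics stored in the
model.

The classifier is a soft-margin maximum-margin machine: the dual
quadratic program (box constraint 0 ≤ λ ≤ c, balance Σλᵢyᵢ = 0) is
solved by an SMO backend; the stored model keeps the support vectors,
multipliers, labels and bias, and all decision values Σλᵢyᵢ K(xᵢ,x)+w₀
are evaluated by the package's own kernel code.  Multi-class problems
use one-vs-one voting with a deterministic tie-break (largest summed
decision magnitude, then lexicographic class name).  `sign(0)` maps
to +1.  Defaults: linear kernel, c = 1.5.

Training samples come from blocks fully inside an annotated polygon
(stride block/2); blocks fully outside all polygons become an explicit
`background` class, capped at 150 per image so the ubiquitous class
does not swamp the pairwise problems.

To build e₂, the per-block label map is majority-filtered (3×3 window,
dynamic limit ⌊n_valid/2⌋+1, single pass by default), rendered as a
class-greylevel image, Gaussian-smoothed, binarized by a local-mean
adaptive threshold, and passed through a Canny detector whose
hysteresis thresholds sit at the 70th/90th percentiles of the nonzero
gradient magnitudes; the binary edges are diffused by a Gaussian
(capture scale) and max-normalized.

Two scale couplings matter here.  The class-image smoothing must be of
order block/3 (default 12 for 37-px blocks): that is what rounds the
blocky, quantized footprint back onto the object boundary — with a
small σ the Canny ridge simply traces the block grid.  And the
adaptive-threshold window must exceed the object diameter (default
151 px): a smaller local-mean window hollows plateaus into edge bands
and hallucinates ghost transitions in smooth tails, displacing the
ridge by half a window.  The local-mean threshold also biases the
binarized boundary outward by roughly the smoothing σ (the threshold
sits well below the half-height of the transition); this is the main
residual error of the supervised field.

## Annotation term

The initial contour is interpolated at 1-px spacing, filled (even-odd
rule, pixel centres on the boundary included), eroded by a 3-px disk
(falling back to the unfilled mask if erosion empties it), and T is the
Euclidean distance transform to the remaining foreground.  η defaults
to 0.05 px⁻¹: the field retains ≈ 60 % of its strength 10 px outside
the annotation and ≈ 13 % at 40 px.

## Operating parameters

| parameter | default | meaning |
|---|---|---|
| block size | 37 px | texture block edge |
| c | 1.5 | soft-margin cost |
| α, β | 1.44, 1.58 | continuity / curvature weights |
| d | 8 px | greedy search half-width |
| δ₁, δ₂ | 0.6, 0.99 | gradient / classifier field weights |
| σ (e₁) | 23 px | gradient smoothing, full-resolution micrographs |
| η | 0.05 px⁻¹ | annotation-distance decay |

The σ = 23 default targets full-resolution micrographs (objects of
~150–350 px).  Length-like scales must shrink with image scale:
`PipelineConfig.for_phantoms()` uses σ = 10 and capture σ = 6 for the
512-px phantom preset, whose objects span ~200 px.

## Synthetic phantoms

The phantom generator emulates the statistical structure of stained
biopsy images at 512×512:

* a pale background (grey 190, noise σ 10) with dark nucleus-like
  clutter blobs (grey 80, radius 3–7 px) that create strong spurious
  gradient edges;
* "glomerulus-like" ellipses (semiaxes ~95–115 px) whose interior is a
  blotchy capillary-tuft analogue: base grey 186 ≈ background, with
  dark blotches (grey 135, radius 8–16 px, ~35 % coverage), so the
  border is a gradual density change rather than a step — weak for raw
  gradients, obvious for texture features;
* "tubulus-like" capsules (width ~85 px) carrying oriented gratings
  whose period distinguishes the normal from the pathological variant;
* the two glomerulus classes differ only by an added grating, i.e. only
  in second-order statistics.

Ground-truth polygons are returned with each image; a rough
initial contour emulates a quick mouse drag by dilating the truth
boundary (18 % of the equivalent radius), jittering the vertices and
resampling, which lands the initial overlap at ω ≈ 0.6–0.85.
Everything is deterministic given the seed.

What the phantoms do *not* model: staining colour (they are grayscale
by construction), out-of-focus blur, illumination gradients, touching
or overlapping structures, and anisotropic tissue deformation.  Passing
the phantom benchmark therefore shows that the pipeline's machinery —
feature extraction, margin classification, field synthesis, greedy
refinement — behaves as designed in the weak-edge/strong-texture
regime; it does not certify accuracy on any particular real stain or
scanner.

## Benchmark sizes and numerical choices

The standard study trains on 6 phantoms and evaluates 20 (four methods
each); it runs in a few minutes on one CPU.  Tests use the same sizes
or smaller.  Other numerical choices: co-occurrence matrices from
uint8-cast intensities; window min–max normalization treats a spread
below 1e-12 as flat; empty∩empty Jaccard is defined as 1; percentages
are reported at one decimal; model JSON round-trips floats exactly.
Degenerate inputs (zero-area contours, single-class training sets,
all-zero confusion matrices, unmapped class labels) raise typed errors
rather than returning sentinels; the one deliberate sentinel is NaN for
undefined precision/recall/ratio metrics (0/0 cases).

## Known limitations

* Block-resolution quantization bounds the supervised field's accuracy;
  objects should span at least ~5 blocks for the classification map to
  outline them (below that the majority filter can erase them).
* The greedy snake cannot recover from initializations beyond the
  field's capture range, and does not handle topology changes.
* The multi-class greylevel rendering feeds a binary threshold, so
  simultaneously adjacent regions of several classes can merge in e₂ if
  their greylevels fall on the same side of the local mean.
* One-vs-one margins are not calibrated probabilities; the ROI label is
  a vote, not a posterior.
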