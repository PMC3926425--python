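# textsnake

Supervised active-contour segmentation and annotation of microscopy
images, driven by texture classification.

## The problem

Quantitative assessment of kidney biopsy micrographs (and similar
histology) requires outlining salient structures — compact glomeruli,
elongated tubules — accurately enough to measure their areas, and
labelling them with the right class.  Drawing those outlines by hand is
slow; fully automatic segmentation struggles because the intensity
edges separating the structures from the surrounding tissue are weak,
while the image is full of strong irrelevant edges (nuclei, debris,
internal capillary structure).  `textsnake` is for image-analysis
practitioners who want a *refinement* tool: the user supplies a quick,
rough outline of a region of interest, and the package snaps it onto
the true boundary and assigns a class label and calibrated area.

## The method

A closed parametric contour v(s) (a *snake*) minimizes

    E = ∫ α |∂v/∂s|² + β |∂²v/∂s²|² + P(v) ds

by the classic greedy algorithm: each vertex inspects a (2d+1)² pixel
window, the continuity, curvature and image terms are min-max
normalized over the window, and the vertex moves to the lowest-energy
candidate.  The external energy P is composed from nonnegative
edge-strength maps e_i ∈ [0,1], weights δ_i, and the Euclidean distance
transform T of the (eroded, filled) initial annotation:

    P(x) = − exp(−η · T(x)) · Σ_i δ_i · e_i(x)

* **e₁** — gradient edges ‖∇(G_σ ∗ I)‖ of the raw image (the classic
  snake field; η = 0 and δ₂ = 0 recover it exactly).
* **e₂** — edges of a supervised *texture classification*: the image is
  tiled into square blocks (default 37 px); each block yields a
  7-feature vector (mean, std, and the GLCM statistics contrast, IDM,
  correlation, entropy, ASM); a maximum-margin kernel classifier
  (soft-margin SVM, Σ λᵢyᵢK(xᵢ,x)+w₀, one-vs-one for multi-class,
  default linear kernel with cost c = 1.5) labels each block; the label
  map is denoised by majority voting, smoothed, adaptively thresholded
  and passed through a Canny detector.
* **T** — anchors the contour near the user's annotation; the field
  fades with distance at rate η.

Trained models, polygon annotations and masks round-trip through JSON /
PNG via `textsnake.io`.  Segmentation quality is measured by the
Jaccard overlap ω = |a₁∩a₂| / |a₁∪a₂|; classifier quality by
confusion-matrix precision/recall/accuracy; areas are calibrated in
µm² from a microns-per-pixel factor.

Because no biopsy dataset ships with the package, `textsnake.synthetic`
generates seeded phantoms: blotchy "glomerulus-like" ellipses and
grating-textured "tubulus-like" capsules whose mean grey level sits
close to a cluttered background — the regime where gradients alone are
unreliable but texture is informative.

## Worked example

`examples/03_supervised_segmentation.py` trains on six annotated
phantoms and refines a rough contour around a glomerulus-like region:

```
training block classifier on 6 annotated phantoms ...
classes: background, glomerulus-normal, glomerulus-pathological, tubulus-normal, tubulus-pathological

target region: glomerulus-normal
overlap vs truth — initial:      0.722
overlap vs truth — block-based:  0.758
overlap vs truth — unsupervised: 0.828
overlap vs truth — supervised:   0.866
assigned label: glomerulus-normal   area: 28439 px
```

The rough outline (ω ≈ 0.72) improves to ω ≈ 0.87 with the full
texture-driven field, clearly ahead of the gradient-only snake and the
raw block map — the ordering the method is designed to produce.  The
other examples demonstrate feature extraction (`01`), the bare greedy
snake (`02`) and calibrated measurement/evaluation (`04`).

A thin CLI wraps the same pipeline: `textsnake synth`, `textsnake
train`, `textsnake segment`, `textsnake evaluate`, `textsnake measure`
(see `textsnake --help`).

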