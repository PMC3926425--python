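"""End-to-end orchestration: train from annotated images, then refine a
rough user contour into a labelled, measured region.

The supervised path builds the external field from the gradient term
(weight delta1), the classifier-derived edge term (weight delta2) and
the annotation distance modulation; the unsupervised path forces
delta2 = 0 and needs no classifier.  The block-classification map is
also exposed directly as a (coarse) segmentation for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import forcefield as _ff
from . import maxmargin as _mm
from . import measure as _measure
from . import synthetic as _synth
from . import texture as _texture
from .io import Calibration
from .snake import Contour, SnakeParams, contour_to_mask, evolve

__all__ = [
    "PipelineConfig",
    "AnnotatedRegion",
    "SegmentationError",
    "train_model",
    "collect_training_samples",
    "segment_supervised",
    "segment_unsupervised",
    "block_segmentation_mask",
    "run_phantom_study",
]

log = logging.getLogger("textsnake")


class SegmentationError(RuntimeError):
    """The snake collapsed to an empty region."""


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the train/segment workflow.

    The defaults are the operating settings for full-resolution
    micrographs: block_size 37 px, linear kernel with cost c = 1.5,
    snake weights alpha = 1.44 / beta = 1.58 with search half-width
    d = 8, field weights delta1 = 0.6 (gradient term) and delta2 = 0.99
    (classifier term), and gradient scale sigma = 23 px.  Length-like
    scales (f1_sigma, capture_sigma) should be reduced proportionally
    for lower-resolution inputs; :meth:`for_phantoms` does so for the
    300x300 phantom preset.
    """

    block_size: int = 37
    kernel: _mm.KernelSpec = _mm.KernelSpec("linear")
    cost: float = 1.5
    snake: SnakeParams = SnakeParams(alpha=1.44, beta=1.58, search_radius=8)
    delta1: float = 0.6
    delta2: float = 0.99
    f1_sigma: float = 23.0
    eta: float = 0.05
    erosion_radius: int = 3
    # class-image smoothing must be commensurate with the block size so
    # that thresholding rounds the blocky footprint back onto the object
    # boundary; the threshold window has to span both sides of it.
    smooth_sigma: float = 12.0
    thresh_window: int = 151
    canny_sigma: float = 1.0
    capture_sigma: float = 3.0
    majority_window: int = 3
    majority_passes: int = 1
    levels: int = _texture.DEFAULT_LEVELS
    offsets: tuple = _texture.DEFAULT_OFFSETS
    training_stride: int | None = None
    calibration: Calibration | None = None
    seed: int = 0

    @classmethod
    def for_phantoms(cls, **overrides) -> "PipelineConfig":
        """Settings for the 512x512 phantom preset, roughly a 2.3x
        down-scale of a full micrograph: the length-like scales shrink
        accordingly (gradient sigma 10, capture sigma 6); everything
        else keeps the full-resolution defaults."""
        defaults = dict(f1_sigma=10.0, capture_sigma=6.0)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class AnnotatedRegion:
    """A refined, labelled, measured region of interest."""

    contour: Contour
    mask: np.ndarray
    label: str | None
    area_px: int
    area_um2: float | None = None
    omega_vs_truth: float | None = None


# ---------------------------------------------------------------------------
# training


def collect_training_samples(training, config: PipelineConfig):
    """Harvest labelled feature vectors from annotated images.

    Blocks fully inside an annotated polygon take that polygon's label;
    blocks fully outside every polygon become 'background' samples.
    Straddling blocks are discarded.  Returns (features, labels).
    """
    stride = config.training_stride or max(1, config.block_size // 2)
    feats: list = []
    labels: list = []
    requested: set = set()
    max_background_per_image = 150  # cap the heavily over-represented class
    for image, records in training:
        image = np.asarray(image)
        masks = []
        for rec in records:
            requested.add(rec.label)
            masks.append((rec.label, contour_to_mask(rec.polygon_array(), image.shape)))
        any_mask = np.zeros(image.shape, dtype=bool)
        for _, msk in masks:
            any_mask |= msk
        fg: list = []
        bg: list = []
        for b in _texture.sample_blocks(image, config.block_size, stride):
            r, c = b.origin
            bs = config.block_size
            window = slice(r, r + bs), slice(c, c + bs)
            label = None
            for name, msk in masks:
                if msk[window].all():
                    label = name
                    break
            if label is not None:
                fg.append((b, label))
            elif not any_mask[window].any():
                bg.append(b)
        if len(bg) > max_background_per_image:
            idx = np.linspace(0, len(bg) - 1, max_background_per_image).round().astype(int)
            bg = [bg[i] for i in idx]
        for b, label in fg + [(b, _synth.BACKGROUND_LABEL) for b in bg]:
            feats.append(_texture.extract_features(b, config.levels, config.offsets).as_array())
            labels.append(label)
    covered = set(labels)
    missing = sorted(requested - covered)
    if missing:
        raise _mm.TrainingError(
            f"no block fits fully inside any region of class(es): {', '.join(missing)}"
        )
    return np.array(feats), np.array(labels, dtype=object)


def train_model(training, config: PipelineConfig = PipelineConfig()) -> _mm.MulticlassModel:
    """Train the block classifier from (image, annotations) pairs.

    The background class is added automatically from unannotated area.
    Features are z-scored with training-set statistics stored in the model.
    """
    X, y = collect_training_samples(training, config)
    names, counts = np.unique(y.astype(str), return_counts=True)
    for name, cnt in zip(names, counts):
        log.info("training samples: %-28s %d", name, cnt)
    if len(names) < 2:
        raise _mm.TrainingError("need at least 2 classes (did annotations cover everything?)")
    return _mm.train_multiclass(X, y, config.kernel, config.cost, standardize=True)


# ---------------------------------------------------------------------------
# segmentation


def _classified_map(image, model, config: PipelineConfig) -> _ff.BlockLabelMap:
    lmap = _ff.classify_blocks(image, model, config.block_size, config.levels, config.offsets)
    return _ff.majority_filter(lmap, config.majority_window, config.majority_passes)


def _class_greylevels(model: _mm.MulticlassModel) -> dict:
    names = sorted(model.class_names)
    levels = np.linspace(0, 255, len(names))
    return {n: int(round(v)) for n, v in zip(names, levels)}


def _finish(image, contour: Contour, config: PipelineConfig, label=None) -> AnnotatedRegion:
    mask = contour_to_mask(contour, np.asarray(image).shape)
    if not mask.any():
        raise SegmentationError("snake collapsed to an empty region")
    px, um2 = _measure.area(mask, config.calibration)
    return AnnotatedRegion(contour=contour, mask=mask, label=label, area_px=px, area_um2=um2)


def _majority_label(lmap: _ff.BlockLabelMap, mask: np.ndarray, image, model,
                    config: PipelineConfig) -> str | None:
    """Majority class over classified blocks whose centres fall inside
    `mask`, disregarding 'background' whenever any object class is
    present (the refined region is by construction an object); ties go
    to the class with the larger mean decision margin, then
    lexicographic order."""
    bs = lmap.block_size
    votes: dict = {}
    inside_blocks: dict = {}
    gn, gm = lmap.labels.shape
    for r in range(gn):
        for c in range(gm):
            cr, cc = r * bs + bs // 2, c * bs + bs // 2
            if mask[cr, cc]:
                name = lmap.labels[r, c]
                votes[name] = votes.get(name, 0) + 1
                inside_blocks.setdefault(name, []).append((r, c))
    if len(votes) > 1:
        votes.pop(_synth.BACKGROUND_LABEL, None)
    if not votes:
        return None
    best = max(votes.values())
    tied = sorted(n for n, v in votes.items() if v == best)
    if len(tied) == 1:
        return tied[0]
    image = np.asarray(image)
    means = {}
    for name in tied:
        margins = []
        for r, c in inside_blocks[name]:
            block = image[r * bs : (r + 1) * bs, c * bs : (c + 1) * bs]
            fv = _texture.extract_features(block, config.levels, config.offsets).as_array()
            x = model.scaling.apply(fv) if model.scaling is not None else fv
            total = 0.0
            for (a, b), mdl in model.pairwise.items():
                if name in (a, b):
                    total += abs(_mm.decision_value(mdl, x))
            margins.append(total)
        means[name] = float(np.mean(margins))
    top = max(means.values())
    return min(n for n in tied if means[n] == top)


def segment_supervised(image, initial: Contour, model: _mm.MulticlassModel,
                       config: PipelineConfig = PipelineConfig()) -> AnnotatedRegion:
    """Refine `initial` using gradient + classifier edge terms and the
    annotation distance modulation; label the result by the majority
    class of the blocks it covers."""
    image = np.asarray(image)
    lmap = _classified_map(image, model, config)
    class_img = _ff.label_map_to_image(lmap, _class_greylevels(model))
    f2 = _ff.edge_term_f2(class_img, config.smooth_sigma, config.thresh_window,
                          config.canny_sigma, config.capture_sigma)
    f1 = _ff.edge_term_f1(image, config.f1_sigma)
    T = _ff.annotation_term(initial, image.shape, config.erosion_radius)
    fld = _ff.compose_external_energy([f1, f2], [config.delta1, config.delta2],
                                      T, config.eta)
    final = evolve(initial, fld, config.snake)
    region = _finish(image, final, config)
    region.label = _majority_label(lmap, region.mask, image, model, config)
    return region


def segment_unsupervised(image, initial: Contour,
                         config: PipelineConfig = PipelineConfig()) -> AnnotatedRegion:
    """Refine `initial` with the gradient term only (classifier term
    forced to zero); no class label is assigned."""
    image = np.asarray(image)
    f1 = _ff.edge_term_f1(image, config.f1_sigma)
    T = _ff.annotation_term(initial, image.shape, config.erosion_radius)
    fld = _ff.compose_external_energy([f1], [config.delta1], T, config.eta)
    final = evolve(initial, fld, config.snake)
    return _finish(image, final, config)


def block_segmentation_mask(image, model: _mm.MulticlassModel,
                            config: PipelineConfig, target_label: str) -> np.ndarray:
    """Coarse segmentation: pixels of blocks classified as `target_label`
    after majority-vote denoising (block-resolution boundary)."""
    image = np.asarray(image)
    lmap = _classified_map(image, model, config)
    greylevels = {n: (255 if n == target_label else 0) for n in model.class_names}
    for name in np.unique(lmap.labels.astype(str)):
        greylevels.setdefault(name, 0)
    return _ff.label_map_to_image(lmap, greylevels) > 0


# ---------------------------------------------------------------------------
# phantom study (the package's own benchmark harness)


def run_phantom_study(n_phantoms: int = 20, seed: int = 0,
                      config: PipelineConfig | None = None,
                      n_training: int = 6) -> dict:
    """Train on phantom images, then segment `n_phantoms` fresh phantoms
    four ways and measure each overlap with the ground truth.

    Returns arrays of Jaccard overlaps keyed 'initial', 'supervised',
    'unsupervised' and 'block', plus the per-phantom assigned labels and
    true labels.  Deterministic given `seed`.
    """
    if config is None:
        config = PipelineConfig.for_phantoms()
    base = (seed * 100003) % (2**31 - 1)

    training = []
    for k in range(n_training):
        spec = _synth.biopsy_phantom_spec(base + k)
        training.append(_synth.generate_phantom(spec))
    model = train_model(training, config)

    out = {"initial": [], "supervised": [], "unsupervised": [], "block": [],
           "assigned_label": [], "true_label": []}
    for k in range(n_phantoms):
        spec = _synth.biopsy_phantom_spec(base + 1000 + k)
        image, records = _synth.generate_phantom(spec)
        truth = contour_to_mask(records[0].polygon_array(), image.shape)
        init = _synth.rough_contour(truth, seed=base + 2000 + k)
        init_mask = contour_to_mask(init, image.shape)

        sup = segment_supervised(image, init, model, config)
        unsup = segment_unsupervised(image, init, config)
        blk = block_segmentation_mask(image, model, config, records[0].label)

        out["initial"].append(_measure.jaccard(init_mask, truth))
        out["supervised"].append(_measure.jaccard(sup.mask, truth))
        out["unsupervised"].append(_measure.jaccard(unsup.mask, truth))
        out["block"].append(_measure.jaccard(blk, truth))
        out["assigned_label"].append(sup.label)
        out["true_label"].append(records[0].label)
    for key in ("initial", "supervised", "unsupervised", "block"):
        out[key] = np.array(out[key])
    return out
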