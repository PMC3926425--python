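"""External-energy (force-field) synthesis.

The field that drives the snake is composed from nonnegative edge-strength
maps e_i in [0, 1] and a distance-transform annotation term T:

    energy(x) = -exp(-eta * T(x)) * sum_i delta_i * e_i(x)

Energy is <= 0 everywhere; minima sit on strong edges close to the
user's initial annotation.  With eta = 0 the modulation vanishes and the
classic gradient-driven field is recovered.

Two edge terms are provided: ``edge_term_f1`` (Gaussian-gradient
magnitude of the raw image) and ``edge_term_f2`` (boundary of the
block-classification map after majority-vote denoising, Gaussian
smoothing, adaptive thresholding and Canny edge detection).  Further
terms can be passed to :func:`compose_external_energy` unchanged, so
alternative edge maps plug in without modification.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from skimage.feature import canny as _canny
from skimage.filters import threshold_local
from skimage.morphology import disk

from . import texture as _texture
from . import maxmargin as _maxmargin
from .snake import Contour, contour_to_mask, resample_contour

__all__ = [
    "BlockLabelMap",
    "ForceField",
    "classify_blocks",
    "majority_filter",
    "label_map_to_image",
    "edge_term_f1",
    "edge_term_f2",
    "annotation_term",
    "compose_external_energy",
]


@dataclass(frozen=True)
class BlockLabelMap:
    """Class labels on the non-overlapping block tiling of an image."""

    labels: np.ndarray  # 2-D object array of class-name strings
    block_size: int
    image_shape: tuple

    def __post_init__(self):
        lab = np.asarray(self.labels, dtype=object)
        n, m = self.image_shape
        expect = (n // self.block_size, m // self.block_size)
        if lab.shape != expect:
            raise ValueError(f"label grid {lab.shape} != expected {expect}")
        object.__setattr__(self, "labels", lab)


@dataclass(frozen=True)
class ForceField:
    """Composed external-energy map plus its named component arrays."""

    energy: np.ndarray
    terms: dict = dc_field(default_factory=dict)
    params: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        e = np.asarray(self.energy, dtype=float)
        if not np.all(np.isfinite(e)):
            raise ValueError("energy must be finite everywhere")
        if e.max() > 1e-12:
            raise ValueError("energy must be <= 0 everywhere")
        object.__setattr__(self, "energy", e)


# ---------------------------------------------------------------------------
# classifier-driven term


def classify_blocks(image: np.ndarray, model: _maxmargin.MulticlassModel,
                    block_size: int, levels: int = _texture.DEFAULT_LEVELS,
                    offsets=_texture.DEFAULT_OFFSETS) -> BlockLabelMap:
    """Label every tiled block of `image` with the classifier's class."""
    image = np.asarray(image)
    blocks = _texture.sample_blocks(image, block_size, stride=block_size)
    n, m = image.shape
    gn, gm = n // block_size, m // block_size
    labels = np.empty((gn, gm), dtype=object)
    for b in blocks:
        fv = _texture.extract_features(b, levels, offsets).as_array()
        r, c = b.origin
        labels[r // block_size, c // block_size] = _maxmargin.predict_multiclass(model, fv)
    return BlockLabelMap(labels=labels, block_size=block_size, image_shape=(n, m))


def majority_filter(label_map: BlockLabelMap, window: int = 3, max_passes: int = 1) -> BlockLabelMap:
    """Majority-vote denoising with a dynamic vote limit.

    A cell is relabelled to class L only if L holds strictly more than
    half of the valid (in-bounds) cells of its window — the dynamic
    limit floor(n_valid/2)+1.  Passes repeat until a fixed point or
    ``max_passes``.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    lab = np.asarray(label_map.labels, dtype=object).copy()
    gn, gm = lab.shape
    h = window // 2
    for _ in range(max_passes):
        out = lab.copy()
        changed = False
        for r in range(gn):
            for c in range(gm):
                win = lab[max(0, r - h) : r + h + 1, max(0, c - h) : c + h + 1].ravel()
                limit = win.size // 2 + 1
                names, counts = np.unique(win.astype(str), return_counts=True)
                k = int(np.argmax(counts))
                if counts[k] >= limit and names[k] != lab[r, c]:
                    out[r, c] = names[k]
                    changed = True
        lab = out
        if not changed:
            break
    return BlockLabelMap(labels=lab, block_size=label_map.block_size,
                         image_shape=label_map.image_shape)


def label_map_to_image(label_map: BlockLabelMap, class_greylevels: dict) -> np.ndarray:
    """Render the block-label grid as a grayscale image.

    Each pixel takes the greylevel of its block; pixels beyond the tiled
    area (image edges) inherit the nearest block's label.
    """
    lab = label_map.labels
    n, m = label_map.image_shape
    bs = label_map.block_size
    gn, gm = lab.shape
    grid = np.empty((gn, gm), dtype=np.uint8)
    for r in range(gn):
        for c in range(gm):
            name = lab[r, c]
            if name not in class_greylevels:
                raise KeyError(f"no greylevel assigned for class {name!r}")
            grid[r, c] = class_greylevels[name]
    rows = np.clip(np.arange(n) // bs, 0, gn - 1)
    cols = np.clip(np.arange(m) // bs, 0, gm - 1)
    return grid[np.ix_(rows, cols)]


def edge_term_f2(class_image: np.ndarray, smooth_sigma: float = 1.0,
                 thresh_window: int = 151, canny_sigma: float = 1.0,
                 capture_sigma: float = 3.0) -> np.ndarray:
    """Edge strength of the classification map, in [0, 1].

    Pipeline: Gaussian smoothing of the class image, local-mean adaptive
    thresholding, Canny edge detection (hysteresis at the 70th/90th
    percentiles of the nonzero gradient magnitudes), then Gaussian
    diffusion of the binary edges (``capture_sigma``) and max-normalization.
    A constant class image yields an all-zero map.

    ``thresh_window`` must exceed the object scale: a window smaller than
    the objects hollows plateaus out into edge bands and hallucinates
    ghost transitions in smooth intensity tails.
    """
    img = np.asarray(class_image, dtype=float)
    smoothed = ndimage.gaussian_filter(img, smooth_sigma)
    if smoothed.max() == smoothed.min():
        return np.zeros_like(img)
    local = threshold_local(smoothed, block_size=thresh_window | 1, method="mean", offset=0)
    binary = (smoothed > local).astype(float)
    grad = ndimage.gaussian_gradient_magnitude(binary, canny_sigma)
    nz = grad[grad > 1e-12]
    if nz.size == 0:
        return np.zeros_like(img)
    lo, hi = np.percentile(nz, [70, 90])
    edges = _canny(binary, sigma=canny_sigma, low_threshold=lo, high_threshold=hi)
    diffused = ndimage.gaussian_filter(edges.astype(float), capture_sigma)
    peak = diffused.max()
    return diffused / peak if peak > 0 else diffused


def edge_term_f1(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-gradient edge strength ||grad(G_sigma * I)||, max-normalized."""
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    grad = ndimage.gaussian_gradient_magnitude(np.asarray(image, dtype=float), sigma)
    peak = grad.max()
    return grad / peak if peak > 0 else grad


def annotation_term(contour: Contour, image_shape: tuple, erosion_radius: int = 3) -> np.ndarray:
    """Euclidean distance to the eroded projection of the initial contour.

    The closed contour is interpolated, filled, eroded by a disk of
    ``erosion_radius`` (falling back to the unfilled mask when erosion
    empties it), and the Euclidean distance transform to the remaining
    foreground is returned (0 on the mask itself).
    """
    if not isinstance(contour, Contour):
        contour = Contour(np.atleast_2d(np.asarray(contour, dtype=float)))
    interp = resample_contour(contour, 1.0)
    mask = contour_to_mask(interp, image_shape)
    if not mask.any():
        raise ValueError("degenerate contour: zero-area projection")
    if erosion_radius > 0:
        eroded = ndimage.binary_erosion(mask, structure=disk(erosion_radius))
        if eroded.any():
            mask = eroded
    return ndimage.distance_transform_edt(~mask)


def compose_external_energy(f_terms, deltas, T: np.ndarray | None = None,
                            eta: float = 0.0, params: dict | None = None) -> ForceField:
    """Combine edge terms and the annotation distance into the energy map.

    energy = -exp(-eta*T) * sum_i delta_i * e_i ; with eta=0 or T=None the
    annotation modulation is disabled.
    """
    f_terms = [np.asarray(f, dtype=float) for f in f_terms]
    deltas = [float(d) for d in deltas]
    if len(f_terms) != len(deltas):
        raise ValueError("need one weight per edge term")
    if any(d < 0 for d in deltas):
        raise ValueError("weights must be >= 0")
    if eta < 0:
        raise ValueError("eta must be >= 0")
    if not f_terms:
        raise ValueError("need at least one edge term")
    shape = f_terms[0].shape
    for f in f_terms:
        if f.shape != shape:
            raise ValueError("edge terms must share one shape")
    pi = np.zeros(shape)
    terms = {}
    for i, (f, d) in enumerate(zip(f_terms, deltas), start=1):
        pi += d * f
        terms[f"f{i}"] = f
    if T is not None and eta > 0:
        T = np.asarray(T, dtype=float)
        if T.shape != shape:
            raise ValueError("annotation term shape mismatch")
        modulation = np.exp(-eta * T)
        terms["T"] = T
        terms["modulation"] = modulation
    else:
        modulation = np.ones(shape)
    energy = -modulation * pi
    return ForceField(energy=energy, terms=terms,
                      params=dict(params or {}, deltas=deltas, eta=eta))
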