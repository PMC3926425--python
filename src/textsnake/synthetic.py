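"""Texture-phantom generator with ground truth.

Phantoms emulate stained kidney-biopsy micrographs at reduced scale:
compact elliptical "glomerulus-like" regions and elongated capsule
"tubulus-like" regions on a pale, lightly cluttered background.  Each
class is a stationary Gaussian noise texture (class-specific mean and
standard deviation) optionally overlaid with an oriented sinusoidal
grating, so that some class pairs are separable only by second-order
(co-occurrence) statistics.  Background clutter (small dark blobs
standing in for nuclei and debris) creates spurious intensity edges
that a purely gradient-driven contour can lock onto.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import AnnotationRecord
from .snake import Contour, contour_to_mask, mask_to_contour, resample_contour
from . import texture as _texture

__all__ = [
    "TextureSpec",
    "RegionSpec",
    "BackgroundSpec",
    "PhantomSpec",
    "CLASS_TEXTURES",
    "generate_phantom",
    "rough_contour",
    "biopsy_phantom_spec",
    "class_separation",
]


@dataclass(frozen=True)
class TextureSpec:
    """Stationary texture: base grey level + Gaussian noise, optionally
    overlaid with an oriented grating and/or round dark blotches
    (capillary-tuft-like internal structure)."""

    base: float
    noise_sigma: float
    grating_period: float | None = None
    grating_contrast: float = 0.0
    grating_angle_deg: float = 0.0
    blotch_level: float | None = None
    blotch_radius: tuple = (6.0, 13.0)
    blotch_coverage: float = 0.0


@dataclass(frozen=True)
class RegionSpec:
    """One foreground region: geometry, class label and texture.

    kind 'ellipse': geometry = {center, semiaxes, angle_deg}
    kind 'tube':    geometry = {p0, p1, width}  (a capsule around segment p0-p1)
    """

    kind: str
    label: str
    texture: TextureSpec
    geometry: dict

    def __post_init__(self):
        if self.kind not in ("ellipse", "tube"):
            raise ValueError(f"unknown region kind {self.kind!r}")


@dataclass(frozen=True)
class BackgroundSpec:
    texture: TextureSpec = TextureSpec(base=190.0, noise_sigma=10.0)
    clutter_count: int = 20
    clutter_radius: tuple = (3.0, 7.0)
    clutter_level: float = 80.0
    clutter_noise_sigma: float = 10.0


@dataclass(frozen=True)
class PhantomSpec:
    image_shape: tuple = (512, 512)
    regions: tuple = ()
    background: BackgroundSpec = BackgroundSpec()
    seed: int = 0


#: default class textures of the "biopsy" preset.  The two glomerulus
#: classes share mean and noise level and differ only by a grating, as do
#: the two tubulus classes: first-order statistics separate glomerulus
#: from tubulus from background, second-order statistics separate the
#: pathological variants.  All region means sit close to the pale
#: background, so the raw intensity edges at region boundaries are weak
#: — the regime the texture-driven field is meant for.
CLASS_TEXTURES = {
    "glomerulus-normal": TextureSpec(
        base=186.0, noise_sigma=10.0, blotch_level=135.0, blotch_coverage=0.35,
        blotch_radius=(8.0, 16.0),
    ),
    "glomerulus-pathological": TextureSpec(
        base=186.0, noise_sigma=10.0, blotch_level=135.0, blotch_coverage=0.35,
        blotch_radius=(8.0, 16.0),
        grating_period=6.0, grating_contrast=25.0, grating_angle_deg=30.0,
    ),
    "tubulus-normal": TextureSpec(
        base=180.0, noise_sigma=10.0, grating_period=9.0, grating_contrast=18.0,
        grating_angle_deg=120.0,
    ),
    "tubulus-pathological": TextureSpec(
        base=180.0, noise_sigma=10.0, grating_period=15.0, grating_contrast=18.0,
        grating_angle_deg=60.0,
    ),
}

BACKGROUND_LABEL = "background"


# ---------------------------------------------------------------------------
# geometry -> polygon


def _ellipse_polygon(center, semiaxes, angle_deg=0.0, n_vertices=72) -> np.ndarray:
    cr, cc = center
    a, b = semiaxes
    th = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = a * np.cos(th)
    c = b * np.sin(th)
    phi = np.deg2rad(angle_deg)
    rr = cr + r * np.cos(phi) - c * np.sin(phi)
    cc_ = cc + r * np.sin(phi) + c * np.cos(phi)
    return np.column_stack([rr, cc_])


def _capsule_polygon(p0, p1, width, n_cap=18) -> np.ndarray:
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    if length == 0:
        raise ValueError("degenerate tube: p0 == p1")
    u = axis / length
    nvec = np.array([-u[1], u[0]])
    r = width / 2.0
    # side, far cap, opposite side, near cap
    side_a = [p0 + r * nvec, p1 + r * nvec]
    theta = np.linspace(0, np.pi, n_cap)
    far_cap = [p1 + r * (np.cos(t) * nvec + np.sin(t) * u) for t in theta]
    side_b = [p1 - r * nvec, p0 - r * nvec]
    near_cap = [p0 + r * (-np.cos(t) * nvec - np.sin(t) * u) for t in theta]
    poly = np.array(side_a + far_cap + side_b + near_cap)
    # drop consecutive duplicates
    keep = [0]
    for i in range(1, len(poly)):
        if np.linalg.norm(poly[i] - poly[keep[-1]]) > 1e-9:
            keep.append(i)
    return poly[keep]


def region_polygon(region: RegionSpec) -> np.ndarray:
    if region.kind == "ellipse":
        g = region.geometry
        return _ellipse_polygon(g["center"], g["semiaxes"], g.get("angle_deg", 0.0))
    g = region.geometry
    return _capsule_polygon(g["p0"], g["p1"], g["width"])


def _fill_texture(shape, spec: TextureSpec, rng: np.random.Generator) -> np.ndarray:
    n, m = shape
    img = np.full((n, m), spec.base, dtype=float)
    if spec.grating_period:
        rr, cc = np.mgrid[0:n, 0:m]
        phi = np.deg2rad(spec.grating_angle_deg)
        phase = (rr * np.sin(phi) + cc * np.cos(phi)) * (2 * np.pi / spec.grating_period)
        img += spec.grating_contrast * np.sin(phase)
    img += rng.normal(0.0, spec.noise_sigma, size=(n, m))
    return img


def _add_blotches(tex: np.ndarray, msk: np.ndarray, spec: TextureSpec,
                  rng: np.random.Generator) -> None:
    """Scatter round dark blotches inside `msk` until roughly
    ``blotch_coverage`` of its area is covered (in place)."""
    if not spec.blotch_coverage or spec.blotch_level is None:
        return
    n, m = tex.shape
    rows, cols = np.nonzero(msk)
    target = spec.blotch_coverage * len(rows)
    covered = np.zeros_like(msk)
    attempts = 0
    while covered.sum() < target and attempts < 500:
        attempts += 1
        k = rng.integers(0, len(rows))
        r0, c0 = rows[k], cols[k]
        rad = rng.uniform(*spec.blotch_radius)
        rr, cc = np.ogrid[0:n, 0:m]
        blob = ((rr - r0) ** 2 + (cc - c0) ** 2 <= rad ** 2) & msk
        tex[blob] = spec.blotch_level + rng.normal(0.0, spec.noise_sigma, size=int(blob.sum()))
        covered |= blob


def generate_phantom(spec: PhantomSpec) -> tuple:
    """Render a phantom image and its ground-truth annotations.

    Returns ``(image, records)`` where `image` is a uint8 array and
    `records` are :class:`~textsnake.io.AnnotationRecord` ground-truth
    polygons, one per region, in region order.  Raises ``ValueError``
    when two regions overlap.
    """
    n, m = spec.image_shape
    rng = np.random.default_rng(spec.seed)

    polys = [region_polygon(r) for r in spec.regions]
    masks = [contour_to_mask(p, (n, m)) for p in polys]
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if np.logical_and(masks[i], masks[j]).any():
                raise ValueError(f"regions {i} and {j} overlap")

    # background first (noise field drawn over the full frame)
    image = _fill_texture((n, m), spec.background.texture, rng)

    # clutter blobs, kept away from the foreground regions
    bg = spec.background
    if bg.clutter_count > 0:
        forbidden = np.zeros((n, m), dtype=bool)
        for msk in masks:
            forbidden |= ndimage.binary_dilation(msk, iterations=6)
        placed = 0
        attempts = 0
        while placed < bg.clutter_count and attempts < bg.clutter_count * 30:
            attempts += 1
            r0 = rng.uniform(0, n)
            c0 = rng.uniform(0, m)
            rad = rng.uniform(*bg.clutter_radius)
            rr, cc = np.ogrid[0:n, 0:m]
            blob = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad ** 2
            if not blob.any() or (blob & forbidden).any():
                continue
            image[blob] = bg.clutter_level + rng.normal(
                0.0, bg.clutter_noise_sigma, size=int(blob.sum())
            )
            placed += 1

    # foreground textures
    for region, msk in zip(spec.regions, masks):
        tex = _fill_texture((n, m), region.texture, rng)
        _add_blotches(tex, msk, region.texture, rng)
        image[msk] = tex[msk]

    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    records = [
        AnnotationRecord(
            polygon=[(float(r), float(c)) for r, c in poly],
            label=region.label,
            image_id=f"phantom-{spec.seed}",
        )
        for region, poly in zip(spec.regions, polys)
    ]
    return image, records


def rough_contour(truth_mask: np.ndarray, jitter: float | None = None,
                  dilation: float | None = None, seed: int = 0) -> Contour:
    """Emulate a user's quick drag around an object.

    The ground-truth boundary is dilated outward by `dilation` pixels,
    each vertex is perturbed by uniform noise up to `jitter` pixels, and
    the result is resampled and clamped to the image frame.  The
    defaults scale with the object (dilation 18% of the equivalent
    radius, jitter 40% of the dilation), which lands the initial overlap
    with the truth in the rough-outline range (about 0.6-0.85)
    regardless of object size.
    """
    mask = np.asarray(truth_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty truth mask")
    if dilation is None:
        dilation = 0.18 * float(np.sqrt(mask.sum() / np.pi))
    if jitter is None:
        jitter = 0.4 * dilation
    if dilation > 0:
        mask = ndimage.binary_dilation(mask, structure=_disk(dilation))
    contour = mask_to_contour(mask, spacing=3.0)
    rng = np.random.default_rng(seed)
    pts = contour.points + rng.uniform(-jitter, jitter, size=contour.points.shape)
    n, m = truth_mask.shape
    pts[:, 0] = np.clip(pts[:, 0], 0, n - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, m - 1)
    return resample_contour(pts, 5.0)


def _disk(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    rr, cc = np.mgrid[-r : r + 1, -r : r + 1]
    return (rr ** 2 + cc ** 2) <= radius ** 2


# ---------------------------------------------------------------------------
# "biopsy" preset


def biopsy_phantom_spec(seed: int = 0, image_shape: tuple = (512, 512)) -> PhantomSpec:
    """Preset phantom: one target glomerulus-like ellipse, one secondary
    ellipse and one tubulus-like capsule, classes cycling with the seed.

    The first region is the segmentation target.  Geometry is jittered
    deterministically by the seed within bounds that keep regions
    disjoint and large enough for a 37x37 block to fit fully inside.
    """
    rng = np.random.default_rng(seed)
    n, m = image_shape
    sy, sx = n / 300.0, m / 300.0

    glom_classes = ["glomerulus-normal", "glomerulus-pathological"]
    tub_classes = ["tubulus-normal", "tubulus-pathological"]
    g_main = glom_classes[seed % 2]
    g_other = glom_classes[(seed + 1) % 2]
    t_class = tub_classes[(seed // 2) % 2]

    target = RegionSpec(
        kind="ellipse",
        label=g_main,
        texture=CLASS_TEXTURES[g_main],
        geometry={
            "center": (rng.uniform(100, 130) * sy, rng.uniform(100, 125) * sx),
            "semiaxes": (rng.uniform(55, 68) * sy, rng.uniform(48, 60) * sx),
            "angle_deg": rng.uniform(0, 180),
        },
    )
    second = RegionSpec(
        kind="ellipse",
        label=g_other,
        texture=CLASS_TEXTURES[g_other],
        geometry={
            "center": (rng.uniform(70, 90) * sy, rng.uniform(240, 252) * sx),
            "semiaxes": (rng.uniform(32, 38) * sy, rng.uniform(29, 33) * sx),
            "angle_deg": 0.0,
        },
    )
    tube = RegionSpec(
        kind="tube",
        label=t_class,
        texture=CLASS_TEXTURES[t_class],
        geometry={
            "p0": (rng.uniform(240, 252) * sy, 45 * sx),
            "p1": (rng.uniform(240, 252) * sy, 255 * sx),
            "width": rng.uniform(48, 56) * sy,
        },
    )
    return PhantomSpec(image_shape=image_shape, regions=(target, second, tube), seed=seed)


# ---------------------------------------------------------------------------
# texture sanity check used by the tests


def class_separation(image: np.ndarray, records, block_size: int = 37,
                     stride: int | None = None) -> dict:
    """Between-class centroid distance over within-class spread, per pair.

    Blocks fully inside each annotated polygon contribute to that class.
    Features are z-scored over the pooled samples first (the scale the
    classifier sees); the ratio for a pair is ||centroid_a - centroid_b||
    divided by the mean of the two within-class mean distances to
    centroid.
    """
    if stride is None:
        stride = max(1, block_size // 2)
    by_class: dict = {}
    for rec in records:
        mask = contour_to_mask(rec.polygon_array(), image.shape)
        for b in _texture.sample_blocks(image, block_size, stride):
            r, c = b.origin
            if mask[r : r + block_size, c : c + block_size].all():
                by_class.setdefault(rec.label, []).append(
                    _texture.extract_features(b).as_array()
                )
    pooled = np.array([x for v in by_class.values() for x in v])
    if len(pooled) >= 2:
        mu = pooled.mean(axis=0)
        sd = pooled.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        by_class = {k: [(x - mu) / sd for x in v] for k, v in by_class.items()}
    stats = {
        k: (np.mean(v, axis=0), float(np.mean([np.linalg.norm(x - np.mean(v, axis=0)) for x in v])))
        for k, v in by_class.items()
        if len(v) >= 2
    }
    ratios = {}
    names = sorted(stats)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            (ca, sa), (cb, sb) = stats[a], stats[b]
            spread = (sa + sb) / 2.0
            ratios[(a, b)] = float(np.linalg.norm(ca - cb) / spread) if spread > 0 else np.inf
    return ratios
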