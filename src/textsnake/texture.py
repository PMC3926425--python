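"""Block sampling and texture feature extraction.

Each square block yields a 7-dimensional feature vector: first-order
statistics (mean, population standard deviation of the raw intensities)
plus five Haralick descriptors of the gray-level co-occurrence matrix
(contrast, inverse difference moment, correlation, entropy, angular
second moment).  GLCM statistics are computed per offset and averaged
over the configured offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Block",
    "FeatureVector",
    "DEFAULT_LEVELS",
    "DEFAULT_OFFSETS",
    "sample_blocks",
    "cooccurrence",
    "extract_features",
    "features_matrix",
]

#: quantization bins for the co-occurrence matrix
DEFAULT_LEVELS = 32

#: distance-1 offsets at 0, 45, 90, 135 degrees
DEFAULT_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

FEATURE_NAMES = ("mean", "std", "contrast", "idm", "correlation", "entropy", "asm")


@dataclass(frozen=True)
class Block:
    """A square sub-image with the (row, col) of its top-left pixel."""

    pixels: np.ndarray
    origin: tuple

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError(f"block must be square 2-D, got shape {p.shape}")


@dataclass(frozen=True)
class FeatureVector:
    """The 7 texture features of one block."""

    mean: float
    std: float
    contrast: float
    idm: float
    correlation: float
    entropy: float
    asm: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "FeatureVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (7,):
            raise ValueError(f"expected 7 features, got shape {arr.shape}")
        return cls(*(float(v) for v in arr))


def sample_blocks(image: np.ndarray, block_size: int, stride: int | None = None) -> list[Block]:
    """Raster-scan `image` and return all fully-contained square blocks.

    Blocks are enumerated row-major.  With the default stride equal to
    ``block_size`` the image is tiled without overlap.
    """
    image = np.asarray(image)
    n, m = image.shape
    if stride is None:
        stride = block_size
    if block_size < 1 or block_size > min(n, m):
        raise ValueError(f"block_size {block_size} does not fit image {n}x{m}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    blocks = []
    for r in range(0, n - block_size + 1, stride):
        for c in range(0, m - block_size + 1, stride):
            blocks.append(Block(image[r : r + block_size, c : c + block_size], (r, c)))
    return blocks


def quantize(pixels: np.ndarray, levels: int) -> np.ndarray:
    """Quantize 8-bit intensities into `levels` equal-width bins over [0, 255]."""
    return (np.asarray(pixels, dtype=np.int64) * levels) // 256


def cooccurrence(block: Block | np.ndarray, levels: int = DEFAULT_LEVELS,
                 offsets=DEFAULT_OFFSETS) -> np.ndarray:
    """Symmetric normalized gray-level co-occurrence matrix.

    Intensities are quantized into `levels` equal-width bins; for every
    offset ``(dr, dc)`` each in-bounds pixel pair is counted in both
    directions, pooled over all offsets, and normalized to sum to 1.
    """
    pixels = block.pixels if isinstance(block, Block) else np.asarray(block)
    if levels < 2:
        raise ValueError("levels must be >= 2")
    offsets = list(offsets)
    if not offsets:
        raise ValueError("offsets must be nonempty")
    q = quantize(pixels, levels)
    counts = np.zeros((levels, levels), dtype=np.int64)
    n, m = q.shape
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(n, n - dr)
        c0, c1 = max(0, -dc), min(m, m - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = q[r0:r1, c0:c1].ravel()
        b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
        counts += np.bincount(a * levels + b, minlength=levels * levels).reshape(levels, levels)
    counts = counts + counts.T  # symmetric counting
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs for the given offsets")
    return counts / total


def _haralick(p: np.ndarray) -> tuple:
    """(contrast, idm, correlation, entropy, asm) of a normalized GLCM."""
    levels = p.shape[0]
    i = np.arange(levels, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff2 = (ii - jj) ** 2
    contrast = float((diff2 * p).sum())
    idm = float((p / (1.0 + diff2)).sum())
    pi = p.sum(axis=1)
    mu_i = float((i * pi).sum())
    sigma_i = float(np.sqrt(((i - mu_i) ** 2 * pi).sum()))
    # symmetric matrix: both marginals coincide
    if sigma_i > 0:
        correlation = float((((ii - mu_i) * (jj - mu_i) * p).sum()) / (sigma_i * sigma_i))
    else:
        correlation = 0.0  # constant block: undefined 0/0, fixed at 0
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    asm = float((p * p).sum())
    return contrast, idm, correlation, entropy, asm


def extract_features(block: Block | np.ndarray, levels: int = DEFAULT_LEVELS,
                     offsets=DEFAULT_OFFSETS) -> FeatureVector:
    """Compute the 7-feature vector of one block.

    Mean and standard deviation use the raw (unquantized) intensities;
    the GLCM terms are computed per offset and averaged over offsets.
    """
    pixels = np.asarray(block.pixels if isinstance(block, Block) else block, dtype=float)
    mean = float(pixels.mean())
    std = float(pixels.std())  # population std
    offsets = list(offsets)
    acc = np.zeros(5)
    for off in offsets:
        acc += np.array(_haralick(cooccurrence(pixels.astype(np.uint8), levels, [off])))
    acc /= len(offsets)
    return FeatureVector(mean, std, *(float(v) for v in acc))


def features_matrix(blocks, levels: int = DEFAULT_LEVELS, offsets=DEFAULT_OFFSETS) -> np.ndarray:
    """Stack feature vectors for a sequence of blocks into an (n, 7) array."""
    return np.array([extract_features(b, levels, offsets).as_array() for b in blocks])
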