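"""Greedy active-contour (snake) evolution.

A closed contour v(s) minimizes the discrete energy

    E = sum_i  alpha |dv/ds|^2 + beta |d^2v/ds^2|^2 + P(v_i)

where P is the external energy supplied by a :class:`~textsnake.forcefield.ForceField`.
Minimization follows the classic greedy scheme: each vertex in turn
examines an integer-offset window of half-width d, the continuity,
curvature and image terms are min-max normalized over the window, and
the vertex moves to the candidate with the lowest weighted sum.  The
contour is periodically resampled to keep vertices evenly spaced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.draw import polygon2mask

__all__ = [
    "Contour",
    "SnakeParams",
    "resample_contour",
    "greedy_step",
    "evolve",
    "contour_to_mask",
    "mask_to_contour",
]


@dataclass(frozen=True)
class Contour:
    """Ordered closed sequence of (row, col) points, real-valued pixels."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
            raise ValueError(f"contour needs >= 4 (row, col) points, got shape {pts.shape}")
        gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(gaps == 0):
            raise ValueError("consecutive duplicate contour points")
        object.__setattr__(self, "points", pts)

    def __len__(self):
        return self.points.shape[0]

    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())


@dataclass(frozen=True)
class SnakeParams:
    """Greedy-snake parameters.

    alpha, beta
        Continuity (tension) and curvature (rigidity) weights.
    search_radius
        Half-width d of the (2d+1)^2 candidate window, pixels.
    max_iter, move_fraction_stop
        Iterate until fewer than ``move_fraction_stop`` of the vertices
        move in a sweep, or ``max_iter`` sweeps.
    resample_spacing
        Target vertex spacing; the contour is resampled every 10 sweeps.
    """

    alpha: float = 1.44
    beta: float = 1.58
    search_radius: int = 8
    max_iter: int = 200
    move_fraction_stop: float = 0.05
    resample_spacing: float = 5.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.search_radius < 1:
            raise ValueError("search_radius must be >= 1")
        if not 0 < self.move_fraction_stop < 1:
            raise ValueError("move_fraction_stop must lie in (0, 1)")


def resample_contour(points, spacing: float) -> Contour:
    """Resample a closed polyline to ~equally spaced vertices.

    The number of output vertices is max(4, round(perimeter / spacing));
    vertices are placed by arc length along the closed input polyline.
    """
    if isinstance(points, Contour):
        pts = points.points
    else:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3:
        raise ValueError("need >= 3 points to resample")
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    perimeter = float(seg.sum())
    if perimeter <= 0:
        raise ValueError("zero-perimeter contour")
    n_out = max(4, int(round(perimeter / spacing)))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(n_out) * perimeter / n_out
    out = np.empty((n_out, 2))
    for k, t in enumerate(targets):
        i = int(np.searchsorted(cum, t, side="right")) - 1
        i = min(i, len(seg) - 1)
        frac = (t - cum[i]) / seg[i] if seg[i] > 0 else 0.0
        out[k] = closed[i] + frac * (closed[i + 1] - closed[i])
    # collapse numerically duplicate neighbours, keep >= 4 vertices
    keep = [0]
    for k in range(1, n_out):
        if np.linalg.norm(out[k] - out[keep[-1]]) > 1e-12:
            keep.append(k)
    out = out[keep]
    if out.shape[0] < 4:
        raise ValueError("contour degenerates below 4 points at this spacing")
    return Contour(out)


def _normalize_window(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi - lo <= 1e-12:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def greedy_step(contour: Contour, field, params: SnakeParams) -> tuple:
    """One greedy sweep over all vertices; returns (contour', moved_count).

    Vertices are visited in order and updated in place, so each vertex
    sees its predecessor's new position (the classic sequential sweep).
    Ties go to the smallest candidate offset magnitude, then row-major
    window order, so a flat landscape leaves the contour unchanged.
    """
    energy = field.energy if hasattr(field, "energy") else np.asarray(field, dtype=float)
    n_rows, n_cols = energy.shape
    pts = contour.points.copy()
    n = pts.shape[0]
    d = params.search_radius

    offs = np.array(
        [(dr, dc) for dr in range(-d, d + 1) for dc in range(-d, d + 1)], dtype=float
    )
    off_mag = np.linalg.norm(offs, axis=1)
    # precedence for ties: offset magnitude, then row-major window order
    order_rank = np.lexsort((np.arange(len(offs)), off_mag))
    rank = np.empty(len(offs), dtype=int)
    rank[order_rank] = np.arange(len(offs))

    closed = np.vstack([pts, pts[:1]])
    mean_spacing = float(np.linalg.norm(np.diff(closed, axis=0), axis=1).mean())

    moved = 0
    for i in range(n):
        prev_pt = pts[(i - 1) % n]
        next_pt = pts[(i + 1) % n]
        cand = pts[i] + offs
        cand[:, 0] = np.clip(cand[:, 0], 0, n_rows - 1)
        cand[:, 1] = np.clip(cand[:, 1], 0, n_cols - 1)

        cont = np.abs(mean_spacing - np.linalg.norm(cand - prev_pt, axis=1))
        curv = ((prev_pt - 2 * cand + next_pt) ** 2).sum(axis=1)
        img = map_coordinates(energy, cand.T, order=1, mode="nearest")

        total = (
            params.alpha * _normalize_window(cont)
            + params.beta * _normalize_window(curv)
            + _normalize_window(img)
        )
        best = np.min(total)
        tied = np.flatnonzero(total <= best + 1e-12)
        choice = tied[np.argmin(rank[tied])]
        new_pt = cand[choice]
        if not np.allclose(new_pt, pts[i]):
            moved += 1
        pts[i] = new_pt
    return Contour(_dedupe(pts)), moved


def _dedupe(pts: np.ndarray) -> np.ndarray:
    """Drop consecutive duplicates produced by clamping; keep closure valid."""
    keep = [0]
    for k in range(1, len(pts)):
        if np.linalg.norm(pts[k] - pts[keep[-1]]) > 1e-12:
            keep.append(k)
    out = pts[keep]
    if len(out) >= 4:
        return out
    # pathological collapse: nudge apart along a tiny spiral to stay a valid contour
    base = pts[0]
    eps = 1e-6
    return np.array(
        [base + [0, 0], base + [0, eps], base + [eps, eps], base + [eps, 0]]
    )


def evolve(initial: Contour, field, params: SnakeParams = SnakeParams()) -> Contour:
    """Iterate greedy sweeps until convergence or ``max_iter``.

    The contour is resampled to ``resample_spacing`` every 10 sweeps to
    keep vertices evenly distributed.  Fully deterministic.
    """
    contour = resample_contour(initial, params.resample_spacing)
    n_iter = 0
    while n_iter < params.max_iter:
        contour, moved = greedy_step(contour, field, params)
        n_iter += 1
        if moved < params.move_fraction_stop * len(contour):
            break
        if n_iter % 10 == 0:
            contour = resample_contour(contour, params.resample_spacing)
    return contour


def contour_to_mask(contour: Contour | np.ndarray, image_shape: tuple) -> np.ndarray:
    """Rasterize the closed contour: pixel centres inside or on the polygon."""
    pts = contour.points if isinstance(contour, Contour) else np.atleast_2d(np.asarray(contour, float))
    return polygon2mask(tuple(image_shape), pts)


def mask_to_contour(mask: np.ndarray, spacing: float = 2.0) -> Contour:
    """Trace the boundary of the largest connected region of a binary mask."""
    from skimage import measure as _skm

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    contours = _skm.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("no boundary found")
    longest = max(contours, key=len)
    return resample_contour(longest, spacing)
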