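"""Image, annotation and model I/O.

Images are held as plain 2-D ``uint8`` numpy arrays in row/column order
(pixel centres at integer coordinates).  Polygon annotations travel in a
small JSON dialect documented under :func:`write_annotations`; trained
classifier models are stored as versioned JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

__all__ = [
    "AnnotationRecord",
    "Calibration",
    "AnnotationError",
    "ModelFormatError",
    "load_gray",
    "save_gray",
    "read_annotations",
    "write_annotations",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


class AnnotationError(ValueError):
    """An annotation record violates the schema."""


class ModelFormatError(ValueError):
    """A model file is unreadable or from an incompatible version."""


@dataclass
class AnnotationRecord:
    """A labelled polygon region on one image.

    Parameters
    ----------
    polygon : sequence of (row, col)
        Vertices in pixel units, 0-based.  The polygon is implicitly
        closed (last vertex connects back to the first).
    label : str
        Class identifier, nonempty.
    label_uri : str, optional
        Opaque external semantic identifier (e.g. an ontology IRI).
    image_id : str
        Identifier of the image the polygon belongs to.
    """

    polygon: list = field(default_factory=list)
    label: str = ""
    label_uri: str | None = None
    image_id: str = ""

    def validate(self, image_shape: tuple | None = None, index: int | None = None) -> None:
        where = f"annotation {index}" if index is not None else "annotation"
        if len(self.polygon) < 3:
            raise AnnotationError(f"{where}: polygon needs >= 3 vertices, got {len(self.polygon)}")
        if not self.label:
            raise AnnotationError(f"{where}: empty class label")
        for r, c in self.polygon:
            if not (np.isfinite(r) and np.isfinite(c)):
                raise AnnotationError(f"{where}: non-finite vertex ({r}, {c})")
            if image_shape is not None:
                n, m = image_shape
                if not (0 <= r <= n - 1 and 0 <= c <= m - 1):
                    raise AnnotationError(
                        f"{where}: vertex ({r}, {c}) outside image {n}x{m}"
                    )

    def polygon_array(self) -> np.ndarray:
        return np.asarray(self.polygon, dtype=float)


@dataclass(frozen=True)
class Calibration:
    """Physical pixel size, microns per pixel (> 0)."""

    microns_per_pixel: float

    def __post_init__(self):
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be strictly positive")


# ---------------------------------------------------------------------------
# images

# ITU-R BT.601 luminance weights for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


def load_gray(path) -> np.ndarray:
    """Load a raster image as an 8-bit grayscale array.

    RGB(A) input is converted to luminance with ITU-R BT.601 weights
    (0.299 R + 0.587 G + 0.114 B), rounded half-up.  Already-gray input
    is passed through unchanged.
    """
    with Image.open(path) as im:
        if im.mode in ("L", "I;16", "I"):
            arr = np.asarray(im.convert("L"))
        elif im.mode in ("RGB", "RGBA", "P"):
            rgb = np.asarray(im.convert("RGB"), dtype=float)
            arr = np.floor(rgb @ _LUMA + 0.5).clip(0, 255).astype(np.uint8)
        else:
            arr = np.asarray(im.convert("L"))
    arr = np.asarray(arr, dtype=np.uint8)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"not a 2-D image: shape {arr.shape}")
    return arr


def save_gray(image: np.ndarray, path) -> None:
    """Write a 2-D uint8 array as a grayscale raster image."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("expected 2-D array")
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path)


def validate_gray(image: np.ndarray) -> np.ndarray:
    """Check shape/range invariants of a grayscale array and return it."""
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"expected nonempty 2-D array, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return arr


# ---------------------------------------------------------------------------
# annotations


def write_annotations(records: Sequence[AnnotationRecord], path, image_id: str | None = None) -> None:
    """Write annotation records as JSON.

    Schema::

        {"image_id": str,
         "annotations": [{"polygon": [[r, c], ...],
                          "label": str,
                          "label_uri": str (omitted when absent)}, ...]}
    """
    records = list(records)
    for i, rec in enumerate(records):
        rec.validate(index=i)
    if image_id is None:
        image_id = records[0].image_id if records else ""
    items = []
    for rec in records:
        item = {"polygon": [[float(r), float(c)] for r, c in rec.polygon], "label": rec.label}
        if rec.label_uri is not None:
            item["label_uri"] = rec.label_uri
        items.append(item)
    payload = {"image_id": image_id, "annotations": items}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotations(path) -> list[AnnotationRecord]:
    """Read annotation records written by :func:`write_annotations`."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(payload, dict) or "annotations" not in payload:
        raise AnnotationError(f"{path}: missing 'annotations' key")
    image_id = payload.get("image_id", "")
    records = []
    for i, item in enumerate(payload["annotations"]):
        if not isinstance(item, dict):
            raise AnnotationError(f"annotation {i}: expected object, got {type(item).__name__}")
        try:
            poly = [(float(r), float(c)) for r, c in item["polygon"]]
        except (KeyError, TypeError, ValueError) as exc:
            raise AnnotationError(f"annotation {i}: malformed polygon") from exc
        rec = AnnotationRecord(
            polygon=poly,
            label=item.get("label", ""),
            label_uri=item.get("label_uri"),
            image_id=image_id,
        )
        rec.validate(index=i)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# models
#
# Serialization lives here; the model classes live in `maxmargin`.  JSON
# round-trips Python floats exactly (repr-based), so predictions are
# preserved bit-for-bit.


def save_model(model, path) -> None:
    """Serialize a trained classifier (binary or multiclass) to JSON."""
    from . import maxmargin

    payload = {"format_version": MODEL_FORMAT_VERSION}
    payload.update(maxmargin.model_to_dict(model))
    Path(path).write_text(json.dumps(payload))


def load_model(path):
    """Load a classifier saved by :func:`save_model`."""
    from . import maxmargin

    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not a valid model file: {exc}") from exc
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: model format version {version!r}, expected {MODEL_FORMAT_VERSION}"
        )
    return maxmargin.model_from_dict(payload)
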