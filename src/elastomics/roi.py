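"""Lesion regions of interest and their propagation across derived images.

A lesion ROI is drawn once (as a closed polygon or supplied directly as
a binary mask) and the *same* mask is applied to the luminance image and
to each of the three channel images, so that any feature difference
between channels is attributable to pixel intensities alone.

Rasterization convention: 0-based row-major pixel grid; pixel (r, c) is
foreground iff its center (r + 0.5, c + 0.5) lies inside the polygon by
the even-odd (ray-crossing) rule.  This rule is deliberately simple
enough to verify against a brute-force point-in-polygon oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .conversion import GrayImage
from .errors import GeometryError, ShapeError


@dataclass(frozen=True)
class ROIPolygon:
    """Closed polygon as an ordered (n, 2) array of (row, col) vertices."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise GeometryError("polygon needs an (n>=3, 2) vertex array")
        object.__setattr__(self, "vertices", v)

    def signed_area(self) -> float:
        """Shoelace signed area (pixels^2); lobes of opposite winding cancel."""
        r, c = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(c * np.roll(r, -1) - np.roll(c, -1) * r))

    def is_degenerate(self) -> bool:
        """True iff all vertices are collinear (the polygon encloses nothing)."""
        v = self.vertices - self.vertices[0]
        d = None
        for w in v[1:]:
            if d is None:
                if not np.allclose(w, 0.0):
                    d = w
            elif abs(d[0] * w[1] - d[1] * w[0]) > 1e-12:
                return False
        return True


@dataclass(frozen=True)
class ROIMask:
    """Binary lesion mask aligned with a target raster."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ShapeError(f"mask must be 2-D, got shape {m.shape}")
        if not m.any():
            raise GeometryError("mask has no foreground pixels")
        object.__setattr__(self, "mask", m)

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def point_in_polygon(points_rc: np.ndarray, polygon: ROIPolygon) -> np.ndarray:
    """Even-odd inclusion test, vectorized over points.

    ``points_rc`` is an (n, 2) array of (row, col) coordinates; returns a
    boolean array.  A point is inside iff a ray cast in the +col
    direction crosses an odd number of edges.
    """
    pts = np.asarray(points_rc, dtype=np.float64)
    pr, pc = pts[:, 0], pts[:, 1]
    verts = polygon.vertices
    inside = np.zeros(len(pts), dtype=bool)
    n = len(verts)
    for i in range(n):
        r1, c1 = verts[i]
        r2, c2 = verts[(i + 1) % n]
        crosses = (r1 > pr) != (r2 > pr)
        with np.errstate(divide="ignore", invalid="ignore"):
            c_at = c1 + (pr - r1) * (c2 - c1) / (r2 - r1)
        inside ^= crosses & (pc < c_at)
    return inside


def polygon_to_mask(poly: ROIPolygon, height: int, width: int) -> ROIMask:
    """Rasterize a polygon by pixel-center even-odd inclusion.

    Raises ``GeometryError`` for zero-area polygons, vertices outside the
    [0, height] x [0, width] bounds, or polygons covering no pixel center.
    """
    if poly.is_degenerate():
        raise GeometryError("degenerate polygon with zero area")
    v = poly.vertices
    if v[:, 0].min() < 0 or v[:, 0].max() > height or v[:, 1].min() < 0 or v[:, 1].max() > width:
        raise GeometryError("polygon vertices fall outside the image bounds")
    rr, cc = np.meshgrid(
        np.arange(height) + 0.5, np.arange(width) + 0.5, indexing="ij"
    )
    centers = np.column_stack([rr.ravel(), cc.ravel()])
    inside = point_in_polygon(centers, poly).reshape(height, width)
    if not inside.any():
        raise GeometryError("polygon encloses no pixel center")
    return ROIMask(inside)


def propagate(mask: ROIMask, *images: GrayImage) -> list[np.ndarray]:
    """Extract the masked values of each image in identical row-major order.

    Returns one 1-D float array per image, each of length
    ``mask.pixel_count``; element k of every list refers to the same
    pixel.  Raises ``ShapeError`` on any dimension mismatch.
    """
    out = []
    for img in images:
        if img.values.shape != mask.shape:
            raise ShapeError(
                f"image shape {img.values.shape} != mask shape {mask.shape}"
            )
        out.append(img.values[mask.mask])
    return out


# ---------------------------------------------------------------------------
# File I/O


def read_mask(path: str | Path, shape: tuple[int, int] | None = None) -> ROIMask:
    """Read a single-channel 0/255 PNG mask (255 = foreground)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    mask = ROIMask(arr >= 128)
    if shape is not None and mask.shape != shape:
        raise ShapeError(f"mask shape {mask.shape} != expected {shape}")
    return mask


def write_mask(mask: ROIMask, path: str | Path) -> None:
    Image.fromarray(np.where(mask.mask, 255, 0).astype(np.uint8), mode="L").save(path)


def read_polygon(path: str | Path) -> ROIPolygon:
    """Read a polygon stored as a JSON list of [row, col] pairs."""
    with open(path) as fh:
        return ROIPolygon(np.asarray(json.load(fh), dtype=np.float64))


def write_polygon(poly: ROIPolygon, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(poly.vertices.tolist(), fh)
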