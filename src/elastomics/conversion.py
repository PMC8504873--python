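"""Color-image preprocessing for color-coded elastograms.

Two routes from an 8-bit RGB shear-wave-elastography frame to grayscale
rasters suitable for radiomics feature extraction:

``to_gray_direct``
    Collapses the three channels into one luminance image,
    ``0.2126 R + 0.7152 G + 0.0722 B``.  This is the conventional
    "direct conversion" and is lossy: distinct colors with equal
    luminance (metamers) become indistinguishable.

``split_channels``
    Decomposes the frame into three single-channel grayscale images
    whose pixel values equal the original R, G and B bytes exactly.
    ``recombine`` is its exact inverse, witnessing losslessness.

The luminance image is kept at full float precision; quantizing back to
8 bits before feature extraction would add a second, unnecessary loss.
PNG export rounds half-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import DomainError, ShapeError

#: Luminance weights for R, G, B (BT.709 / "Lightness" convention).
LUMINANCE_WEIGHTS = (0.2126, 0.7152, 0.0722)


@dataclass(frozen=True)
class ColorImage:
    """An 8-bit RGB raster, shape (height, width, 3), dtype uint8."""

    rgb: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.rgb)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ShapeError(f"expected (H, W, 3) array, got shape {arr.shape}")
        if arr.dtype != np.uint8:
            raise DomainError(f"expected uint8 channels, got {arr.dtype}")
        object.__setattr__(self, "rgb", arr)

    @property
    def height(self) -> int:
        return self.rgb.shape[0]

    @property
    def width(self) -> int:
        return self.rgb.shape[1]

    @property
    def r(self) -> np.ndarray:
        return self.rgb[:, :, 0]

    @property
    def g(self) -> np.ndarray:
        return self.rgb[:, :, 1]

    @property
    def b(self) -> np.ndarray:
        return self.rgb[:, :, 2]


@dataclass(frozen=True)
class GrayImage:
    """A real-valued grayscale raster in [0, 255] with provenance.

    ``provenance`` is one of ``direct``, ``channel_R``, ``channel_G``,
    ``channel_B`` and records which conversion produced the image.
    """

    values: np.ndarray
    provenance: str

    _PROVENANCES = ("direct", "channel_R", "channel_G", "channel_B")

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2:
            raise ShapeError(f"expected 2-D array, got shape {arr.shape}")
        if self.provenance not in self._PROVENANCES:
            raise DomainError(f"unknown provenance {self.provenance!r}")
        if arr.size and (arr.min() < 0 or arr.max() > 255):
            raise DomainError("gray values must lie in [0, 255]")
        object.__setattr__(self, "values", arr)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ChannelTriplet:
    """The three single-channel grayscale images of one color frame."""

    r: GrayImage
    g: GrayImage
    b: GrayImage

    def __post_init__(self) -> None:
        shapes = {self.r.values.shape, self.g.values.shape, self.b.values.shape}
        if len(shapes) != 1:
            raise ShapeError(f"channel images differ in shape: {shapes}")

    def __iter__(self):
        return iter((self.r, self.g, self.b))


def to_gray_direct(image: ColorImage) -> GrayImage:
    """Luminance conversion ``0.2126 R + 0.7152 G + 0.0722 B``.

    Evaluated as ``(2126 R + 7152 G + 722 B) / 10000`` so the sum is an
    exact integer in float64 and achromatic pixels (R=G=B=v) map to
    exactly v.  No quantization is applied.
    """
    r = image.rgb[:, :, 0].astype(np.int64)
    g = image.rgb[:, :, 1].astype(np.int64)
    b = image.rgb[:, :, 2].astype(np.int64)
    gray = (2126 * r + 7152 * g + 722 * b) / 10000.0
    return GrayImage(values=gray, provenance="direct")


def split_channels(image: ColorImage) -> ChannelTriplet:
    """Lossless decomposition into R, G, B single-channel images."""
    return ChannelTriplet(
        r=GrayImage(image.rgb[:, :, 0].astype(np.float64), "channel_R"),
        g=GrayImage(image.rgb[:, :, 1].astype(np.float64), "channel_G"),
        b=GrayImage(image.rgb[:, :, 2].astype(np.float64), "channel_B"),
    )


def recombine(triplet: ChannelTriplet) -> ColorImage:
    """Stack three channel images back into a color image.

    Inverse of :func:`split_channels`.  Channel values must be integral
    (they represent raw bytes); non-integral input raises ``DomainError``.
    """
    channels = []
    for img in triplet:
        vals = img.values
        if not np.all(vals == np.round(vals)):
            raise DomainError("channel values must be integral to recombine")
        channels.append(vals.astype(np.uint8))
    return ColorImage(np.stack(channels, axis=-1))


def round_half_up_u8(values: np.ndarray) -> np.ndarray:
    """Round half up and clip to the 8-bit range [0, 255]."""
    return np.clip(np.floor(np.asarray(values, dtype=np.float64) + 0.5), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# File I/O


def read_color_image(path: str | Path) -> ColorImage:
    """Read an 8-bit RGB PNG/TIFF.  Images with an alpha channel are rejected."""
    with Image.open(path) as im:
        if im.mode == "RGB":
            arr = np.asarray(im, dtype=np.uint8)
        elif im.mode in ("RGBA", "LA", "PA"):
            raise DomainError(f"{path}: alpha channel not supported; flatten the image first")
        else:
            raise DomainError(f"{path}: expected 8-bit RGB, got mode {im.mode!r}")
    return ColorImage(arr)


def write_color_image(image: ColorImage, path: str | Path) -> None:
    Image.fromarray(image.rgb, mode="RGB").save(path)


def write_gray_image(image: GrayImage, path: str | Path) -> None:
    """Export a grayscale image as 8-bit PNG (round half up)."""
    Image.fromarray(round_half_up_u8(image.values), mode="L").save(path)


_SUFFIX = {"direct": "_gray", "channel_R": "_R", "channel_G": "_G", "channel_B": "_B"}


def export_conversions(image: ColorImage, stem: str | Path) -> list[Path]:
    """Write the direct-gray and three channel images next to ``stem``.

    Returns the written paths, suffixed ``_gray``, ``_R``, ``_G``, ``_B``.
    """
    stem = Path(stem)
    images = [to_gray_direct(image), *split_channels(image)]
    paths = []
    for img in images:
        p = stem.with_name(stem.name + _SUFFIX[img.provenance] + ".png")
        write_gray_image(img, p)
        paths.append(p)
    return paths
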