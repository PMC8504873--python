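"""Synthetic color elastogram cohorts.

Shear-wave elastography displays tissue stiffness (kPa) as a color
overlay running dark blue (softest) through green to red (stiffest).
This module emulates that display well enough to exercise every
downstream stage — conversion, ROI propagation, feature extraction,
modelling, evaluation — without clinical images:

* a smooth background stiffness field (liver parenchyma) with
  spatially correlated noise,
* one elliptical lesion per image whose stiffness statistics depend on
  the benign/malignant label,
* a fixed dark-blue → green → red colormap with linear interpolation,
* an exact elliptical ROI mask per lesion.

Two cohort modes:

``stiffness_contrast``
    Benign and malignant lesions differ in mean stiffness (benign soft,
    malignant stiff), so the classes differ in *every* representation.

``metameric``
    The two classes' lesion colors sit on a common luminance isoline
    (same 0.2126R + 0.7152G + 0.0722B, different R/B balance), so they
    are separable in the RGB channels but collapse to the same gray
    value under direct luminance conversion.  This isolates the
    information loss of direct conversion as the only class signal.

Defaults put healthy-parenchyma background around 8 kPa, benign lesions
around 30 kPa and malignant around 70 kPa on a 0–150 kPa color scale,
the ballpark of clinical liver SWE displays.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .conversion import ColorImage, round_half_up_u8, write_color_image
from .errors import ConfigError, GeometryError
from .roi import ROIMask, write_mask

#: Colormap control colors: darkest blue, pure green, pure red.
DARK_BLUE = (0.0, 0.0, 139.0)
GREEN = (0.0, 255.0, 0.0)
RED = (255.0, 0.0, 0.0)

BENIGN = "benign"
MALIGNANT = "malignant"


@dataclass(frozen=True)
class StiffnessField:
    """A 2-D grid of tissue stiffness values in kPa."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[0] < 32 or arr.shape[1] < 32:
            raise ConfigError(f"stiffness field must be >= 32x32, got {arr.shape}")
        if not np.all(np.isfinite(arr)) or arr.min() < 0:
            raise ConfigError("stiffness values must be finite and >= 0")
        object.__setattr__(self, "values", arr)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class LesionSpec:
    """Geometry and stiffness statistics of one elliptical lesion."""

    center: tuple[float, float]  # (row, col), px
    semi_axes: tuple[float, float]  # (a, b), px
    orientation: float  # radians
    mean_stiffness: float  # kPa
    stiffness_sd: float  # kPa
    label: str  # benign | malignant

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if a < 5 or b < 5:
            raise GeometryError("lesion semi-axes must be >= 5 px")
        if self.label not in (BENIGN, MALIGNANT):
            raise ConfigError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class ClassParams:
    """Stiffness statistics of one lesion class.

    ``mean_stiffness`` / ``between_lesion_sd`` describe how the
    per-lesion mean is drawn across the cohort; ``pixel_sd`` is the
    within-lesion pixel noise.
    """

    mean_stiffness: float
    between_lesion_sd: float
    pixel_sd: float


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; the defaults define the study conditions."""

    height: int = 128
    width: int = 128
    background_mean: float = 8.0  # kPa, healthy liver
    background_sd: float = 1.5  # kPa
    noise_correlation_length: float = 3.0  # px, blur radius of the noise
    vmin: float = 0.0  # kPa, colormap low end (dark blue)
    vmax: float = 150.0  # kPa, colormap high end (red)
    benign: ClassParams = field(default_factory=lambda: ClassParams(30.0, 6.0, 5.0))
    malignant: ClassParams = field(default_factory=lambda: ClassParams(70.0, 10.0, 8.0))
    #: lesion semi-axis range, px
    axis_range: tuple[float, float] = (8.0, 18.0)
    mode: str = "stiffness_contrast"  # or "metameric"
    #: metameric mode: the two base colors are an exact integer metamer of
    #: the luminance formula — their difference (34, -20, 98) is twice the
    #: null vector (17, -10, 49) of (2126, 7152, 722), so both map to
    #: luminance 105.05 exactly while R differs by 34 levels.
    metameric_benign_rgb: tuple[int, int, int] = (84, 110, 118)
    metameric_malignant_rgb: tuple[int, int, int] = (50, 130, 20)
    #: per-pixel texture: integer G jitter (shifts luminance identically in
    #: both classes) plus a coin-flip step along the metamer null vector
    #: (changes color, provably never luminance).
    metameric_g_jitter_sd: float = 3.0
    metameric_null_vector: tuple[int, int, int] = (17, -10, 49)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vmin >= self.vmax:
            raise ConfigError("vmin must be < vmax")
        if self.mode not in ("stiffness_contrast", "metameric"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        for p in (self.benign, self.malignant):
            if not (self.vmin <= p.mean_stiffness <= self.vmax):
                raise ConfigError("class mean stiffness outside colormap range")

    def class_params(self, label: str) -> ClassParams:
        return self.benign if label == BENIGN else self.malignant


def ellipse_mask(
    height: int, width: int, center: tuple[float, float],
    semi_axes: tuple[float, float], orientation: float,
) -> np.ndarray:
    """Boolean mask of a rotated ellipse evaluated at integer pixel coords."""
    rr, cc = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
    dr = rr - center[0]
    dc = cc - center[1]
    ct, st = np.cos(orientation), np.sin(orientation)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _check_inside(config: SyntheticConfig, lesion: LesionSpec) -> None:
    r, c = lesion.center
    radius = max(lesion.semi_axes)
    if (r - radius < 0 or r + radius > config.height - 1
            or c - radius < 0 or c + radius > config.width - 1):
        raise GeometryError("lesion ellipse extends outside the image")


def _correlated_noise(shape: tuple[int, int], sd: float, corr: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Smoothed white noise rescaled so its marginal sd equals ``sd``."""
    white = rng.standard_normal(shape)
    if corr <= 0:
        return sd * white
    smooth = gaussian_filter(white, sigma=corr, mode="reflect")
    s = smooth.std()
    if s == 0:
        return np.zeros(shape)
    return sd * smooth / s


def generate_field(
    config: SyntheticConfig, lesion: LesionSpec, seed: int | np.random.Generator,
) -> StiffnessField:
    """Simulate one stiffness field: correlated background + i.i.d. lesion.

    Background pixels are ``background_mean`` plus spatially correlated
    noise of marginal sd ``background_sd``; lesion pixels are i.i.d.
    normal with the lesion's own mean/sd (so the ROI sample mean obeys
    the usual sd/sqrt(n) standard error).  Values are clipped at 0 kPa.
    Deterministic given the seed.
    """
    _check_inside(config, lesion)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = (config.height, config.width)
    bg = config.background_mean + _correlated_noise(
        shape, config.background_sd, config.noise_correlation_length, rng
    )
    inside = ellipse_mask(config.height, config.width, lesion.center,
                          lesion.semi_axes, lesion.orientation)
    values = bg
    values[inside] = lesion.mean_stiffness + lesion.stiffness_sd * rng.standard_normal(
        int(inside.sum())
    )
    return StiffnessField(np.clip(values, 0.0, None))


def colorize(field: StiffnessField, vmin: float, vmax: float) -> ColorImage:
    """Map stiffness to the dark-blue -> green -> red display colormap.

    Piecewise-linear interpolation through three control points:
    vmin -> (0, 0, 139), midpoint -> (0, 255, 0), vmax -> (255, 0, 0).
    Out-of-range stiffness is clipped; channels are rounded half up to
    8 bits.
    """
    if vmin >= vmax:
        raise ConfigError("vmin must be < vmax")
    x = np.clip(field.values, vmin, vmax)
    xp = [vmin, 0.5 * (vmin + vmax), vmax]
    channels = [
        np.interp(x, xp, [DARK_BLUE[k], GREEN[k], RED[k]]) for k in range(3)
    ]
    return ColorImage(np.stack([round_half_up_u8(ch) for ch in channels], axis=-1))


@dataclass(frozen=True)
class CohortItem:
    """One labelled synthetic lesion: image, exact ROI mask, metadata."""

    id: str
    image: ColorImage
    mask: ROIMask
    label: str
    lesion: LesionSpec


def _draw_lesion(config: SyntheticConfig, label: str,
                 rng: np.random.Generator) -> LesionSpec:
    lo, hi = config.axis_range
    a = rng.uniform(lo, hi)
    b = rng.uniform(lo, hi)
    margin = max(a, b) + 1.0
    center = (
        rng.uniform(margin, config.height - 1 - margin),
        rng.uniform(margin, config.width - 1 - margin),
    )
    orientation = rng.uniform(0.0, np.pi)
    p = config.class_params(label)
    mean = rng.normal(p.mean_stiffness, p.between_lesion_sd)
    mean = float(np.clip(mean, config.vmin + 2.0, config.vmax - 2.0))
    return LesionSpec(center, (a, b), orientation, mean, p.pixel_sd, label)


def _metameric_recolor(
    config: SyntheticConfig, image_rgb: np.ndarray, inside: np.ndarray,
    label: str, rng: np.random.Generator,
) -> np.ndarray:
    """Paint the lesion with a class color on an exact luminance isoline.

    The benign and malignant base colors are exact metamers of the
    luminance formula (their difference is an integer null vector of the
    weights 0.2126/0.7152/0.0722 scaled by 10000), and per-pixel texture
    is G jitter (class-independent luminance shift) plus a coin-flip
    step along the same null vector (no luminance shift at all).  The
    luminance image of the lesion therefore has an identical
    distribution — identical down to the attainable value lattice — in
    both classes, while R, G and B each separate the classes.
    """
    base = np.asarray(
        config.metameric_benign_rgb if label == BENIGN
        else config.metameric_malignant_rgb, dtype=np.float64,
    )
    null = np.asarray(config.metameric_null_vector, dtype=np.float64)
    n = int(inside.sum())
    jitter = np.round(config.metameric_g_jitter_sd * rng.standard_normal(n))
    step = rng.integers(0, 2, size=n).astype(np.float64)
    colors = base[None, :] + step[:, None] * null[None, :]
    colors[:, 1] += jitter
    out = image_rgb.copy()
    out[inside] = round_half_up_u8(colors)
    return out


def generate_cohort(
    config: SyntheticConfig, n_benign: int, n_malignant: int, seed: int,
) -> list[CohortItem]:
    """Generate a labelled cohort with exactly the requested class counts.

    Images alternate labels in a fixed interleaved order (benign first)
    so neither class is confounded with generation order; the whole
    cohort is a deterministic function of (config, seed).
    """
    if n_benign < 1 or n_malignant < 1:
        raise ConfigError("need at least one lesion per class")
    labels = [BENIGN] * n_benign + [MALIGNANT] * n_malignant
    # deterministic interleave: benign at evenly spaced slots
    order = np.argsort(np.concatenate([
        np.linspace(0, 1, n_benign, endpoint=False),
        (np.linspace(0, 1, n_malignant, endpoint=False) + 0.5 / max(n_malignant, 1)),
    ]), kind="stable")
    labels = [labels[i] for i in order]

    root = np.random.SeedSequence(seed)
    children = root.spawn(len(labels))
    items: list[CohortItem] = []
    for i, (label, child) in enumerate(zip(labels, children)):
        rng = np.random.default_rng(child)
        lesion = _draw_lesion(config, label, rng)
        field_ = generate_field(config, lesion, rng)
        image = colorize(field_, config.vmin, config.vmax)
        inside = ellipse_mask(config.height, config.width, lesion.center,
                              lesion.semi_axes, lesion.orientation)
        if config.mode == "metameric":
            image = ColorImage(_metameric_recolor(config, image.rgb, inside, label, rng))
        items.append(CohortItem(
            id=f"lesion_{i:04d}", image=image, mask=ROIMask(inside),
            label=label, lesion=lesion,
        ))
    return items


def write_cohort(items: list[CohortItem], out_dir: str | Path) -> Path:
    """Write images/masks as PNG plus a manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "image_path", "mask_path", "label"])
        for item in items:
            img_p = out_dir / "images" / f"{item.id}.png"
            mask_p = out_dir / "masks" / f"{item.id}.png"
            write_color_image(item.image, img_p)
            write_mask(item.mask, mask_p)
            writer.writerow([item.id, str(img_p), str(mask_p), item.label])
    return manifest
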