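"""Radiomics feature bank for (grayscale image, ROI mask) pairs.

The bank covers the classic intensity and texture families used
throughout the ultrasomics literature:

* first-order statistics of the masked intensities (19 features),
* gray-level co-occurrence matrix (GLCM / Haralick) features (10),
* gray-level run-length matrix (GLRLM / Galloway) features (5),
* mask-only shape descriptors (4), emitted once per lesion.

Each family can be computed on the original image or on filtered
versions (Laplacian-of-Gaussian at several scales, level-1 stationary
wavelet subbands).  Texture matrices are built from equal-width
discretization of the ROI intensities; the bank configuration fixes the
bin counts, GLCM pixel distances and whether directional features are
averaged or emitted per direction.  The per-image feature count is a
pure function of the configuration (``FeatureBankConfig.size``).

For the two preprocessing routes of a color elastogram:

``extract_direct``  applies the bank once, to the luminance image
(feature names prefixed ``gray_``); ``extract_rgb3`` applies the same
bank to each of the R, G, B channel images (prefixes ``R_``, ``G_``,
``B_``), tripling the intensity-feature count.

The ``paper_size`` preset spans a 14-filter x (bins x distance) grid
sized to 5,936 intensity features per image (17,808 over three
channels), a per-image budget typical of large ultrasomics banks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pywt
from scipy.ndimage import gaussian_laplace

from .conversion import ColorImage, GrayImage, split_channels, to_gray_direct
from .errors import ConfigError, DomainError, FeatureExtractionError, SchemaError
from .roi import ROIMask

# ---------------------------------------------------------------------------
# Configuration

#: GLCM offsets (row, col) for unit distance; scaled by the distance setting.
GLCM_DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))
GLCM_ANGLES = ("0", "45", "90", "135")
GLRLM_DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))

N_FIRST_ORDER = 19
N_GLCM = 10
N_GLRLM = 5
N_SHAPE = 4


@dataclass(frozen=True)
class FeatureBankConfig:
    """Which features are computed, at which discretization, on which filters."""

    families: tuple[str, ...] = ("first_order", "glcm", "glrlm", "shape")
    filters: tuple[str, ...] = ("original",)
    first_order_bins: int = 32
    glcm_bins: tuple[int, ...] = (32,)
    glcm_distances: tuple[int, ...] = (1,)
    glcm_average_directions: bool = True
    glrlm_bins: tuple[int, ...] = (32,)
    glrlm_average_directions: bool = True

    def __post_init__(self) -> None:
        known = {"first_order", "glcm", "glrlm", "shape"}
        if not self.families or not set(self.families) <= known:
            raise ConfigError(f"families must be a non-empty subset of {known}")
        for b in (self.first_order_bins, *self.glcm_bins, *self.glrlm_bins):
            if b < 8:
                raise ConfigError("bin counts must be >= 8")

    # -- counting -----------------------------------------------------------
    def intensity_size(self) -> int:
        """Per-image count of intensity features (shape excluded)."""
        per_filter = 0
        if "first_order" in self.families:
            per_filter += N_FIRST_ORDER
        if "glcm" in self.families:
            n_dir = 1 if self.glcm_average_directions else len(GLCM_DIRECTIONS)
            per_filter += len(self.glcm_bins) * len(self.glcm_distances) * n_dir * N_GLCM
        if "glrlm" in self.families:
            n_dir = 1 if self.glrlm_average_directions else len(GLRLM_DIRECTIONS)
            per_filter += len(self.glrlm_bins) * n_dir * N_GLRLM
        return len(self.filters) * per_filter

    def size(self, channels: int = 1) -> int:
        """Total vector length for ``channels`` channel images."""
        return channels * self.intensity_size() + (
            N_SHAPE if "shape" in self.families else 0
        )

    # -- presets -------------------------------------------------------------
    @classmethod
    def default(cls) -> "FeatureBankConfig":
        return cls()

    @classmethod
    def minimal(cls) -> "FeatureBankConfig":
        """First-order only; the fastest bank that still ranks lesions."""
        return cls(families=("first_order",))

    @classmethod
    def paper_size(cls) -> "FeatureBankConfig":
        """Large-bank preset: 5,936 intensity features per image.

        14 filter images (original, LoG sigma 0.5..4.5, four level-1
        stationary-wavelet subbands) x [19 first-order + per-direction
        GLCM over a {8,16,32}-bins x {1,2,3}-distance grid (360) +
        direction-averaged GLRLM over nine bin counts (45)] = 14 x 424.
        Shape features are omitted so the three-channel count is exactly
        three times the single-image count.
        """
        log_filters = tuple(f"log-sigma-{s:.1f}" for s in
                            (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5))
        wavelets = ("wavelet-LL", "wavelet-LH", "wavelet-HL", "wavelet-HH")
        return cls(
            families=("first_order", "glcm", "glrlm"),
            filters=("original",) + log_filters + wavelets,
            first_order_bins=32,
            glcm_bins=(8, 16, 32),
            glcm_distances=(1, 2, 3),
            glcm_average_directions=False,
            glrlm_bins=(8, 12, 16, 24, 32, 48, 64, 96, 128),
            glrlm_average_directions=True,
        )


# ---------------------------------------------------------------------------
# Image filters


def apply_filter(values: np.ndarray, name: str) -> np.ndarray:
    """Return the filtered image named by the bank configuration."""
    if name == "original":
        return values
    if name.startswith("log-sigma-"):
        sigma = float(name.removeprefix("log-sigma-"))
        return gaussian_laplace(values, sigma=sigma, mode="reflect")
    if name.startswith("wavelet-"):
        band = name.removeprefix("wavelet-")
        return _swt_band(values, band)
    raise ConfigError(f"unknown filter {name!r}")


def _swt_band(values: np.ndarray, band: str) -> np.ndarray:
    """Level-1 stationary (undecimated) Haar wavelet subband, same shape."""
    h, w = values.shape
    padded = np.pad(values, ((0, h % 2), (0, w % 2)), mode="reflect")
    (ll, (lh, hl, hh)), = pywt.swt2(padded, "db1", level=1, norm=True)
    bands = {"LL": ll, "LH": lh, "HL": hl, "HH": hh}
    if band not in bands:
        raise ConfigError(f"unknown wavelet band {band!r}")
    return bands[band][:h, :w]


# ---------------------------------------------------------------------------
# Discretization


def discretize(values: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width bin labels 1..bins over the ROI's [min, max] range.

    A constant ROI maps to label 1 everywhere.
    """
    vals = np.asarray(values, dtype=np.float64)
    if vals.size == 0:
        raise DomainError("cannot discretize an empty value list")
    if bins < 2:
        raise DomainError("need at least 2 bins")
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return np.ones(vals.shape, dtype=np.int64)
    labels = np.floor((vals - lo) / (hi - lo) * bins).astype(np.int64) + 1
    return np.minimum(labels, bins)


# ---------------------------------------------------------------------------
# First-order statistics


def first_order(values: np.ndarray, bins: int = 32) -> dict[str, float]:
    """The 19 first-order features of a masked intensity sample.

    Moments are population moments (ddof=0); skewness is g1 = m3/m2^1.5
    and kurtosis the (non-excess) m4/m2^2, both defined as 0 for a
    constant sample.  Entropy is Shannon entropy in bits of the
    equal-width discretized histogram; energy is the sum of squared
    intensities and RMS the root of their mean.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise DomainError("empty value list")
    mean = v.mean()
    dev = v - mean
    m2 = np.mean(dev ** 2)
    if m2 > 0:
        skew = np.mean(dev ** 3) / m2 ** 1.5
        kurt = np.mean(dev ** 4) / m2 ** 2
    else:
        skew = 0.0
        kurt = 0.0
    labels = discretize(v, bins)
    counts = np.bincount(labels)[1:]
    p = counts[counts > 0] / v.size
    entropy = float(-(p * np.log2(p)).sum())
    p10, p25, med, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    return {
        "mean": float(mean),
        "median": float(med),
        "min": float(v.min()),
        "max": float(v.max()),
        "range": float(v.max() - v.min()),
        "variance": float(m2),
        "sd": float(np.sqrt(m2)),
        "skewness": float(skew),
        "kurtosis": float(kurt),
        "energy": float(np.sum(v ** 2)),
        "entropy": entropy,
        "p10": float(p10),
        "p25": float(p25),
        "p75": float(p75),
        "p90": float(p90),
        "iqr": float(p75 - p25),
        "mad": float(np.mean(np.abs(dev))),
        "robust_mad": float(np.median(np.abs(v - med))),
        "rms": float(np.sqrt(np.mean(v ** 2))),
    }


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(labels: np.ndarray, mask: np.ndarray, offset: tuple[int, int],
                bins: int) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one offset.

    Counts ordered pairs (p, p+offset) with both pixels in the mask,
    accumulates them symmetrically and normalizes to sum 1.  Returns the
    zero matrix if the offset yields no pairs.
    """
    dr, dc = offset
    h, w = labels.shape
    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    a = labels[r0s:r0e, c0s:c0e]
    b = labels[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    valid = mask[r0s:r0e, c0s:c0e] & mask[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    mat = np.zeros((bins, bins), dtype=np.float64)
    if valid.any():
        i = a[valid] - 1
        j = b[valid] - 1
        np.add.at(mat, (i, j), 1.0)
        np.add.at(mat, (j, i), 1.0)
        mat /= mat.sum()
    return mat


def glcm_features_from_matrix(p: np.ndarray) -> dict[str, float]:
    """The 10 Haralick-style features of one normalized GLCM."""
    bins = p.shape[0]
    i = np.arange(1, bins + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = ii - jj
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    var_i = float(((ii - mu_i) ** 2 * p).sum())
    var_j = float(((jj - mu_j) ** 2 * p).sum())
    asm = float((p ** 2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum()) if nz.size else 0.0
    if var_i > 0 and var_j > 0:
        corr = float((((ii - mu_i) * (jj - mu_j) * p).sum())
                     / np.sqrt(var_i * var_j))
    else:
        corr = 1.0  # constant ROI: perfectly correlated by convention
    s = ii + jj - mu_i - mu_j
    return {
        "contrast": float((diff ** 2 * p).sum()),
        "dissimilarity": float((np.abs(diff) * p).sum()),
        "homogeneity": float((p / (1.0 + diff ** 2)).sum()),
        "asm": asm,
        "energy": float(np.sqrt(asm)),
        "entropy": entropy,
        "correlation": corr,
        "cluster_shade": float((s ** 3 * p).sum()),
        "cluster_prominence": float((s ** 4 * p).sum()),
        "max_probability": float(p.max()),
    }


def glcm_features(labels: np.ndarray, mask: np.ndarray, bins: int,
                  distance: int = 1, average: bool = True) -> dict[str, float]:
    """GLCM features over the four standard directions at one distance.

    ``average=True`` averages each feature over directions (Haralick
    convention); otherwise features are emitted per direction with an
    ``ang{0,45,90,135}_`` prefix.  Raises on ROIs of fewer than 2 pixels.
    """
    if mask.sum() < 2:
        raise FeatureExtractionError("GLCM undefined on ROIs of < 2 pixels")
    per_dir = []
    for (dr, dc) in GLCM_DIRECTIONS:
        mat = glcm_matrix(labels, mask, (dr * distance, dc * distance), bins)
        per_dir.append(glcm_features_from_matrix(mat))
    if average:
        return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}
    out: dict[str, float] = {}
    for ang, feats in zip(GLCM_ANGLES, per_dir):
        for k, val in feats.items():
            out[f"ang{ang}_{k}"] = val
    return out


# ---------------------------------------------------------------------------
# GLRLM


def _runs_along(labels: np.ndarray, mask: np.ndarray,
                direction: tuple[int, int]) -> list[tuple[int, int]]:
    """All maximal runs (gray level, length) along one direction.

    Runs are maximal sequences of equal labels over consecutive in-mask
    pixels; a masked-out pixel breaks the run.
    """
    h, w = labels.shape
    lines: list[tuple[np.ndarray, np.ndarray]] = []
    if direction == (0, 1):
        for r in range(h):
            lines.append((labels[r], mask[r]))
    elif direction == (1, 0):
        for c in range(w):
            lines.append((labels[:, c], mask[:, c]))
    elif direction == (1, 1):
        for off in range(-h + 1, w):
            lines.append((np.diagonal(labels, off), np.diagonal(mask, off)))
    elif direction == (1, -1):
        fl, fm = labels[:, ::-1], mask[:, ::-1]
        for off in range(-h + 1, w):
            lines.append((np.diagonal(fl, off), np.diagonal(fm, off)))
    else:
        raise ConfigError(f"unsupported run direction {direction}")
    runs = []
    for lab, msk in lines:
        current = None
        length = 0
        for v, inside in zip(lab, msk):
            if inside and current == v:
                length += 1
            else:
                if current is not None and length:
                    runs.append((int(current), length))
                current = int(v) if inside else None
                length = 1 if inside else 0
        if current is not None and length:
            runs.append((int(current), length))
    return runs


def glrlm_matrix(labels: np.ndarray, mask: np.ndarray,
                 direction: tuple[int, int], bins: int) -> np.ndarray:
    """Run-length matrix r[g-1, l-1] = number of runs of level g, length l."""
    n = int(mask.sum())
    mat = np.zeros((bins, max(n, 1)), dtype=np.float64)
    for g, length in _runs_along(labels, mask, direction):
        mat[g - 1, length - 1] += 1
    return mat


def glrlm_features_from_matrix(r: np.ndarray, n_pixels: int) -> dict[str, float]:
    """The 5 Galloway run-length features of one run matrix."""
    total = r.sum()
    if total == 0:
        raise FeatureExtractionError("no runs in ROI")
    lengths = np.arange(1, r.shape[1] + 1, dtype=np.float64)
    run_per_length = r.sum(axis=0)
    run_per_level = r.sum(axis=1)
    return {
        "short_run_emphasis": float((run_per_length / lengths ** 2).sum() / total),
        "long_run_emphasis": float((run_per_length * lengths ** 2).sum() / total),
        "gray_level_nonuniformity": float((run_per_level ** 2).sum() / total),
        "run_length_nonuniformity": float((run_per_length ** 2).sum() / total),
        "run_percentage": float(total / n_pixels),
    }


def glrlm_features(labels: np.ndarray, mask: np.ndarray, bins: int,
                   average: bool = True) -> dict[str, float]:
    """GLRLM features over the four standard directions."""
    if mask.sum() < 2:
        raise FeatureExtractionError("GLRLM undefined on ROIs of < 2 pixels")
    n_pixels = int(mask.sum())
    per_dir = [
        glrlm_features_from_matrix(glrlm_matrix(labels, mask, d, bins), n_pixels)
        for d in GLRLM_DIRECTIONS
    ]
    if average:
        return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}
    out: dict[str, float] = {}
    for (dr, dc), feats in zip(GLRLM_DIRECTIONS, per_dir):
        for k, val in feats.items():
            out[f"dir{dr}{'m' if dc < 0 else ''}{abs(dc)}_{k}"] = val
    return out


# ---------------------------------------------------------------------------
# Shape


def shape_features(mask: ROIMask) -> dict[str, float]:
    """Mask-only descriptors: area, perimeter, circularity, axis ratio.

    Perimeter counts exposed pixel edges (a 10x10 square has 40);
    circularity is 4*pi*A/P^2; the axis ratio is sqrt(l1/l2) of the
    pixel-coordinate covariance eigenvalues, with the 1/12 single-pixel
    spread added so degenerate (line-like) masks stay finite.
    """
    m = mask.mask
    area = float(m.sum())
    pad = np.pad(m, 1)
    perimeter = 0.0
    for axis in (0, 1):
        perimeter += float(np.sum(np.diff(pad, axis=axis) != 0))
    rr, cc = np.nonzero(m)
    coords = np.column_stack([rr, cc]).astype(np.float64)
    cov = np.cov(coords.T, ddof=0) if len(coords) > 1 else np.zeros((2, 2))
    eig = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1] + 1.0 / 12.0
    return {
        "area": area,
        "perimeter": perimeter,
        "circularity": float(4.0 * np.pi * area / perimeter ** 2),
        "axis_ratio": float(np.sqrt(eig[0] / eig[1])),
    }


# ---------------------------------------------------------------------------
# Bank application


def _intensity_bank(image: GrayImage, mask: ROIMask,
                    bank: FeatureBankConfig) -> dict[str, float]:
    """All intensity features of one grayscale image under one bank."""
    if image.values.shape != mask.shape:
        raise SchemaError("image and mask dimensions differ")
    out: dict[str, float] = {}
    for filt in bank.filters:
        img = apply_filter(image.values, filt)
        roi_values = img[mask.mask]
        if "first_order" in bank.families:
            for k, v in first_order(roi_values, bank.first_order_bins).items():
                out[f"{filt}_firstorder_{k}"] = v
        if "glcm" in bank.families:
            for bins in bank.glcm_bins:
                labels = np.zeros(mask.shape, dtype=np.int64)
                labels[mask.mask] = discretize(roi_values, bins)
                for dist in bank.glcm_distances:
                    feats = glcm_features(labels, mask.mask, bins, dist,
                                          bank.glcm_average_directions)
                    for k, v in feats.items():
                        out[f"{filt}_glcm_b{bins}_d{dist}_{k}"] = v
        if "glrlm" in bank.families:
            for bins in bank.glrlm_bins:
                labels = np.zeros(mask.shape, dtype=np.int64)
                labels[mask.mask] = discretize(roi_values, bins)
                feats = glrlm_features(labels, mask.mask, bins,
                                       bank.glrlm_average_directions)
                for k, v in feats.items():
                    out[f"{filt}_glrlm_b{bins}_{k}"] = v
    return out


def extract_direct(image: ColorImage, mask: ROIMask,
                   bank: FeatureBankConfig) -> dict[str, float]:
    """Feature vector of the luminance-converted image (prefix ``gray_``)."""
    gray = to_gray_direct(image)
    vec = {f"gray_{k}": v for k, v in _intensity_bank(gray, mask, bank).items()}
    if "shape" in bank.families:
        for k, v in shape_features(mask).items():
            vec[f"gray_original_shape_{k}"] = v
    return vec


def extract_rgb3(image: ColorImage, mask: ROIMask,
                 bank: FeatureBankConfig) -> dict[str, float]:
    """Feature vector of the three channel images (prefixes ``R_/G_/B_``).

    The intensity bank is applied to each channel, tripling the count;
    mask-only shape features (channel-independent) are emitted once
    under the ``gray_`` prefix, exactly as in :func:`extract_direct`.
    """
    triplet = split_channels(image)
    vec: dict[str, float] = {}
    for prefix, img in zip(("R", "G", "B"), triplet):
        for k, v in _intensity_bank(img, mask, bank).items():
            vec[f"{prefix}_{k}"] = v
    if "shape" in bank.families:
        for k, v in shape_features(mask).items():
            vec[f"gray_original_shape_{k}"] = v
    return vec


# ---------------------------------------------------------------------------
# Feature tables


@dataclass
class FeatureTable:
    """Lesions x features with ids and binary labels (0 benign, 1 malignant)."""

    ids: list[str]
    labels: np.ndarray
    feature_names: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.shape != (len(self.ids), len(self.feature_names)):
            raise SchemaError("matrix shape does not match ids x feature names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise SchemaError("duplicate feature names")
        if not np.all(np.isfinite(self.X)):
            raise SchemaError("feature table contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.ids)

    def select(self, names: list[str]) -> "FeatureTable":
        """Restrict to named columns (in the given order)."""
        index = {name: k for k, name in enumerate(self.feature_names)}
        missing = [name for name in names if name not in index]
        if missing:
            raise SchemaError(f"missing feature columns: {missing[:5]}")
        cols = [index[name] for name in names]
        return FeatureTable(self.ids, self.labels, list(names), self.X[:, cols])

    def subset(self, row_idx: np.ndarray) -> "FeatureTable":
        row_idx = np.asarray(row_idx)
        return FeatureTable([self.ids[i] for i in row_idx], self.labels[row_idx],
                            self.feature_names, self.X[row_idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "id", self.ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        names = [c for c in df.columns if c not in ("id", "label")]
        return cls(df["id"].astype(str).tolist(), df["label"].to_numpy(),
                   names, df[names].to_numpy(dtype=np.float64))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        return cls.from_frame(pd.read_csv(path))


LABEL_CODES = {"benign": 0, "malignant": 1}


def build_feature_table(items, bank: FeatureBankConfig,
                        method: str = "rgb3") -> FeatureTable:
    """Extract one feature vector per cohort item.

    ``method`` is ``"direct"`` (luminance arm) or ``"rgb3"`` (channel
    arm).  All vectors must share the same names, which holds whenever
    the same bank is applied to same-size images.
    """
    extract = {"direct": extract_direct, "rgb3": extract_rgb3}[method]
    ids, labels, rows = [], [], []
    names: list[str] | None = None
    for item in items:
        vec = extract(item.image, item.mask, bank)
        if names is None:
            names = list(vec)
        elif list(vec) != names:
            raise SchemaError(f"inconsistent feature names for {item.id}")
        ids.append(item.id)
        labels.append(LABEL_CODES[item.label])
        rows.append([vec[k] for k in names])
    if names is None:
        raise DomainError("empty cohort")
    return FeatureTable(ids, np.asarray(labels), names, np.asarray(rows))
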