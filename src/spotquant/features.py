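"""The 51-entry chemometric descriptor of a spot ROI.

Each of the fifteen chromatic channels (R, G, B, H, S, V, L*, a*, b*,
X, Y, Z, Yn, I, Q) contributes its mean, skewness and kurtosis over the ROI
pixel sample — 45 moment features.  Six further values come from the
gray-level co-occurrence matrix (GLCM) of the standard-gray image restricted
to the ROI: contrast, correlation, energy, homogeneity, entropy, plus the
mean unquantized gray intensity.  45 + 6 = 51.

Conventions: kurtosis is non-excess (Gaussian = 3); a numerically constant
sample reports skewness 0 and kurtosis 3; GLCM entropy is in bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorspaces import CHROMATIC_CHANNELS, channel_stack, rgb_to_gray
from .preprocessing import RoiMask, SpotImage, extract_roi_pixels

_VAR_EPS = 1e-12

#: Names of the 45 moment features, channel-major.
MOMENT_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{ch}_{stat}" for ch in CHROMATIC_CHANNELS for stat in ("mean", "skew", "kurt")
)

#: Names of the 6 texture/intensity features computed on gray_standard.
TEXTURE_FEATURE_NAMES: tuple[str, ...] = (
    "glcm_contrast",
    "glcm_correlation",
    "glcm_energy",
    "glcm_homogeneity",
    "glcm_entropy",
    "gray_intensity",
)

#: The full, ordered 51-name feature schema.
FEATURE_NAMES: tuple[str, ...] = MOMENT_FEATURE_NAMES + TEXTURE_FEATURE_NAMES

#: Version tag embedded in persisted feature tables and models.
FEATURE_SCHEMA_VERSION = "spotquant-features-1"


class DegenerateGlcm(Exception):
    """Raised when an ROI admits no valid co-occurring pixel pairs."""


@dataclass
class FeatureVector:
    """Ordered 51-entry descriptor of one ROI."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError(
                f"expected {len(self.names)} feature values, got shape {self.values.shape}"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


@dataclass
class GlcmMatrix:
    """Normalized gray-level co-occurrence matrix.

    ``p`` is Ng x Ng, sums to 1; with ``symmetric`` accumulation p = p.T.
    """

    p: np.ndarray
    Ng: int
    offset: tuple[int, int]
    symmetric: bool

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (self.Ng, self.Ng):
            raise ValueError(f"GLCM must be {self.Ng}x{self.Ng}, got {self.p.shape}")
        if self.p.min() < 0:
            raise ValueError("GLCM entries must be nonnegative")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("GLCM must be normalized to sum 1")


def channel_stats(values) -> tuple[float, float, float]:
    """Mean, skewness and non-excess kurtosis of a pixel sample.

    Skewness is m3 / m2^1.5 and kurtosis m4 / m2^2 with population central
    moments m_k.  If m2 < 1e-12 the sample is treated as constant:
    skewness 0, kurtosis 3 (the Gaussian reference value).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty sample")
    mean = float(v.mean())
    d = v - mean
    m2 = float(np.mean(d * d))
    if m2 < _VAR_EPS:
        return mean, 0.0, 3.0
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    return mean, m3 / m2**1.5, m4 / (m2 * m2)


def quantize_gray(gray, Ng: int) -> np.ndarray:
    """Quantize gray values in [0, 255] into Ng uniform levels 0..Ng-1."""
    g = np.asarray(gray, dtype=float)
    levels = np.floor(g * Ng / 256.0).astype(int)
    return np.clip(levels, 0, Ng - 1)


def compute_glcm(
    gray,
    mask=None,
    Ng: int = 8,
    offset: tuple[int, int] = (0, 1),
    symmetric: bool = True,
) -> GlcmMatrix:
    """Co-occurrence matrix of a masked gray image.

    Gray values in [0, 255] are binned uniformly into ``Ng`` levels; a pair
    is counted only when both its pixels fall inside the mask.  With
    ``symmetric=True`` both orders of every pair are accumulated.  The
    matrix is normalized to sum 1.

    Raises
    ------
    DegenerateGlcm
        If the mask admits no pixel pair at the given offset.
    """
    g = np.asarray(gray, dtype=float)
    if g.ndim != 2:
        raise ValueError(f"gray image must be 2-D, got shape {g.shape}")
    if Ng < 2:
        raise ValueError(f"Ng must be >= 2, got {Ng}")
    if mask is None:
        mask = np.ones(g.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != g.shape:
        raise ValueError("mask shape must match the gray image")

    levels = quantize_gray(g, Ng)
    dr, dc = int(offset[0]), int(offset[1])
    h, w = g.shape
    if abs(dr) >= h or abs(dc) >= w:
        raise DegenerateGlcm(f"offset {offset} exceeds image extent {(h, w)}")

    def _slices(d: int, n: int) -> tuple[slice, slice]:
        if d >= 0:
            return slice(0, n - d), slice(d, n)
        return slice(-d, n), slice(0, n + d)

    rs, rd = _slices(dr, h)
    cs, cd = _slices(dc, w)
    valid = mask[rs, cs] & mask[rd, cd]
    i = levels[rs, cs][valid]
    j = levels[rd, cd][valid]
    counts = np.bincount(i * Ng + j, minlength=Ng * Ng).astype(float).reshape(Ng, Ng)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise DegenerateGlcm("no valid pixel pairs inside the mask at this offset")
    return GlcmMatrix(p=counts / total, Ng=Ng, offset=(dr, dc), symmetric=symmetric)


def glcm_metrics(glcm: GlcmMatrix, gray_roi) -> tuple[float, float, float, float, float, float]:
    """Six texture/intensity metrics from a GLCM and the unquantized ROI.

    Returns ``(contrast, correlation, energy, homogeneity, entropy,
    intensity)``.  Correlation is defined as 1 when the marginal spread
    vanishes (a constant image is perfectly correlated with itself);
    entropy uses log base 2 with 0·log 0 := 0; intensity is the mean of the
    unquantized gray ROI values.
    """
    p = glcm.p
    idx = np.arange(glcm.Ng, dtype=float)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    contrast = float(((ii - jj) ** 2 * p).sum())
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((idx * pi).sum())
    mu_j = float((idx * pj).sum())
    sd_i = float(np.sqrt(((idx - mu_i) ** 2 * pi).sum()))
    sd_j = float(np.sqrt(((idx - mu_j) ** 2 * pj).sum()))
    if sd_i * sd_j < _VAR_EPS:
        correlation = 1.0
    else:
        correlation = float(((ii - mu_i) * (jj - mu_j) * p).sum() / (sd_i * sd_j))
    energy = float((p * p).sum())
    homogeneity = float((p / (1.0 + np.abs(ii - jj))).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    intensity = float(np.mean(np.asarray(gray_roi, dtype=float)))
    return contrast, correlation, energy, homogeneity, entropy, intensity


def extract_features(
    image: SpotImage,
    mask: RoiMask,
    Ng: int = 8,
    offset: tuple[int, int] = (0, 1),
    symmetric: bool = True,
) -> FeatureVector:
    """Build the full 51-entry descriptor of one masked spot.

    The 45 moment features are order-invariant functions of the ROI pixel
    multiset; the 6 texture features are computed on the standard-gray
    image restricted to the mask.
    """
    pixels = extract_roi_pixels(image, mask)
    stack = channel_stack(pixels)
    values = []
    for ch in CHROMATIC_CHANNELS:
        values.extend(channel_stats(stack[ch]))
    gray_img, _ = rgb_to_gray(image.pixels)
    glcm = compute_glcm(gray_img, mask.mask, Ng=Ng, offset=offset, symmetric=symmetric)
    values.extend(glcm_metrics(glcm, gray_img[mask.mask]))
    return FeatureVector(np.asarray(values, dtype=float))
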