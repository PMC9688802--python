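"""Color-space conversions used to build the chemometric feature set.

Every ROI pixel is expanded into fifteen chromatic channels —
RGB, HSV, CIE XYZ, CIELAB (L*, a*, b*) and NTSC YIQ (luma Yn, in-phase I,
quadrature Q) — plus two 0–255 gray variants:

``gray_standard``
    Standard luminance gray, ``255 * (0.299 R + 0.587 G + 0.114 B)``;
    0 is black and 255 is white.
``response``
    The assay readout channel, ``255 - gray_standard``, so that a darker
    (more developed) spot gives a larger response.  Chromogenic color
    development darkens the spot, which makes the response increase with
    analyte concentration.

The YIQ matrix is pinned to the FCC NTSC coefficients rounded to four
decimals.  Both chroma rows sum to zero, so the attainable extrema over the
RGB unit cube are exactly ``|I| <= 0.5959`` (at pure red/cyan) and
``|Q| <= 0.5229`` (at magenta/green).

HSV, XYZ and CIELAB follow the sRGB / D65 conventions of ``skimage.color``;
hue is reported in degrees in [0, 360) with achromatic pixels assigned H = 0.
"""

from __future__ import annotations

import numpy as np
from skimage import color as _skcolor

#: Pinned RGB -> YIQ transform (rows: luma Yn, in-phase I, quadrature Q).
YIQ_MATRIX = np.array(
    [
        [0.299, 0.587, 0.114],
        [0.5959, -0.2746, -0.3213],
        [0.2115, -0.5229, 0.3114],
    ]
)

#: Luminance weights shared by gray_standard and the YIQ luma row.
LUMA_WEIGHTS = YIQ_MATRIX[0]

#: The fifteen chromatic channels feeding the 45 moment features, in the
#: fixed order that defines the public feature schema.
CHROMATIC_CHANNELS: tuple[str, ...] = (
    "R", "G", "B",
    "H", "S", "V",
    "Lstar", "astar", "bstar",
    "X", "Y", "Z",
    "Yn", "I", "Q",
)

#: The two gray variants (used for texture features, not moment features).
GRAY_CHANNELS: tuple[str, ...] = ("gray_standard", "response")


def _validate_rgb(rgb) -> np.ndarray:
    arr = np.asarray(rgb, dtype=float)
    if arr.ndim < 1 or arr.shape[-1] != 3:
        raise ValueError(f"expected RGB with a trailing axis of 3, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("RGB components must be finite")
    if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
        raise ValueError(
            f"RGB components must lie in [0, 1]; got range "
            f"[{arr.min():.4g}, {arr.max():.4g}]"
        )
    return np.clip(arr, 0.0, 1.0)


def rgb_to_yiq(rgb) -> np.ndarray:
    """Convert RGB in [0,1] to NTSC YIQ via the pinned 4-decimal matrix.

    Accepts a single triple or any ``(..., 3)`` array; returns the same
    shape with (Yn, I, Q) on the last axis.  Yn lies in [0, 1],
    I in [-0.5959, 0.5959] and Q in [-0.5229, 0.5229].
    """
    arr = _validate_rgb(rgb)
    return arr @ YIQ_MATRIX.T


def rgb_to_hsv(rgb) -> np.ndarray:
    """Convert RGB in [0,1] to HSV with hue in degrees [0, 360).

    Uses the standard hexcone model; achromatic pixels get H = 0.
    """
    arr = _validate_rgb(rgb)
    flat = arr.reshape(-1, 3)
    hsv = _skcolor.rgb2hsv(flat)
    hsv[:, 0] = (hsv[:, 0] * 360.0) % 360.0
    return hsv.reshape(arr.shape)


def rgb_to_xyz_lab(rgb) -> np.ndarray:
    """Convert sRGB in [0,1] to (X, Y, Z, L*, a*, b*) under D65.

    Returns an array with the last axis of length 6.  X, Y, Z use the
    sRGB gamma-expanded linear transform (white at X=0.9505, Y=1, Z=1.0888);
    L* lies in [0, 100].
    """
    arr = _validate_rgb(rgb)
    flat = arr.reshape(-1, 3)
    xyz = _skcolor.rgb2xyz(flat)
    lab = _skcolor.rgb2lab(flat)
    out = np.concatenate([xyz, lab], axis=-1)
    return out.reshape(arr.shape[:-1] + (6,))


def rgb_to_gray(rgb) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(gray_standard, response)`` on the 0–255 scale.

    ``gray_standard`` is luminance gray (0 black, 255 white);
    ``response = 255 - gray_standard`` is the inverted readout channel in
    which a darker developed spot scores higher.
    """
    arr = _validate_rgb(rgb)
    gray = 255.0 * (arr @ LUMA_WEIGHTS)
    return gray, 255.0 - gray


def channel_stack(pixels) -> dict[str, np.ndarray]:
    """Expand an (N, 3) RGB pixel sample into all named channels.

    Returns a dict keyed by :data:`CHROMATIC_CHANNELS` followed by
    :data:`GRAY_CHANNELS`, each value an (N,) array.  The transforms are
    pixelwise and deterministic, so a constant input yields constant
    channels.
    """
    arr = _validate_rgb(pixels)
    if arr.ndim != 2:
        arr = arr.reshape(-1, 3)
    hsv = rgb_to_hsv(arr)
    xyzlab = rgb_to_xyz_lab(arr)
    yiq = rgb_to_yiq(arr)
    gray, response = rgb_to_gray(arr)
    stack: dict[str, np.ndarray] = {
        "R": arr[:, 0], "G": arr[:, 1], "B": arr[:, 2],
        "H": hsv[:, 0], "S": hsv[:, 1], "V": hsv[:, 2],
        "Lstar": xyzlab[:, 3], "astar": xyzlab[:, 4], "bstar": xyzlab[:, 5],
        "X": xyzlab[:, 0], "Y": xyzlab[:, 1], "Z": xyzlab[:, 2],
        "Yn": yiq[:, 0], "I": yiq[:, 1], "Q": yiq[:, 2],
        "gray_standard": gray, "response": response,
    }
    return stack
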