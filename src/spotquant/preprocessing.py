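"""Raw photograph -> analyzed region of interest.

A spot photograph is resized and denoised, the chromogenic spot is located
by its chromatic contrast with the paper background, and the final ROI is
the fitted disc eroded toward its center so that rim and coffee-ring
artifacts are excluded from all downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as _label
from skimage.morphology import disk, opening as _opening
from skimage.transform import resize as _resize


class NoSpotFound(Exception):
    """Raised when no spot-like component of sufficient area is detected."""


@dataclass
class SpotImage:
    """An RGB raster with values in [0, 1] plus free-form metadata."""

    pixels: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[-1] != 3:
            raise ValueError(
                f"SpotImage requires an H x W x 3 raster, got shape {self.pixels.shape}"
            )
        if self.pixels.size == 0:
            raise ValueError("SpotImage raster is empty")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("SpotImage values must lie in [0, 1]")
        self.pixels = np.clip(self.pixels, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class RoiMask:
    """Boolean raster selecting the analyzed pixels of one spot.

    ``center`` is (row, col) and ``radius`` the fitted disc radius in
    pixels, both 0-based.  The mask is always a subset of the fitted disc.
    """

    mask: np.ndarray
    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("RoiMask is empty")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def load_image(path: str | Path) -> SpotImage:
    """Read a PNG/JPEG file into a SpotImage (values scaled to [0, 1])."""
    path = Path(path)
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=float) / 255.0
    return SpotImage(arr, metadata={"source": str(path)})


def save_image(image: SpotImage, path: str | Path) -> None:
    """Write a SpotImage as an 8-bit RGB PNG."""
    arr = np.clip(np.round(image.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(Path(path), format="PNG")


def save_mask(mask: RoiMask, path: str | Path) -> None:
    """Write a boolean mask as a 0/255 grayscale PNG for inspection."""
    arr = (mask.mask.astype(np.uint8)) * 255
    Image.fromarray(arr, mode="L").save(Path(path), format="PNG")


def preprocess(
    image: SpotImage,
    target_size: tuple[int, int] = (256, 256),
    denoise_kernel: int = 3,
) -> SpotImage:
    """Center-crop to the target aspect ratio, resize, median-filter.

    Parameters
    ----------
    target_size:
        Output (height, width) in pixels.
    denoise_kernel:
        Odd median-filter window per channel; 1 disables filtering.
    """
    if denoise_kernel < 1 or denoise_kernel % 2 == 0:
        raise ValueError(f"denoise_kernel must be odd and >= 1, got {denoise_kernel}")
    th, tw = int(target_size[0]), int(target_size[1])
    if th < 1 or tw < 1:
        raise ValueError(f"target_size must be positive, got {target_size}")
    px = image.pixels
    h, w = px.shape[:2]

    # center-crop to the target aspect ratio before scaling
    target_aspect = tw / th
    if w / h > target_aspect:
        new_w = max(1, int(round(h * target_aspect)))
        off = (w - new_w) // 2
        px = px[:, off : off + new_w]
    elif w / h < target_aspect:
        new_h = max(1, int(round(w / target_aspect)))
        off = (h - new_h) // 2
        px = px[off : off + new_h, :]

    if px.shape[:2] != (th, tw):
        px = _resize(px, (th, tw, 3), order=1, anti_aliasing=px.shape[0] > th, preserve_range=True)
    if denoise_kernel > 1:
        px = ndimage.median_filter(px, size=(denoise_kernel, denoise_kernel, 1))
    return SpotImage(np.clip(px, 0.0, 1.0), metadata=dict(image.metadata))


def _modal_background_color(px: np.ndarray, bins: int = 16) -> np.ndarray:
    """Robust background color: modal histogram cell of the border frame.

    The spot sits in the interior of the photograph, so a frame along the
    image border samples only paper.  Within that frame the most populated
    coarse RGB histogram cell picks the dominant (modal) paper color,
    ignoring stray dark specks.
    """
    h, w = px.shape[:2]
    t = max(2, min(h, w) // 16)
    frame = np.concatenate(
        [
            px[:t].reshape(-1, 3),
            px[-t:].reshape(-1, 3),
            px[t:-t, :t].reshape(-1, 3),
            px[t:-t, -t:].reshape(-1, 3),
        ]
    )
    q = np.minimum((frame * bins).astype(int), bins - 1)
    codes = (q[:, 0] * bins + q[:, 1]) * bins + q[:, 2]
    mode = np.bincount(codes).argmax()
    return frame[codes == mode].mean(axis=0)


def segment_spot(
    image: SpotImage,
    shrink_factor: float = 0.8,
    min_area: int = 64,
) -> RoiMask:
    """Locate the spot and return a disc ROI eroded to ``shrink_factor``.

    The spot is the largest connected component of pixels chromatically
    distinct from the modal background color.  Chromatic distance is
    computed after removing each pixel's own mean brightness, so a global
    (achromatic) brightness offset does not move the segmentation.  The
    component is summarized by an equal-area disc; the returned mask is
    that disc with radius scaled by ``shrink_factor`` to exclude rim and
    coffee-ring artifacts.

    Raises
    ------
    NoSpotFound
        If no chromatically distinct component of at least ``min_area``
        pixels exists.
    """
    if not 0.0 < shrink_factor <= 1.0:
        raise ValueError(f"shrink_factor must lie in (0, 1], got {shrink_factor}")
    px = image.pixels
    bg = _modal_background_color(px)

    # brightness-free chromatic coordinates: subtract each pixel's own mean
    cpx = px - px.mean(axis=-1, keepdims=True)
    cbg = bg - bg.mean()
    dist = np.linalg.norm(cpx - cbg, axis=-1)

    if dist.max() - dist.min() < 1e-6:
        raise NoSpotFound("image is chromatically uniform; no spot present")
    thr = threshold_otsu(dist)
    fg = _opening(dist > thr, footprint=disk(2))
    lbl = _label(fg)
    if lbl.max() == 0:
        raise NoSpotFound("no connected component above the chromatic threshold")
    sizes = np.bincount(lbl.ravel())[1:]
    comp = lbl == (int(np.argmax(sizes)) + 1)
    area = int(comp.sum())
    if area < min_area:
        raise NoSpotFound(f"largest component has {area} px < min_area={min_area}")

    rows, cols = np.nonzero(comp)
    center = (float(rows.mean()), float(cols.mean()))
    radius = float(np.sqrt(area / np.pi))
    rr, cc = np.ogrid[: px.shape[0], : px.shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    mask = d2 <= (shrink_factor * radius) ** 2
    return RoiMask(mask=mask, center=center, radius=radius)


def extract_roi_pixels(image: SpotImage, mask: RoiMask) -> np.ndarray:
    """Return the masked pixels as an (N, 3) array in row-major order.

    A pure selection: the returned values are exactly the image values at
    the True positions of the mask.
    """
    if mask.mask.shape != image.shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match image shape {image.shape}"
        )
    if not mask.mask.any():
        raise ValueError("mask selects no pixels")
    return image.pixels[mask.mask]
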