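"""Synthetic assay images with full ground truth.

Real photographs of enzymatic paper-pad assays are rarely shareable, so the
pipeline is exercised on simulated spots that carry the same statistical
structure: a circular chromogenic spot on paper-textured background whose
mean response intensity follows the logarithmic dose–response

    response = a * ln(concentration_mM) + b     (clamped)

with defaults a = 36.958 and b = 61.367 on the 0–255 response scale
(response = 255 - standard gray, so darker spots score higher).  On top of
the deterministic ramp the simulator adds smooth multiplicative paper-fiber
texture, per-pixel Gaussian noise on the response scale and a linear
illumination gradient centered on the spot, and
can step the target response down over storage days to emulate shelf-life
decay of the reagents.

All randomness flows from explicit integer seeds; identical parameters give
bit-identical images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .colorspaces import LUMA_WEIGHTS
from .preprocessing import RoiMask, SpotImage, save_image, save_mask

_MEAN_TOL = 0.5  # pre-noise ROI mean must match the target this closely


class ParameterizationError(ValueError):
    """Raised when a requested response is unattainable by the color ramp."""


@dataclass(frozen=True)
class ResponseModel:
    """Logarithmic dose–response: clamp(a·ln(x) + b) on the 0–255 scale.

    ``a`` is the slope in response units per ln(mM), ``b`` the intercept
    (the response at exactly 1 mM, before clamping).
    """

    a: float = 36.958
    b: float = 61.367
    clamp_lo: float = 0.0
    clamp_hi: float = 255.0

    def __post_init__(self) -> None:
        if not self.clamp_lo < self.clamp_hi:
            raise ValueError("clamp_lo must be < clamp_hi")

    def evaluate(self, conc: float) -> float:
        return evaluate_response(self, conc)


@dataclass(frozen=True)
class SceneParams:
    """Geometry, colors and noise of one simulated photograph."""

    image_size: tuple[int, int] = (256, 256)
    spot_center: tuple[int, int] = (128, 128)
    spot_radius: int = 80
    paper_rgb: tuple[float, float, float] = (0.96, 0.95, 0.92)
    stain_rgb: tuple[float, float, float] = (0.35, 0.24, 0.08)
    illum_gradient: float = 0.08
    noise_sd: float = 4.0
    texture_sd: float = 0.015
    texture_scale: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        cr, cc = self.spot_center
        r = self.spot_radius
        if not (r <= cr <= h - 1 - r and r <= cc <= w - 1 - r):
            raise ValueError("spot must lie fully inside the image")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.texture_sd < 0 or self.texture_scale <= 0:
            raise ValueError("texture_sd must be >= 0 and texture_scale > 0")
        if not 0.0 <= self.illum_gradient <= 0.5:
            raise ValueError("illum_gradient must lie in [0, 0.5]")


@dataclass
class GroundTruth:
    """Known concentration, true spot mask and pre-noise target response."""

    concentration: float
    true_mask: RoiMask
    target_response: float


def evaluate_response(model: ResponseModel, conc: float) -> float:
    """Mean spot response predicted by the model at ``conc`` mM (clamped)."""
    if not conc > 0:
        raise ValueError(f"concentration must be positive, got {conc}")
    y = model.a * math.log(conc) + model.b
    return float(min(max(y, model.clamp_lo), model.clamp_hi))


def _response_of_rgb(rgb) -> float:
    return float(255.0 * (1.0 - np.dot(np.asarray(rgb, dtype=float), LUMA_WEIGHTS)))


def ramp_clamped_model(
    scene: SceneParams, a: float = 36.958, b: float = 61.367
) -> ResponseModel:
    """A ResponseModel whose clamp equals the scene's attainable response range.

    The color ramp from ``paper_rgb`` to ``stain_rgb`` can only realize
    responses between the two endpoint responses; clamping the dose–response
    there represents saturation of the chromogen (a fully developed spot
    cannot get darker), which is what happens physically at molar-range
    glucose levels.
    """
    lo = _response_of_rgb(scene.paper_rgb)
    hi = _response_of_rgb(scene.stain_rgb)
    return ResponseModel(a=a, b=b, clamp_lo=min(lo, hi), clamp_hi=max(lo, hi))


def _disc_mask(scene: SceneParams) -> np.ndarray:
    h, w = scene.image_size
    rr, cc = np.ogrid[:h, :w]
    cr, ccol = scene.spot_center
    return (rr - cr) ** 2 + (cc - ccol) ** 2 <= scene.spot_radius**2


def simulate_spot(
    model: ResponseModel,
    scene: SceneParams,
    conc: float,
    rng: np.random.Generator | None = None,
    target_override: float | None = None,
) -> tuple[SpotImage, GroundTruth]:
    """Render one spot photograph with known ground truth.

    Spot pixels interpolate ``paper_rgb`` -> ``stain_rgb`` so that the
    pre-noise mean response over the true disc equals the model response at
    ``conc`` (or ``target_override``); then an illumination gradient
    (zero-mean over the spot) and per-pixel Gaussian response noise are
    applied.

    Raises
    ------
    ParameterizationError
        If the target response lies outside the range the color ramp can
        reach, naming the offending bound.
    """
    target = model.evaluate(conc) if target_override is None else float(target_override)
    resp_paper = _response_of_rgb(scene.paper_rgb)
    resp_stain = _response_of_rgb(scene.stain_rgb)
    lo, hi = min(resp_paper, resp_stain), max(resp_paper, resp_stain)
    if target < lo - 1e-9 or target > hi + 1e-9:
        bound = ("lower", lo) if target < lo else ("upper", hi)
        raise ParameterizationError(
            f"target response {target:.3f} is unattainable: the paper->stain ramp "
            f"is bounded {bound[0]} at {bound[1]:.3f}"
        )

    t = (target - resp_paper) / (resp_stain - resp_paper)
    paper = np.asarray(scene.paper_rgb, dtype=float)
    stain = np.asarray(scene.stain_rgb, dtype=float)
    h, w = scene.image_size
    px = np.broadcast_to(paper, (h, w, 3)).copy()
    disc = _disc_mask(scene)
    px[disc] = paper + t * (stain - paper)

    # affine touch-up: adding the same delta to all channels shifts the
    # response by -255*delta, making the disc mean exactly the target
    mean_resp = float(255.0 * (1.0 - px[disc] @ LUMA_WEIGHTS).mean())
    px[disc] -= (target - mean_resp) / 255.0

    # illumination gradient, linear across columns and centered on the spot
    # so its mean over the (symmetric) disc is 1
    if scene.illum_gradient > 0:
        cols = np.arange(w, dtype=float)
        f = 1.0 - scene.illum_gradient * (cols - scene.spot_center[1]) / w
        px = px * f[None, :, None]

    if rng is None and (scene.texture_sd > 0 or scene.noise_sd > 0):
        rng = np.random.default_rng(scene.seed)

    # paper fiber mottle: a smooth multiplicative reflectance field,
    # renormalized to mean exactly 1 over the disc so the pre-noise mean
    # response contract is preserved
    if scene.texture_sd > 0:
        raw = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), scene.texture_scale)
        raw /= raw.std()
        tex = 1.0 + scene.texture_sd * raw
        tex /= tex[disc].mean()
        px = px * tex[:, :, None]

    if scene.noise_sd > 0:
        noise = rng.normal(0.0, scene.noise_sd, size=(h, w))
        px = px - noise[:, :, None] / 255.0

    px = np.clip(px, 0.0, 1.0)
    image = SpotImage(px, metadata={"concentration_mM": conc, "target_response": target})
    truth = GroundTruth(
        concentration=conc,
        true_mask=RoiMask(mask=disc, center=tuple(map(float, scene.spot_center)),
                          radius=float(scene.spot_radius)),
        target_response=target,
    )
    return image, truth


def simulate_calibration_responses(
    model: ResponseModel,
    concentrations,
    replicates: int = 3,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate-level mean responses with additive Gaussian noise.

    The direct (image-free) analogue of reading the mean spot response at
    each concentration; used for calibration-recovery studies.
    Returns matched arrays ``(concentrations, responses)`` of length
    ``len(concentrations) * replicates``.
    """
    concs = np.asarray(list(concentrations), dtype=float)
    if concs.size == 0:
        raise ValueError("empty concentration list")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    x = np.repeat(concs, replicates)
    y = np.array([model.evaluate(c) for c in x]) + rng.normal(0.0, noise_sd, size=x.size)
    return x, y


@dataclass
class SimulatedRecord:
    """One simulated image plus its manifest row."""

    image: SpotImage
    truth: GroundTruth
    concentration: float
    replicate: int
    day: int
    seed: int
    image_path: str | None = None


def _sub_seeds(seed: int, n: int) -> np.ndarray:
    # deterministic fan-out of one global seed into per-image seeds
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)


def simulate_dataset(
    model: ResponseModel,
    scene: SceneParams,
    concentrations,
    replicates: int = 3,
    seed: int = 0,
    out_dir: str | Path | None = None,
    day: int = 0,
    write_masks: bool = False,
) -> tuple[list[SimulatedRecord], pd.DataFrame]:
    """One image per (concentration, replicate), with a CSV-ready manifest.

    Per-image sub-seeds are derived deterministically from ``seed``, so two
    runs with the same arguments produce identical manifests and images.
    When ``out_dir`` is given the images (and optionally the ground-truth
    masks) are written as PNGs and the manifest as ``manifest.csv``.
    """
    concs = list(concentrations)
    if not concs:
        raise ValueError("empty concentration list")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    seeds = _sub_seeds(seed, len(concs) * replicates)
    records: list[SimulatedRecord] = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "images").mkdir(parents=True, exist_ok=True)
        if write_masks:
            (out / "masks").mkdir(parents=True, exist_ok=True)
    k = 0
    for conc in concs:
        for rep in range(replicates):
            sub = int(seeds[k])
            rng = np.random.default_rng(sub)
            image, truth = simulate_spot(model, scene, conc, rng=rng)
            path = None
            if out is not None:
                path = f"images/conc{conc:g}_rep{rep}.png"
                save_image(image, out / path)
                if write_masks:
                    save_mask(truth.true_mask, out / f"masks/conc{conc:g}_rep{rep}.png")
            records.append(
                SimulatedRecord(image, truth, float(conc), rep, day, sub, path)
            )
            k += 1
    manifest = pd.DataFrame(
        {
            "image_path": [r.image_path for r in records],
            "concentration_mM": [r.concentration for r in records],
            "replicate": [r.replicate for r in records],
            "day": [r.day for r in records],
            "seed": [r.seed for r in records],
        }
    )
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    return records, manifest


def simulate_stability_series(
    model: ResponseModel,
    scene: SceneParams,
    conc: float,
    days,
    decay_fraction_at_end: float = 0.62,
    seed: int = 0,
) -> list[SimulatedRecord]:
    """Day-indexed images whose target response decays monotonically.

    The day-0 target is the model response at ``conc``; by the final day it
    has decayed exponentially to ``(1 - decay_fraction_at_end)`` of its
    starting value, emulating loss of reagent activity during storage.
    """
    days = list(days)
    if len(days) < 1:
        raise ValueError("need at least one day")
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError("days must be strictly ascending")
    if not 0.0 <= decay_fraction_at_end < 1.0:
        raise ValueError("decay_fraction_at_end must lie in [0, 1)")
    base = model.evaluate(conc)
    span = days[-1] - days[0]
    if span > 0 and decay_fraction_at_end > 0:
        k = -math.log(1.0 - decay_fraction_at_end) / span
    else:
        k = 0.0
    seeds = _sub_seeds(seed, len(days))
    records = []
    for i, d in enumerate(days):
        target = base * math.exp(-k * (d - days[0]))
        rng = np.random.default_rng(int(seeds[i]))
        image, truth = simulate_spot(model, scene, conc, rng=rng, target_override=target)
        records.append(
            SimulatedRecord(image, truth, float(conc), 0, int(d), int(seeds[i]))
        )
    return records
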