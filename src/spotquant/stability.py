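"""Shelf-life decay of the developed color.

Stored reagent pads lose activity: the same analyte concentration develops a
fainter color after days of storage.  The decay is summarized as the per-day
mean response (inverted-gray, so fading color is a falling number) and the
percent intensity change between the first and last day; a positive
percentage is decay, a negative one intensification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .colorspaces import rgb_to_gray
from .preprocessing import RoiMask, SpotImage, extract_roi_pixels


@dataclass
class StabilitySeries:
    """Day-indexed mean responses for one storage condition."""

    condition: str
    days: list[int]
    mean_response: list[float]

    def __post_init__(self) -> None:
        if len(self.days) != len(self.mean_response):
            raise ValueError("days and mean_response must be matched")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly ascending")
        if not np.all(np.isfinite(self.mean_response)):
            raise ValueError("mean responses must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition,
                "day": self.days,
                "mean_response": self.mean_response,
            }
        )


def summarize_day(images: list[SpotImage], masks: list[RoiMask]) -> float:
    """Mean response over each ROI, averaged across the day's images."""
    if not images:
        raise ValueError("need at least one image")
    if len(images) != len(masks):
        raise ValueError("images and masks must be matched")
    means = []
    for image, mask in zip(images, masks):
        _, response = rgb_to_gray(extract_roi_pixels(image, mask))
        means.append(float(response.mean()))
    return float(np.mean(means))


def build_series(
    day_to_images: dict[int, tuple[list[SpotImage], list[RoiMask]]],
    condition: str = "default",
) -> StabilitySeries:
    """Summarize a day-indexed image collection into a StabilitySeries."""
    days = sorted(day_to_images)
    means = [summarize_day(*day_to_images[d]) for d in days]
    return StabilitySeries(condition=condition, days=days, mean_response=means)


def percent_intensity_change(series: StabilitySeries) -> float:
    """Percent change from first to last day: ``100·(1 - last/first)``.

    Positive values mean the color faded; negative values mean it
    intensified.
    """
    if len(series.days) < 2:
        raise ValueError("need at least two days")
    first = series.mean_response[0]
    last = series.mean_response[-1]
    if first <= 0:
        raise ValueError("first-day response must be positive")
    return float(100.0 * (1.0 - last / first))
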