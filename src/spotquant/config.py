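"""Pipeline configuration: one YAML document drives every stage.

A single global seed fans out deterministically into per-stage and
per-image sub-seeds, so a whole simulate→extract→calibrate→train run is
reproducible from the config alone.  The config round-trips through YAML
unchanged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .synthetic import ResponseModel, SceneParams, ramp_clamped_model

#: mM-range design points (physiological glucose range).
DEFAULT_CONCENTRATIONS_MM = [0.5, 1.0, 2.0, 5.0, 8.0, 11.0, 14.0, 17.0, 20.0]
#: M-range design points (0.1–0.5 M expressed in mM).
DEFAULT_CONCENTRATIONS_HIGH_MM = [100.0, 200.0, 300.0, 400.0, 500.0]


def _default_scene() -> dict:
    return {
        "image_size": [256, 256],
        "spot_center": [128, 128],
        "spot_radius": 80,
        "paper_rgb": [0.96, 0.95, 0.92],
        "stain_rgb": [0.35, 0.24, 0.08],
        "illum_gradient": 0.08,
        "noise_sd": 4.0,
    }


@dataclass
class PipelineConfig:
    seed: int = 0
    scene: dict = field(default_factory=_default_scene)
    # clamp "ramp" ties the response model to the scene's attainable range
    model: dict = field(
        default_factory=lambda: {"a": 36.958, "b": 61.367, "clamp": "ramp"}
    )
    concentrations_mM: list = field(
        default_factory=lambda: list(DEFAULT_CONCENTRATIONS_MM)
    )
    concentrations_high_mM: list = field(
        default_factory=lambda: list(DEFAULT_CONCENTRATIONS_HIGH_MM)
    )
    replicates: int = 3
    preprocess: dict = field(
        default_factory=lambda: {"target_size": [256, 256], "denoise_kernel": 3}
    )
    segment: dict = field(
        default_factory=lambda: {"shrink_factor": 0.8, "min_area": 64}
    )
    glcm: dict = field(
        default_factory=lambda: {"Ng": 8, "offset": [0, 1], "symmetric": True}
    )
    calibration: dict = field(
        default_factory=lambda: {
            "valid_range": [0.5, 14.0],
            "fit_max_mM": 20.0,
            "blank_mean": None,
            "blank_sd": None,
        }
    )
    train: dict = field(
        default_factory=lambda: {"kernel": "rbf", "cv_folds": 3, "test_size": 0.3}
    )
    stability: dict = field(
        default_factory=lambda: {
            "conc_mM": 14.0,
            "days": [0, 2, 4, 7, 14],
            "decay_fraction_at_end": 0.62,
            "condition": "trehalose_4C",
        }
    )

    # -- resolution helpers -------------------------------------------------

    def scene_params(self, seed: int | None = None) -> SceneParams:
        s = self.scene
        return SceneParams(
            image_size=tuple(s["image_size"]),
            spot_center=tuple(s["spot_center"]),
            spot_radius=int(s["spot_radius"]),
            paper_rgb=tuple(s["paper_rgb"]),
            stain_rgb=tuple(s["stain_rgb"]),
            illum_gradient=float(s["illum_gradient"]),
            noise_sd=float(s["noise_sd"]),
            seed=self.seed if seed is None else seed,
        )

    def response_model(self) -> ResponseModel:
        m = self.model
        if m.get("clamp") == "ramp":
            return ramp_clamped_model(self.scene_params(), a=m["a"], b=m["b"])
        lo, hi = m.get("clamp", [0.0, 255.0])
        return ResponseModel(a=m["a"], b=m["b"], clamp_lo=lo, clamp_hi=hi)

    def all_concentrations(self) -> list[float]:
        return list(self.concentrations_mM) + list(self.concentrations_high_mM)

    # -- (de)serialization ---------------------------------------------------

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        payload = yaml.safe_load(p.read_text() if p.exists() else str(source))
        return cls(**payload) if payload else cls()
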