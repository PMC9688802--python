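"""Logarithmic calibration of the spot response and limit of detection.

The dose–response of the assay is linear in log-concentration,
``y = a·ln(x) + b``, so the "non-linear" calibration curve is fitted by
ordinary least squares of the response on ln(concentration) — this
reproduces the functional form exactly without iterative fitting.  The
inverse map ``x = exp((y - b)/a)`` converts a measured response into a
concentration estimate, flagged as extrapolated outside the validated
concentration range.

Limit of detection follows the signal-domain 3.3σ convention: the smallest
response reliably distinguishable from blanks is ``blank_mean +
3.3·blank_sd``, and the LOD is that response mapped through the inverse
calibration.  The log model has no constant concentration-space slope, so
the classical 3.3σ/slope expression is applied in signal space before
inversion.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

_SS_EPS = 1e-12


@dataclass
class CalibrationFit:
    """Fitted logarithmic response model and its quality summaries.

    ``a``: response units per ln(mM); ``b``: response units (the response
    at 1 mM); ``valid_range``: concentration interval (mM) over which the
    calibration is trusted; ``lod``: limit of detection in mM, None until
    :func:`compute_lod` is applied.
    """

    a: float
    b: float
    r_squared: float
    residual_sd: float
    n: int
    valid_range: tuple[float, float] = (0.5, 14.0)
    lod: float | None = None

    def predict(self, conc) -> np.ndarray:
        x = np.asarray(conc, dtype=float)
        if np.any(x <= 0):
            raise ValueError("concentration must be positive")
        return self.a * np.log(x) + self.b

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload["valid_range"] = list(self.valid_range)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CalibrationFit":
        p = Path(source)
        payload = json.loads(p.read_text() if p.exists() else str(source))
        payload["valid_range"] = tuple(payload["valid_range"])
        return cls(**payload)


def fit_log_calibration(
    concentrations,
    responses,
    valid_range: tuple[float, float] = (0.5, 14.0),
) -> CalibrationFit:
    """Least-squares fit of response on ln(concentration).

    Requires at least 3 distinct positive concentrations.  ``r_squared``
    is 1 - SSres/SStot (defined as 0 when the responses are constant) and
    ``residual_sd`` is sqrt(SSres / (n - 2)).
    """
    x = np.asarray(list(concentrations), dtype=float)
    y = np.asarray(list(responses), dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and responses must be matched 1-D sequences")
    if np.any(x <= 0):
        raise ValueError("all concentrations must be positive")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    lx = np.log(x)
    design = np.column_stack([lx, np.ones_like(lx)])
    (a, b), *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - (a * lx + b)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r_squared = 0.0 if ss_tot < _SS_EPS else 1.0 - ss_res / ss_tot
    residual_sd = math.sqrt(ss_res / (x.size - 2)) if x.size > 2 else 0.0
    return CalibrationFit(
        a=float(a),
        b=float(b),
        r_squared=float(r_squared),
        residual_sd=float(residual_sd),
        n=int(x.size),
        valid_range=tuple(valid_range),
    )


def invert_calibration(fit: CalibrationFit, response, with_flag: bool = False):
    """Map response(s) back to concentration in mM: ``exp((y - b)/a)``.

    With ``with_flag=True`` also returns a boolean array marking estimates
    that fall outside ``fit.valid_range`` (extrapolated).
    """
    if fit.a == 0:
        raise ValueError("calibration with zero slope is not invertible")
    y = np.asarray(response, dtype=float)
    conc = np.exp((y - fit.b) / fit.a)
    if with_flag:
        lo, hi = fit.valid_range
        return conc, (conc < lo) | (conc > hi)
    return conc


def compute_lod(
    fit: CalibrationFit,
    blank_mean: float,
    blank_sd: float,
    response_range: tuple[float, float] = (0.0, 255.0),
) -> float:
    """Limit of detection in mM from blank statistics.

    ``y_lod = blank_mean + 3.3·blank_sd`` is inverted through the fit.
    The factor 3.3 combines the conventional false-positive and
    false-negative z-scores (≈1.645 each).
    """
    if blank_sd < 0:
        raise ValueError("blank_sd must be >= 0")
    if not fit.a > 0:
        raise ValueError("LOD requires a positive calibration slope")
    y_lod = blank_mean + 3.3 * blank_sd
    if not response_range[0] <= y_lod <= response_range[1]:
        raise ValueError(
            f"LOD response {y_lod:.3f} lies outside the attainable range {response_range}"
        )
    return float(invert_calibration(fit, y_lod))
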