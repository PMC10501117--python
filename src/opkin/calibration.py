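"""Synthetic calibration curves and ordinary least-squares inversion.

The instruments are calibrated with known standards (DHA for the ascorbate
channel, H2O2 for the peroxide channel); this module generates synthetic
calibration points with seeded Gaussian noise and fits/inverts the linear
response, so calibration handling is testable without instrument data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

#: declared synthetic instrument responses: slope (response per uM), intercept
DECLARED_LINES = {
    "DHA": (120.0, 50.0),    # fluorescence counts per uM DHA
    "H2O2": (80.0, 30.0),
}


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationCurve:
    """Known concentrations (uM) vs instrument response, with an OLS fit."""

    concentrations: np.ndarray
    responses: np.ndarray
    kind: str = ""
    slope: float = float("nan")
    intercept: float = float("nan")
    residual_sd: float = float("nan")
    stderr_slope: float = float("nan")

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.size < 3:
            raise CalibrationError("calibration needs at least 3 points")
        if self.concentrations.size != self.responses.size:
            raise CalibrationError("concentration/response length mismatch")

    def fit(self) -> "CalibrationCurve":
        x, y = self.concentrations, self.responses
        if np.ptp(x) == 0:
            raise CalibrationError("degenerate calibration: all x equal")
        res = stats.linregress(x, y)
        self.slope = float(res.slope)
        self.intercept = float(res.intercept)
        self.stderr_slope = float(res.stderr)
        resid = y - (self.slope * x + self.intercept)
        dof = max(x.size - 2, 1)
        self.residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
        if self.slope <= 0:
            raise CalibrationError("calibration slope must be positive")
        return self

    def invert(self, responses: Sequence[float]) -> np.ndarray:
        """Map instrument responses back to concentrations (uM)."""
        if np.isnan(self.slope):
            self.fit()
        r = np.asarray(responses, dtype=float)
        return (r - self.intercept) / self.slope


def make_calibration(kind: str, n_points: int = 10, noise_sd: float = 0.0,
                     seed: int = 0, conc_max: float = 10.0) -> CalibrationCurve:
    """Generate a synthetic calibration series for a known standard.

    Responses follow the declared line for ``kind`` plus seeded Gaussian
    noise of absolute standard deviation ``noise_sd``; identical seeds give
    identical points.
    """
    if kind not in DECLARED_LINES:
        raise CalibrationError(
            f"unknown calibration kind {kind!r}; expected one of "
            f"{sorted(DECLARED_LINES)}"
        )
    if n_points < 3:
        raise CalibrationError("n_points must be >= 3")
    slope, intercept = DECLARED_LINES[kind]
    rng = np.random.default_rng(seed)
    conc = np.linspace(0.0, conc_max, n_points)
    resp = slope * conc + intercept
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd, size=n_points)
    return CalibrationCurve(conc, resp, kind=kind)


def fit_and_apply_calibration(curve: CalibrationCurve,
                              responses: Sequence[float]) -> np.ndarray:
    """OLS-fit the curve and invert the given responses to concentrations."""
    return curve.fit().invert(responses)
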