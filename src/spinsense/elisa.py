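"""Linear ELISA calibration and limit-of-detection statistics.

A colorimetric sandwich assay read at 450 nm gives absorbance linear in
antigen concentration over the working range (here 0–200 ng/mL).
:func:`fit_calibration` performs the ordinary least-squares fit,
returning a results-style :class:`CalibrationCurve`;
:func:`compute_lod` derives the limit of detection as
``k * SD_blank / slope`` with the conventional k = 3; and
:func:`predict_concentration` inverts the line for unknowns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidArgument

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "LODResult",
    "fit_calibration",
    "compute_lod",
    "predict_concentration",
]


@dataclass(frozen=True)
class CalibrationPoint:
    concentration: float  # ng/mL
    absorbance: float  # AU at 450 nm
    replicate: int = 0

    def __post_init__(self):
        if self.concentration < 0:
            raise InvalidArgument("concentration must be nonnegative")


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS fit of absorbance on concentration.

    ``slope`` in AU per ng/mL, ``intercept`` in AU; ``residual_sd`` uses
    n - 2 degrees of freedom; ``slope_se`` / ``intercept_se`` are the
    usual OLS standard errors.
    """

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n: int
    slope_se: float = float("nan")
    intercept_se: float = float("nan")

    def predict(self, concentration) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(concentration, dtype=float)

    def summary(self) -> str:
        return (
            f"Calibration fit (n={self.n}):\n"
            f"  slope      {self.slope:.6g} AU per ng/mL (SE {self.slope_se:.3g})\n"
            f"  intercept  {self.intercept:.6g} AU (SE {self.intercept_se:.3g})\n"
            f"  R^2        {self.r_squared:.5f}\n"
            f"  residual SD {self.residual_sd:.4g} AU"
        )


@dataclass(frozen=True)
class LODResult:
    lod: float  # ng/mL
    blank_sd: float  # AU
    k_factor: float
    method: str


def fit_calibration(points: list[CalibrationPoint]) -> CalibrationCurve:
    """Unweighted OLS of absorbance on concentration.

    Requires at least three points spanning at least two distinct
    concentrations; replicates enter individually (equivalent to
    count-weighting the distinct levels).
    """
    x = np.array([p.concentration for p in points], dtype=float)
    y = np.array([p.absorbance for p in points], dtype=float)
    if x.size < 3:
        raise InvalidArgument("need at least 3 calibration points")
    if np.ptp(x) == 0:
        raise InvalidArgument("all concentrations identical; cannot fit a line")

    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    residual_sd = float(np.sqrt((resid**2).sum() / (x.size - 2)))
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        residual_sd=residual_sd,
        n=int(x.size),
        slope_se=float(fit.stderr),
        intercept_se=float(fit.intercept_stderr),
    )


def compute_lod(
    curve: CalibrationCurve, blanks: list[float], k: float = 3.0
) -> LODResult:
    """Limit of detection: ``k * SD(blanks) / slope``.

    ``blanks`` are replicate blank absorbances; their sample standard
    deviation (n - 1) is used. ``k`` defaults to the conventional 3
    (~99 % one-sided confidence against the blank).
    """
    if curve.slope <= 0:
        raise InvalidArgument("LOD requires a positive calibration slope")
    blanks = np.asarray(blanks, dtype=float)
    if blanks.size < 2:
        raise InvalidArgument("need at least 2 blank replicates")
    if k < 0:
        raise InvalidArgument("k must be nonnegative")
    sd = float(blanks.std(ddof=1))
    return LODResult(
        lod=k * sd / curve.slope,
        blank_sd=sd,
        k_factor=float(k),
        method=f"{k:g}*SD_blank/slope",
    )


def predict_concentration(
    curve: CalibrationCurve, absorbance: float
) -> tuple[float, bool]:
    """Invert the calibration line for one absorbance.

    Returns ``(concentration, below_blank)``: readings below the
    intercept would invert to negative concentrations and are clamped
    to 0 with the flag set.
    """
    if curve.slope == 0:
        raise InvalidArgument("cannot invert a flat calibration line")
    conc = (float(absorbance) - curve.intercept) / curve.slope
    if conc < 0:
        return 0.0, True
    return conc, False
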