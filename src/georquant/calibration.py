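"""Linear calibration and ICH-style validation statistics.

The method is validated against the ICH Q2 parameters: linearity of peak
area ``A`` versus concentration ``C`` (``A = m C``, intercept-free by
default, matching how chromatographic response lines for this panel are
reported), limits of detection and quantification

    LOD = 3.3 sigma / S,    LOQ = 10 sigma / S,

with ``S`` the slope and ``sigma`` a standard deviation of the response,
repeatability as relative standard deviation RSD(%) = 100 sigma / mean, and
accuracy as recovery R(%) = 100 C_exp / C_theoretical.

``sigma`` in the LOD/LOQ pair is ambiguous in common usage: it may be the
standard error of the slope or the residual standard deviation of the
regression.  Both are implemented (``sigma_mode``), every curve records
which one it used, and no mode is canonized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "CalibrationCurve",
    "PrecisionResult",
    "RecoveryResult",
    "Quantification",
    "fit_calibration",
    "compute_lod",
    "compute_loq",
    "repeatability",
    "recovery",
    "quantify",
    "LOD_FACTOR",
    "LOQ_FACTOR",
]

LOD_FACTOR = 3.3
LOQ_FACTOR = 10.0


@dataclass
class CalibrationCurve:
    """Fitted response line for one analyte at one wavelength."""

    analyte: str
    wavelength: int
    slope: float
    slope_sd: float
    intercept: float
    r_squared: float
    sigma: float
    sigma_mode: str
    lod: float
    loq: float
    n_points: int
    through_origin: bool = True
    linearity_range: tuple[float, float] | None = None

    def equation(self) -> str:
        """Printable regression equation, e.g. ``y = (167894 +- 1570)x``."""
        s = f"y = ({self.slope:.6g} +- {self.slope_sd:.3g})x"
        if not self.through_origin:
            s += f" + {self.intercept:.6g}"
        return s

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "wavelength": self.wavelength,
            "slope": self.slope,
            "slope_sd": self.slope_sd,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "sigma": self.sigma,
            "sigma_mode": self.sigma_mode,
            "lod": self.lod,
            "loq": self.loq,
            "n_points": self.n_points,
            "through_origin": self.through_origin,
            "linearity_range": list(self.linearity_range)
            if self.linearity_range else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        d = dict(d)
        lr = d.get("linearity_range")
        d["linearity_range"] = tuple(lr) if lr else None
        return cls(**d)


@dataclass
class PrecisionResult:
    """Repeatability at one concentration level."""

    analyte: str
    level: float
    concentrations: list[float]
    mean: float
    sd: float
    rsd: float  # percent


@dataclass
class RecoveryResult:
    """Accuracy at one concentration level."""

    analyte: str
    level: float           # C_theoretical, mM
    measured_mean: float   # C_exp, mM
    recovery: float        # percent
    recovery_sd: float     # percent


@dataclass
class Quantification:
    """A single back-calculated concentration with quality flags."""

    value: float
    below_loq: bool = False
    clipped: bool = False
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_calibration(
    points: Sequence[tuple[float, float]],
    through_origin: bool = True,
    sigma_mode: str = "slope_sd",
    analyte: str = "",
    wavelength: int = 205,
    linearity_range: tuple[float, float] | None = None,
) -> CalibrationCurve:
    """Ordinary least squares of peak area on concentration.

    Parameters
    ----------
    points
        ``(concentration_mM, area)`` pairs; at least two distinct levels.
    through_origin
        Fit ``A = m C`` (default) or ``A = m C + b``.
    sigma_mode
        ``"slope_sd"`` stores the slope standard error as the LOD/LOQ
        sigma; ``"residual_sd"`` stores the regression residual standard
        deviation.

    Notes
    -----
    ``r_squared`` is computed against the mean-centered total sum of
    squares in both modes, the convention used when judging calibration
    linearity, so through-origin and intercept fits are comparable.
    """
    if sigma_mode not in ("slope_sd", "residual_sd"):
        raise ValueError("sigma_mode must be 'slope_sd' or 'residual_sd'")
    pts = [(float(c), float(a)) for c, a in points]
    if len(pts) < 2:
        raise ValueError("need at least 2 calibration points")
    conc = np.array([p[0] for p in pts])
    area = np.array([p[1] for p in pts])
    if np.any(conc < 0):
        raise ValueError("negative concentration in calibration points")
    if np.any(area < 0):
        raise ValueError("negative area in calibration points")
    if np.unique(conc).size < 2:
        raise ValueError(
            "all concentrations identical: calibration design is rank "
            "deficient"
        )

    X = conc[:, None] if through_origin else sm.add_constant(conc)
    fit = sm.OLS(area, X).fit()
    if through_origin:
        slope, intercept = float(fit.params[0]), 0.0
        slope_sd = float(fit.bse[0])
    else:
        intercept, slope = float(fit.params[0]), float(fit.params[1])
        slope_sd = float(fit.bse[1])
    resid = area - (slope * conc + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((area - area.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    dof = len(pts) - (1 if through_origin else 2)
    residual_sd = float(np.sqrt(ss_res / dof)) if dof > 0 else 0.0
    sigma = slope_sd if sigma_mode == "slope_sd" else residual_sd
    if slope <= 0:
        raise ValueError("fitted slope is not positive; cannot calibrate")

    curve = CalibrationCurve(
        analyte=analyte,
        wavelength=wavelength,
        slope=slope,
        slope_sd=slope_sd,
        intercept=intercept,
        r_squared=r_squared,
        sigma=sigma,
        sigma_mode=sigma_mode,
        lod=0.0,
        loq=0.0,
        n_points=len(pts),
        through_origin=through_origin,
        linearity_range=linearity_range
        or (float(conc.min()), float(conc.max())),
    )
    curve.lod = compute_lod(curve)
    curve.loq = compute_loq(curve)
    return curve


def compute_lod(curve: CalibrationCurve) -> float:
    """Limit of detection, LOD = 3.3 sigma / S (mM)."""
    if curve.sigma is None:
        raise ValueError("curve.sigma unset; fit with a sigma_mode first")
    if curve.slope <= 0:
        raise ValueError("slope must be > 0")
    return LOD_FACTOR * curve.sigma / curve.slope


def compute_loq(curve: CalibrationCurve) -> float:
    """Limit of quantification, LOQ = 10 sigma / S = (10/3.3) LOD (mM)."""
    if curve.sigma is None:
        raise ValueError("curve.sigma unset; fit with a sigma_mode first")
    if curve.slope <= 0:
        raise ValueError("slope must be > 0")
    return LOQ_FACTOR * curve.sigma / curve.slope


# ---------------------------------------------------------------------------
# precision / accuracy
# ---------------------------------------------------------------------------

def repeatability(
    concentrations: Sequence[float],
    analyte: str = "",
    level: float | None = None,
) -> PrecisionResult:
    """Repeatability (instrumental precision) of replicate concentrations.

    Sample standard deviation (n-1 denominator) and
    RSD(%) = 100 sigma / mean.
    """
    vals = [float(v) for v in concentrations]
    if len(vals) < 2:
        raise ValueError("need at least 2 replicates")
    mean = float(np.mean(vals))
    if mean == 0:
        raise ValueError("mean concentration is 0; RSD undefined")
    sd = float(np.std(vals, ddof=1))
    return PrecisionResult(
        analyte=analyte,
        level=float(level) if level is not None else mean,
        concentrations=vals,
        mean=mean,
        sd=sd,
        rsd=100.0 * sd / mean,
    )


def recovery(
    measured: Sequence[float],
    theoretical: float,
    analyte: str = "",
) -> RecoveryResult:
    """Recovery R(%) = 100 * mean(measured) / theoretical, with scatter."""
    if theoretical <= 0:
        raise ValueError("theoretical concentration must be > 0")
    vals = [float(v) for v in measured]
    if not vals:
        raise ValueError("no measured values")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return RecoveryResult(
        analyte=analyte,
        level=float(theoretical),
        measured_mean=mean,
        recovery=100.0 * mean / theoretical,
        recovery_sd=100.0 * sd / theoretical,
    )


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def quantify(area: float, curve: CalibrationCurve) -> Quantification:
    """Back-calculate a concentration, C = (A - b) / m, with flags.

    A negative back-calculated value clips to 0 (``clipped``); values below
    the curve's LOQ carry ``below_loq``.
    """
    if curve.slope <= 0:
        raise ValueError("slope must be > 0")
    value = (float(area) - curve.intercept) / curve.slope
    q = Quantification(value=value)
    if value < 0:
        q.value = 0.0
        q.clipped = True
        q.flags.append("negative-clipped")
    if q.value < curve.loq:
        q.below_loq = True
        q.flags.append("below-LOQ")
    return q
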