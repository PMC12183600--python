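"""Two-wavelength indirect quantification of a co-eluting pair.

Formic acid (FA) and glyceraldehyde (GlyAld) elute together at 19.46 min,
so their 205 nm signal is one merged peak.  GlyAld, unlike FA, also absorbs
at 300 nm, which breaks the degeneracy:

1.  quantify GlyAld directly from the 300 nm peak,
2.  predict GlyAld's share of the 205 nm area from its 205 nm response
    line, ``A_GlyAld,205 = m_GlyAld,205 * C_GlyAld + b``,
3.  attribute the remainder of the merged area to FA,
    ``A_FA,205 = A_mix,205 - A_GlyAld,205`` (absorbance additivity),
4.  back-calculate ``C_FA`` from FA's 205 nm response line.

The machinery is generic: any co-eluting pair where one member has a
private wavelength can be wired through these functions; the GEOR FA/GlyAld
pair is simply the default.  Because step 3 is a subtraction, small
negative FA areas are statistically inevitable at trace FA levels and are
clipped to zero with a flag rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .calibration import CalibrationCurve, Quantification, quantify

__all__ = [
    "CoelutionResult",
    "QuantError",
    "quantify_glyald",
    "indirect_fa",
    "percent_error",
]


@dataclass
class CoelutionResult:
    """Outcome of the indirect determination for one injection.

    ``a_fa_205`` is the raw deduced area (it satisfies
    ``a_mix_205 == a_glyald_205_pred + a_fa_205`` exactly, before any
    clipping); ``c_fa`` is the final, clipped concentration.
    """

    c_glyald: float
    a_mix_205: float
    a_glyald_205_pred: float
    a_fa_205: float
    c_fa: float
    below_loq: bool = False
    clipped: bool = False
    flags: list[str] = field(default_factory=list)


@dataclass
class QuantError:
    """Relative quantification error of one measurement."""

    experimental: float
    theoretical: float
    error: float  # percent


def quantify_glyald(
    area_300: float,
    curve_glyald_300: CalibrationCurve,
) -> Quantification:
    """GlyAld concentration from its private 300 nm peak area.

    The 300 nm peak is attributed entirely to GlyAld (FA does not respond
    there); the curve must be a GlyAld line at 300 nm.
    """
    c = curve_glyald_300
    if c.wavelength != 300:
        raise ValueError(
            f"expected a 300 nm curve, got {c.wavelength} nm"
        )
    if c.analyte and c.analyte != "GlyAld":
        raise ValueError(f"expected a GlyAld curve, got {c.analyte!r}")
    return quantify(area_300, c)


def indirect_fa(
    a_mix_205: float,
    c_glyald: float,
    curve_glyald_205: CalibrationCurve,
    curve_fa_205: CalibrationCurve,
) -> CoelutionResult:
    """Deduce the FA concentration hidden in the merged 205 nm peak.

    Parameters
    ----------
    a_mix_205
        Integrated area of the merged co-elution peak at 205 nm.
    c_glyald
        GlyAld concentration (mM), normally from :func:`quantify_glyald`.
    curve_glyald_205, curve_fa_205
        205 nm response lines of the two co-eluting analytes.

    Never raises on a negative deduced area — the result is clipped and
    flagged so batch runs survive trace-level noise.
    """
    if c_glyald < 0:
        raise ValueError("c_glyald must be >= 0")
    a_glyald_pred = (curve_glyald_205.slope * c_glyald
                     + curve_glyald_205.intercept)
    a_fa = a_mix_205 - a_glyald_pred
    res = CoelutionResult(
        c_glyald=c_glyald,
        a_mix_205=a_mix_205,
        a_glyald_205_pred=a_glyald_pred,
        a_fa_205=a_fa,
        c_fa=0.0,
    )
    q = quantify(max(a_fa, 0.0), curve_fa_205)
    res.c_fa = q.value
    res.below_loq = q.below_loq
    if a_fa < 0 or q.clipped:
        res.clipped = True
        res.flags.append("negative-area-clipped")
    if q.below_loq:
        res.flags.append("below-LOQ")
    return res


def percent_error(experimental: float, theoretical: float) -> QuantError:
    """Relative error, Error(%) = 100 * |E - T| / T."""
    if theoretical <= 0:
        raise ValueError("theoretical value must be > 0")
    return QuantError(
        experimental=float(experimental),
        theoretical=float(theoretical),
        error=100.0 * abs(experimental - theoretical) / theoretical,
    )
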