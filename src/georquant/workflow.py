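"""End-to-end conveniences tying the pipeline stages together.

These helpers run the same code path a user would: render or load
chromatograms, detect/assign/integrate peaks, fit response lines, and
apply the direct or indirect quantification — no shortcuts past the peak
detector.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from . import calibration, coelution, peaks, simulate

__all__ = [
    "peak_area_for",
    "calibrate_from_standards",
    "quantify_mixture",
]


def peak_area_for(
    chrom: simulate.Chromatogram,
    wavelength: int,
    analyte: str,
    library: simulate.CompoundLibrary,
    tolerance: float = peaks.DEFAULT_ASSIGN_TOLERANCE,
    **detect_kwargs,
) -> float:
    """Detect, assign, and return the integrated area for one analyte.

    The analyte may sit inside a co-elution group (the merged FA/GlyAld
    peak): the matching peak's whole area is returned, which is exactly
    what the indirect procedure consumes.  Returns 0.0 when no matching
    peak is found (nothing detectable at this wavelength).
    """
    found = peaks.detect_peaks(chrom, wavelength, **detect_kwargs)
    assigned = peaks.assign_peaks(found, library, tolerance)
    matches = [p for p in assigned if analyte in p.coelution_group]
    if not matches:
        return 0.0
    return max(p.area for p in matches)


def calibrate_from_standards(
    analyte: str,
    wavelength: int,
    library: simulate.CompoundLibrary,
    noise: simulate.NoiseModel,
    levels: Sequence[float] = (0.1, 0.5, 1.0, 2.5, 5.0),
    replicates: int = 3,
    through_origin: bool = True,
    sigma_mode: str = "slope_sd",
    **detect_kwargs,
) -> calibration.CalibrationCurve:
    """Simulate a standard series and fit its response line end to end.

    Every injection goes through baseline estimation, peak detection,
    assignment and trapezoidal integration before the ordinary
    least-squares fit — the full measurement chain, so the fitted slope
    carries the whole pipeline's error, not just the generator's.
    """
    series = simulate.simulate_calibration_series(
        analyte, list(levels), replicates, library, noise)
    points = []
    for chrom in series:
        area = peak_area_for(chrom, wavelength, analyte, library,
                             **detect_kwargs)
        points.append((chrom.meta["level_mM"], area))
    return calibration.fit_calibration(
        points, through_origin=through_origin, sigma_mode=sigma_mode,
        analyte=analyte, wavelength=wavelength,
        linearity_range=(min(levels), max(levels)),
    )


def quantify_mixture(
    chrom: simulate.Chromatogram,
    library: simulate.CompoundLibrary,
    curves: Mapping[tuple[str, int], calibration.CalibrationCurve],
    **detect_kwargs,
) -> dict[str, calibration.Quantification | coelution.CoelutionResult]:
    """Quantify every curve-covered analyte in one injection.

    Direct analytes use their 205 nm (or stated) curve; the co-eluting
    FA/GlyAld pair is resolved by the two-wavelength indirect procedure
    whenever the three needed curves — GlyAld at 300 and 205 nm, FA at
    205 nm — are provided.  Keys of ``curves`` are ``(analyte,
    wavelength)``.
    """
    out: dict[str, object] = {}
    indirect_keys = {("GlyAld", 300), ("GlyAld", 205), ("FA", 205)}
    run_indirect = indirect_keys <= set(curves)
    for (analyte, wl), curve in curves.items():
        if run_indirect and (analyte, wl) in indirect_keys:
            continue
        area = peak_area_for(chrom, wl, analyte, library, **detect_kwargs)
        out[analyte] = calibration.quantify(area, curve)
    if run_indirect:
        a300 = peak_area_for(chrom, 300, "GlyAld", library, **detect_kwargs)
        a205 = peak_area_for(chrom, 205, "GlyAld", library, **detect_kwargs)
        q_gly = coelution.quantify_glyald(a300, curves[("GlyAld", 300)])
        res = coelution.indirect_fa(
            a205, q_gly.value, curves[("GlyAld", 205)], curves[("FA", 205)])
        out["GlyAld"] = q_gly
        out["FA"] = res
    return out  # type: ignore[return-value]
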