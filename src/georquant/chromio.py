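"""Readers/writers for chromatograms, peak tables, reports, and run config.

File conventions
----------------
A chromatogram is one plain-text file: ``#``-prefixed header lines carrying
metadata (matrix, dilution factor, injection id, seed), then a tab-delimited
table with columns ``time_min``, ``A205``, ``A300`` (any ``A<nm>`` column is
accepted).  Values round-trip at full double precision.  One chromatogram
per file; a calibration series is a directory of such files.

Reports (validation, quantification) are JSON for machines plus a rendered
text table laid out like a standard ICH validation summary: one column per
analyte, rows for linearity range, regression equation, R^2, LOD, LOQ,
repeatability RSD at three levels and recovery at three levels.
Concentrations are printed with 3 decimals and percentages with 2; stored
JSON keeps full precision.
"""

from __future__ import annotations

import json
import logging
import re
import sys
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .simulate import Chromatogram

__all__ = [
    "read_chromatogram",
    "write_chromatogram",
    "peaks_to_table",
    "write_peak_table",
    "read_peak_table",
    "write_validation_report",
    "RunConfig",
    "configure_logging",
    "get_logger",
]

_LOG = logging.getLogger("georquant")


def configure_logging(verbosity: int = 0) -> None:
    """Route package logs to stderr; verbosity 0=WARNING, 1=INFO, 2+=DEBUG."""
    level = {0: logging.WARNING, 1: logging.INFO}.get(verbosity, logging.DEBUG)
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    _LOG.handlers[:] = [handler]
    _LOG.setLevel(level)


def get_logger(name: str = "") -> logging.Logger:
    return _LOG.getChild(name) if name else _LOG


# ---------------------------------------------------------------------------
# chromatogram files
# ---------------------------------------------------------------------------

_META_CASTS = {"dilution_factor": float, "seed": int,
               "level_mM": float, "replicate": int}


def write_chromatogram(chrom: Chromatogram, path: str | Path) -> Path:
    """Write one chromatogram as a headered tab-delimited text file."""
    path = Path(path)
    lines = ["# georquant chromatogram v1"]
    for key, val in chrom.meta.items():
        lines.append(f"# {key}: {val}")
    cols = ["time_min"] + [f"A{wl}" for wl in chrom.wavelengths]
    lines.append("\t".join(cols))
    data = np.column_stack(
        [chrom.times] + [chrom.traces[wl] for wl in chrom.wavelengths])
    for row in data:
        lines.append("\t".join(repr(float(x)) for x in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_chromatogram(path: str | Path) -> Chromatogram:
    """Read a chromatogram file written by :func:`write_chromatogram`.

    Raises
    ------
    ValueError
        On a non-monotonic time column (the offending line is named) or a
        malformed table.
    """
    path = Path(path)
    meta: dict[str, Any] = {}
    header_lines = 0
    with path.open() as fh:
        raw = fh.readlines()
    for line in raw:
        if not line.startswith("#"):
            break
        header_lines += 1
        m = re.match(r"#\s*([^:]+?)\s*:\s*(.*?)\s*$", line)
        if m:
            key, val = m.group(1), m.group(2)
            meta[key] = _META_CASTS.get(key, str)(val)
    df = pd.read_csv(path, sep="\t", skiprows=header_lines,
                     float_precision="round_trip")
    if "time_min" not in df.columns:
        raise ValueError(f"{path}: missing 'time_min' column")
    times = df["time_min"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if bad.size:
        # +2: 1-based line numbering plus the column-header line
        lineno = header_lines + int(bad[0]) + 2 + 1
        raise ValueError(
            f"{path}: time column not strictly increasing at line {lineno}"
        )
    traces = {}
    for col in df.columns:
        m = re.fullmatch(r"A(\d+)", col)
        if m:
            traces[int(m.group(1))] = df[col].to_numpy(dtype=float)
    if not traces:
        raise ValueError(f"{path}: no absorbance columns (expected e.g. A205)")
    return Chromatogram(times=times, traces=traces, meta=meta)


# ---------------------------------------------------------------------------
# peak tables
# ---------------------------------------------------------------------------

_PEAK_COLUMNS = ["injection_id", "analyte", "coelution_group", "apex_time",
                 "left_bound", "right_bound", "height", "area", "wavelength"]


def peaks_to_table(peaks: Sequence, injection_id: str = "") -> pd.DataFrame:
    """Flatten detected peaks into a tidy table (one row per peak)."""
    rows = []
    for p in peaks:
        rows.append({
            "injection_id": injection_id,
            "analyte": p.assigned_analyte or "unassigned",
            "coelution_group": "+".join(p.coelution_group),
            "apex_time": p.apex_time,
            "left_bound": p.left_bound,
            "right_bound": p.right_bound,
            "height": p.height,
            "area": p.area,
            "wavelength": p.wavelength,
        })
    return pd.DataFrame(rows, columns=_PEAK_COLUMNS)


def write_peak_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_peak_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------

def _fmt_conc(x: float) -> str:
    return f"{x:.3f}"


def _fmt_pct(x: float) -> str:
    return f"{x:.2f}"


def write_validation_report(
    curves: Sequence,
    precision: Mapping[str, Mapping[float, Any]] | None,
    recovery: Mapping[str, Mapping[float, Any]] | None,
    path: str | Path,
) -> dict:
    """Emit the method-validation summary as JSON plus a rendered table.

    Parameters
    ----------
    curves
        One :class:`~georquant.calibration.CalibrationCurve` per analyte.
    precision
        ``{analyte: {level_mM: PrecisionResult}}`` repeatability results.
    recovery
        ``{analyte: {level_mM: RecoveryResult}}`` accuracy results.
    path
        Output path for the JSON report; a ``.txt`` sibling holds the
        rendered table.

    Returns
    -------
    dict
        The JSON-serialised report structure.
    """
    precision = precision or {}
    recovery = recovery or {}
    report: dict[str, Any] = {"analytes": {}}
    for c in curves:
        entry: dict[str, Any] = {
            "wavelength": c.wavelength,
            "linearity_range_mM": list(c.linearity_range)
            if c.linearity_range else None,
            "slope": c.slope,
            "slope_sd": c.slope_sd,
            "intercept": c.intercept,
            "equation": c.equation(),
            "r_squared": c.r_squared,
            "sigma_mode": c.sigma_mode,
            "lod_mM": c.lod,
            "loq_mM": c.loq,
            "n_points": c.n_points,
            "rsd_percent": {
                str(level): pr.rsd
                for level, pr in sorted(precision.get(c.analyte, {}).items())
            },
            "recovery_percent": {
                str(level): {"mean": rr.recovery, "sd": rr.recovery_sd}
                for level, rr in sorted(recovery.get(c.analyte, {}).items())
            },
        }
        report["analytes"][c.analyte] = entry

    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    txt = render_validation_table(curves, precision, recovery)
    path.with_suffix(".txt").write_text(txt)
    return report


def render_validation_table(curves, precision, recovery) -> str:
    """Rendered validation table: one analyte per column, 13 metric rows."""
    precision = precision or {}
    recovery = recovery or {}
    names = [c.analyte for c in curves]
    rows: list[tuple[str, list[str]]] = []

    def levels_of(store):
        lv = sorted({l for a in store.values() for l in a})
        return lv

    rows.append(("Linearity range (mM)", [
        f"{_fmt_conc(c.linearity_range[0])}-{_fmt_conc(c.linearity_range[1])}"
        if c.linearity_range else "-" for c in curves]))
    rows.append(("Regression equation", [c.equation() for c in curves]))
    rows.append(("R^2", [f"{c.r_squared:.4f}" for c in curves]))
    rows.append(("LOD (mM)", [_fmt_conc(c.lod) for c in curves]))
    rows.append(("LOQ (mM)", [_fmt_conc(c.loq) for c in curves]))
    rows.append(("Repeatability (RSD, %)", ["" for _ in curves]))
    plevels = levels_of(precision) or [None, None, None]
    for level in plevels:
        vals = []
        for c in curves:
            pr = precision.get(c.analyte, {}).get(level)
            vals.append(_fmt_pct(pr.rsd) if pr is not None else "-")
        label = f"  at {level} mM" if level is not None else "  -"
        rows.append((label, vals))
    rows.append(("Recovery (R, %)", ["" for _ in curves]))
    rlevels = levels_of(recovery) or [None, None, None]
    for level in rlevels:
        vals = []
        for c in curves:
            rr = recovery.get(c.analyte, {}).get(level)
            vals.append(
                f"{_fmt_pct(rr.recovery)} +- {_fmt_pct(rr.recovery_sd)}"
                if rr is not None else "-")
        label = f"  at {level} mM" if level is not None else "  -"
        rows.append((label, vals))

    label_w = max((len(r[0]) for r in rows), default=10)
    col_ws = [max(len(n), max((len(r[1][i]) for r in rows), default=1))
              for i, n in enumerate(names)]
    out = [" " * label_w + "  " + "  ".join(
        n.rjust(w) for n, w in zip(names, col_ws))]
    for label, vals in rows:
        out.append(label.ljust(label_w) + "  " + "  ".join(
            v.rjust(w) for v, w in zip(vals, col_ws)))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    area_cv: float = 0.005
    baseline_sd: float = 0.02
    baseline_drift: float = 0.0
    seed: int = 0


class DetectionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_height: float = 0.1        # 5 x default baseline_sd
    min_prominence: float = 0.06   # 3 x default baseline_sd
    baseline_window: float = 2.0   # min
    assignment_tolerance: float = 0.15  # min


class CalibrationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    through_origin: bool = True
    sigma_mode: str = Field("slope_sd", pattern="^(slope_sd|residual_sd)$")


class ElectroConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    selectivity_mode: str = Field("mole", pattern="^(mole|carbon|electron)$")
    volume_L: float | None = None
    charge_C: float | None = None
    z_overrides: dict[str, float] = {}
    include_below_loq: bool = False


class RunConfig(BaseModel):
    """Whole-run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    library_overrides: dict[str, dict[str, Any]] = {}
    noise: NoiseConfig = NoiseConfig()
    detection: DetectionConfig = DetectionConfig()
    calibration: CalibrationConfig = CalibrationConfig()
    electrochem: ElectroConfig = ElectroConfig()

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.model_dump_json(indent=2) + "\n")
        return path
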