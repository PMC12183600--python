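"""Synthetic HPLC-DAD chromatograms for the glycerol electrooxidation panel.

The glycerol electrooxidation reaction (GEOR) yields a panel of C1-C3
oxygenates — oxalic (OA), tartronic (TA), glyceric (GA), glycolic (GCA),
formic (FA) acids, glyceraldehyde (GlyAld), dihydroxyacetone (DHA) — plus
unconverted glycerol.  An ion-exclusion HPLC separation with a diode array
detector records absorbance at 205 nm (all analytes) and 300 nm (GlyAld),
with FA and GlyAld co-eluting in a single merged peak.

This module emulates that instrument: each analyte contributes a Gaussian
(optionally exponentially modified Gaussian) peak whose area at wavelength
``λ`` is ``response[λ] · concentration · ε``, with ``ε`` a lognormal
injection-repeatability factor, on top of additive baseline noise and
optional linear drift.  Areas are exactly proportional to concentration in
the noise-free limit, which is what makes closed-form oracles possible
downstream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Mapping, Sequence
import warnings

import numpy as np
from scipy import special

__all__ = [
    "CompoundSpec",
    "CompoundLibrary",
    "NoiseModel",
    "Chromatogram",
    "DEFAULT_GRID",
    "PANEL",
    "default_library",
    "simulate_injection",
    "simulate_calibration_series",
    "simulate_electrolysis_sample",
    "gaussian_peak",
    "emg_peak",
]

#: default acquisition grid: 30 min run sampled every 0.01 min
DEFAULT_GRID: tuple[float, float, float] = (0.0, 30.0, 0.01)

#: the eight validated analytes (the quantification panel)
PANEL: tuple[str, ...] = (
    "OA", "TA", "GA", "GCA", "FA", "GlyAld", "DHA", "glycerol",
)

#: acid-quench dilution: 1000 uL sample + 250 uL 0.5 M H2SO4
QUENCH_DILUTION_FACTOR: float = 1.25

#: retention time of the alkaline-matrix salt peak (min)
SALT_RETENTION_TIME: float = 11.38


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundSpec:
    """One analyte of the panel.

    Parameters
    ----------
    name
        Short panel identifier (``"OA"``, ``"GlyAld"``, ...).
    retention_time
        Peak apex position in minutes under the fixed separation conditions.
    peak_sigma
        Gaussian standard deviation of the peak, minutes.
    response
        Map wavelength (nm) -> calibration slope in area-units per mM.
    z_electrons
        Electrons transferred per mole of product formed from glycerol
        (oxidation-state bookkeeping; exact rational).
    n_carbons
        Carbon atoms per molecule (for carbon-basis selectivity).
    linear_range
        Validated linear concentration range (low, high) in mM.
    full_name
        Human-readable name used in reports.
    """

    name: str
    retention_time: float
    peak_sigma: float
    response: Mapping[int, float]
    z_electrons: Fraction
    n_carbons: int
    linear_range: tuple[float, float]
    full_name: str = ""

    def __post_init__(self) -> None:
        if self.retention_time <= 0:
            raise ValueError(f"{self.name}: retention_time must be > 0")
        if self.peak_sigma <= 0:
            raise ValueError(f"{self.name}: peak_sigma must be > 0")
        if any(m < 0 for m in self.response.values()):
            raise ValueError(f"{self.name}: response slopes must be >= 0")
        lo, hi = self.linear_range
        if not lo < hi:
            raise ValueError(f"{self.name}: linear_range low must be < high")


@dataclass(frozen=True)
class CompoundLibrary:
    """The analyte panel: retention times, response factors, bookkeeping."""

    entries: tuple[CompoundSpec, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("duplicate analyte names in library")

    def __contains__(self, name: str) -> bool:
        return any(e.name == name for e in self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    def get(self, name: str) -> CompoundSpec:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(f"analyte {name!r} not in library")

    def subset(self, names: Sequence[str]) -> "CompoundLibrary":
        """Library restricted to ``names`` (order preserved)."""
        return CompoundLibrary(tuple(self.get(n) for n in names))


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic structure of a simulated injection.

    ``area_cv`` is the fractional coefficient of variation of the injected
    amount (multiplicative, lognormal, unit mean); ``baseline_sd`` is
    additive white detector noise in absorbance units; ``baseline_drift``
    a linear drift in absorbance units per minute.  Identical seed and
    inputs give bit-identical chromatograms.
    """

    area_cv: float = 0.005
    baseline_sd: float = 0.02
    baseline_drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.area_cv < 0:
            raise ValueError("area_cv must be >= 0")
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be >= 0")

    def child(self, *tokens) -> "NoiseModel":
        """Noise model with a seed derived stably from ``tokens``."""
        return replace(self, seed=derive_seed(self.seed, *tokens))


ZERO_NOISE = NoiseModel(area_cv=0.0, baseline_sd=0.0, baseline_drift=0.0, seed=0)


@dataclass
class Chromatogram:
    """A time grid with one absorbance trace per recorded wavelength."""

    times: np.ndarray
    traces: dict[int, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size < 2:
            raise ValueError("time grid needs at least 2 points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        for wl, tr in self.traces.items():
            tr = np.asarray(tr, dtype=float)
            if tr.shape != self.times.shape:
                raise ValueError(
                    f"trace at {wl} nm has length {tr.size}, "
                    f"grid has {self.times.size}"
                )
            self.traces[wl] = tr

    @property
    def wavelengths(self) -> tuple[int, ...]:
        return tuple(sorted(self.traces))

    def trace(self, wavelength: int) -> np.ndarray:
        try:
            return self.traces[wavelength]
        except KeyError:
            raise KeyError(
                f"no trace recorded at {wavelength} nm "
                f"(available: {sorted(self.traces)})"
            ) from None


# ---------------------------------------------------------------------------
# default panel
# ---------------------------------------------------------------------------

DEFAULT_PEAK_SIGMA = 0.12  # min; partially overlaps lactic/glycolic only

# GlyAld's 300 nm slope is not validated in the main calibration table; this
# default is a configurable placeholder that every algorithm treats as data.
GLYALD_300NM_SLOPE_DEFAULT = 4000.0

_STANDARD_RANGE = (0.1, 5.0)

_DEFAULT_SPECS: tuple[CompoundSpec, ...] = (
    CompoundSpec("salt", SALT_RETENTION_TIME, DEFAULT_PEAK_SIGMA,
                 {205: 5000.0, 300: 0.0}, Fraction(0), 0, (0.1, 10.0),
                 "matrix salt (alkaline quench artifact)"),
    CompoundSpec("OA", 12.37, DEFAULT_PEAK_SIGMA,
                 {205: 167894.0, 300: 0.0}, Fraction(22, 3), 2,
                 _STANDARD_RANGE, "oxalic acid"),
    CompoundSpec("TA", 13.64, DEFAULT_PEAK_SIGMA,
                 {205: 34133.0, 300: 0.0}, Fraction(8), 3,
                 _STANDARD_RANGE, "tartronic acid"),
    CompoundSpec("GA", 17.13, DEFAULT_PEAK_SIGMA,
                 {205: 9994.0, 300: 0.0}, Fraction(4), 3,
                 _STANDARD_RANGE, "glyceric acid"),
    CompoundSpec("lactic", 17.88, DEFAULT_PEAK_SIGMA,
                 {205: 7000.0, 300: 0.0}, Fraction(2), 3,
                 _STANDARD_RANGE, "lactic acid"),
    CompoundSpec("GCA", 18.31, DEFAULT_PEAK_SIGMA,
                 {205: 7441.0, 300: 0.0}, Fraction(10, 3), 2,
                 _STANDARD_RANGE, "glycolic acid"),
    CompoundSpec("FA", 19.46, DEFAULT_PEAK_SIGMA,
                 {205: 6309.0, 300: 0.0}, Fraction(8, 3), 1,
                 _STANDARD_RANGE, "formic acid"),
    CompoundSpec("GlyAld", 19.46, DEFAULT_PEAK_SIGMA,
                 {205: 12566.0, 300: GLYALD_300NM_SLOPE_DEFAULT},
                 Fraction(2), 3, _STANDARD_RANGE, "glyceraldehyde"),
    CompoundSpec("DHA", 20.76, DEFAULT_PEAK_SIGMA,
                 {205: 17903.0, 300: 0.0}, Fraction(2), 3,
                 _STANDARD_RANGE, "dihydroxyacetone"),
    CompoundSpec("glycerol", 22.46, DEFAULT_PEAK_SIGMA,
                 {205: 30.6, 300: 0.0}, Fraction(0), 3,
                 (16.0, 40.0), "glycerol"),
)


def default_library(
    overrides: Mapping[str, Mapping[str, object]] | None = None,
    include_extras: bool = True,
) -> CompoundLibrary:
    """The GEOR analyte library with optional per-analyte field overrides.

    Parameters
    ----------
    overrides
        ``{analyte_name: {field: value}}`` partial updates; only known
        analyte names are accepted.
    include_extras
        Keep the lactic-acid entry and the alkaline salt pseudo-analyte in
        addition to the eight validated panel analytes.

    Returns
    -------
    CompoundLibrary
        FA and GlyAld share retention time 19.46 min by construction (their
        co-elution is a property of the separation, not of any sample).
    """
    overrides = dict(overrides or {})
    known = {s.name for s in _DEFAULT_SPECS}
    unknown = sorted(set(overrides) - known)
    if unknown:
        raise KeyError(f"unknown analyte name(s) in overrides: {unknown}")
    specs = []
    for spec in _DEFAULT_SPECS:
        if not include_extras and spec.name in ("lactic", "salt"):
            continue
        if spec.name in overrides:
            fields = dict(overrides[spec.name])
            if "linear_range" in fields:
                fields["linear_range"] = tuple(fields["linear_range"])  # type: ignore[arg-type]
            if "response" in fields:
                fields["response"] = {int(k): float(v)
                                      for k, v in dict(fields["response"]).items()}  # type: ignore[call-overload]
            if "z_electrons" in fields and not isinstance(fields["z_electrons"], Fraction):
                fields["z_electrons"] = Fraction(str(fields["z_electrons"]))
            spec = replace(spec, **fields)  # type: ignore[arg-type]
        specs.append(spec)
    return CompoundLibrary(tuple(specs))


# ---------------------------------------------------------------------------
# peak shapes
# ---------------------------------------------------------------------------

def gaussian_peak(t: np.ndarray, area: float, center: float,
                  sigma: float) -> np.ndarray:
    """Gaussian with total integral ``area``."""
    z = (t - center) / sigma
    return area / (sigma * np.sqrt(2.0 * np.pi)) * np.exp(-0.5 * z * z)


def emg_peak(t: np.ndarray, area: float, center: float, sigma: float,
             tau: float) -> np.ndarray:
    """Exponentially modified Gaussian (right-tailed) with integral ``area``.

    ``tau`` is the exponential time constant in minutes; the limit
    ``tau -> 0`` recovers the pure Gaussian.
    """
    if tau <= 0:
        return gaussian_peak(t, area, center, sigma)
    # scipy-style stable evaluation via scaled complementary error function
    arg = (sigma / tau - (t - center) / sigma) / np.sqrt(2.0)
    out = (area / (2.0 * tau)
           * np.exp(0.5 * (sigma / tau) ** 2 - (t - center) / tau)
           * special.erfc(arg))
    # guard overflow far into the left wing
    return np.where(np.isfinite(out), out, 0.0)


def derive_seed(root: int, *tokens) -> int:
    """Stable sub-seed (< 2**31) from a root seed and hashable tokens."""
    digest = zlib.crc32(repr(tokens).encode("utf8")) & 0x7FFFFFFF
    return (int(root) * 2654435761 + digest) % (2**31 - 1)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_injection(
    sample: Mapping[str, float],
    library: CompoundLibrary,
    noise: NoiseModel = ZERO_NOISE,
    grid: tuple[float, float, float] = DEFAULT_GRID,
    peak_shape: str = "gaussian",
    emg_tau: float = 0.05,
    meta: Mapping[str, object] | None = None,
) -> Chromatogram:
    """Render one injection of ``sample`` as a two-wavelength chromatogram.

    Each analyte contributes, at every recorded wavelength, a peak of area
    ``response[wl] * concentration * eps`` centred at its retention time,
    where ``eps`` is a unit-mean lognormal injection factor with coefficient
    of variation ``noise.area_cv`` (one draw per analyte, shared across
    wavelengths — injected amount, not detector, varies).  Additive white
    noise of sd ``noise.baseline_sd`` and linear drift complete the trace.

    Raises
    ------
    KeyError
        For analytes absent from ``library``.
    ValueError
        For negative concentrations or a grid not covering every present
        analyte's peak to +-5 sigma.
    """
    t0, t1, dt = grid
    if not (t1 > t0 and dt > 0):
        raise ValueError("grid must satisfy t_end > t_start and dt > 0")
    times = np.arange(t0, t1 + 0.5 * dt, dt)

    present = sorted(sample)
    for name in present:
        if name not in library:
            raise KeyError(f"analyte {name!r} not in library")
        if sample[name] < 0:
            raise ValueError(f"negative concentration for {name!r}")
        spec = library.get(name)
        if sample[name] > 0:
            if (spec.retention_time - 5 * spec.peak_sigma < t0
                    or spec.retention_time + 5 * spec.peak_sigma > t1):
                raise ValueError(
                    f"grid does not cover {name!r} peak to +-5 sigma"
                )
            if dt > spec.peak_sigma / 5.0:
                warnings.warn(
                    f"grid step {dt} min is coarse for {name!r} "
                    f"(peak_sigma {spec.peak_sigma} min); integration "
                    "accuracy degrades", stacklevel=2,
                )

    wavelengths = sorted({wl for e in library for wl in e.response})
    rng = np.random.default_rng(noise.seed)

    # unit-mean lognormal injection factor per analyte, in sorted-name order
    eps: dict[str, float] = {}
    for name in present:
        if noise.area_cv > 0:
            s2 = np.log1p(noise.area_cv**2)
            eps[name] = float(rng.lognormal(mean=-0.5 * s2,
                                            sigma=np.sqrt(s2)))
        else:
            eps[name] = 1.0

    traces: dict[int, np.ndarray] = {}
    for wl in wavelengths:
        trace = np.zeros_like(times)
        for name in present:
            conc = sample[name]
            if conc == 0:
                continue
            spec = library.get(name)
            m = spec.response.get(wl, 0.0)
            if m == 0.0:
                continue
            area = m * conc * eps[name]
            if peak_shape == "gaussian":
                trace += gaussian_peak(times, area, spec.retention_time,
                                       spec.peak_sigma)
            elif peak_shape == "emg":
                trace += emg_peak(times, area, spec.retention_time,
                                  spec.peak_sigma, emg_tau)
            else:
                raise ValueError(f"unknown peak_shape {peak_shape!r}")
        if noise.baseline_sd > 0:
            trace = trace + rng.normal(0.0, noise.baseline_sd, times.size)
        if noise.baseline_drift != 0.0:
            trace = trace + noise.baseline_drift * times
        traces[wl] = trace

    base_meta = {
        "matrix": "standard",
        "dilution_factor": 1.0,
        "injection_id": "",
        "seed": noise.seed,
    }
    base_meta.update(meta or {})
    return Chromatogram(times=times, traces=traces, meta=base_meta)


def simulate_calibration_series(
    analyte: str,
    levels: Sequence[float],
    replicates: int,
    library: CompoundLibrary,
    noise: NoiseModel = ZERO_NOISE,
    grid: tuple[float, float, float] = DEFAULT_GRID,
) -> list[Chromatogram]:
    """Simulated calibration standards: ``replicates`` injections per level.

    Per-injection random streams are derived deterministically from
    ``noise.seed`` and the (analyte, level index, replicate index) triple,
    so the series is reproducible and insensitive to evaluation order.
    Levels outside the analyte's validated linear range only warn.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    spec = library.get(analyte)
    lo, hi = spec.linear_range
    for c in levels:
        if not (lo <= c <= hi):
            warnings.warn(
                f"level {c} mM outside {analyte}'s linear range "
                f"({lo}-{hi} mM)", stacklevel=2,
            )
    out = []
    for i, level in enumerate(levels):
        for r in range(replicates):
            child = noise.child(analyte, i, r)
            chrom = simulate_injection(
                {analyte: float(level)}, library, child, grid,
                meta={
                    "injection_id": f"{analyte}-L{i}-R{r}",
                    "level_mM": float(level),
                    "replicate": r,
                },
            )
            out.append(chrom)
    return out


def simulate_electrolysis_sample(
    products: Mapping[str, float],
    matrix: str,
    library: CompoundLibrary,
    noise: NoiseModel = ZERO_NOISE,
    grid: tuple[float, float, float] = DEFAULT_GRID,
    salt_level_mM: float = 1.0,
    injection_id: str = "electrolysis",
) -> Chromatogram:
    """One quenched electrolysis aliquot rendered as a chromatogram.

    Cell concentrations are divided by the acid-quench dilution factor 1.25
    (1000 uL aliquot + 250 uL 0.5 M H2SO4) before injection; an alkaline
    matrix additionally shows the salt pseudo-peak at 11.38 min.  The
    returned metadata records ``dilution_factor`` so downstream
    quantification can restore cell concentrations.
    """
    if matrix not in ("alkaline", "acidic"):
        raise ValueError(f"unknown matrix {matrix!r}; use 'alkaline' or 'acidic'")
    for name in products:
        if name not in library:
            raise KeyError(f"product {name!r} not in library")
    injected = {name: conc / QUENCH_DILUTION_FACTOR
                for name, conc in products.items()}
    if matrix == "alkaline":
        if "salt" not in library:
            raise KeyError(
                "alkaline matrix requires the 'salt' pseudo-analyte in the "
                "library (default_library(include_extras=True))"
            )
        injected["salt"] = salt_level_mM
    return simulate_injection(
        injected, library, noise, grid,
        meta={
            "matrix": matrix,
            "dilution_factor": QUENCH_DILUTION_FACTOR,
            "injection_id": injection_id,
        },
    )
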