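"""Selectivity and Faradaic-efficiency accounting for electrolysis runs.

Quantified product concentrations, the passed charge and the cell volume
are turned into the two headline numbers of a glycerol electrooxidation
experiment: the product selectivity distribution and the overall Faradaic
efficiency (FE).

FE is plain charge bookkeeping.  Forming ``n_i`` moles of product ``i``
from glycerol requires ``z_i`` electrons per mole (oxidation-state
bookkeeping relative to glycerol's mean carbon oxidation state of -2/3:
GlyAld and DHA 2, glyceric 4, tartronic 8, glycolic 10/3, formic 8/3,
oxalic 22/3), so

    FE(%) = 100 * F * sum_i z_i * C_i * V / Q

with F = 96485 C/mol, C_i the cell concentration (dilution-corrected),
V the electrolyte volume and Q the passed charge.  Gaseous products
(CO2, O2) are invisible to HPLC, so FE below 100 % is reported as-is.

Selectivity supports three bases — mole fraction (default), carbon-weighted
and electron-weighted — because per-product bar percentages in this field
are composition fractions but conventions vary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .simulate import CompoundLibrary, default_library

__all__ = [
    "FARADAY",
    "ElectrolysisResult",
    "correct_dilution",
    "selectivity",
    "faradaic_efficiency",
    "charge_fraction",
    "summarize_electrolysis",
]

#: Faraday constant, C per mole of electrons
FARADAY = 96485.0

_MODES = ("mole", "carbon", "electron")


@dataclass
class ElectrolysisResult:
    """Quantified electrolysis outcome with charge bookkeeping."""

    products: dict[str, float]          # cell concentrations, mM
    volume: float                       # liters
    charge_Q: float                     # coulombs
    z_table: dict[str, float]           # electrons per mole formed
    n_carbon_table: dict[str, int] = field(default_factory=dict)
    selectivity: dict[str, float] = field(default_factory=dict)  # percent
    fe_percent: float = 0.0
    selectivity_mode: str = "mole"
    flags: list[str] = field(default_factory=list)


def correct_dilution(measured_mM: float, dilution_factor: float) -> float:
    """Undo the acid-quench dilution: cell = measured * factor.

    The default sample treatment (1000 uL aliquot + 250 uL 0.5 M H2SO4)
    gives factor 1250/1000 = 1.25.
    """
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    if measured_mM < 0:
        raise ValueError("measured concentration must be >= 0")
    return measured_mM * dilution_factor


def _weights(names, mode: str, library: CompoundLibrary):
    if mode == "mole":
        return {n: 1.0 for n in names}
    if mode == "carbon":
        return {n: float(library.get(n).n_carbons) for n in names}
    if mode == "electron":
        return {n: float(library.get(n).z_electrons) for n in names}
    raise ValueError(f"unknown selectivity mode {mode!r}; use one of {_MODES}")


def selectivity(
    products: Mapping[str, float],
    mode: str = "mole",
    library: CompoundLibrary | None = None,
) -> dict[str, float]:
    """Percentage share of each product in the quantified distribution.

    ``mole`` (default): 100 * C_i / sum C_j; ``carbon`` weights each
    concentration by carbon count; ``electron`` by electrons transferred.
    The returned percentages always sum to 100.
    """
    if any(c < 0 for c in products.values()):
        raise ValueError("product concentrations must be >= 0")
    total_pos = {n: c for n, c in products.items() if c > 0}
    if not total_pos:
        raise ValueError("no products with positive concentration")
    library = library or default_library()
    w = _weights(products, mode, library)
    denom = sum(w[n] * c for n, c in products.items())
    if denom <= 0:
        raise ValueError(
            f"all products carry zero weight in mode {mode!r}"
        )
    return {n: 100.0 * w[n] * c / denom for n, c in products.items()}


def faradaic_efficiency(result: ElectrolysisResult) -> float:
    """FE(%) = 100 * F * sum_i z_i C_i V / Q over the quantified products."""
    if result.charge_Q <= 0:
        raise ValueError("charge_Q must be > 0")
    if result.volume <= 0:
        raise ValueError("volume must be > 0")
    total = 0.0
    for name, c_mM in result.products.items():
        if c_mM == 0:
            continue
        if name not in result.z_table:
            raise KeyError(f"no electrons-per-mole entry for product {name!r}")
        total += result.z_table[name] * (c_mM * 1e-3) * result.volume
    return 100.0 * FARADAY * total / result.charge_Q


def charge_fraction(
    c0_glycerol_mM: float,
    volume_L: float,
    z: float,
    charge_Q: float,
) -> float:
    """Passed charge as % of full conversion of the starting glycerol.

    ``100 * Q / (z * F * c0 * V)`` — e.g. the charge required to turn the
    whole glycerol inventory into a z-electron product.
    """
    if c0_glycerol_mM <= 0 or volume_L <= 0 or z <= 0:
        raise ValueError("c0, volume and z must be > 0")
    if charge_Q < 0:
        raise ValueError("charge must be >= 0")
    full = z * FARADAY * (c0_glycerol_mM * 1e-3) * volume_L
    return 100.0 * charge_Q / full


def summarize_electrolysis(
    measured_mM: Mapping[str, float],
    dilution_factor: float,
    volume_L: float,
    charge_Q: float,
    library: CompoundLibrary | None = None,
    selectivity_mode: str = "mole",
    z_overrides: Mapping[str, float] | None = None,
    loq_mM: Mapping[str, float] | None = None,
    include_below_loq: bool = False,
) -> ElectrolysisResult:
    """Assemble the full electrolysis summary from measured concentrations.

    Measured (injected) concentrations are dilution-corrected to cell
    concentrations; products below their LOQ are excluded from both
    selectivity and FE unless ``include_below_loq`` is set (exclusions are
    flagged).  ``z_overrides`` replaces library electron counts per analyte.
    """
    library = library or default_library()
    flags: list[str] = []
    cell: dict[str, float] = {}
    for name, c in measured_mM.items():
        cc = correct_dilution(c, dilution_factor)
        if loq_mM is not None and name in loq_mM and not include_below_loq:
            # LOQ is defined on the injected scale; compare there
            if c < loq_mM[name]:
                flags.append(f"{name}: below LOQ, excluded")
                continue
        cell[name] = cc
    z_table = {n: float(library.get(n).z_electrons) for n in cell}
    z_table.update({k: float(v) for k, v in (z_overrides or {}).items()})
    result = ElectrolysisResult(
        products=cell,
        volume=volume_L,
        charge_Q=charge_Q,
        z_table=z_table,
        n_carbon_table={n: library.get(n).n_carbons for n in cell},
        selectivity_mode=selectivity_mode,
        flags=flags,
    )
    result.selectivity = selectivity(cell, selectivity_mode, library)
    result.fe_percent = faradaic_efficiency(result)
    return result
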