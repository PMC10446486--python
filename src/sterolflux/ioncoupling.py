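"""Electrochemical ion gradients and transport coupling stoichiometry.

The free energy of moving one mole of ion from the extracellular to the
intracellular side of a membrane is

    ΔG = RT ln(c_in / c_out) + z F ΔV,

with ΔV = V_in − V_out (so a physiological resting potential is negative)
and z the ion charge in elementary units.  Negative ΔG means influx is
favorable.  A transporter that must pay an export cost ΔG_export > 0 can
harvest the downhill electrochemical energy of n coupling ions; the
predicted stoichiometry is the ceiling of ΔG_export divided by the energy
released per ion in its coupling direction.

Sign conventions, worth restating because they bite: `electrochemical_dg`
is always quoted for the out→in (influx) direction.  An influx-coupled ion
(Na⁺ here) drives transport with −ΔG; an efflux-coupled ion (K⁺) drives it
with +ΔG.  The coupling direction is an explicit argument, never inferred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import FARADAY, R_KJ

__all__ = [
    "IonSpecies",
    "MembraneCondition",
    "StoichiometryCurve",
    "CouplingResult",
    "SODIUM",
    "POTASSIUM",
    "electrochemical_dg",
    "nernst_potential",
    "coupling_ions",
    "stoichiometry_curve",
]


@dataclass(frozen=True)
class IonSpecies:
    """An ion with its intra-/extracellular concentrations (mM)."""

    name: str
    z: int
    c_in: float
    c_out: float

    def __post_init__(self) -> None:
        if self.c_in <= 0 or self.c_out <= 0:
            raise ValueError("concentrations must be positive")
        if self.z == 0:
            raise ValueError("ion charge must be nonzero")

    def reversed_gradient(self) -> "IonSpecies":
        return replace(self, c_in=self.c_out, c_out=self.c_in)


#: Standard cellular concentrations used throughout: Na⁺ 12 mM in / 145 mM out.
SODIUM = IonSpecies("Na+", z=+1, c_in=12.0, c_out=145.0)

#: K⁺ 150 mM in / 4 mM out.
POTASSIUM = IonSpecies("K+", z=+1, c_in=150.0, c_out=4.0)


@dataclass(frozen=True)
class MembraneCondition:
    """Membrane potential ΔV = V_in − V_out (mV) and temperature (K)."""

    delta_v: float
    temperature: float = 310.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def electrochemical_dg(ion: IonSpecies, cond: MembraneCondition) -> float:
    """ΔG (kJ·mol⁻¹) of moving one mole of the ion from outside to inside.

    ΔG = RT ln(c_in/c_out) + zFΔV.  Negative means influx is favorable.
    """
    chemical = R_KJ * cond.temperature * math.log(ion.c_in / ion.c_out)
    electrical = ion.z * FARADAY * (cond.delta_v * 1e-3) * 1e-3  # C/mol·V → kJ/mol
    return chemical + electrical


def nernst_potential(ion: IonSpecies, temperature: float = 310.0) -> float:
    """Equilibrium potential (mV) at which the ion's electrochemical ΔG is zero.

    ΔV_eq = −(RT / zF) ln(c_in/c_out).
    """
    rt = R_KJ * temperature * 1e3  # J/mol
    return -(rt / (ion.z * FARADAY)) * math.log(ion.c_in / ion.c_out) * 1e3


@dataclass(frozen=True)
class CouplingResult:
    """Stoichiometry prediction for one export cost and one condition."""

    ion: IonSpecies
    condition: MembraneCondition
    direction: str
    export_dg: float
    driving_energy: float       # kJ/mol released per ion in its coupling direction
    ratio: float | None         # export_dg / driving_energy, None when infeasible
    count: int | None           # ceiling(ratio)
    feasible: bool


def _driving_energy(ion: IonSpecies, cond: MembraneCondition, direction: str) -> float:
    dg_in = electrochemical_dg(ion, cond)
    if direction == "influx":
        return -dg_in
    if direction == "efflux":
        return dg_in
    raise ValueError("transport_direction must be 'influx' or 'efflux'")


def coupling_ions(
    export_dg: float,
    ion: IonSpecies,
    cond: MembraneCondition,
    transport_direction: str,
) -> CouplingResult:
    """Number of coupling ions needed to pay an export cost.

    ``export_dg`` must be positive (a favorable export needs no coupling).
    The driving energy is what one ion releases moving in
    ``transport_direction``; if it is not positive the coupling is
    infeasible at this potential (e.g. K⁺ efflux beyond its equilibrium
    potential).  Otherwise ratio = export_dg / driving and the integer
    stoichiometry is its ceiling.
    """
    if export_dg <= 0:
        raise ValueError("export_dg must be positive; favorable transport needs no coupling")
    driving = _driving_energy(ion, cond, transport_direction)
    if driving <= 0:
        return CouplingResult(ion, cond, transport_direction, export_dg, driving,
                              ratio=None, count=None, feasible=False)
    ratio = export_dg / driving
    return CouplingResult(ion, cond, transport_direction, export_dg, driving,
                          ratio=ratio, count=math.ceil(ratio), feasible=True)


@dataclass
class StoichiometryCurve:
    """Coupling-ion requirement across a membrane-potential grid.

    One curve per export cost: the per-ion driving energy, the continuous
    ratio (as plotted), the integer ceiling count, and a feasibility mask
    (False where the ion cannot drive transport at that potential).
    """

    ion: IonSpecies
    direction: str
    export_dg: float
    temperature: float
    delta_v: np.ndarray
    driving_energy: np.ndarray
    ratio: np.ndarray           # NaN where infeasible
    count: np.ndarray           # float array with NaN where infeasible
    feasible: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "delta_v_mV": self.delta_v,
                "driving_kJ_per_mol": self.driving_energy,
                "ratio": self.ratio,
                "count": self.count,
                "feasible": self.feasible,
                "export_dg": self.export_dg,
                "ion": self.ion.name,
                "direction": self.direction,
            }
        )

    def plot(self, ax=None, continuous: bool = True):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = self.ratio if continuous else self.count
        ax.plot(self.delta_v, y, label=f"{self.ion.name} {self.export_dg:g} kJ/mol")
        ax.set_xlabel("membrane potential ΔV (mV)")
        ax.set_ylabel("coupling ions per substrate")
        ax.legend()
        return ax


def stoichiometry_curve(
    export_dgs: Iterable[float],
    ion: IonSpecies,
    delta_v_grid: Sequence[float],
    temperature: float = 310.0,
    transport_direction: str = "influx",
) -> list[StoichiometryCurve]:
    """Tabulate coupling-ion curves over a ΔV grid, one per export cost."""
    dv = np.asarray(list(delta_v_grid), dtype=float)
    if dv.size == 0:
        raise ValueError("delta_v grid must be nonempty")
    exports = [float(e) for e in export_dgs]
    if not exports:
        raise ValueError("at least one export ΔG is required")
    driving = np.array(
        [_driving_energy(ion, MembraneCondition(v, temperature), transport_direction) for v in dv]
    )
    curves = []
    for e in exports:
        if e <= 0:
            raise ValueError("export ΔG values must be positive")
        feasible = driving > 0
        ratio = np.where(feasible, e / np.where(feasible, driving, 1.0), np.nan)
        count = np.where(feasible, np.ceil(ratio), np.nan)
        curves.append(
            StoichiometryCurve(
                ion=ion,
                direction=transport_direction,
                export_dg=e,
                temperature=temperature,
                delta_v=dv.copy(),
                driving_energy=driving.copy(),
                ratio=ratio,
                count=count,
                feasible=feasible,
            )
        )
    return curves
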