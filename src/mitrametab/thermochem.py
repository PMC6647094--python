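"""Rigid-rotor harmonic-oscillator thermochemistry and aqueous standard
Gibbs energies.

Each species' gas-phase Gibbs energy is assembled from its electronic
energy plus ideal-gas statistical-mechanics contributions at temperature T:

* translation — Sackur–Tetrode entropy at 1 atm, 3/2 RT thermal energy;
* rotation — classical rigid rotor with symmetry number (monoatomic,
  linear and nonlinear cases);
* vibration — harmonic oscillators from the unscaled frequencies, with
  zero-point energy Sum(1/2 h nu);
* electronic — spin degeneracy only.

The aqueous standard Gibbs energy adds the gas->solution standard-state
correction RT ln(c * RT/P) (about +1.89 kcal/mol for 1 M at 298.15 K, with
an extra RT ln(55.34) for liquid water at 55.34 M) and the implicit-solvent
transfer free energy carried on the record.  If the solvation energy was
produced under a convention that already contains the 1 atm -> 1 M term,
set ``solvation_includes_1M=True`` and only the RT ln(c/1 M) part is added.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .constants import (
    AMU,
    C_LIGHT,
    H_PLANCK,
    HARTREE_TO_KCAL,
    J_PER_KCAL,
    KB,
    N_A,
    P_STANDARD,
    R_CAL,
    R_KCAL,
    T_STANDARD,
)
from .qmio import SpeciesRecord

__all__ = [
    "ThermoError",
    "ThermoResult",
    "ReactionEnergy",
    "rrho_thermo",
    "standard_state_correction",
    "gibbs_aqueous",
    "reaction_energy",
    "thermo_table",
]


class ThermoError(ValueError):
    """Refused or impossible thermochemistry computation."""


@dataclass(frozen=True)
class ThermoResult:
    """Derived thermochemistry of one species at a fixed temperature.

    Energies are in kcal/mol on the absolute electronic-energy scale
    (electronic energy converted at 1 hartree = 627.5095 kcal/mol);
    entropy is in cal/(mol K).
    """

    label: str
    temperature: float  # K
    zpe: float  # kcal/mol
    thermal_enthalpy_correction: float  # kcal/mol, ZPE + thermal + RT
    entropy: float  # cal/(mol K)
    gibbs_gas_1atm: float  # kcal/mol
    gibbs_gas_1M: float  # kcal/mol
    gibbs_aqueous: float | None = None  # kcal/mol

    @property
    def enthalpy(self) -> float:
        """H = E_elec + thermal enthalpy correction, kcal/mol."""
        return self.gibbs_gas_1atm + self.temperature * self.entropy / 1000.0


def _vibrational_terms(frequencies: np.ndarray, T: float):
    """(ZPE kcal/mol, thermal E kcal/mol, S cal/(mol K)) for harmonic modes."""
    nu = frequencies * 100.0 * C_LIGHT  # cm^-1 -> Hz
    theta = H_PLANCK * nu / KB  # K
    zpe = 0.5 * H_PLANCK * nu.sum() * N_A / J_PER_KCAL if nu.size else 0.0
    if not nu.size:
        return 0.0, 0.0, 0.0
    # x/(e^x - 1) and ln(1 - e^-x) via expm1/log1p for numerical stability;
    # overflow of e^x at very low T is benign (terms go to zero)
    x = theta / T
    with np.errstate(over="ignore"):
        expm = np.expm1(x)
        e_therm = R_KCAL * (theta / expm).sum()
        s_vib = R_CAL * ((x / expm) - np.log1p(-np.exp(-x))).sum()
    return zpe, e_therm, s_vib


def rrho_thermo(record: SpeciesRecord, T: float = T_STANDARD) -> ThermoResult:
    """Gas-phase RRHO thermochemistry of one species at 1 atm."""
    if T <= 0:
        raise ThermoError("temperature must be positive")
    if any(f <= 0 for f in record.frequencies):
        raise ThermoError(
            f"{record.label}: imaginary/zero frequency present; not a confirmed minimum"
        )
    if record.is_monoatomic and record.frequencies:
        raise ThermoError(
            f"{record.label}: monoatomic species cannot carry vibrational frequencies"
        )

    # translation
    m_kg = record.masses.sum() * AMU
    q_trans = (2.0 * math.pi * m_kg * KB * T / H_PLANCK**2) ** 1.5 * (
        KB * T / P_STANDARD
    )
    s_trans = R_CAL * (math.log(q_trans) + 2.5)
    e_trans = 1.5 * R_KCAL * T

    # rotation
    if record.is_monoatomic:
        s_rot, e_rot = 0.0, 0.0
    else:
        moments = record.principal_moments() * AMU * 1e-20  # kg m^2
        sigma = record.symmetry_number
        if record.is_linear:
            q_rot = 8.0 * math.pi**2 * moments[2] * KB * T / (sigma * H_PLANCK**2)
            s_rot = R_CAL * (math.log(q_rot) + 1.0)
            e_rot = R_KCAL * T
        else:
            q_rot = (
                math.sqrt(math.pi)
                / sigma
                * (8.0 * math.pi**2 * KB * T / H_PLANCK**2) ** 1.5
                * math.sqrt(float(np.prod(moments)))
            )
            s_rot = R_CAL * (math.log(q_rot) + 1.5)
            e_rot = 1.5 * R_KCAL * T

    zpe, e_vib, s_vib = _vibrational_terms(np.asarray(record.frequencies, float), T)
    s_elec = R_CAL * math.log(record.spin_multiplicity)

    entropy = s_trans + s_rot + s_vib + s_elec
    h_corr = zpe + e_trans + e_rot + e_vib + R_KCAL * T
    e_elec = record.electronic_energy * HARTREE_TO_KCAL
    g_gas_1atm = e_elec + h_corr - T * entropy / 1000.0
    g_gas_1m = g_gas_1atm + standard_state_correction(1.0, T)
    return ThermoResult(
        label=record.label,
        temperature=T,
        zpe=zpe,
        thermal_enthalpy_correction=h_corr,
        entropy=entropy,
        gibbs_gas_1atm=g_gas_1atm,
        gibbs_gas_1M=g_gas_1m,
    )


def ideal_gas_concentration(T: float = T_STANDARD) -> float:
    """Concentration of an ideal gas at 1 atm, mol/L (~1/24.46 at 298.15 K)."""
    if T <= 0:
        raise ThermoError("temperature must be positive")
    return P_STANDARD / (KB * N_A * T) / 1000.0


def standard_state_correction(c: float, T: float = T_STANDARD) -> float:
    """Gibbs correction (kcal/mol) from the 1 atm ideal-gas standard state
    to a c mol/L solution standard state: RT ln(c / c_gas(T)).

    For c = 1 M at 298.15 K this is RT ln(24.46) = +1.89 kcal/mol; water at
    55.34 M gains a further RT ln(55.34) = +2.38 kcal/mol.
    """
    if c <= 0 or T <= 0:
        raise ThermoError("concentration and temperature must be positive")
    return R_KCAL * T * math.log(c / ideal_gas_concentration(T))


def gibbs_aqueous(
    record: SpeciesRecord,
    T: float = T_STANDARD,
    solvation_includes_1M: bool = False,
) -> ThermoResult:
    """Complete thermochemistry including the aqueous standard Gibbs energy."""
    if record.solvation_energy is None:
        raise ThermoError(f"{record.label}: record carries no solvation energy")
    base = rrho_thermo(record, T)
    if solvation_includes_1M:
        g_aq = (
            base.gibbs_gas_1atm
            + record.solvation_energy
            + R_KCAL * T * math.log(record.standard_concentration)
        )
    else:
        g_aq = (
            base.gibbs_gas_1atm
            + standard_state_correction(record.standard_concentration, T)
            + record.solvation_energy
        )
    return ThermoResult(
        label=base.label,
        temperature=base.temperature,
        zpe=base.zpe,
        thermal_enthalpy_correction=base.thermal_enthalpy_correction,
        entropy=base.entropy,
        gibbs_gas_1atm=base.gibbs_gas_1atm,
        gibbs_gas_1M=base.gibbs_gas_1M,
        gibbs_aqueous=g_aq,
    )


@dataclass(frozen=True)
class ReactionEnergy:
    """Stoichiometry-weighted standard Gibbs reaction energies of one step."""

    step_id: str
    dG_gas: float  # kcal/mol, 1 atm gas standard states
    dG_aqueous: float  # kcal/mol, solution standard states


def reaction_energy(step, thermo: Mapping[str, ThermoResult]) -> ReactionEnergy:
    """Sum(nu G(products)) - Sum(nu G(reactants)) on both energy scales.

    All species must be present at the same temperature and carry aqueous
    Gibbs energies.
    """
    labels = list(step.reactants) + list(step.products)
    missing = [lb for lb in labels if lb not in thermo]
    if missing:
        raise ThermoError(
            f"step {step.step_id}: missing thermochemistry for {sorted(missing)}"
        )
    temps = {thermo[lb].temperature for lb in labels}
    if len(temps) > 1:
        raise ThermoError(
            f"step {step.step_id}: mixed temperatures {sorted(temps)} refused"
        )
    no_aq = [lb for lb in labels if thermo[lb].gibbs_aqueous is None]
    if no_aq:
        raise ThermoError(
            f"step {step.step_id}: no aqueous Gibbs energy for {sorted(no_aq)}"
        )
    dg_gas = 0.0
    dg_aq = 0.0
    for side, sign in ((step.reactants, -1.0), (step.products, 1.0)):
        for label, nu in side.items():
            w = sign * float(nu)
            dg_gas += w * thermo[label].gibbs_gas_1atm
            dg_aq += w * thermo[label].gibbs_aqueous
    return ReactionEnergy(step_id=step.step_id, dG_gas=dg_gas, dG_aqueous=dg_aq)


def thermo_table(
    records: Iterable[SpeciesRecord],
    T: float = T_STANDARD,
    solvation_includes_1M: bool = False,
) -> dict[str, ThermoResult]:
    """Per-species complete thermochemistry keyed by label."""
    out = {}
    for r in records:
        out[r.label] = gibbs_aqueous(r, T, solvation_includes_1M)
    return out
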