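"""Synthetic species records with known ground-truth reaction energies.

The generator emulates the structure of a real quantum-chemistry data set
for the metabolite network without doing any electronic-structure work:
every species receives a *target* aqueous standard Gibbs energy built by
group-contribution arithmetic (parent offset + per-position substitution
contributions + cofactor constants + optional per-reaction offsets +
seeded Gaussian noise), an all-positive harmonic frequency set, a fake
geometry, and a charge-dependent solvation energy.  The electronic energy
is then back-solved so that the full pipeline (RRHO thermochemistry +
standard-state corrections + solvation) reproduces the target exactly.

The back-solve uses this module's own closed-form ideal-gas partition
function expression (G_corr = ZPE - RT ln q, a single formula) rather than
the enthalpy/entropy route in :mod:`mitrametab.thermochem`; the two
derivations agreeing to numerical precision is itself a consistency check.

Ground-truth step energies are computed by the same group arithmetic,
independently of the pipeline, so parameter-recovery tests have an oracle.

Default energy parameters emulate the qualitative pattern reported for
this system: sulfation, oxidation and reduction strongly exergonic;
demethylation most favorable at position 9; glucuronidation most favorable
at position 17; the 7-hydroxy parent lowered by 38.3 kcal/mol relative to
mitragynine under the balanced-hydroxylation comparison, with 7-hydroxy
modifiers lowering d17/g17 and raising g9 step energies.  The numbers are
statistical stand-ins, not chemistry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import (
    AMU,
    C_LIGHT,
    H_PLANCK,
    HARTREE_TO_KCAL,
    J_PER_KCAL,
    KB,
    N_A,
    P_STANDARD,
    R_KCAL,
    T_STANDARD,
)
from .grammar import Grammar, MetaboliteCode, default_grammar, enumerate_metabolites, enumerate_transitions, formula_of
from .network import CofactorSpecies, load_cofactors, reaction_template
from .qmio import Atom, SpeciesRecord

__all__ = [
    "SyntheticSpecError",
    "SyntheticSpec",
    "SyntheticStudy",
    "generate_records",
    "make_fixture_output",
]


class SyntheticSpecError(ValueError):
    """Inconsistent synthetic-data specification."""


DEFAULT_GROUP_ENERGIES: dict[str, float] = {
    # cumulative kcal/mol contribution of each substitution state relative
    # to the unmodified state m of the same position
    "9:d": -4.0,
    "9:g": -11.0,
    "9:s": -48.0,
    "16:d": 0.0,
    "16:g": -4.5,
    "17:d": 1.0,
    "17:o": -49.0,
    "17:r": -21.0,
    "17:G": -32.0,
}

DEFAULT_PARENT_ENERGIES: dict[str, float] = {"M": 0.0, "H": -38.3}

DEFAULT_COFACTOR_ENERGIES: dict[str, float] = {
    "water": -2.0,
    "methanol": -4.0,
    "glucuronic_acid": -8.0,
    "sulfate": -15.0,
    "hydronium": -3.0,
    "nicotinamide_H": -10.0,
    "dihydronicotinamide": -6.0,
    "oxygen": 0.0,
}

# per-ion solvation constants (kcal/mol) with magnitudes typical of small
# aqueous ions; species without an entry fall back to the |charge| rule
DEFAULT_COFACTOR_SOLVATION: dict[str, float] = {
    "hydronium": -110.0,
    "sulfate": -250.0,
    "nicotinamide_H": -60.0,
}

DEFAULT_PARENT_TP_OFFSETS: dict[str, dict[tuple[str, str], float]] = {
    "H": {
        ("O_demethylation", "17"): -3.0,
        ("glucuronidation", "17"): -2.0,
        ("glucuronidation", "9"): +2.0,
    }
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study; regeneration from ``seed`` is
    deterministic."""

    seed: int = 0
    group_energies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_ENERGIES)
    )
    parent_energies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PARENT_ENERGIES)
    )
    cofactor_energies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COFACTOR_ENERGIES)
    )
    per_type_position_offsets: Mapping[tuple[str, str], float] = field(
        default_factory=dict
    )
    parent_type_position_offsets: Mapping[str, Mapping[tuple[str, str], float]] = field(
        default_factory=lambda: {
            p: dict(v) for p, v in DEFAULT_PARENT_TP_OFFSETS.items()
        }
    )
    noise_sd: float = 0.0  # kcal/mol, per-species Gaussian noise
    charge_solvation_scale: float = 60.0  # kcal/mol per unit |charge|
    neutral_solvation: float = -2.0  # kcal/mol baseline for neutral species
    cofactor_solvation: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COFACTOR_SOLVATION)
    )
    n_atoms_range: tuple[int, int] = (4, 9)
    frequency_range: tuple[float, float] = (200.0, 3500.0)
    temperature: float = T_STANDARD
    oxidation_mode: str = "nicotinamide"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise SyntheticSpecError("noise_sd must be >= 0")
        lo, hi = self.frequency_range
        if lo <= 0 or hi <= lo:
            raise SyntheticSpecError("frequency_range must be strictly positive")
        lo, hi = self.n_atoms_range
        if lo < 3 or hi < lo:
            raise SyntheticSpecError("n_atoms_range must satisfy 3 <= lo <= hi")


@dataclass(frozen=True)
class SyntheticStudy:
    """Output of one generator run: records plus independent ground truth."""

    spec: SyntheticSpec
    records: tuple[SpeciesRecord, ...]
    truth_steps: pd.DataFrame  # step_id, parent, reaction_type, position,
    #                            step_index, dG_gas, dG_aq (noiseless truth)
    species_targets: Mapping[str, float]  # label -> target aqueous G, kcal/mol


# ---------------------------------------------------------------------------
# independent ideal-gas Gibbs correction (single ln-q expression)


def _gibbs_correction_1atm(
    masses_amu: np.ndarray,
    coords: np.ndarray,
    frequencies: Sequence[float],
    T: float,
    symmetry_number: int = 1,
    spin_multiplicity: int = 1,
) -> float:
    """G(T, 1 atm) - E_elec in kcal/mol, via G_corr = ZPE - RT ln q."""
    rt = R_KCAL * T
    m_kg = float(masses_amu.sum()) * AMU
    ln_q = math.log((2.0 * math.pi * m_kg * KB * T / H_PLANCK**2) ** 1.5 * KB * T / P_STANDARD)
    n = len(masses_amu)
    if n > 1:
        com = (masses_amu[:, None] * coords).sum(axis=0) / masses_amu.sum()
        x = coords - com
        tensor = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                if i == j:
                    tensor[i, j] = (masses_amu * ((x**2).sum(axis=1) - x[:, i] ** 2)).sum()
                else:
                    tensor[i, j] = -(masses_amu * x[:, i] * x[:, j]).sum()
        moments_amu = np.sort(np.linalg.eigvalsh(tensor))  # amu Angstrom^2
        moments = moments_amu * AMU * 1e-20  # kg m^2
        linear = moments_amu[0] < 1e-6 * max(moments_amu[2], 1.0)
        if linear:
            ln_q += math.log(
                8.0 * math.pi**2 * moments[2] * KB * T / (symmetry_number * H_PLANCK**2)
            )
        else:
            ln_q += math.log(
                math.sqrt(math.pi)
                / symmetry_number
                * (8.0 * math.pi**2 * KB * T / H_PLANCK**2) ** 1.5
                * math.sqrt(float(np.prod(moments)))
            )
    zpe = 0.0
    for f in frequencies:
        nu = f * 100.0 * C_LIGHT
        zpe += 0.5 * H_PLANCK * nu * N_A / J_PER_KCAL
        x = H_PLANCK * nu / (KB * T)
        ln_q -= math.log1p(-math.exp(-x))
    ln_q += math.log(spin_multiplicity)
    return zpe - rt * ln_q


def _standard_state_term(c: float, T: float) -> float:
    """RT ln(c / c_gas(1 atm, T)), kcal/mol — written independently."""
    c_gas_mol_per_L = P_STANDARD / (KB * N_A * T) / 1000.0
    return R_KCAL * T * math.log(c / c_gas_mol_per_L)


# ---------------------------------------------------------------------------
# group-contribution truth


def _state_path(machine, state: str):
    """Transitions along the (unique shortest) DAG path m -> state."""
    if state == "m":
        return []
    prev = {"m": None}
    frontier = ["m"]
    while frontier:
        nxt = []
        for u in frontier:
            for t in machine.transitions:
                if t.from_state == u and t.to_state not in prev:
                    prev[t.to_state] = t
                    nxt.append(t.to_state)
        frontier = nxt
    if state not in prev:
        raise SyntheticSpecError(f"state {state!r} unreachable at position {machine.position}")
    path = []
    s = state
    while prev[s] is not None:
        t = prev[s]
        path.append(t)
        s = t.from_state
    return list(reversed(path))


class _TruthModel:
    """Noiseless group-contribution energies; pure arithmetic, no pipeline."""

    def __init__(self, spec: SyntheticSpec, grammar: Grammar):
        self.spec = spec
        self.grammar = grammar

    def _offset(self, parent: str, reaction_type: str, position: str) -> float:
        v = self.spec.per_type_position_offsets.get((reaction_type, position), 0.0)
        v += self.spec.parent_type_position_offsets.get(parent, {}).get(
            (reaction_type, position), 0.0
        )
        return v

    def state_contribution(self, parent: str, position: str, state: str) -> float:
        if state == "m":
            return 0.0
        key = f"{position}:{state}"
        if key not in self.spec.group_energies:
            raise SyntheticSpecError(f"missing group energy for {key!r}")
        machine = self.grammar.machine(position)
        base = self.spec.group_energies[key]
        return base + sum(
            self._offset(parent, t.reaction_type, position)
            for t in _state_path(machine, state)
        )

    def metabolite_target(self, code: MetaboliteCode) -> float:
        if code.parent not in self.spec.parent_energies:
            raise SyntheticSpecError(f"missing parent energy for {code.parent!r}")
        total = self.spec.parent_energies[code.parent]
        for psm, state in zip(self.grammar.positions, code.states):
            total += self.state_contribution(code.parent, psm.position, state)
        return total

    def cofactor_target(self, name: str) -> float:
        if name not in self.spec.cofactor_energies:
            raise SyntheticSpecError(f"missing cofactor energy for {name!r}")
        return self.spec.cofactor_energies[name]

    def step_energy(self, edge) -> float:
        """Truth aqueous reaction energy of one grammar transition."""
        d = self.metabolite_target(edge.target) - self.metabolite_target(edge.source)
        reagents, products = reaction_template(
            edge.reaction_type, edge.position, self.spec.oxidation_mode
        )
        for name, nu in products.items():
            d += float(nu) * self.cofactor_target(name)
        for name, nu in reagents.items():
            d -= float(nu) * self.cofactor_target(name)
        return d


# ---------------------------------------------------------------------------
# record generation

_ELEMENTS = ("C", "N", "O", "H")


def _element_masses() -> dict[str, float]:
    from rdkit import Chem

    pt = Chem.GetPeriodicTable()
    return {el: pt.GetAtomicWeight(el) for el in _ELEMENTS}


def _solvation_noiseless(spec: SyntheticSpec, charge: int, label: str = "") -> float:
    if label in spec.cofactor_solvation:
        return spec.cofactor_solvation[label]
    return spec.neutral_solvation - spec.charge_solvation_scale * abs(charge)


def generate_records(
    spec: SyntheticSpec,
    metabolites: Iterable[MetaboliteCode] | None = None,
    cofactors: Mapping[str, CofactorSpecies] | None = None,
    grammar: Grammar | None = None,
) -> SyntheticStudy:
    """Generate one synthetic study: species records plus ground truth.

    By default covers the full enumerated metabolite set of every parent in
    ``spec.parent_energies`` plus all shipped cofactors.
    """
    grammar = grammar or default_grammar()
    parents = sorted(spec.parent_energies)
    if metabolites is None:
        metabolites = enumerate_metabolites(grammar, parents)
    metabolites = sorted(metabolites, key=lambda c: c.text)
    cofactors = cofactors if cofactors is not None else load_cofactors()
    truth = _TruthModel(spec, grammar)
    rng = np.random.default_rng(spec.seed)
    masses = _element_masses()
    T = spec.temperature

    # (label, charge, standard concentration, target G_aq)
    species: list[tuple[str, int, float, float]] = []
    for code in metabolites:
        sp = formula_of(code, grammar)
        species.append((code.text, sp.charge, 1.0, truth.metabolite_target(code)))
    for name in sorted(cofactors):
        c = cofactors[name]
        species.append(
            (name, c.charge, c.standard_concentration_M, truth.cofactor_target(name))
        )

    records = []
    targets = {}
    for label, charge, conc, target in species:
        noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
        g_target = target + noise
        targets[label] = g_target
        n = int(rng.integers(spec.n_atoms_range[0], spec.n_atoms_range[1] + 1))
        elements = [str(e) for e in rng.choice(_ELEMENTS, size=n)]
        coords = rng.uniform(-2.0, 2.0, size=(n, 3))
        freqs = np.sort(
            rng.uniform(spec.frequency_range[0], spec.frequency_range[1], size=3 * n - 6)
        )
        solv = _solvation_noiseless(spec, charge, label)
        if spec.noise_sd > 0:
            solv += rng.normal(0.0, 0.2 * spec.noise_sd)
        m = np.array([masses[e] for e in elements])
        gcorr = _gibbs_correction_1atm(m, coords, freqs, T)
        e_elec_kcal = g_target - gcorr - _standard_state_term(conc, T) - solv
        records.append(
            SpeciesRecord(
                label=label,
                electronic_energy=e_elec_kcal / HARTREE_TO_KCAL,
                frequencies=tuple(float(f) for f in freqs),
                atoms=tuple(
                    Atom(element=e, mass=masses[e], xyz=tuple(map(float, xyz)))
                    for e, xyz in zip(elements, coords)
                ),
                charge=charge,
                spin_multiplicity=1,
                symmetry_number=1,
                solvation_energy=solv,
                standard_concentration=conc,
            )
        )

    selected = {c.text for c in metabolites}
    rows = []
    for edge in enumerate_transitions(grammar, parents):
        if edge.source.text not in selected or edge.target.text not in selected:
            continue
        dg_aq = truth.step_energy(edge)
        # truth gas-phase energy: strip the (noiseless) solvation and
        # standard-state terms with the step's stoichiometry
        reagents, products = reaction_template(
            edge.reaction_type, edge.position, spec.oxidation_mode
        )
        strip = 0.0
        for name, nu in products.items():
            c = cofactors[name]
            strip += float(nu) * (
                _solvation_noiseless(spec, c.charge, name)
                + _standard_state_term(c.standard_concentration_M, T)
            )
        for name, nu in reagents.items():
            c = cofactors[name]
            strip -= float(nu) * (
                _solvation_noiseless(spec, c.charge, name)
                + _standard_state_term(c.standard_concentration_M, T)
            )
        for code, sign in ((edge.target, 1.0), (edge.source, -1.0)):
            q = formula_of(code, grammar).charge
            strip += sign * (
                _solvation_noiseless(spec, q) + _standard_state_term(1.0, T)
            )
        rows.append(
            {
                "step_id": f"{edge.source.text}->{edge.target.text}",
                "parent": edge.source.parent,
                "reaction_type": edge.reaction_type,
                "position": edge.position,
                "step_index": grammar.step_index(edge.target),
                "dG_gas": dg_aq - strip,
                "dG_aq": dg_aq,
            }
        )
    truth_steps = pd.DataFrame(rows).sort_values("step_id").reset_index(drop=True)
    return SyntheticStudy(
        spec=spec,
        records=tuple(records),
        truth_steps=truth_steps,
        species_targets=targets,
    )


# ---------------------------------------------------------------------------
# fixture emission in the qcout dialect


def make_fixture_output(record: SpeciesRecord, truncate: bool = False) -> str:
    """Render a record as a ``qcout``-dialect text log, closing the loop
    parser -> thermochemistry -> analysis on synthetic data.

    With ``truncate=True`` the normal-termination marker is omitted, which
    :func:`mitrametab.qmio.parse_qm_output` must reject.
    """
    lines = []
    lines.append("$comment")
    lines.append(f"  {record.label}")
    lines.append("$end")
    lines.append("")
    lines.append("$molecule")
    lines.append(f"  {record.charge} {record.spin_multiplicity}")
    for a in record.atoms:
        lines.append(
            f"  {a.element:<2s} {a.xyz[0]:14.6f} {a.xyz[1]:14.6f} {a.xyz[2]:14.6f}"
        )
    lines.append("$end")
    lines.append("")
    lines.append(f" Total energy in the final basis set = {record.electronic_energy:.10f}")
    lines.append("")
    lines.append(" VIBRATIONAL ANALYSIS")
    for i in range(0, len(record.frequencies), 3):
        chunk = record.frequencies[i : i + 3]
        lines.append(" Frequency: " + "".join(f" {f:10.2f}" for f in chunk))
    lines.append(f" Rotational symmetry number = {record.symmetry_number}")
    if record.solvation_energy is not None:
        lines.append(
            f" Free energy of solvation = {record.solvation_energy:.4f} kcal/mol"
        )
    if not truncate:
        lines.append(" *** Normal termination ***")
    return "\n".join(lines) + "\n"
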