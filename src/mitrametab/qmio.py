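"""Species thermochemistry records and their file formats.

A :class:`SpeciesRecord` carries everything the thermochemistry stage needs
about one molecule: electronic energy (hartree), harmonic vibrational
frequencies (cm^-1), atoms with masses and Cartesian coordinates, charge,
spin multiplicity, rotational symmetry number, the aqueous solvation free
energy (kcal/mol) and the solution standard-state concentration (mol/L;
1 M for solutes, 55.34 M for water).

Two on-disk representations are supported:

* the **portable record format** (``species-record/1``), a versioned YAML
  schema that is the pipeline's canonical input — synthetic and real data
  enter identically through it; and
* a **quantum-chemistry output dialect** (``qcout``), a plain-text log
  layout with ``$molecule ... $end`` geometry blocks, final-energy and
  ``Frequency:`` lines and an optional solvation-energy line, read by
  :func:`parse_qm_output`.  The shipped fixtures define this contract.

Gas-phase and solvated results may arrive as separate jobs; merge them with
:func:`merge_records` (solvation energy from the solvated job, everything
else from the gas-phase frequency job).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "QmIoError",
    "RecordValidationError",
    "ParseError",
    "Atom",
    "SpeciesRecord",
    "read_record",
    "read_records",
    "write_record",
    "write_records",
    "parse_qm_output",
    "merge_records",
    "assemble_table",
    "SpeciesTable",
]

FORMAT_TAG = "species-record/1"


class QmIoError(ValueError):
    """Base error for species-record I/O."""


class RecordValidationError(QmIoError):
    """A record violates the schema invariants."""


class ParseError(QmIoError):
    """Quantum-chemistry output could not be parsed."""

    def __init__(self, message: str, offset: int | None = None) -> None:
        self.offset = offset
        if offset is not None:
            message = f"{message} (byte offset {offset})"
        super().__init__(message)


@dataclass(frozen=True)
class Atom:
    element: str
    mass: float  # amu
    xyz: tuple[float, float, float]  # Angstrom


@dataclass(frozen=True)
class SpeciesRecord:
    label: str
    electronic_energy: float  # hartree
    frequencies: tuple[float, ...]  # cm^-1
    atoms: tuple[Atom, ...]
    charge: int = 0
    spin_multiplicity: int = 1
    symmetry_number: int = 1
    solvation_energy: float | None = None  # kcal/mol
    standard_concentration: float = 1.0  # mol/L
    is_minimum: bool = True

    def __post_init__(self) -> None:
        if len(self.atoms) < 1:
            raise RecordValidationError(f"{self.label}: record must contain atoms")
        if self.spin_multiplicity < 1:
            raise RecordValidationError(f"{self.label}: spin multiplicity must be >= 1")
        if self.symmetry_number < 1:
            raise RecordValidationError(f"{self.label}: symmetry number must be >= 1")
        if self.standard_concentration <= 0:
            raise RecordValidationError(
                f"{self.label}: standard concentration must be positive"
            )
        if self.is_minimum and any(f <= 0 for f in self.frequencies):
            raise RecordValidationError(
                f"{self.label}: non-positive frequency in a record flagged as a "
                "minimum; set is_minimum: false to store a non-minimum"
            )

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def principal_moments(self) -> np.ndarray:
        """Principal moments of inertia in amu*Angstrom^2, ascending."""
        m = self.masses
        x = self.coordinates
        com = (m[:, None] * x).sum(axis=0) / m.sum()
        x = x - com
        ixx = (m * (x[:, 1] ** 2 + x[:, 2] ** 2)).sum()
        iyy = (m * (x[:, 0] ** 2 + x[:, 2] ** 2)).sum()
        izz = (m * (x[:, 0] ** 2 + x[:, 1] ** 2)).sum()
        ixy = -(m * x[:, 0] * x[:, 1]).sum()
        ixz = -(m * x[:, 0] * x[:, 2]).sum()
        iyz = -(m * x[:, 1] * x[:, 2]).sum()
        tensor = np.array([[ixx, ixy, ixz], [ixy, iyy, iyz], [ixz, iyz, izz]])
        return np.sort(np.linalg.eigvalsh(tensor))

    @property
    def is_monoatomic(self) -> bool:
        return len(self.atoms) == 1

    @property
    def is_linear(self) -> bool:
        """True when the smallest principal moment vanishes and the other
        two are equal (within numerical tolerance)."""
        if self.is_monoatomic:
            return False
        moments = self.principal_moments()
        return moments[0] < 1e-6 * max(moments[2], 1.0)


# ---------------------------------------------------------------------------
# portable format


def _record_to_dict(record: SpeciesRecord) -> dict:
    d = {
        "format": FORMAT_TAG,
        "label": record.label,
        "electronic_energy_hartree": float(record.electronic_energy),
        "frequencies_cm1": [float(f) for f in record.frequencies],
        "atoms": [
            [a.element, float(a.mass), float(a.xyz[0]), float(a.xyz[1]), float(a.xyz[2])]
            for a in record.atoms
        ],
        "charge": int(record.charge),
        "spin_multiplicity": int(record.spin_multiplicity),
        "symmetry_number": int(record.symmetry_number),
        "standard_concentration_M": float(record.standard_concentration),
        "is_minimum": bool(record.is_minimum),
    }
    if record.solvation_energy is not None:
        d["solvation_energy_kcal"] = float(record.solvation_energy)
    return d


_MANDATORY = (
    "label",
    "electronic_energy_hartree",
    "frequencies_cm1",
    "atoms",
    "charge",
    "spin_multiplicity",
)


def _record_from_dict(d: Mapping) -> SpeciesRecord:
    if d.get("format") != FORMAT_TAG:
        raise QmIoError(f"unsupported record format {d.get('format')!r}")
    for key in _MANDATORY:
        if key not in d:
            raise RecordValidationError(f"missing mandatory field {key!r}")
    atoms = tuple(
        Atom(element=str(a[0]), mass=float(a[1]), xyz=(float(a[2]), float(a[3]), float(a[4])))
        for a in d["atoms"]
    )
    return SpeciesRecord(
        label=str(d["label"]),
        electronic_energy=float(d["electronic_energy_hartree"]),
        frequencies=tuple(float(f) for f in d["frequencies_cm1"]),
        atoms=atoms,
        charge=int(d["charge"]),
        spin_multiplicity=int(d["spin_multiplicity"]),
        symmetry_number=int(d.get("symmetry_number", 1)),
        solvation_energy=(
            float(d["solvation_energy_kcal"]) if "solvation_energy_kcal" in d else None
        ),
        standard_concentration=float(d.get("standard_concentration_M", 1.0)),
        is_minimum=bool(d.get("is_minimum", True)),
    )


def write_record(record: SpeciesRecord, target) -> None:
    """Write one record as a portable YAML document."""
    text = yaml.safe_dump(_record_to_dict(record), sort_keys=False)
    if hasattr(target, "write"):
        target.write(text)
    else:
        Path(target).write_text(text, encoding="utf-8")


def write_records(records: Iterable[SpeciesRecord], target) -> None:
    """Write a multi-record archive (YAML document stream)."""
    text = yaml.safe_dump_all(
        [_record_to_dict(r) for r in records], sort_keys=False
    )
    if hasattr(target, "write"):
        target.write(text)
    else:
        Path(target).write_text(text, encoding="utf-8")


def _load_yaml_source(source) -> list:
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    return [d for d in yaml.safe_load_all(text) if d is not None]


def read_record(source) -> SpeciesRecord:
    docs = _load_yaml_source(source)
    if len(docs) != 1:
        raise QmIoError(f"expected exactly one record, found {len(docs)}")
    return _record_from_dict(docs[0])


def read_records(source) -> list[SpeciesRecord]:
    """Read records from an archive file, a single-record file, or a
    directory of such files."""
    if not hasattr(source, "read") and Path(source).is_dir():
        out = []
        for path in sorted(Path(source).glob("*.yaml")):
            out.extend(read_records(path))
        return out
    return [_record_from_dict(d) for d in _load_yaml_source(source)]


# ---------------------------------------------------------------------------
# quantum-chemistry output dialect

_ENERGY_RE = re.compile(r"Total energy in the final basis set\s*=\s*(-?\d+\.\d+)")
_FREQ_RE = re.compile(r"^\s*Frequency:((?:\s+-?\d+(?:\.\d+)?)+)\s*$", re.MULTILINE)
_SOLV_RE = re.compile(r"Free energy of solvation\s*=\s*(-?\d+(?:\.\d+)?)\s*kcal/mol")
_SYM_RE = re.compile(r"Rotational symmetry number\s*=\s*(\d+)")
_TERM_RE = re.compile(r"\*\*\* normal termination \*\*\*", re.IGNORECASE)


def _element_weight(symbol: str) -> float:
    from rdkit import Chem

    return Chem.GetPeriodicTable().GetAtomicWeight(symbol)


def parse_qm_output(source, dialect: str = "qcout", label: str | None = None) -> SpeciesRecord:
    """Parse one completed frequency job (optionally with a solvation
    single point) from a quantum-chemistry text log.

    The ``qcout`` dialect expects a ``$molecule``/``$end`` block whose first
    line is ``charge multiplicity``, a final-basis total-energy line,
    ``Frequency:`` rows, and a normal-termination marker.  Atomic masses are
    taken from standard atomic weights by element symbol.
    """
    if dialect != "qcout":
        raise QmIoError(f"unknown dialect {dialect!r}")
    text = source.read() if hasattr(source, "read") else Path(source).read_text(
        encoding="utf-8"
    )

    mol_start = text.find("$molecule")
    if mol_start < 0:
        raise ParseError("no $molecule block found", offset=0)
    mol_end = text.find("$end", mol_start)
    if mol_end < 0:
        raise ParseError("unterminated $molecule block", offset=mol_start)
    body = [
        ln.strip()
        for ln in text[mol_start + len("$molecule"): mol_end].splitlines()
        if ln.strip()
    ]
    if not body:
        raise ParseError("empty $molecule block", offset=mol_start)
    try:
        charge_s, mult_s = body[0].split()
        charge, multiplicity = int(charge_s), int(mult_s)
    except ValueError:
        raise ParseError(
            "first $molecule line must be '<charge> <multiplicity>'", offset=mol_start
        ) from None
    atoms = []
    for ln in body[1:]:
        parts = ln.split()
        if len(parts) != 4:
            raise ParseError(f"unparseable geometry line {ln!r}", offset=mol_start)
        el = parts[0]
        try:
            xyz = tuple(float(p) for p in parts[1:])
        except ValueError:
            raise ParseError(f"unparseable coordinates in {ln!r}", offset=mol_start) from None
        atoms.append(Atom(element=el, mass=_element_weight(el), xyz=xyz))
    if not atoms:
        raise ParseError("no atoms in $molecule block", offset=mol_start)

    if not _TERM_RE.search(text):
        raise ParseError("truncated job: no normal-termination marker", offset=len(text))

    energies = _ENERGY_RE.findall(text)
    if not energies:
        raise ParseError("no final electronic energy found", offset=len(text))
    electronic_energy = float(energies[-1])

    freqs: list[float] = []
    for m in _FREQ_RE.finditer(text):
        freqs.extend(float(v) for v in m.group(1).split())
    if len(atoms) > 1 and not freqs:
        raise ParseError("no frequency section found", offset=len(text))

    solv = _SOLV_RE.search(text)
    sym = _SYM_RE.search(text)

    comment = None
    cstart = text.find("$comment")
    if cstart >= 0:
        cend = text.find("$end", cstart)
        if cend > cstart:
            lines = [
                ln.strip()
                for ln in text[cstart + len("$comment"): cend].splitlines()
                if ln.strip()
            ]
            if lines:
                comment = lines[0]

    return SpeciesRecord(
        label=label or comment or "unnamed",
        electronic_energy=electronic_energy,
        frequencies=tuple(freqs),
        atoms=tuple(atoms),
        charge=charge,
        spin_multiplicity=multiplicity,
        symmetry_number=int(sym.group(1)) if sym else 1,
        solvation_energy=float(solv.group(1)) if solv else None,
        standard_concentration=1.0,
        is_minimum=all(f > 0 for f in freqs),
    )


def merge_records(gas: SpeciesRecord, solvated: SpeciesRecord) -> SpeciesRecord:
    """Combine a gas-phase frequency job with a solvation single point:
    solvation energy from the solvated record, everything else from the
    gas-phase record."""
    if gas.label != solvated.label:
        raise QmIoError(
            f"cannot merge records with different labels: {gas.label!r} vs "
            f"{solvated.label!r}"
        )
    if solvated.solvation_energy is None:
        raise QmIoError(f"{solvated.label}: solvated record carries no solvation energy")
    return replace(gas, solvation_energy=solvated.solvation_energy)


# ---------------------------------------------------------------------------
# species table


class SpeciesTable(dict):
    """Label -> SpeciesRecord mapping with coverage reporting."""

    def missing_species(self, steps) -> dict[str, list[str]]:
        """Map each unresolvable species label to the step ids needing it."""
        report: dict[str, list[str]] = {}
        for step in steps:
            for label in list(step.reactants) + list(step.products):
                if label not in self:
                    report.setdefault(label, []).append(step.step_id)
        return report

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "label": r.label,
                "electronic_energy_hartree": r.electronic_energy,
                "n_atoms": len(r.atoms),
                "n_frequencies": len(r.frequencies),
                "charge": r.charge,
                "spin_multiplicity": r.spin_multiplicity,
                "symmetry_number": r.symmetry_number,
                "solvation_energy_kcal": r.solvation_energy,
                "standard_concentration_M": r.standard_concentration,
            }
            for r in self.values()
        ]
        return pd.DataFrame(rows)


def assemble_table(records: Iterable[SpeciesRecord]) -> SpeciesTable:
    """Key records by label; duplicate labels are an error."""
    table = SpeciesTable()
    for r in records:
        if r.label in table:
            raise QmIoError(f"duplicate species label {r.label!r}")
        table[r.label] = r
    return table
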