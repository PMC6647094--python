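"""Balanced metabolic reaction steps between metabolite codes.

Each grammar transition becomes a stoichiometric equation between exactly
two metabolites plus fixed cofactor species (water, methanol, glucuronic
acid, sulfate, hydronium, the protonated-nicotinamide/dihydronicotinamide
redox couple, optionally molecular oxygen).  Every step is element- and
charge-balanced by construction and re-validated against a species table.

The cofactor assignment per reaction class is the minimal balanced scheme
consistent with the reagent and product species considered here; it is an
inference of this package, not an enzymatic mechanism:

* O-demethylation / ester hydrolysis:  R-OCH3 + H2O -> R-OH + CH3OH
* oxidation (aldehyde -> acid), nicotinamide mode:
      R-CHO + NicH+ + 2 H2O -> R-COOH + DHN + H3O+
  or, in O2 mode:  R-CHO + 1/2 O2 -> R-COOH
* reduction (aldehyde -> alcohol):
      R-CHO + DHN + H3O+ -> R-CH2OH + NicH+ + H2O
* glucuronidation:  R-OH + C6H10O7 -> R-O-C6H9O6 + H2O
* sulfation:  R-OH + SO4(2-) + H3O+ -> R-OSO3(-) + 2 H2O
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Iterable, Mapping

import yaml

from .grammar import (
    Grammar,
    GrammarError,
    MetaboliteCode,
    MolecularSpecies,
    default_grammar,
    enumerate_transitions,
    formula_of,
)

__all__ = [
    "REACTION_TYPES",
    "NetworkError",
    "BalanceError",
    "CofactorSpecies",
    "ReactionStep",
    "load_cofactors",
    "reaction_template",
    "build_network",
    "validate_balance",
    "curated_subset",
    "study_species",
    "steps_table",
    "to_graph",
    "write_dot",
]

REACTION_TYPES = (
    "ester_hydrolysis",
    "O_demethylation",
    "oxidation",
    "reduction",
    "glucuronidation",
    "sulfation",
)

OXIDATION_MODES = ("nicotinamide", "o2")


class NetworkError(ValueError):
    """Illegal reaction-network construction."""


class BalanceError(NetworkError):
    """A reaction step failed element or charge balance."""


@dataclass(frozen=True)
class CofactorSpecies:
    name: str
    formula: Mapping[str, int]
    charge: int
    role: str = "both"  # reagent | product | both
    symmetry_number: int = 1
    spin_multiplicity: int = 1
    linear: bool = False
    standard_concentration_M: float = 1.0

    def as_species(self) -> MolecularSpecies:
        return MolecularSpecies(label=self.name, formula=self.formula, charge=self.charge)


def load_cofactors() -> dict[str, CofactorSpecies]:
    """The shipped cofactor reference table, keyed by name."""
    ref = resources.files("mitrametab.data").joinpath("cofactors.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    if raw.get("format") != "cofactor-table/1":
        raise NetworkError("not a cofactor-table/1 document")
    out = {}
    for name, c in raw["cofactors"].items():
        out[name] = CofactorSpecies(
            name=name,
            formula={k: int(v) for k, v in c["formula"].items()},
            charge=int(c.get("charge", 0)),
            symmetry_number=int(c.get("symmetry_number", 1)),
            spin_multiplicity=int(c.get("spin_multiplicity", 1)),
            linear=bool(c.get("linear", False)),
            standard_concentration_M=float(c.get("standard_concentration_M", 1.0)),
        )
    return out


@dataclass(frozen=True)
class ReactionStep:
    """One balanced metabolic step.

    ``reactants`` and ``products`` map species labels to positive rational
    stoichiometric coefficients and each contain exactly one metabolite
    (``source``/``target``).  ``step_index`` counts grammar transitions
    separating the product metabolite from the parent all-m code.
    """

    source: MetaboliteCode
    target: MetaboliteCode
    reaction_type: str
    position: str
    parent: str
    step_index: int
    reactants: Mapping[str, Fraction] = field(default_factory=dict)
    products: Mapping[str, Fraction] = field(default_factory=dict)

    @property
    def step_id(self) -> str:
        return f"{self.source.text}->{self.target.text}"

    def equation(self) -> str:
        def side(terms: Mapping[str, Fraction]) -> str:
            parts = []
            for label in sorted(terms):
                nu = terms[label]
                parts.append(label if nu == 1 else f"{nu} {label}")
            return " + ".join(parts)

        return f"{side(self.reactants)} -> {side(self.products)}"

    def reversed(self) -> "ReactionStep":
        return ReactionStep(
            source=self.target,
            target=self.source,
            reaction_type=self.reaction_type,
            position=self.position,
            parent=self.parent,
            step_index=self.step_index,
            reactants=dict(self.products),
            products=dict(self.reactants),
        )


# (reaction_type [, mode]) -> (cofactor reagents, cofactor products)
_TEMPLATES: dict[str, tuple[dict[str, Fraction], dict[str, Fraction]]] = {
    "ester_hydrolysis": ({"water": Fraction(1)}, {"methanol": Fraction(1)}),
    "O_demethylation": ({"water": Fraction(1)}, {"methanol": Fraction(1)}),
    "oxidation:nicotinamide": (
        {"nicotinamide_H": Fraction(1), "water": Fraction(2)},
        {"dihydronicotinamide": Fraction(1), "hydronium": Fraction(1)},
    ),
    "oxidation:o2": ({"oxygen": Fraction(1, 2)}, {}),
    "reduction": (
        {"dihydronicotinamide": Fraction(1), "hydronium": Fraction(1)},
        {"nicotinamide_H": Fraction(1), "water": Fraction(1)},
    ),
    "glucuronidation": ({"glucuronic_acid": Fraction(1)}, {"water": Fraction(1)}),
    "sulfation": (
        {"sulfate": Fraction(1), "hydronium": Fraction(1)},
        {"water": Fraction(2)},
    ),
}

# (type, position) pairs legal under the shipped grammar
_LEGAL_PAIRS = {
    ("O_demethylation", "9"),
    ("O_demethylation", "17"),
    ("ester_hydrolysis", "16"),
    ("glucuronidation", "9"),
    ("glucuronidation", "16"),
    ("glucuronidation", "17"),
    ("sulfation", "9"),
    ("oxidation", "17"),
    ("reduction", "17"),
}


def reaction_template(
    reaction_type: str, position: str, oxidation_mode: str = "nicotinamide"
) -> tuple[dict[str, Fraction], dict[str, Fraction]]:
    """Cofactor reagents and products (with coefficients) for a step class."""
    if oxidation_mode not in OXIDATION_MODES:
        raise NetworkError(f"unknown oxidation mode {oxidation_mode!r}")
    if (reaction_type, str(position)) not in _LEGAL_PAIRS:
        raise NetworkError(
            f"no reaction template for ({reaction_type!r}, position {position})"
        )
    key = reaction_type
    if reaction_type == "oxidation":
        key = f"oxidation:{oxidation_mode}"
    reagents, products = _TEMPLATES[key]
    return dict(reagents), dict(products)


def _merge(side: Mapping[str, Fraction], extra: Mapping[str, Fraction]) -> dict:
    out = dict(side)
    for k, v in extra.items():
        out[k] = out.get(k, Fraction(0)) + v
    return {k: v for k, v in out.items() if v != 0}


def build_species_table(
    metabolites: Iterable[MetaboliteCode],
    grammar: Grammar | None = None,
    cofactors: Mapping[str, CofactorSpecies] | None = None,
) -> dict[str, MolecularSpecies]:
    """Label -> composition table covering metabolites and cofactors."""
    grammar = grammar or default_grammar()
    cofactors = cofactors if cofactors is not None else load_cofactors()
    table = {c.name: c.as_species() for c in cofactors.values()}
    for code in metabolites:
        table[code.text] = formula_of(code, grammar)
    return table


def build_network(
    metabolites: Iterable[MetaboliteCode],
    grammar: Grammar | None = None,
    oxidation_mode: str = "nicotinamide",
    edges: Iterable[tuple[str, str]] | None = None,
) -> list[ReactionStep]:
    """One balanced :class:`ReactionStep` per grammar transition whose two
    endpoints are both in *metabolites*.

    If *edges* is given (pairs of code texts), only those transitions are
    kept — used for curated subsets whose arrow set is narrower than the
    grammar allows.  Every step is validated for element and charge balance
    before being returned.
    """
    grammar = grammar or default_grammar()
    metabolites = list(metabolites)
    selected = {c.text for c in metabolites}
    parents = sorted({c.parent for c in metabolites})
    wanted = None if edges is None else {(a, b) for a, b in edges}
    species = build_species_table(metabolites, grammar)
    steps = []
    for e in enumerate_transitions(grammar, parents):
        if e.source.text not in selected or e.target.text not in selected:
            continue
        if wanted is not None and (e.source.text, e.target.text) not in wanted:
            continue
        reagents, prods = reaction_template(e.reaction_type, e.position, oxidation_mode)
        step = ReactionStep(
            source=e.source,
            target=e.target,
            reaction_type=e.reaction_type,
            position=e.position,
            parent=e.source.parent,
            step_index=grammar.step_index(e.target),
            reactants=_merge({e.source.text: Fraction(1)}, reagents),
            products=_merge({e.target.text: Fraction(1)}, prods),
        )
        violations = validate_balance(step, species)
        if violations:
            raise BalanceError(
                f"step {step.step_id} is unbalanced: " + "; ".join(violations)
            )
        steps.append(step)
    if wanted is not None:
        missing = wanted - {(s.source.text, s.target.text) for s in steps}
        if missing:
            raise NetworkError(
                f"requested edges are not legal grammar transitions: {sorted(missing)}"
            )
    steps.sort(key=lambda s: (s.source.text, s.target.text))
    return steps


def validate_balance(
    step: ReactionStep, species: Mapping[str, MolecularSpecies]
) -> list[str]:
    """Per-element and charge discrepancies of a step; empty list = pass."""
    totals: dict[str, Fraction] = {}
    charge = Fraction(0)
    for side, sign in ((step.reactants, 1), (step.products, -1)):
        for label, nu in side.items():
            if label not in species:
                raise NetworkError(f"unresolvable species label {label!r}")
            sp = species[label]
            for el, n in sp.formula.items():
                totals[el] = totals.get(el, Fraction(0)) + sign * nu * n
            charge += sign * nu * sp.charge
    violations = [
        f"element {el}: net {float(v):+g}" for el, v in sorted(totals.items()) if v != 0
    ]
    if charge != 0:
        violations.append(f"charge: net {float(charge):+g}")
    return violations


def curated_subset(
    parent: str = "M",
    grammar: Grammar | None = None,
    oxidation_mode: str = "nicotinamide",
) -> tuple[list[MetaboliteCode], list[ReactionStep], dict[str, dict]]:
    """The curated experimental pathway subset for one parent: 18 metabolite
    codes, 21 steps, plus per-code evidence flags.

    The subset is a reconstruction of the published rat/human LC-MS pathway
    scheme (see the shipped ``pathway_subset_reconstructed.yaml``): the
    published pathway diagram is the only source and its exact arrow set is curated
    data, so three grammar-derivable edges between the 18 codes are
    deliberately absent.  Evidence flags (rat / human / bracketed
    intermediate) are carried as annotation only.
    """
    grammar = grammar or default_grammar()
    if parent not in grammar.parents:
        raise GrammarError(f"unknown parent tag {parent!r}")
    ref = resources.files("mitrametab.data").joinpath(
        "pathway_subset_reconstructed.yaml"
    )
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    if raw.get("format") != "pathway-subset/1":
        raise NetworkError("not a pathway-subset/1 document")
    codes = []
    flags = {}
    for entry in raw["metabolites"]:
        code = grammar.parse(f"{parent}_{entry['code']}")
        codes.append(code)
        flags[code.text] = {
            "rat": bool(entry["rat"]),
            "human": bool(entry["human"]),
            "bracketed": bool(entry["bracketed"]),
        }
    edges = [
        (f"{parent}_{s['from']}", f"{parent}_{s['to']}") for s in raw["steps"]
    ]
    steps = build_network(codes, grammar, oxidation_mode, edges=edges)
    return codes, steps, flags


def study_species(grammar: Grammar | None = None) -> list[MetaboliteCode]:
    """The 36-compound study set: the curated subset for both parents."""
    grammar = grammar or default_grammar()
    out = []
    for parent in sorted(grammar.parents):
        codes, _, _ = curated_subset(parent, grammar)
        out.extend(codes)
    return sorted(out, key=lambda c: c.text)


def steps_table(steps: Iterable[ReactionStep]):
    """Steps as a pandas DataFrame (for TSV export)."""
    import pandas as pd

    rows = [
        {
            "step_id": s.step_id,
            "parent": s.parent,
            "reaction_type": s.reaction_type,
            "position": s.position,
            "step_index": s.step_index,
            "equation": s.equation(),
        }
        for s in steps
    ]
    return pd.DataFrame(rows)


def to_graph(steps: Iterable[ReactionStep]):
    """networkx DiGraph with metabolites as nodes and steps as edges."""
    import networkx as nx

    g = nx.DiGraph()
    for s in steps:
        g.add_node(s.source.text)
        g.add_node(s.target.text)
        g.add_edge(
            s.source.text,
            s.target.text,
            reaction_type=s.reaction_type,
            position=str(s.position),
            step_index=s.step_index,
        )
    return g


def write_dot(steps: Iterable[ReactionStep], path) -> None:
    """Minimal Graphviz DOT export (nodes + labelled directed edges)."""
    lines = ["digraph metabolism {"]
    steps = list(steps)
    nodes = sorted({s.source.text for s in steps} | {s.target.text for s in steps})
    for n in nodes:
        lines.append(f'  "{n}";')
    for s in steps:
        lines.append(
            f'  "{s.source.text}" -> "{s.target.text}" '
            f'[label="{s.reaction_type}@{s.position}"];'
        )
    lines.append("}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
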