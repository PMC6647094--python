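"""Positional substitution grammar for mitragynine-family metabolites.

Mitragynine (parent tag ``M``) and 7-hydroxymitragynine (``H``) are
metabolized at three positions: the aromatic 9-methoxy group, the 16-methyl
ester and the 17-enol methyl ether.  Each position carries a small ordered
set of substitution states connected by single metabolic transitions
(demethylation/hydrolysis, oxidation, reduction, conjugation with
glucuronic acid or sulfate).  A metabolite is identified by its parent tag
plus one state letter per position, written ``M_mmm``, ``H_dmr`` and so on.

This module loads a grammar definition (positions, states, transitions,
formula deltas) from a YAML config, enumerates all metabolite codes and all
single-step transitions, and derives molecular formulas and charges.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, NamedTuple

import yaml

__all__ = [
    "GrammarError",
    "UnknownParentError",
    "IllegalStateError",
    "Transition",
    "PositionStateMachine",
    "MolecularSpecies",
    "MetaboliteCode",
    "Grammar",
    "load_grammar",
    "default_grammar",
    "enumerate_metabolites",
    "enumerate_transitions",
    "parse_code",
    "format_code",
    "formula_of",
    "hill_formula",
    "monoisotopic_mass",
    "molecular_weight",
]


class GrammarError(ValueError):
    """Malformed grammar definition or illegal operation on one."""


class UnknownParentError(GrammarError):
    """Parent tag not defined by the grammar."""


class IllegalStateError(GrammarError):
    """A state letter that is not legal at its position."""

    def __init__(self, state: str, position: str) -> None:
        self.state = state
        self.position = position
        super().__init__(f"state {state!r} is not legal at position {position}")


class Transition(NamedTuple):
    from_state: str
    to_state: str
    reaction_type: str


@dataclass(frozen=True)
class PositionStateMachine:
    """States and legal metabolic transitions at one reactive position.

    The transition graph must be a DAG rooted at the unmodified state ``m``
    with every state reachable; this guarantees each metabolite has a
    well-defined step count from the parent compound.
    """

    position: str
    states: tuple[str, ...]
    transitions: tuple[Transition, ...]

    def __post_init__(self) -> None:
        if "m" not in self.states:
            raise GrammarError(f"position {self.position}: root state 'm' missing")
        seen = set()
        for s in self.states:
            if s in seen:
                raise GrammarError(f"position {self.position}: duplicate state {s!r}")
            seen.add(s)
        for t in self.transitions:
            if t.from_state == t.to_state:
                raise GrammarError(
                    f"position {self.position}: self-transition on {t.from_state!r}"
                )
            if t.from_state not in seen or t.to_state not in seen:
                raise GrammarError(
                    f"position {self.position}: transition {t} uses unknown state"
                )
        # reachability + acyclicity via depth computation
        self.depth("m")
        for s in self.states:
            self.depth(s)

    def depth(self, state: str) -> int:
        """Number of transitions separating *state* from the root ``m``.

        Raises :class:`GrammarError` if the state is unreachable or the
        graph is cyclic (paths of unbounded length).
        """
        if state not in self.states:
            raise IllegalStateError(state, self.position)
        # BFS from 'm'; grammar graphs are tiny
        dist = {"m": 0}
        frontier = ["m"]
        for _ in range(len(self.states) + 1):
            nxt = []
            for u in frontier:
                for t in self.transitions:
                    if t.from_state == u and t.to_state not in dist:
                        dist[t.to_state] = dist[u] + 1
                        nxt.append(t.to_state)
            frontier = nxt
        if len(dist) < len(self.states):
            missing = set(self.states) - set(dist)
            raise GrammarError(
                f"position {self.position}: states unreachable from 'm': {sorted(missing)}"
            )
        return dist[state]


@dataclass(frozen=True)
class MolecularSpecies:
    """A labelled molecular composition: element counts plus net charge."""

    label: str
    formula: Mapping[str, int]
    charge: int = 0

    def __post_init__(self) -> None:
        for el, n in self.formula.items():
            if n <= 0:
                raise GrammarError(
                    f"{self.label}: element count {el}={n} must be strictly positive"
                )
        object.__setattr__(self, "formula", dict(self.formula))

    @property
    def hill(self) -> str:
        return hill_formula(self.formula)


def hill_formula(formula: Mapping[str, int]) -> str:
    """Hill-notation string: C first, H second, then alphabetical."""
    parts = []
    rest = dict(formula)
    for el in ("C", "H"):
        if el in rest:
            n = rest.pop(el)
            parts.append(el + (str(n) if n != 1 else ""))
    for el in sorted(rest):
        n = rest[el]
        parts.append(el + (str(n) if n != 1 else ""))
    return "".join(parts)


def _element_masses():
    from rdkit import Chem

    return Chem.GetPeriodicTable()


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass in amu from element counts."""
    pt = _element_masses()
    return sum(pt.GetMostCommonIsotopeMass(el) * n for el, n in formula.items())


def molecular_weight(formula: Mapping[str, int]) -> float:
    """Average molecular weight in g/mol from element counts."""
    pt = _element_masses()
    return sum(pt.GetAtomicWeight(el) * n for el, n in formula.items())


@dataclass(frozen=True)
class MetaboliteCode:
    """Parent tag plus one substitution state per position, e.g. ``M_dmr``."""

    parent: str
    states: tuple[str, ...]

    @property
    def text(self) -> str:
        return f"{self.parent}_{''.join(self.states)}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text

    def state_at(self, grammar: "Grammar", position: str) -> str:
        return self.states[grammar.position_index(position)]


@dataclass(frozen=True)
class Grammar:
    """A full metabolite grammar: positions, parents and formula deltas."""

    positions: tuple[PositionStateMachine, ...]
    parents: Mapping[str, MolecularSpecies]
    # formula_deltas[position][state] -> ({element: delta}, charge_delta)
    formula_deltas: Mapping[str, Mapping[str, tuple[Mapping[str, int], int]]] = field(
        default_factory=dict
    )

    def position_index(self, position: str) -> int:
        for i, psm in enumerate(self.positions):
            if psm.position == position:
                return i
        raise GrammarError(f"unknown position {position!r}")

    def machine(self, position: str) -> PositionStateMachine:
        return self.positions[self.position_index(position)]

    def parse(self, text: str) -> MetaboliteCode:
        return parse_code(text, self)

    def step_index(self, code: MetaboliteCode) -> int:
        """Total number of grammar transitions separating *code* from
        its parent's all-``m`` code."""
        return sum(
            psm.depth(s) for psm, s in zip(self.positions, code.states)
        )


def _parse_deltas(raw: Mapping) -> dict:
    out: dict = {}
    for pos, states in (raw or {}).items():
        out[str(pos)] = {}
        for state, delta in states.items():
            d = dict(delta)
            charge = int(d.pop("charge", 0))
            out[str(pos)][str(state)] = ({k: int(v) for k, v in d.items()}, charge)
    return out


def load_grammar(source) -> Grammar:
    """Load a grammar from a YAML file path, file object or string."""
    if hasattr(source, "read"):
        raw = yaml.safe_load(source.read())
    else:
        text = str(source)
        if "\n" in text or text.lstrip().startswith(("format:", "{")):
            raw = yaml.safe_load(text)
        else:
            with open(text, "r", encoding="utf-8") as fh:
                raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or raw.get("format") != "metabolite-grammar/1":
        raise GrammarError("not a metabolite-grammar/1 document")
    positions = []
    for entry in raw["positions"]:
        transitions = tuple(
            Transition(t["from"], t["to"], t["reaction"]) for t in entry["transitions"]
        )
        positions.append(
            PositionStateMachine(
                position=str(entry["position"]),
                states=tuple(entry["states"]),
                transitions=transitions,
            )
        )
    parents = {}
    for tag, p in raw.get("parents", {}).items():
        parents[str(tag)] = MolecularSpecies(
            label=str(tag), formula=p["formula"], charge=int(p.get("charge", 0))
        )
    return Grammar(
        positions=tuple(positions),
        parents=parents,
        formula_deltas=_parse_deltas(raw.get("formula_deltas")),
    )


def default_grammar() -> Grammar:
    """The shipped mitragynine/7-hydroxymitragynine grammar."""
    ref = resources.files("mitrametab.data").joinpath("grammar_default.yaml")
    return load_grammar(ref.read_text(encoding="utf-8"))


def enumerate_metabolites(
    grammar: Grammar, parents: Iterable[str]
) -> list[MetaboliteCode]:
    """All metabolite codes: the Cartesian product of per-position states
    for each parent, in lexicographic order (parent first)."""
    parents = sorted(set(parents))
    for p in parents:
        if p not in grammar.parents:
            raise UnknownParentError(f"unknown parent tag {p!r}")
    out = []
    for parent in parents:
        for combo in itertools.product(*(psm.states for psm in grammar.positions)):
            out.append(MetaboliteCode(parent=parent, states=combo))
    out.sort(key=lambda c: c.text)
    return out


class GrammarTransitionEdge(NamedTuple):
    source: MetaboliteCode
    target: MetaboliteCode
    position: str
    reaction_type: str


def enumerate_transitions(
    grammar: Grammar, parents: Iterable[str]
) -> list[GrammarTransitionEdge]:
    """All single-step edges: metabolite pairs differing at exactly one
    position by one legal transition."""
    edges = []
    for code in enumerate_metabolites(grammar, parents):
        for i, psm in enumerate(grammar.positions):
            for t in psm.transitions:
                if code.states[i] == t.from_state:
                    target_states = list(code.states)
                    target_states[i] = t.to_state
                    edges.append(
                        GrammarTransitionEdge(
                            source=code,
                            target=MetaboliteCode(code.parent, tuple(target_states)),
                            position=psm.position,
                            reaction_type=t.reaction_type,
                        )
                    )
    edges.sort(key=lambda e: (e.source.text, e.target.text))
    return edges


def parse_code(text: str, grammar: Grammar | None = None) -> MetaboliteCode:
    """Parse a code such as ``"H_dmr"`` into a :class:`MetaboliteCode`.

    Raises :class:`IllegalStateError` naming the offending position when a
    state letter is not legal there, and :class:`UnknownParentError` for an
    unknown parent tag.
    """
    grammar = grammar or default_grammar()
    if "_" not in text:
        raise GrammarError(f"malformed code {text!r}: expected '<parent>_<states>'")
    parent, _, states = text.partition("_")
    if parent not in grammar.parents:
        raise UnknownParentError(f"unknown parent tag {parent!r} in {text!r}")
    if len(states) != len(grammar.positions):
        raise GrammarError(
            f"code {text!r} has {len(states)} state letters; "
            f"grammar defines {len(grammar.positions)} positions"
        )
    for s, psm in zip(states, grammar.positions):
        if s not in psm.states:
            raise IllegalStateError(s, psm.position)
    return MetaboliteCode(parent=parent, states=tuple(states))


def format_code(code: MetaboliteCode) -> str:
    return code.text


def formula_of(
    code: MetaboliteCode,
    grammar: Grammar | None = None,
    parent_formulas: Mapping[str, MolecularSpecies] | None = None,
) -> MolecularSpecies:
    """Molecular formula and charge of a metabolite code.

    Starts from the parent formula (default: mitragynine C23H30N2O4,
    7-hydroxymitragynine C23H30N2O5, both neutral) and applies per-state
    element/charge deltas relative to the all-``m`` state.
    """
    grammar = grammar or default_grammar()
    parent_formulas = parent_formulas or grammar.parents
    if code.parent not in parent_formulas:
        raise UnknownParentError(f"unknown parent tag {code.parent!r}")
    base = parent_formulas[code.parent]
    formula = dict(base.formula)
    charge = base.charge
    for psm, state in zip(grammar.positions, code.states):
        if state == "m":
            continue
        try:
            delta, dq = grammar.formula_deltas[psm.position][state]
        except KeyError:
            raise GrammarError(
                f"no formula delta for state {state!r} at position {psm.position}"
            ) from None
        for el, dn in delta.items():
            n = formula.get(el, 0) + dn
            if n < 0:
                raise GrammarError(
                    f"{code.text}: delta for {state!r} at position {psm.position} "
                    f"drives {el} count negative ({formula.get(el, 0)} {dn:+d})"
                )
            if n == 0:
                formula.pop(el, None)
            else:
                formula[el] = n
        charge += dq
    return MolecularSpecies(label=code.text, formula=formula, charge=charge)


def metabolite_table(
    grammar: Grammar, parents: Iterable[str]
):
    """Per-metabolite rows (code, Hill formula, charge, step index) as a
    pandas DataFrame, for TSV export."""
    import pandas as pd

    rows = []
    for code in enumerate_metabolites(grammar, parents):
        sp = formula_of(code, grammar)
        rows.append(
            {
                "code": code.text,
                "formula": sp.hill,
                "charge": sp.charge,
                "step_index": grammar.step_index(code),
            }
        )
    return pd.DataFrame(rows)
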