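"""Aggregate views over step reaction energies.

Three views are produced from a table of per-step standard Gibbs reaction
energies:

* **relative energy ladders** — cumulative aqueous Gibbs energy of every
  metabolite relative to its parent compound, summed along reaction paths
  (path independence is verified first: the network is a thermodynamic
  state function, so any two routes to the same metabolite must agree);
* **reaction-type x position averages** — unweighted arithmetic means of
  step energies grouped by reaction class and position, per parent;
* **substitution effects** — differences (7-hydroxy parent minus
  mitragynine parent) per matched step and per (type, position) group.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .network import ReactionStep
from .thermochem import ReactionEnergy, ThermoResult, reaction_energy

__all__ = [
    "AnalysisError",
    "energy_table",
    "relative_ladder",
    "position_type_averages",
    "substitution_effect",
    "render_outputs",
]

logger = logging.getLogger(__name__)

PATH_TOLERANCE = 1e-6  # kcal/mol; pure floating-point summation noise


class AnalysisError(ValueError):
    """Inconsistent inputs to an aggregation (unreachable metabolite,
    path-dependent energies, duplicate steps)."""


def energy_table(
    steps: Iterable[ReactionStep],
    energies: Mapping[str, ThermoResult] | Iterable[ReactionEnergy],
) -> pd.DataFrame:
    """One row per step: id, parent, reaction type, position, step index,
    dG_gas and dG_aq in kcal/mol.

    ``energies`` is either a per-species thermochemistry table (energies are
    computed here) or precomputed :class:`ReactionEnergy` objects.
    """
    steps = list(steps)
    if isinstance(energies, Mapping):
        computed = [reaction_energy(s, energies) for s in steps]
    else:
        computed = list(energies)
    by_id = {e.step_id: e for e in computed}
    rows = []
    for s in steps:
        if s.step_id not in by_id:
            raise AnalysisError(f"no reaction energy for step {s.step_id}")
        e = by_id[s.step_id]
        rows.append(
            {
                "step_id": s.step_id,
                "parent": s.parent,
                "reaction_type": s.reaction_type,
                "position": str(s.position),
                "step_index": s.step_index,
                "dG_gas": e.dG_gas,
                "dG_aq": e.dG_aqueous,
            }
        )
    df = pd.DataFrame(rows)
    if df["step_id"].duplicated().any():
        dups = df.loc[df["step_id"].duplicated(), "step_id"].tolist()
        raise AnalysisError(f"duplicate step ids: {dups}")
    return df.sort_values("step_id").reset_index(drop=True)


def relative_ladder(
    steps: Iterable[ReactionStep],
    table: pd.DataFrame,
    parent: str,
    tolerance: float = PATH_TOLERANCE,
) -> dict[str, float]:
    """Cumulative dG_aq of every metabolite relative to the parent code.

    Energies are summed along a spanning tree from the parent all-m code;
    every network edge is then re-checked against the assigned levels, so a
    path-dependent (unbalanced) network raises :class:`AnalysisError`.
    """
    steps = [s for s in steps if s.parent == parent]
    if not steps:
        raise AnalysisError(f"no steps for parent {parent!r}")
    dg = dict(zip(table["step_id"], table["dG_aq"]))
    g = nx.DiGraph()
    for s in steps:
        if s.step_id not in dg:
            raise AnalysisError(f"no energy for step {s.step_id}")
        g.add_edge(s.source.text, s.target.text, dG=dg[s.step_id])
    n_positions = len(next(iter(g.nodes)).split("_", 1)[1])
    root = f"{parent}_{'m' * n_positions}"
    if root not in g.nodes:
        raise AnalysisError(f"parent code {root!r} not present in the network")
    levels = {root: 0.0}
    for u, v in nx.bfs_edges(g.to_undirected(as_view=True), root):
        if g.has_edge(u, v):
            levels[v] = levels[u] + g[u][v]["dG"]
        else:
            levels[v] = levels[u] - g[v][u]["dG"]
    unreachable = set(g.nodes) - set(levels)
    if unreachable:
        raise AnalysisError(
            f"metabolites unreachable from {root}: {sorted(unreachable)}"
        )
    for u, v, data in g.edges(data=True):
        dev = abs(levels[v] - levels[u] - data["dG"])
        if dev > tolerance:
            raise AnalysisError(
                f"path-dependent energies: edge {u}->{v} deviates by {dev:.3g} "
                f"kcal/mol (> {tolerance:g}); the network is not balanced"
            )
    return levels


def position_type_averages(table: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean dG_aq (and dG_gas) per (parent, reaction type,
    position) group, with group sizes."""
    if table.empty:
        raise AnalysisError("empty energy table")
    grouped = (
        table.groupby(["parent", "reaction_type", "position"], as_index=False)
        .agg(
            n=("step_id", "size"),
            mean_dG_aq=("dG_aq", "mean"),
            mean_dG_gas=("dG_gas", "mean"),
        )
        .sort_values(["parent", "reaction_type", "position"])
        .reset_index(drop=True)
    )
    return grouped


def _strip_parent(step_id: str) -> str:
    src, _, tgt = step_id.partition("->")
    return f"{src.split('_', 1)[1]}->{tgt.split('_', 1)[1]}"


def substitution_effect(
    table_m: pd.DataFrame, table_h: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-step and per-(type, position) energy differences H minus M.

    Steps are matched by their parent-independent transition (the code
    suffixes); unmatched steps are reported and excluded.  Returns
    (per-step ddG table, per-group average ddG table, unmatched step ids).
    """
    m = table_m.assign(key=table_m["step_id"].map(_strip_parent))
    h = table_h.assign(key=table_h["step_id"].map(_strip_parent))
    merged = m.merge(h, on="key", suffixes=("_M", "_H"), how="outer", indicator=True)
    unmatched = merged.loc[merged["_merge"] != "both"]
    unmatched_ids = sorted(
        unmatched["step_id_M"].dropna().tolist()
        + unmatched["step_id_H"].dropna().tolist()
    )
    if unmatched_ids:
        logger.warning("substitution_effect: unmatched steps excluded: %s", unmatched_ids)
    both = merged.loc[merged["_merge"] == "both"].copy()
    per_step = pd.DataFrame(
        {
            "transition": both["key"],
            "reaction_type": both["reaction_type_M"],
            "position": both["position_M"],
            "step_index": both["step_index_M"],
            "ddG_aq": both["dG_aq_H"] - both["dG_aq_M"],
            "ddG_gas": both["dG_gas_H"] - both["dG_gas_M"],
        }
    ).sort_values("transition").reset_index(drop=True)
    per_group = (
        per_step.groupby(["reaction_type", "position"], as_index=False)
        .agg(n=("transition", "size"), mean_ddG_aq=("ddG_aq", "mean"))
        .sort_values(["reaction_type", "position"])
        .reset_index(drop=True)
    )
    return per_step, per_group, unmatched_ids


def render_outputs(
    ladders: Mapping[str, Mapping[str, float]],
    averages: pd.DataFrame,
    outdir,
    energy_tables: Mapping[str, pd.DataFrame] | None = None,
) -> list[str]:
    """Write ladder and average-bar figures (SVG) plus TSVs; returns the
    paths written.  Deterministic: reruns produce byte-identical TSVs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    # ladder figure: one panel per parent, levels sorted by step count
    n_panels = max(len(ladders), 1)
    fig, axes = plt.subplots(1, n_panels, figsize=(6 * n_panels, 5), squeeze=False)
    for ax, (parent, levels) in zip(axes[0], sorted(ladders.items())):
        if not levels:
            logger.warning("empty ladder for parent %s", parent)
            continue
        ordered = sorted(levels.items(), key=lambda kv: kv[1])
        for i, (code, e) in enumerate(ordered):
            ax.hlines(e, i - 0.35, i + 0.35)
            ax.annotate(
                code, (i, e), textcoords="offset points", xytext=(0, 4),
                ha="center", fontsize=7, rotation=60,
            )
        ax.set_title(f"relative aqueous G, parent {parent}")
        ax.set_ylabel("dG relative to parent (kcal/mol)")
        ax.set_xticks([])
    ladder_svg = outdir / "ladders.svg"
    fig.savefig(ladder_svg)
    plt.close(fig)
    written.append(str(ladder_svg))

    # averages bar chart
    fig, ax = plt.subplots(figsize=(8, 5))
    if not averages.empty:
        labels = [
            f"{r.reaction_type[:5]}@{r.position}/{r.parent}"
            for r in averages.itertuples()
        ]
        ax.bar(range(len(labels)), averages["mean_dG_aq"])
        ax.set_xticks(range(len(labels)))
        ax.set_xticklabels(labels, rotation=75, fontsize=7)
        ax.set_ylabel("mean dG_aq (kcal/mol)")
    avg_svg = outdir / "averages.svg"
    fig.savefig(avg_svg)
    plt.close(fig)
    written.append(str(avg_svg))

    for parent, levels in sorted(ladders.items()):
        df = pd.DataFrame(
            sorted(levels.items()), columns=["code", "dG_aq_relative"]
        )
        p = outdir / f"ladder_{parent}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.6f")
        written.append(str(p))
    p = outdir / "averages.tsv"
    averages.to_csv(p, sep="\t", index=False, float_format="%.6f")
    written.append(str(p))
    if energy_tables:
        for parent, df in sorted(energy_tables.items()):
            p = outdir / f"energies_{parent}.tsv"
            df.to_csv(p, sep="\t", index=False, float_format="%.6f")
            written.append(str(p))
    return written
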