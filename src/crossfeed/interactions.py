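"""Prediction of synergistic species interactions by pathway cover.

Given the binary species × reaction capability table produced by the
annotation stage, a pathway (an ordered set of reactions) and optional
constraints, this module reports

* *complete* species — able to perform every pathway reaction alone —
  and
* *combinations* — species sets of size >= 2 whose joint capabilities
  cover the required fraction of the pathway while satisfying every
  constraint, with per-reaction contributor attribution.

Constraints mirror common experimental design choices: subsets of
reactions that one member must carry alone (e.g., a multi-step
conversion whose intermediate is not exchanged), transporter
requirements, a cap on combination size, and the pathway-completeness
fraction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations as itercombos
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .gpr import REACTION_PATTERN, SpeciesReactionTable

__all__ = [
    "InteractionError",
    "PathwayDef",
    "ConstraintSet",
    "Combination",
    "InteractionResult",
    "complete_species",
    "satisfies_constraints",
    "covers",
    "enumerate_combinations",
    "compare_to_observations",
    "export_network",
    "read_pathways_tsv",
    "read_constraints_tsv",
    "write_interactions",
]

MAX_ENUM_SPECIES = 30


class InteractionError(ValueError):
    pass


@dataclass(frozen=True)
class PathwayDef:
    name: str
    reactions: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.reactions:
            raise InteractionError(f"pathway {self.name} has no reactions")


@dataclass(frozen=True)
class ConstraintSet:
    """Constraints applied to candidate species combinations.

    ``single_species_subsets``: each reaction subset must be fully
    carried by at least one member on its own.
    ``transporter_mode``: 'off' (no check), 'any_member' (some member
    carries a transporter reaction) or 'every_member'.
    ``completeness_fraction``: fraction of pathway reactions a
    combination must jointly cover (1.0 = full cover).
    """

    single_species_subsets: tuple[frozenset[str], ...] = ()
    transporter_reactions: frozenset[str] = frozenset()
    transporter_mode: str = "off"
    max_combination_size: int | None = None
    completeness_fraction: float = 1.0
    include_complete_in_combinations: bool = True

    def __post_init__(self) -> None:
        if self.transporter_mode not in ("off", "any_member", "every_member"):
            raise InteractionError(
                f"unknown transporter_mode {self.transporter_mode!r}"
            )
        if not 0.0 < self.completeness_fraction <= 1.0:
            raise InteractionError("completeness_fraction must be in (0, 1]")
        if self.max_combination_size is not None and self.max_combination_size < 2:
            raise InteractionError("max_combination_size must be >= 2")
        if any(not s for s in self.single_species_subsets):
            raise InteractionError("empty single-species reaction subset")


@dataclass(frozen=True)
class Combination:
    members: tuple[str, ...]
    contributors: tuple[tuple[str, tuple[str, ...]], ...]  # reaction -> members

    def contributor_map(self) -> dict[str, tuple[str, ...]]:
        return dict(self.contributors)


@dataclass
class InteractionResult:
    pathway: PathwayDef
    complete_species: list[str]
    combinations: list[Combination]


def _check_reactions(table: SpeciesReactionTable, reactions: Iterable[str]) -> None:
    known = set(table.reactions)
    unknown = [r for r in reactions if r not in known]
    if unknown:
        raise InteractionError(
            f"reactions absent from the capability table: {unknown}"
        )


def complete_species(
    table: SpeciesReactionTable, pathway: PathwayDef
) -> list[str]:
    """Species whose own row covers every pathway reaction."""
    _check_reactions(table, pathway.reactions)
    out = []
    for sp in table.species:
        caps = table.reactions_of(sp)
        if all(r in caps for r in pathway.reactions):
            out.append(sp)
    return sorted(out)


def satisfies_constraints(
    combo: Iterable[str],
    table: SpeciesReactionTable,
    constraints: ConstraintSet,
) -> bool:
    """Constraint predicate over one species set (coverage not included)."""
    members = sorted(set(combo))
    if not members:
        raise InteractionError("empty species combination")
    caps = {sp: table.reactions_of(sp) for sp in members}
    for subset in constraints.single_species_subsets:
        if not any(subset <= caps[sp] for sp in members):
            return False
    if constraints.transporter_mode == "any_member":
        if not any(caps[sp] & constraints.transporter_reactions for sp in members):
            return False
    elif constraints.transporter_mode == "every_member":
        if not all(caps[sp] & constraints.transporter_reactions for sp in members):
            return False
    if (
        constraints.max_combination_size is not None
        and len(members) > constraints.max_combination_size
    ):
        return False
    return True


def covers(
    combo: Iterable[str],
    table: SpeciesReactionTable,
    pathway: PathwayDef,
    completeness_fraction: float = 1.0,
) -> bool:
    """True when the members jointly cover enough pathway reactions."""
    members = set(combo)
    joint: set[str] = set()
    for sp in members:
        joint |= table.reactions_of(sp)
    needed = math.ceil(completeness_fraction * len(pathway.reactions))
    covered = sum(1 for r in pathway.reactions if r in joint)
    return covered >= needed


def enumerate_combinations(
    table: SpeciesReactionTable,
    pathway: PathwayDef,
    constraints: ConstraintSet | None = None,
) -> InteractionResult:
    """All species combinations whose joint genomic potential covers
    the pathway under the constraints.

    Complete species are always reported separately; whether they may
    also appear inside combinations is governed by
    ``include_complete_in_combinations``.  Output order is by
    combination size, then lexicographic, so runs are reproducible.
    """
    constraints = constraints or ConstraintSet()
    _check_reactions(table, pathway.reactions)
    _check_reactions(table, constraints.transporter_reactions)
    for subset in constraints.single_species_subsets:
        _check_reactions(table, subset)

    complete = complete_species(table, pathway)
    pool = sorted(table.species)
    if not constraints.include_complete_in_combinations:
        pool = [sp for sp in pool if sp not in set(complete)]
    if len(pool) > MAX_ENUM_SPECIES:
        raise InteractionError(
            f"{len(pool)} candidate species exceed the enumeration bound of "
            f"{MAX_ENUM_SPECIES}; tighten constraints or reduce the pool"
        )

    caps = {sp: table.reactions_of(sp) for sp in pool}
    max_size = constraints.max_combination_size or len(pool)
    needed = math.ceil(constraints.completeness_fraction * len(pathway.reactions))
    found: list[Combination] = []
    for size in range(2, max_size + 1):
        for members in itercombos(pool, size):
            joint: set[str] = set()
            for sp in members:
                joint |= caps[sp]
            covered = [r for r in pathway.reactions if r in joint]
            if len(covered) < needed:
                continue
            if not satisfies_constraints(members, table, constraints):
                continue
            contributors = tuple(
                (r, tuple(sp for sp in members if r in caps[sp]))
                for r in covered
            )
            found.append(Combination(members=members, contributors=contributors))
    return InteractionResult(
        pathway=pathway, complete_species=complete, combinations=found
    )


def compare_to_observations(
    result: InteractionResult,
    table: SpeciesReactionTable,
    pathway: PathwayDef,
    constraints: ConstraintSet | None = None,
    observed: Sequence[tuple[Iterable[str], bool]] = (),
) -> tuple[int, int]:
    """How many observed growing consortia the genomic potential explains.

    An observed set counts as explained when it contains a complete
    species, or when its members jointly cover the pathway and satisfy
    the constraints.  Returns ``(explained, total_grown)``.
    """
    constraints = constraints or ConstraintSet()
    known = set(table.species)
    complete = set(result.complete_species)
    explained = 0
    total_grown = 0
    for members, grew in observed:
        members = sorted(set(members))
        unknown = [sp for sp in members if sp not in known]
        if unknown:
            raise InteractionError(f"unknown species in observation: {unknown}")
        if not grew:
            continue
        total_grown += 1
        if set(members) & complete:
            explained += 1
        elif covers(members, table, pathway, constraints.completeness_fraction) and satisfies_constraints(
            members, table, constraints
        ):
            explained += 1
    return explained, total_grown


# --------------------------------------------------------------------------
# Network export
# --------------------------------------------------------------------------

_KEGG_REACTION_URL = "https://www.genome.jp/entry/{rid}"

_HTML_TEMPLATE = """<!DOCTYPE html>
<html>
<head><meta charset="utf-8"><title>Species–reaction network</title>
<style>
 body {{ font-family: sans-serif; }}
 svg {{ border: 1px solid #ccc; }}
 .species {{ fill: #4878d0; }}
 .reaction {{ fill: #ee854a; }}
 text {{ font-size: 11px; }}
 line {{ stroke: #999; stroke-width: 1; }}
</style></head>
<body>
<h2>Species–reaction capability network</h2>
<svg id="net" width="900" height="700"></svg>
<script>
const graph = {graph_json};
const svg = document.getElementById("net");
const W = 900, H = 700;
const species = graph.nodes.filter(n => n.kind === "species");
const reactions = graph.nodes.filter(n => n.kind === "reaction");
const pos = {{}};
species.forEach((n, i) => {{
  pos[n.id] = [150, 60 + i * (H - 120) / Math.max(1, species.length - 1)];
}});
reactions.forEach((n, i) => {{
  pos[n.id] = [750, 60 + i * (H - 120) / Math.max(1, reactions.length - 1)];
}});
const ns = "http://www.w3.org/2000/svg";
graph.links.forEach(e => {{
  const l = document.createElementNS(ns, "line");
  const [x1, y1] = pos[e.source], [x2, y2] = pos[e.target];
  l.setAttribute("x1", x1); l.setAttribute("y1", y1);
  l.setAttribute("x2", x2); l.setAttribute("y2", y2);
  svg.appendChild(l);
}});
graph.nodes.forEach(n => {{
  const [x, y] = pos[n.id];
  const c = document.createElementNS(ns, "circle");
  c.setAttribute("cx", x); c.setAttribute("cy", y); c.setAttribute("r", 8);
  c.setAttribute("class", n.kind);
  const t = document.createElementNS(ns, "text");
  t.setAttribute("x", n.kind === "species" ? x - 12 : x + 12);
  t.setAttribute("y", y + 4);
  t.setAttribute("text-anchor", n.kind === "species" ? "end" : "start");
  t.textContent = n.id;
  if (n.url) {{
    const a = document.createElementNS(ns, "a");
    a.setAttribute("href", n.url);
    a.appendChild(c); a.appendChild(t);
    svg.appendChild(a);
  }} else {{
    svg.appendChild(c); svg.appendChild(t);
  }}
}});
</script>
</body></html>
"""


def export_network(
    table: SpeciesReactionTable,
    pathway: PathwayDef | None,
    out_path: str | Path,
) -> nx.Graph:
    """Write the bipartite species–reaction network.

    Emits ``<out_path>.json`` (node-link JSON) and ``<out_path>.html``
    (static page embedding the graph).  Edges are exactly the 1-cells
    of the capability table, restricted to the pathway's reactions
    when a pathway is given.  KEGG-style reaction ids (``R#####``)
    carry a hyperlink to their KEGG entry.
    """
    if not table.species:
        raise InteractionError("empty capability table")
    reactions = list(pathway.reactions) if pathway is not None else table.reactions
    _check_reactions(table, reactions)
    graph = nx.Graph()
    for sp in table.species:
        graph.add_node(sp, kind="species", bipartite=0)
    for r in reactions:
        url = _KEGG_REACTION_URL.format(rid=r) if REACTION_PATTERN.match(r) else None
        graph.add_node(r, kind="reaction", bipartite=1, url=url)
    for sp in table.species:
        caps = table.reactions_of(sp)
        for r in reactions:
            if r in caps:
                graph.add_edge(sp, r)

    out_path = Path(out_path)
    data = nx.node_link_data(graph, edges="links")
    # stable ordering for byte-identical re-runs
    data["nodes"] = sorted(data["nodes"], key=lambda n: (n["kind"], n["id"]))
    data["links"] = sorted(
        ({"source": min(l["source"], l["target"]), "target": max(l["source"], l["target"])}
         for l in data["links"]),
        key=lambda l: (l["source"], l["target"]),
    )
    graph_json = json.dumps(data, indent=1, sort_keys=True)
    out_path.with_suffix(".json").write_text(graph_json)
    out_path.with_suffix(".html").write_text(
        _HTML_TEMPLATE.format(graph_json=graph_json)
    )
    return graph


# --------------------------------------------------------------------------
# Config files and result output
# --------------------------------------------------------------------------

def read_pathways_tsv(path: str | Path) -> list[PathwayDef]:
    """TSV with columns pathway_name, comma-separated reaction ids."""
    pathways: list[PathwayDef] = []
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if lineno == 1 and line.split("\t")[0].strip().lower() == "pathway_name":
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise InteractionError(
                f"{path}: line {lineno}: expected pathway_name<TAB>reactions"
            )
        reactions = tuple(
            r.strip() for r in fields[1].split(",") if r.strip()
        )
        pathways.append(PathwayDef(name=fields[0].strip(), reactions=reactions))
    if not pathways:
        raise InteractionError(f"{path}: no pathways defined")
    return pathways


def read_constraints_tsv(path: str | Path) -> dict[str, ConstraintSet]:
    """TSV columns: pathway_name, single_species_subsets (groups split
    by ';', reactions by ','), transporters (comma list), max_size,
    completeness, and optionally transporter_mode."""
    out: dict[str, ConstraintSet] = {}
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if lineno == 1 and line.split("\t")[0].strip().lower() == "pathway_name":
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise InteractionError(
                f"{path}: line {lineno}: expected at least 5 tab-separated columns"
            )
        name = fields[0].strip()
        subsets = tuple(
            frozenset(r.strip() for r in group.split(",") if r.strip())
            for group in fields[1].split(";")
            if group.strip()
        )
        transporters = frozenset(
            r.strip() for r in fields[2].split(",") if r.strip()
        )
        max_size = int(fields[3]) if fields[3].strip() else None
        completeness = float(fields[4]) if fields[4].strip() else 1.0
        mode = fields[5].strip() if len(fields) > 5 and fields[5].strip() else (
            "any_member" if transporters else "off"
        )
        out[name] = ConstraintSet(
            single_species_subsets=subsets,
            transporter_reactions=transporters,
            transporter_mode=mode,
            max_combination_size=max_size,
            completeness_fraction=completeness,
        )
    return out


def write_interactions(
    result: InteractionResult, directory: str | Path
) -> None:
    """Write ``complete_species.txt`` and ``combinations.tsv`` for one
    pathway into the interactions folder."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prefix = result.pathway.name
    (directory / f"{prefix}_complete_species.txt").write_text(
        "\n".join(result.complete_species) + ("\n" if result.complete_species else "")
    )
    lines = ["members\tsize\treaction_contributors"]
    for combo in result.combinations:
        attribution = ";".join(
            f"{r}:{','.join(sps)}" for r, sps in combo.contributors
        )
        lines.append(
            f"{','.join(combo.members)}\t{len(combo.members)}\t{attribution}"
        )
    (directory / f"{prefix}_combinations.tsv").write_text("\n".join(lines) + "\n")
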