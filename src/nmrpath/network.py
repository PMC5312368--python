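"""Bipartite metabolite-enzyme network from KGML-style pathway files.

Each pathway file contributes compound nodes, enzyme nodes (gene entries are
collapsed to their enzyme identity) and compound-enzyme incidences derived
from reactions (an enzyme is linked to each substrate and product of its
reaction) and from compound-typed relation elements. All fragments are
merged by node id into one "biograph"; pathway membership is accumulated on
nodes and edges.

Perturbed subnetworks are the union, over significantly correlated
metabolite pairs, of every node and edge lying on any shortest path between
the pair. Interior metabolite nodes of those paths are NMR-invisible
intermediates; metabolites absent from the pathway files are kept as
external nodes connected only by their correlation edges. Edges are
unweighted and undirected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from lxml import etree

from .errors import ArgumentError, GraphLookupError, MergeError, ParseError

__all__ = [
    "PathwayFragment",
    "MetabolicGraph",
    "PerturbedNetwork",
    "parse_kgml",
    "build_biograph",
    "shortest_path_length",
    "extract_subnetwork",
    "write_outputs",
]

_ENTRY_PREFIXES = ("cpd:", "ec:", "gn:", "ko:", "rn:", "path:")


def _strip_prefix(name: str) -> str:
    for p in _ENTRY_PREFIXES:
        if name.startswith(p):
            return name[len(p):]
    return name


@dataclass
class PathwayFragment:
    pathway_id: str
    title: str
    graph: nx.Graph


@dataclass
class MetabolicGraph:
    """Merged bipartite metabolite-enzyme graph with pathway membership."""

    graph: nx.Graph
    pathway_ids: list[str] = field(default_factory=list)
    pathway_titles: dict[str, str] = field(default_factory=dict)

    def metabolites(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["type"] == "metabolite")

    def enzymes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["type"] == "enzyme")

    @property
    def counts(self) -> dict[str, int]:
        return {
            "n_pathways": len(self.pathway_ids),
            "n_metabolites": len(self.metabolites()),
            "n_enzymes": len(self.enzymes()),
            "n_relations": self.graph.number_of_edges(),
        }

    def is_bipartite(self) -> bool:
        return all(
            self.graph.nodes[u]["type"] != self.graph.nodes[v]["type"]
            for u, v in self.graph.edges
        )


def parse_kgml(path) -> PathwayFragment:
    """Parse one KGML-dialect file into a bipartite pathway fragment."""
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "pathway":
        raise ParseError(f"{path}: root element is <{root.tag}>, expected <pathway>")
    pid = _strip_prefix(root.get("name", path.stem))
    title = root.get("title", pid)
    g = nx.Graph()
    entry_nodes: dict[str, tuple[str, str]] = {}  # entry id -> (node id, node type)
    reaction_enzymes: dict[str, list[str]] = {}  # reaction name -> enzyme node ids

    for entry in root.findall("entry"):
        etype = entry.get("type")
        name = entry.get("name", "")
        eid = entry.get("id")
        if etype == "compound":
            node, ntype = _strip_prefix(name), "metabolite"
        elif etype in ("enzyme", "gene", "ortholog"):
            node, ntype = _strip_prefix(name), "enzyme"
        elif etype in ("map", "group"):
            continue  # cross-references, no network node
        else:
            raise ParseError(
                f"{path}: unknown entry type '{etype}' (entry id {eid}, line {entry.sourceline})"
            )
        if node in g and g.nodes[node]["type"] != ntype:
            raise ParseError(f"{path}: node '{node}' declared with conflicting types")
        g.add_node(node, type=ntype, name=node, pathways=(pid,))
        entry_nodes[eid] = (node, ntype)
        for rname in (entry.get("reaction") or "").split():
            reaction_enzymes.setdefault(rname, []).append(node)

    def _edge(a: str, b: str) -> None:
        g.add_edge(a, b, pathways=(pid,))

    for rx in root.findall("reaction"):
        rname = rx.get("name", "")
        enzymes = list(reaction_enzymes.get(rname, []))
        if not enzymes:
            rid = rx.get("id")
            if rid in entry_nodes and entry_nodes[rid][1] == "enzyme":
                enzymes = [entry_nodes[rid][0]]
        compounds = []
        for child in rx:
            if child.tag in ("substrate", "product"):
                compounds.append(_strip_prefix(child.get("name", "")))
        for enz in enzymes:
            for c in compounds:
                if c in g and g.nodes[c]["type"] == "metabolite":
                    _edge(enz, c)

    for rel in root.findall("relation"):
        for sub in rel.findall("subtype"):
            if sub.get("name") != "compound":
                continue
            cid = sub.get("value")
            if cid not in entry_nodes or entry_nodes[cid][1] != "metabolite":
                continue
            cnode = entry_nodes[cid][0]
            for key in ("entry1", "entry2"):
                eid = rel.get(key)
                if eid in entry_nodes and entry_nodes[eid][1] == "enzyme":
                    _edge(entry_nodes[eid][0], cnode)

    return PathwayFragment(pathway_id=pid, title=title, graph=g)


def build_biograph(fragments: list[PathwayFragment]) -> MetabolicGraph:
    """Node-id union merge of pathway fragments into one biograph."""
    if not fragments:
        raise ArgumentError("at least one pathway fragment is required")
    merged = nx.Graph()
    titles: dict[str, str] = {}
    for frag in fragments:
        titles[frag.pathway_id] = frag.title
        for node, data in frag.graph.nodes(data=True):
            if node in merged:
                if merged.nodes[node]["type"] != data["type"]:
                    raise MergeError(
                        f"node '{node}' is '{merged.nodes[node]['type']}' in one pathway "
                        f"and '{data['type']}' in '{frag.pathway_id}'"
                    )
                pw = set(merged.nodes[node]["pathways"]) | set(data["pathways"])
                merged.nodes[node]["pathways"] = tuple(sorted(pw))
            else:
                merged.add_node(node, **{**data, "pathways": tuple(data["pathways"])})
        for u, v, data in frag.graph.edges(data=True):
            if merged.has_edge(u, v):
                pw = set(merged.edges[u, v]["pathways"]) | set(data["pathways"])
                merged.edges[u, v]["pathways"] = tuple(sorted(pw))
            else:
                merged.add_edge(u, v, pathways=tuple(data["pathways"]))
    return MetabolicGraph(
        graph=merged,
        pathway_ids=sorted(titles),
        pathway_titles=titles,
    )


def shortest_path_length(g: MetabolicGraph, m1: str, m2: str) -> float:
    """Unweighted hop count between two metabolite nodes; inf if unreachable.

    Metabolite-metabolite distances are even by bipartiteness; the self
    distance is 0. A missing id raises a lookup error, distinct from
    unreachability.
    """
    for m in (m1, m2):
        if m not in g.graph:
            raise GraphLookupError(f"node '{m}' is not in the graph")
        if g.graph.nodes[m]["type"] != "metabolite":
            raise ArgumentError(f"node '{m}' is not a metabolite")
    try:
        return float(nx.shortest_path_length(g.graph, m1, m2))
    except nx.NetworkXNoPath:
        return float("inf")


@dataclass
class PerturbedNetwork:
    graph: nx.Graph
    roles: dict[str, str]  # node -> correlated-measured | intermediate | enzyme | external
    directions: dict[str, str]  # measured metabolite -> up | down | unchanged
    correlation_edges: list[tuple[str, str, float]]
    skipped_pairs: list[tuple[str, str, float]]  # too far (beyond max_len) or unreachable
    unmapped: list[str]  # metabolites absent from the pathway files

    @property
    def counts(self) -> dict[str, int]:
        roles = list(self.roles.values())
        return {
            "n_correlated": roles.count("correlated-measured"),
            "n_intermediates": roles.count("intermediate"),
            "n_enzymes": roles.count("enzyme"),
            "n_external": roles.count("external"),
            "n_relations": sum(
                1 for _, _, d in self.graph.edges(data=True) if d.get("kind") != "correlation"
            ),
        }


def extract_subnetwork(
    g: MetabolicGraph,
    metabolite_pairs: dict[tuple[str, str], float] | list[tuple[str, str]],
    directions: dict[str, str] | None = None,
    max_len: float = float("inf"),
) -> PerturbedNetwork:
    """Union of all shortest paths between each correlated metabolite pair.

    Pairs farther apart than ``max_len`` (or unreachable) are skipped and
    reported. Metabolites not present in the biograph are attached as
    external nodes connected only by their correlation edges.
    """
    if not metabolite_pairs:
        raise ArgumentError("empty metabolite pair list")
    if not isinstance(metabolite_pairs, dict):
        metabolite_pairs = {tuple(sorted(p)): float("nan") for p in metabolite_pairs}
    sub = nx.Graph()
    roles: dict[str, str] = {}
    skipped: list[tuple[str, str, float]] = []
    unmapped: list[str] = []
    corr_edges: list[tuple[str, str, float]] = []

    def _mark(node: str, role: str) -> None:
        # correlated-measured wins over intermediate; enzyme/external are fixed
        prev = roles.get(node)
        rank = {"external": 0, "enzyme": 1, "intermediate": 2, "correlated-measured": 3}
        if prev is None or rank[role] > rank[prev]:
            roles[node] = role

    for (a, b), r in sorted(metabolite_pairs.items()):
        corr_edges.append((a, b, r))
        a_in = a in g.graph and g.graph.nodes[a]["type"] == "metabolite"
        b_in = b in g.graph and g.graph.nodes[b]["type"] == "metabolite"
        for node, present in ((a, a_in), (b, b_in)):
            if not present and node not in unmapped:
                unmapped.append(node)
        if not (a_in and b_in):
            for node, present in ((a, a_in), (b, b_in)):
                sub.add_node(node)
                _mark(node, "correlated-measured" if present else "external")
            sub.add_edge(a, b, kind="correlation", r=r)
            continue
        try:
            d = nx.shortest_path_length(g.graph, a, b)
        except nx.NetworkXNoPath:
            skipped.append((a, b, float("inf")))
            continue
        if d > max_len:
            skipped.append((a, b, float(d)))
            continue
        for path in nx.all_shortest_paths(g.graph, a, b):
            for node in path:
                sub.add_node(node, **g.graph.nodes[node])
                ntype = g.graph.nodes[node]["type"]
                if ntype == "enzyme":
                    _mark(node, "enzyme")
                elif node in (a, b):
                    _mark(node, "correlated-measured")
                else:
                    _mark(node, "intermediate")
            for u, v in zip(path, path[1:]):
                sub.add_edge(u, v, **g.graph.edges[u, v])
        sub.add_edge(a, b, kind="correlation", r=r)
    dirs = {
        n: (directions or {}).get(n, "unchanged")
        for n, role in roles.items()
        if role == "correlated-measured"
    }
    return PerturbedNetwork(
        graph=sub,
        roles=roles,
        directions=dirs,
        correlation_edges=corr_edges,
        skipped_pairs=skipped,
        unmapped=unmapped,
    )


def write_outputs(net: PerturbedNetwork, out_dir, stem: str) -> None:
    """GraphML + SIF + JSON manifest for a perturbed network."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    export = nx.Graph()
    for n, d in net.graph.nodes(data=True):
        export.add_node(n, type=d.get("type", "external"), role=net.roles.get(n, ""))
    for u, v, d in net.graph.edges(data=True):
        export.add_edge(
            u, v, kind=d.get("kind", "relation"), pathways=";".join(d.get("pathways", ()))
        )
    nx.write_graphml(export, out_dir / f"{stem}.graphml")
    with open(out_dir / f"{stem}.sif", "w") as fh:
        for u, v, d in sorted(net.graph.edges(data=True)):
            kind = d.get("kind", "relation")
            fh.write(f"{u}\t{kind}\t{v}\n")
    manifest = {
        "roles": dict(sorted(net.roles.items())),
        "directions": dict(sorted(net.directions.items())),
        "unmapped": sorted(net.unmapped),
        "skipped_pairs": [[a, b, d] for a, b, d in net.skipped_pairs],
        "counts": net.counts,
    }
    with open(out_dir / f"{stem}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
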