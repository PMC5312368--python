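"""Pathway topology analysis: impact by relative betweenness centrality.

Each pathway is projected to its metabolite-level graph (two metabolites
are adjacent iff they share an enzyme in that pathway). Pathway impact is
the sum of betweenness centralities of the hit metabolites divided by the
sum over all pathway metabolites, so alterations at topologically central
nodes weigh more than alterations at marginal nodes. Betweenness uses the
unordered-pair convention (each pair s != t counted once); the convention
cancels in the impact ratio. A pathway is significantly altered when its
impact reaches the threshold (default 0.3); a hypergeometric upper-tail
enrichment p-value is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy import stats

from .errors import ArgumentError
from .network import MetabolicGraph

__all__ = [
    "PathwayImpactRow",
    "metabolite_projection",
    "betweenness",
    "pathway_impact",
    "enrichment_p",
    "significant_pathways",
    "pathway_impact_table",
]


@dataclass
class PathwayImpactRow:
    pathway_id: str
    name: str
    impact: float
    enrichment_p: float
    hits: int
    pathway_size: int
    significant: bool


def metabolite_projection(g: MetabolicGraph, pathway_id: str) -> nx.Graph:
    """Metabolite-level graph of one pathway (shared-enzyme adjacency)."""
    gg = g.graph
    mets = [
        n
        for n, d in gg.nodes(data=True)
        if d["type"] == "metabolite" and pathway_id in d["pathways"]
    ]
    if not mets:
        raise ArgumentError(f"pathway '{pathway_id}' has no metabolites")
    proj = nx.Graph()
    proj.add_nodes_from(mets)
    for enz, d in gg.nodes(data=True):
        if d["type"] != "enzyme" or pathway_id not in d["pathways"]:
            continue
        neigh = [
            m
            for m in gg.neighbors(enz)
            if gg.nodes[m]["type"] == "metabolite"
            and pathway_id in gg.edges[enz, m]["pathways"]
        ]
        for a_i in range(len(neigh)):
            for b_i in range(a_i + 1, len(neigh)):
                proj.add_edge(neigh[a_i], neigh[b_i])
    return proj


def betweenness(pathway_graph: nx.Graph) -> dict[str, float]:
    """Unordered-pair betweenness centrality per metabolite (unnormalized)."""
    if pathway_graph.number_of_nodes() == 0:
        raise ArgumentError("empty pathway graph")
    return nx.betweenness_centrality(pathway_graph, normalized=False)


def pathway_impact(pathway_graph: nx.Graph, hit_metabolites) -> float:
    """Sum of hit betweenness over total pathway betweenness.

    Falls back to hits / pathway size when every centrality is zero (e.g.
    complete or 2-node pathways).
    """
    hits = set(hit_metabolites)
    members = set(pathway_graph.nodes)
    outside = hits - members
    if outside:
        warnings.warn(f"{len(outside)} hit metabolites are not pathway members; ignored")
    hits &= members
    if not hits:
        return 0.0
    bc = betweenness(pathway_graph)
    total = sum(bc.values())
    if total == 0:
        return len(hits) / len(members)
    return sum(bc[m] for m in hits) / total


def enrichment_p(
    hits_in_pathway: int, pathway_size: int, total_hits: int, universe_size: int
) -> float:
    """Hypergeometric upper tail P(X >= hits_in_pathway)."""
    if not (
        0 <= hits_in_pathway <= min(pathway_size, total_hits)
        and pathway_size <= universe_size
        and total_hits <= universe_size
    ):
        raise ArgumentError(
            f"inconsistent counts: hits={hits_in_pathway}, size={pathway_size}, "
            f"total_hits={total_hits}, universe={universe_size}"
        )
    if hits_in_pathway == 0:
        return 1.0
    return float(stats.hypergeom.sf(hits_in_pathway - 1, universe_size, pathway_size, total_hits))


def significant_pathways(
    rows: list[PathwayImpactRow] | pd.DataFrame, impact_threshold: float = 0.3
) -> pd.DataFrame:
    """Rows with >= 1 hit and impact >= threshold, by impact desc then p asc."""
    frame = rows if isinstance(rows, pd.DataFrame) else _rows_to_frame(rows)
    out = frame[(frame["impact"] >= impact_threshold) & (frame["hits"] >= 1)].copy()
    return out.sort_values(["impact", "enrichment_p"], ascending=[False, True]).reset_index(
        drop=True
    )


def _rows_to_frame(rows: list[PathwayImpactRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id,
                "name": r.name,
                "impact": r.impact,
                "enrichment_p": r.enrichment_p,
                "hits": r.hits,
                "pathway_size": r.pathway_size,
                "significant": r.significant,
            }
            for r in rows
        ]
    )


def pathway_impact_table(
    g: MetabolicGraph,
    hit_metabolites,
    impact_threshold: float = 0.3,
    universe: list[str] | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Impact + enrichment for every pathway in the biograph.

    The enrichment universe defaults to all biograph metabolites. A
    Benjamini-Hochberg column is added when ``bh_correct`` is set; raw p
    remains the reported quantity.
    """
    universe = universe if universe is not None else g.metabolites()
    hits = set(hit_metabolites) & set(universe)
    rows: list[PathwayImpactRow] = []
    for pid in g.pathway_ids:
        proj = metabolite_projection(g, pid)
        members = set(proj.nodes)
        in_path = hits & members
        impact = pathway_impact(proj, in_path) if in_path else 0.0
        p = enrichment_p(len(in_path), len(members), len(hits), len(universe))
        rows.append(
            PathwayImpactRow(
                pathway_id=pid,
                name=g.pathway_titles.get(pid, pid),
                impact=impact,
                enrichment_p=p,
                hits=len(in_path),
                pathway_size=len(members),
                significant=impact >= impact_threshold,
            )
        )
    frame = _rows_to_frame(rows)
    if bh_correct and len(frame):
        from statsmodels.stats.multitest import multipletests

        frame["enrichment_p_bh"] = multipletests(frame["enrichment_p"], method="fdr_bh")[1]
    return frame.sort_values(["impact", "enrichment_p"], ascending=[False, True]).reset_index(
        drop=True
    )
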