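"""Shared fixtures-in-code: mini pipelines and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
Pearson by the textbook sum formula, all-pairs distances by Floyd-Warshall,
betweenness by exhaustive shortest-path enumeration over all simple paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from nmrpath import chemometrics as chem
from nmrpath import preprocess as pre
from nmrpath import srv as srvmod
from nmrpath import synthdata as syn

WATER = (4.6, 5.7)


def spectra_to_clusters(m, singlet_size=0.01, threshold=0.8, align=True, max_shift=3):
    """exclude -> align -> normalize -> SRV, returning (matrix, clusters, cluster_matrix)."""
    m = pre.exclude_region(m, *WATER)
    if align:
        m, _ = pre.align_segments(m, pre.tiled_segments(m.ppm, 0.1, WATER), max_shift)
    m = pre.normalize_total_sum(m)
    params = srvmod.SrvParams(
        singlet_size=singlet_size, resolution=m.resolution, landscape_threshold=threshold
    )
    clusters = srvmod.build_clusters(srvmod.coupling_landscape(m), params, m.ppm)
    cm = srvmod.summarize_clusters(m, clusters)
    return m, clusters, cm


def recovery_dataset(seed, group_sizes=None, effects=None, factors=None, overrides=None,
                     n_metabolites=12, resolution=0.002, halfwidth=0.008):
    """Two-group synthetic data rendered and SRV-clustered; returns
    (truth, matrix, clusters, cluster_matrix, names)."""
    lib = syn.make_metabolite_library(
        n_metabolites, seed=seed, max_peaks=1, disjoint=True, halfwidth=halfwidth
    )
    names = [s.name for s in lib]
    design = syn.SimulationDesign(
        group_sizes=group_sizes or {"CON": 200, "GC": 200},
        effect_matrix=effects or {},
        latent_factors=factors or [],
        residual_sd=0.2,
        residual_sd_overrides=overrides or {},
        noise_sd=0.005,
        jitter_sd=0.002,
        seed=seed,
    )
    truth = syn.simulate_concentrations(design, lib)
    raw = syn.render_spectra(truth, lib, design, resolution=resolution)
    m, clusters, cm = spectra_to_clusters(raw)
    return truth, m, clusters, cm, names


def simple_matrix(values, groups=None, hi=9.0, resolution=0.01):
    """Wrap a 2-D array into a SpectrumMatrix on a synthetic descending axis."""
    values = np.asarray(values, dtype=float)
    n, b = values.shape
    ppm = hi - resolution * (np.arange(b) + 0.5)
    return pre.SpectrumMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        group_labels=list(groups) if groups is not None else ["A"] * n,
        ppm=ppm,
        intensities=values,
    )


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def pearson_brute(x, y):
    """Textbook Pearson correlation, no numpy.corrcoef."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def floyd_warshall(nodes, edges):
    """All-pairs distances over undirected unit-weight edges."""
    inf = float("inf")
    dist = {(a, b): (0.0 if a == b else inf) for a in nodes for b in nodes}
    for u, v in edges:
        dist[(u, v)] = dist[(v, u)] = 1.0
    for k in nodes:
        for i in nodes:
            dik = dist[(i, k)]
            if dik == inf:
                continue
            for j in nodes:
                alt = dik + dist[(k, j)]
                if alt < dist[(i, j)]:
                    dist[(i, j)] = alt
    return dist


def all_simple_paths(adj, s, t, limit):
    """All simple paths s..t of length <= limit (DFS)."""
    out = []

    def dfs(node, path):
        if node == t:
            out.append(list(path))
            return
        if len(path) > limit:
            return
        for nxt in adj[node]:
            if nxt not in path:
                path.append(nxt)
                dfs(nxt, path)
                path.pop()

    dfs(s, [s])
    return out


def _adjacency(graph):
    adj = {n: sorted(graph.neighbors(n)) for n in graph.nodes}
    return adj


def shortest_paths_enumerated(graph, s, t):
    """All shortest paths by exhaustive simple-path enumeration."""
    adj = _adjacency(graph)
    paths = all_simple_paths(adj, s, t, limit=graph.number_of_nodes())
    if not paths:
        return []
    d = min(len(p) for p in paths)
    return [p for p in paths if len(p) == d]


def betweenness_brute(graph):
    """Unordered-pair betweenness by exhaustive enumeration."""
    bc = {v: 0.0 for v in graph.nodes}
    for s, t in itertools.combinations(sorted(graph.nodes), 2):
        sp = shortest_paths_enumerated(graph, s, t)
        if not sp:
            continue
        for v in graph.nodes:
            if v in (s, t):
                continue
            bc[v] += sum(v in p for p in sp) / len(sp)
    return bc


def null_scaled(seed, ns=43, nv=40):
    """Autoscaled pure-noise matrix with the 11-vs-32 class vector."""
    rng = np.random.default_rng(seed)
    Xs = chem.autoscale(rng.normal(size=(ns, nv)))
    y = np.array([-1.0] * 32 + [1.0] * (ns - 32))
    return Xs, y
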