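"""R-STOCSY and OR-STOCSY on SRV cluster matrices.

The cluster-cluster autocorrelation matrix C = X'X / (NS - 1), computed on
the autoscaled cluster matrix X (NS spectra x NV clusters), equals the
pairwise Pearson correlation of the raw cluster intensities. Thresholding
|r| >= 0.9 yields significant correlations; pairs of clusters assigned to
the same metabolite are intra-metabolite correlations (useful for resonance
assignment), pairs mapping to different metabolites are inter-metabolite
correlations (pathway-driven covariation) and feed the network stage.

OR-STOCSY first applies an orthogonal filter for a pairwise stage-versus-
control contrast: the class-orthogonal components of the OPLS extraction
are subtracted from X, removing structured variation unrelated to the
contrast, and the columns are re-autoscaled so C stays a true correlation
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .chemometrics import ScaledMatrix, autoscale
from .errors import ArgumentError, InsufficientDataError, RankError
from .preprocess import AssignmentMap
from .srv import ClusterSet

__all__ = [
    "CorrelationMatrix",
    "CorrelationEdge",
    "correlation_matrix",
    "orthogonal_filter",
    "threshold_edges",
    "classify_edges",
    "assign_clusters",
    "inter_metabolite_pairs",
    "plot_pseudo_2d",
]


@dataclass
class CorrelationMatrix:
    C: np.ndarray
    columns: list[str]
    ns: int
    variant: str = "R-STOCSY"  # or "OR-STOCSY"
    filter_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = self.C
        if c.shape[0] != c.shape[1]:
            raise ArgumentError("correlation matrix must be square")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ArgumentError("correlation matrix must be symmetric")


@dataclass(frozen=True)
class CorrelationEdge:
    i: int
    j: int  # i < j, cluster indices
    r: float
    type: str = "unassigned"  # intra | inter | unassigned
    metabolite_i: str | None = None
    metabolite_j: str | None = None


def correlation_matrix(Xs: ScaledMatrix, variant: str = "R-STOCSY") -> CorrelationMatrix:
    """C = X'X/(NS-1) on the autoscaled cluster matrix."""
    if Xs.ns < 3:
        raise InsufficientDataError("correlation matrix needs >= 3 spectra")
    C = Xs.X.T @ Xs.X / (Xs.ns - 1)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return CorrelationMatrix(C=C, columns=list(Xs.columns), ns=Xs.ns, variant=variant)


def orthogonal_filter(Xs: ScaledMatrix, y, n_ortho: int = 1) -> tuple[ScaledMatrix, np.ndarray]:
    """Remove the ``n_ortho`` dominant class-orthogonal components.

    Orthogonal signal correction: each column of X is projected onto the
    orthogonal complement of y, the leading principal component of that
    projection is taken as the orthogonal score (exactly uncorrelated with
    y by construction), and its rank-one contribution is deflated from X.
    Columns are re-autoscaled afterwards so the downstream autocorrelation
    matrix stays a true correlation matrix.

    Returns the filtered matrix and the removed score vectors.
    """
    if n_ortho < 1:
        raise ArgumentError("n_ortho must be >= 1")
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    ny = np.linalg.norm(yc)
    if ny < 1e-14:
        raise ArgumentError("y has no class contrast")
    py = yc / ny
    Xd = Xs.X.copy()
    removed = []
    for _ in range(n_ortho):
        Xperp = Xd - np.outer(py, py @ Xd)
        u, s, vt = np.linalg.svd(Xperp, full_matrices=False)
        if s[0] < 1e-10:
            break  # no structured orthogonal variation left
        v = vt[0]
        k = int(np.argmax(np.abs(v)))
        if v[k] < 0:
            v = -v
            u = -u  # deterministic sign
        t_orth = u[:, 0] * s[0]
        p_orth = Xd.T @ t_orth / float(t_orth @ t_orth)
        Xd -= np.outer(t_orth, p_orth)
        removed.append(t_orth)
    if np.linalg.norm(Xd) < 1e-12:
        raise RankError("orthogonal filter deflated the matrix to zero")
    filtered = autoscale(Xd, columns=list(Xs.columns))
    scores = np.column_stack(removed) if removed else np.zeros((Xs.ns, 0))
    return filtered, scores


def threshold_edges(C: CorrelationMatrix, threshold: float = 0.9) -> list[CorrelationEdge]:
    """All off-diagonal pairs with |r| >= threshold, i < j, by |r| descending."""
    if not 0.0 < threshold <= 1.0:
        raise ArgumentError("threshold must lie in (0, 1]")
    n = C.C.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    r = C.C[iu, ju]
    keep = np.abs(r) >= threshold - 1e-12  # tolerate roundoff at threshold 1.0
    edges = [
        CorrelationEdge(i=int(a), j=int(b), r=float(v))
        for a, b, v in zip(iu[keep], ju[keep], r[keep])
    ]
    return sorted(edges, key=lambda e: (-abs(e.r), e.i, e.j))


def assign_clusters(clusters: ClusterSet, amap: AssignmentMap) -> list[str | None]:
    """Cluster -> metabolite by maximal ppm-window overlap.

    Ties break toward the metabolite whose window midpoint is nearest the
    cluster center; clusters overlapping no window map to None.
    """
    out: list[str | None] = []
    for c in clusters:
        best_met, best_ov, best_dist = None, 0.0, float("inf")
        for met in sorted(amap.windows):
            for lo, hi in amap.windows[met]:
                ov = min(c.ppm_hi, hi) - max(c.ppm_lo, lo)
                if ov <= 0:
                    continue
                dist = abs(0.5 * (lo + hi) - c.ppm_center)
                if ov > best_ov + 1e-12 or (
                    abs(ov - best_ov) <= 1e-12 and dist < best_dist
                ):
                    best_met, best_ov, best_dist = met, ov, dist
        out.append(best_met)
    return out


def classify_edges(
    edges: list[CorrelationEdge], clusters: ClusterSet, amap: AssignmentMap
) -> list[CorrelationEdge]:
    """Attach metabolite labels and intra/inter/unassigned types to edges."""
    assigned = assign_clusters(clusters, amap)
    out = []
    for e in edges:
        mi, mj = assigned[e.i], assigned[e.j]
        if mi is None or mj is None:
            etype = "unassigned"
        elif mi == mj:
            etype = "intra"
        else:
            etype = "inter"
        out.append(
            CorrelationEdge(i=e.i, j=e.j, r=e.r, type=etype, metabolite_i=mi, metabolite_j=mj)
        )
    return out


def inter_metabolite_pairs(edges: list[CorrelationEdge]) -> dict[tuple[str, str], float]:
    """Deduplicated inter-metabolite pairs with the strongest |r| per pair."""
    pairs: dict[tuple[str, str], float] = {}
    for e in edges:
        if e.type != "inter":
            continue
        key = tuple(sorted((e.metabolite_i, e.metabolite_j)))
        if key not in pairs or abs(e.r) > abs(pairs[key]):
            pairs[key] = e.r
    return pairs


def edges_to_frame(edges: list[CorrelationEdge], clusters: ClusterSet) -> pd.DataFrame:
    rows = []
    cl = clusters.clusters
    for e in edges:
        rows.append(
            {
                "cluster_i": f"c{e.i + 1:04d}",
                "cluster_j": f"c{e.j + 1:04d}",
                "ppm_i": cl[e.i].ppm_center,
                "ppm_j": cl[e.j].ppm_center,
                "r": e.r,
                "type": e.type,
                "metabolite_i": e.metabolite_i,
                "metabolite_j": e.metabolite_j,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_i",
            "cluster_j",
            "ppm_i",
            "ppm_j",
            "r",
            "type",
            "metabolite_i",
            "metabolite_j",
        ],
    )


def plot_pseudo_2d(
    C: CorrelationMatrix, clusters: ClusterSet, path, threshold: float = 0.9
) -> None:
    """Pseudo-2D correlation map (ppm x ppm, signed color scale)."""
    centers = [c.ppm_center for c in clusters]
    masked = np.where(np.abs(C.C) >= threshold, C.C, np.nan)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.pcolormesh(centers, centers, masked, cmap="bwr", vmin=-1, vmax=1)
    ax.invert_xaxis()
    ax.invert_yaxis()
    ax.set_xlabel("ppm")
    ax.set_ylabel("ppm")
    ax.set_title(f"{C.variant} (|r| >= {threshold})")
    fig.colorbar(im, ax=ax, label="r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
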