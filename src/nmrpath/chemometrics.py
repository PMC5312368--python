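"""Multivariate and univariate statistics for cluster-level NMR data.

Implements the discrimination chain used on SRV cluster matrices:

* column autoscaling (unit variance, ddof=1) with zero-variance columns
  dropped and reported;
* NIPALS PCA with row-wise cross-validated Q2;
* two-class PLS-DA (PLS1, y coded -1/+1) with 7-fold cross-validation and a
  response permutation test (RPT) whose validity verdict requires the
  original Q2 to exceed every permuted Q2 and the Q2 regression line to
  intercept the vertical axis below zero;
* OPLS-DA: orthogonal components are extracted by the orthogonal-projection
  procedure (weight w proportional to X'y; the orthogonal weight is the
  loading minus its projection on w; deflate), then a single predictive
  component tp1 is fitted on the deflated matrix. VIP is computed on the
  predictive component, so mean(VIP^2) = 1 by construction;
* the critical-value rule for loading correlations r relative to tp1:
  r* = sqrt(t^2 / (t^2 + df)) with t the two-tailed Student-t quantile and
  df = n1 + n2 - 2, giving the red/orange/blue significance coloring;
* linear discriminant boundaries on 2-D score spaces;
* one-way ANOVA with Tukey-Kramer multiple comparisons and the z-score
  matrix used for heatmap display.

Component sign convention: each loading/weight vector is signed so its
largest-magnitude element is positive; score plots are reproducible up to
this convention only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ArgumentError, InsufficientDataError, RankError

__all__ = [
    "ScaledMatrix",
    "autoscale",
    "PcaModel",
    "pca",
    "PlsModel",
    "plsda",
    "RptReport",
    "permutation_test",
    "OplsModel",
    "oplsda",
    "critical_r",
    "SignificanceRule",
    "select_differential",
    "LinearBoundary",
    "linear_boundary",
    "AnovaResult",
    "anova_tukey",
    "zscore_matrix",
    "encode_classes",
]

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500


@dataclass
class ScaledMatrix:
    """Column-autoscaled matrix (mean 0, sd 1 with ddof=1)."""

    X: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    columns: list[str]
    dropped: list[str]

    @property
    def ns(self) -> int:
        return self.X.shape[0]

    @property
    def nv(self) -> int:
        return self.X.shape[1]


def autoscale(X_raw, columns: list[str] | None = None) -> ScaledMatrix:
    """Center to mean 0 and scale to unit sd per column.

    Zero-variance columns are removed with a warning; their ids are
    recorded in ``dropped``.
    """
    X = np.asarray(X_raw, dtype=float)
    if X.ndim != 2:
        raise ArgumentError("autoscale expects a 2-D samples x variables matrix")
    ns, nv = X.shape
    if ns < 3:
        raise InsufficientDataError(f"autoscale needs >= 3 samples, got {ns}")
    if columns is None:
        columns = [f"v{j + 1:04d}" for j in range(nv)]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    scale = np.maximum(np.abs(mean), 1.0)
    keep = sd > 1e-12 * scale
    dropped = [c for c, k in zip(columns, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance columns: {dropped[:5]}...")
    Xs = (X[:, keep] - mean[keep]) / sd[keep]
    return ScaledMatrix(
        X=Xs,
        mean=mean[keep],
        sd=sd[keep],
        columns=[c for c, k in zip(columns, keep) if k],
        dropped=dropped,
    )


def encode_classes(labels, control: str | None = None) -> np.ndarray:
    """Map two class labels onto -1/+1 with the control class coded -1."""
    labels = list(labels)
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ArgumentError(f"exactly two classes required, got {uniq}")
    if control is None:
        control = uniq[0]
    if control not in uniq:
        raise ArgumentError(f"control '{control}' not among classes {uniq}")
    return np.array([-1.0 if l == control else 1.0 for l in labels])


def _sign_fix(p: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sign each loading so its largest-magnitude element is positive."""
    k = int(np.argmax(np.abs(p)))
    if p[k] < 0:
        return -p, -t
    return p, t


def _nipals_pca(X: np.ndarray, n_comp: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    Xd = X.copy()
    n, p = Xd.shape
    T = np.zeros((n, n_comp))
    P = np.zeros((p, n_comp))
    ss_total = float((X**2).sum())
    r2x = np.zeros(n_comp)
    for a in range(n_comp):
        j0 = int(np.argmax(Xd.var(axis=0)))
        t = Xd[:, j0].copy()
        if float(t @ t) == 0.0:
            raise RankError(f"matrix rank exhausted before component {a + 1}")
        for _ in range(_NIPALS_MAX_ITER):
            w = Xd.T @ t / float(t @ t)
            w /= np.linalg.norm(w)
            t_new = Xd @ w
            if np.linalg.norm(t_new - t) <= _NIPALS_TOL * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
        w, t = _sign_fix(w, t)
        Xd -= np.outer(t, w)
        T[:, a] = t
        P[:, a] = w
        r2x[a] = float(t @ t) / ss_total
    return T, P, r2x


@dataclass
class PcaModel:
    scores: np.ndarray
    loadings: np.ndarray
    r2x: np.ndarray  # per component
    q2_cum: float
    columns: list[str] = field(default_factory=list)

    @property
    def r2x_cum(self) -> float:
        return float(self.r2x.sum())


def _cv_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Contiguous-block folds after a seeded shuffle."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    k = min(k, n)
    return [np.sort(block) for block in np.array_split(order, k)]


def pca(Xs: ScaledMatrix, n_comp: int = 2, cv_folds: int = 7, seed: int = 0) -> PcaModel:
    """NIPALS PCA with naive row-wise cross-validated Q2(cum).

    Q2 is computed by leaving row blocks out, refitting, projecting the
    held-out rows on the training loadings, and pooling the PRESS.
    """
    rank = int(np.linalg.matrix_rank(Xs.X))
    if n_comp > rank:
        raise RankError(f"n_comp={n_comp} exceeds matrix rank {rank}")
    T, P, r2x = _nipals_pca(Xs.X, n_comp)
    press = 0.0
    ss = 0.0
    for test in _cv_folds(Xs.ns, cv_folds, seed):
        train = np.setdiff1d(np.arange(Xs.ns), test)
        if len(train) < 2:
            continue
        Xtr = Xs.X[train]
        a = min(n_comp, int(np.linalg.matrix_rank(Xtr)))
        if a == 0:
            continue
        _, Ptr, _ = _nipals_pca(Xtr, a)
        Xte = Xs.X[test]
        resid = Xte - Xte @ Ptr @ Ptr.T
        press += float((resid**2).sum())
        ss += float((Xte**2).sum())
    q2 = 1.0 - press / ss if ss > 0 else float("nan")
    return PcaModel(scores=T, loadings=P, r2x=r2x, q2_cum=q2, columns=list(Xs.columns))


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


def _pls_fit(X: np.ndarray, yc: np.ndarray, n_comp: int):
    """NIPALS PLS1 on centered y; returns W, T, P, q arrays."""
    Xd = X.copy()
    yd = yc.astype(float).copy()
    n, p = Xd.shape
    W = np.zeros((p, n_comp))
    T = np.zeros((n, n_comp))
    P = np.zeros((p, n_comp))
    q = np.zeros(n_comp)
    used = 0
    for a in range(n_comp):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-14:
            break
        pvec = Xd.T @ t / tt
        qa = float(yd @ t / tt)
        Xd -= np.outer(t, pvec)
        yd = yd - qa * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, pvec, qa
        used += 1
    return W[:, :used], T[:, :used], P[:, :used], q[:used]


def _pls_coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Regression coefficients b with y_hat = X b (centered spaces)."""
    M = P.T @ W
    return W @ np.linalg.solve(M, q)


def _pls_vip(W: np.ndarray, T: np.ndarray, q: np.ndarray) -> np.ndarray:
    p = W.shape[0]
    ssy = q**2 * (T**2).sum(axis=0)
    denom = float(ssy.sum())
    if denom == 0:
        return np.zeros(p)
    return np.sqrt(p * (W**2 @ ssy) / denom)


@dataclass
class PlsModel:
    weights: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    y_loadings: np.ndarray
    r2y: float
    q2: float
    vip: np.ndarray
    y: np.ndarray
    columns: list[str] = field(default_factory=list)


def _check_two_classes(y: np.ndarray, min_per_class: int = 3) -> tuple[int, int]:
    vals, counts = np.unique(y, return_counts=True)
    if len(vals) != 2:
        raise ArgumentError(f"y must have exactly two classes, got {len(vals)}")
    if counts.min() < min_per_class:
        raise ArgumentError(f"each class needs >= {min_per_class} members, got {counts.tolist()}")
    neg = int(counts[np.argmin(vals)])
    pos = int(counts[np.argmax(vals)])
    return neg, pos


def _q2(X: np.ndarray, y: np.ndarray, n_comp: int, cv_folds: int, seed: int) -> float:
    press = 0.0
    ss = 0.0
    n = len(y)
    for test in _cv_folds(n, cv_folds, seed):
        train = np.setdiff1d(np.arange(n), test)
        if len(train) < 3:
            continue
        ytr = y[train]
        ybar = ytr.mean()
        W, T, P, q = _pls_fit(X[train], ytr - ybar, n_comp)
        if W.shape[1] == 0:
            continue
        b = _pls_coefficients(W, P, q)
        yhat = X[test] @ b + ybar
        press += float(((y[test] - yhat) ** 2).sum())
        ss += float(((y[test] - ybar) ** 2).sum())
    return 1.0 - press / ss if ss > 0 else float("nan")


def plsda(
    Xs: ScaledMatrix, y, n_comp: int = 2, cv_folds: int = 7, seed: int = 0
) -> PlsModel:
    """Two-class PLS-DA (PLS1 regression on y in {-1, +1})."""
    y = np.asarray(y, dtype=float)
    _check_two_classes(y)
    yc = y - y.mean()
    W, T, P, q = _pls_fit(Xs.X, yc, n_comp)
    if W.shape[1] == 0:
        raise RankError("no PLS component could be extracted")
    yhat = T @ q
    r2y = 1.0 - float(((yc - yhat) ** 2).sum()) / float((yc**2).sum())
    q2 = _q2(Xs.X, y, n_comp, cv_folds, seed)
    return PlsModel(
        weights=W,
        scores=T,
        loadings=P,
        y_loadings=q,
        r2y=r2y,
        q2=q2,
        vip=_pls_vip(W, T, q),
        y=y,
        columns=list(Xs.columns),
    )


@dataclass
class RptReport:
    """Response permutation test report."""

    permutations: pd.DataFrame  # columns: corr, r2, q2 (last row = original)
    r2_intercept: float
    q2_intercept: float
    r2_original: float
    q2_original: float
    valid: bool


def permutation_test(
    Xs: ScaledMatrix,
    y,
    n_perm: int = 200,
    seed: int = 0,
    n_comp: int = 2,
    cv_folds: int = 7,
) -> RptReport:
    """Refit under permuted class labels while keeping X intact.

    The verdict is valid iff the original Q2 exceeds every permuted Q2 and
    the regression line of the Q2 points (including the original at
    |corr| = 1) crosses the vertical axis below zero.
    """
    y = np.asarray(y, dtype=float)
    _check_two_classes(y)
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_perm):
        yp = rng.permutation(y)
        model = plsda_quiet(Xs, yp, n_comp, cv_folds, seed)
        c = abs(float(np.corrcoef(yp, y)[0, 1]))
        rows.append((c, model[0], model[1]))
    orig = plsda_quiet(Xs, y, n_comp, cv_folds, seed)
    rows.append((1.0, orig[0], orig[1]))
    frame = pd.DataFrame(rows, columns=["corr", "r2", "q2"])
    r2_line = stats.linregress(frame["corr"], frame["r2"])
    q2_line = stats.linregress(frame["corr"], frame["q2"])
    perm_q2 = frame["q2"].to_numpy()[:-1]
    valid = bool(orig[1] > perm_q2.max() and q2_line.intercept < 0)
    return RptReport(
        permutations=frame,
        r2_intercept=float(r2_line.intercept),
        q2_intercept=float(q2_line.intercept),
        r2_original=orig[0],
        q2_original=orig[1],
        valid=valid,
    )


def plsda_quiet(Xs: ScaledMatrix, y, n_comp: int, cv_folds: int, seed: int):
    """(R2Y, Q2) of a PLS-DA fit without building the full model object."""
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    W, T, P, q = _pls_fit(Xs.X, yc, n_comp)
    if W.shape[1] == 0:
        return 0.0, float("nan")
    yhat = T @ q
    r2y = 1.0 - float(((yc - yhat) ** 2).sum()) / float((yc**2).sum())
    return r2y, _q2(Xs.X, y, n_comp, cv_folds, seed)


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


@dataclass
class OplsModel:
    tp: np.ndarray  # predictive scores (tp1)
    pp: np.ndarray  # predictive loadings
    w: np.ndarray  # predictive weights (unit norm)
    to: np.ndarray  # orthogonal scores, shape (n, n_ortho)
    po: np.ndarray  # orthogonal loadings, shape (p, n_ortho)
    wo: np.ndarray  # orthogonal weights, shape (p, n_ortho)
    r2y: float
    vip: np.ndarray
    loading_r: np.ndarray  # corr of each (autoscaled) variable with tp1
    y: np.ndarray
    n1: int  # class coded -1 (control)
    n2: int  # class coded +1
    columns: list[str] = field(default_factory=list)

    @property
    def df(self) -> int:
        return self.n1 + self.n2 - 2


def oplsda(Xs: ScaledMatrix, y, n_ortho: int = 1) -> OplsModel:
    """OPLS-DA with ``n_ortho`` orthogonal components and one predictive tp1.

    The predictive score is oriented so that corr(tp1, y) >= 0, making
    positive loading correlations mean "up in the +1 class".
    """
    y = np.asarray(y, dtype=float)
    n1, n2 = _check_two_classes(y)
    if n_ortho < 0:
        raise ArgumentError("n_ortho must be >= 0")
    yc = y - y.mean()
    Xd = Xs.X.copy()
    n, p = Xd.shape
    to = np.zeros((n, n_ortho))
    po = np.zeros((p, n_ortho))
    wo = np.zeros((p, n_ortho))
    for a in range(n_ortho):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            raise RankError(f"deflation left a zero matrix before orthogonal component {a + 1}")
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        pvec = Xd.T @ t / tt
        w_orth = pvec - float(w @ pvec) * w
        nwo = np.linalg.norm(w_orth)
        if nwo < 1e-12:
            raise RankError(f"no orthogonal variation left for component {a + 1}")
        w_orth /= nwo
        t_orth = Xd @ w_orth
        p_orth = Xd.T @ t_orth / float(t_orth @ t_orth)
        Xd -= np.outer(t_orth, p_orth)
        to[:, a], po[:, a], wo[:, a] = t_orth, p_orth, w_orth
    w = Xd.T @ yc
    nw = np.linalg.norm(w)
    if nw < 1e-14:
        raise RankError("deflation left a zero matrix before the predictive component")
    w /= nw
    tp = Xd @ w
    if float(tp @ yc) < 0:
        w, tp = -w, -tp
    pp = Xd.T @ tp / float(tp @ tp)
    qa = float(yc @ tp / float(tp @ tp))
    r2y = 1.0 - float(((yc - qa * tp) ** 2).sum()) / float((yc**2).sum())
    vip = np.sqrt(p) * np.abs(w)  # single predictive component; mean(VIP^2) = 1
    tc = tp - tp.mean()
    xc = Xs.X - Xs.X.mean(axis=0)
    denom = np.linalg.norm(xc, axis=0) * np.linalg.norm(tc)
    loading_r = np.where(denom > 0, xc.T @ tc / np.where(denom > 0, denom, 1.0), 0.0)
    return OplsModel(
        tp=tp,
        pp=pp,
        w=w,
        to=to,
        po=po,
        wo=wo,
        r2y=r2y,
        vip=vip,
        loading_r=np.clip(loading_r, -1.0, 1.0),
        y=y,
        n1=n1,
        n2=n2,
        columns=list(Xs.columns),
    )


# ---------------------------------------------------------------------------
# significance rules
# ---------------------------------------------------------------------------


def critical_r(n1: int, n2: int, alpha: float, decimals: int | None = 3) -> float:
    """Two-tailed critical Pearson r at significance ``alpha``.

    df = n1 + n2 - 2; r* = sqrt(t^2 / (t^2 + df)) with t the Student-t
    quantile at 1 - alpha/2. Rounded to 3 decimals for reporting by default
    (``decimals=None`` returns full precision).
    """
    df = n1 + n2 - 2
    if df < 3:
        raise ArgumentError(f"df = n1 + n2 - 2 = {df} < 3")
    if not 0.0 < alpha < 1.0:
        raise ArgumentError("alpha must lie in (0, 1)")
    t = stats.t.ppf(1.0 - alpha / 2.0, df)
    r = float(np.sqrt(t**2 / (t**2 + df)))
    return round(r, decimals) if decimals is not None else r


@dataclass
class SignificanceRule:
    vip_threshold: float = 1.0
    alpha_strong: float = 0.01
    alpha_weak: float = 0.05


def select_differential(
    model: OplsModel, rule: SignificanceRule | None = None
) -> pd.DataFrame:
    """Label variables very_significant / significant / NS.

    very_significant: VIP > 1 and |r| above the alpha=0.01 critical value;
    significant: VIP > 1 and |r| between the 0.05 and 0.01 critical values;
    otherwise NS. Direction is the sign of the loading correlation (tp1 is
    oriented toward the +1 class).
    """
    rule = rule or SignificanceRule()
    r_strong = critical_r(model.n1, model.n2, rule.alpha_strong)
    r_weak = critical_r(model.n1, model.n2, rule.alpha_weak)
    labels = []
    directions = []
    for vip, r in zip(model.vip, model.loading_r):
        if vip > rule.vip_threshold and abs(r) > r_strong:
            labels.append("very_significant")
        elif vip > rule.vip_threshold and abs(r) > r_weak:
            labels.append("significant")
        else:
            labels.append("NS")
        directions.append("up" if r > 0 else ("down" if r < 0 else "unchanged"))
    return pd.DataFrame(
        {
            "variable": model.columns or [f"v{j + 1:04d}" for j in range(len(model.vip))],
            "vip": model.vip,
            "r": model.loading_r,
            "label": labels,
            "direction": directions,
        }
    )


@dataclass
class LinearBoundary:
    coef: np.ndarray  # boundary normal in score space
    intercept: float
    misclassified: int
    pseudo_inverse: bool


def linear_boundary(scores: np.ndarray, labels) -> LinearBoundary:
    """Equal-covariance linear discriminant boundary on a 2-D score space."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ArgumentError("linear_boundary expects a 2-column score matrix")
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ArgumentError("exactly two classes required")
    pooled = np.zeros((2, 2))
    for c in np.unique(labels):
        sub = scores[labels == c]
        if len(sub) > 1:
            pooled += np.cov(sub.T) * (len(sub) - 1)
    pseudo = bool(np.linalg.cond(pooled) > 1e12) if np.isfinite(np.linalg.cond(pooled)) else True
    lda = LinearDiscriminantAnalysis(solver="svd")
    lda.fit(scores, labels)
    pred = lda.predict(scores)
    return LinearBoundary(
        coef=lda.coef_[0].copy(),
        intercept=float(lda.intercept_[0]),
        misclassified=int((pred != labels).sum()),
        pseudo_inverse=pseudo,
    )


# ---------------------------------------------------------------------------
# univariate battery
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    table: pd.DataFrame  # metabolite, F, p
    group_means: pd.DataFrame  # metabolite x group
    group_sems: pd.DataFrame
    tukey: dict[str, pd.DataFrame]  # metabolite -> pairwise adjusted p


def anova_tukey(table: pd.DataFrame) -> AnovaResult:
    """One-way ANOVA + Tukey-Kramer per metabolite.

    ``table`` is the relative-integral frame: a 'group' column followed by
    one column per metabolite.
    """
    if "group" not in table.columns:
        raise ArgumentError("table must contain a 'group' column")
    groups = table["group"]
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ArgumentError("at least two groups required")
    if counts.min() < 2:
        raise ArgumentError(f"every group needs >= 2 members, got {counts.to_dict()}")
    mets = [c for c in table.columns if c != "group"]
    order = list(dict.fromkeys(groups))
    rows, tukey = [], {}
    means = pd.DataFrame(index=mets, columns=order, dtype=float)
    sems = pd.DataFrame(index=mets, columns=order, dtype=float)
    for met in mets:
        samples = [table.loc[groups == g, met].to_numpy() for g in order]
        f, p = stats.f_oneway(*samples)
        rows.append((met, float(f), float(p)))
        for g, x in zip(order, samples):
            means.loc[met, g] = x.mean()
            sems.loc[met, g] = x.std(ddof=1) / np.sqrt(len(x))
        res = pairwise_tukeyhsd(table[met].to_numpy(), groups.to_numpy())
        tukey[met] = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )[["group1", "group2", "meandiff", "p-adj"]].rename(columns={"p-adj": "p_adj"})
    return AnovaResult(
        table=pd.DataFrame(rows, columns=["metabolite", "F", "p"]),
        group_means=means,
        group_sems=sems,
        tukey=tukey,
    )


def plot_scores(scores: np.ndarray, labels, path, xlabel: str = "t1", ylabel: str = "t2") -> None:
    """Two-component scores plot colored by class label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = np.asarray(scores)
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 4))
    for lab in np.unique(labels):
        sel = labels == lab
        ax.scatter(scores[sel, 0], scores[sel, 1], label=str(lab), s=18)
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def zscore_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Metabolites x samples z-score matrix for heatmap display.

    Each metabolite (row of the output) is centered to mean 0 and scaled to
    sd 1 (ddof=1) across samples.
    """
    mets = [c for c in table.columns if c != "group"]
    sub = table[mets]
    z = (sub - sub.mean()) / sub.std(ddof=1)
    return z.T
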