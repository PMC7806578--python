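"""Feature-selection statistics for aligned peak-region matrices.

The substrate is a runs × features table of TIC volumes.  Rows are first
normalized to % response (each run's volumes as percentages of its row sum),
removing injection- and derivatization-scale differences.  Unsupervised
structure is explored by PCA; class-discriminant features are selected by a
Kruskal–Wallis test with Dunn's post hoc z-tests and Bonferroni correction
across pairs, and ranked by PLS-DA variable importance in projection (VIP),
with the conventional VIP ≥ 1 gate.  Inter-channel consistency is assessed by
per-feature ordinary least squares of one channel's responses against the
70 eV reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

from .fingerprint import FeatureMatrix


def percent_response(matrix):
    """Normalize each run's volumes to percentages of its row total.

    Accepts a :class:`FeatureMatrix` or a DataFrame; rows sum to 100 and the
    result is invariant to any per-run scale factor.
    """
    df = matrix.volumes if isinstance(matrix, FeatureMatrix) else matrix
    sums = df.sum(axis=1)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero total response for run(s): {list(zero.index)}")
    out = df.mul(100.0 / sums, axis=0)
    if isinstance(matrix, FeatureMatrix):
        return FeatureMatrix(volumes=out, groups=matrix.groups, channel=matrix.channel)
    return out


def pca(matrix, n_components: int = 2):
    """Mean-centered PCA.

    Returns ``(scores, loadings, explained)`` where ``scores`` is
    (runs × components), ``loadings`` (components × features, orthonormal
    rows) and ``explained`` the fraction of variance per component
    (non-increasing, sums ≤ 1).
    """
    df = matrix.volumes if isinstance(matrix, FeatureMatrix) else pd.DataFrame(matrix)
    X = df.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 runs and 2 features")
    n_components = min(n_components, min(X.shape[0] - 1, X.shape[1]))
    model = PCA(n_components=n_components)
    scores = model.fit_transform(X - X.mean(axis=0))
    return scores, model.components_, model.explained_variance_ratio_


@dataclass
class SelectionResult:
    """Per-feature Kruskal–Wallis results with Dunn/Bonferroni post hoc."""

    pvalues: pd.Series                  # raw KW p per feature
    adjusted: pd.DataFrame              # Bonferroni-adjusted p per group pair
    selected: pd.Series                 # boolean gate at alpha
    alpha: float
    groups: tuple[str, ...]


def _dunn_pairwise(values: np.ndarray, labels: np.ndarray,
                   groups: list[str]) -> dict[tuple[str, str], float]:
    """Dunn's z-test p-values (unadjusted) for all group pairs, tie-corrected."""
    n = len(values)
    ranks = sps.rankdata(values)
    _uniq, counts = np.unique(values, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    var_unit = n * (n + 1) / 12.0 - tie_term
    mean_ranks = {g: ranks[labels == g].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    out = {}
    for g1, g2 in combinations(groups, 2):
        se = np.sqrt(var_unit * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        out[(g1, g2)] = 2.0 * sps.norm.sf(abs(z))
    return out


def kw_dunn_bonferroni(matrix, groups, alpha: float = 0.05,
                       pair_of_interest: tuple[str, str] | None = None) -> SelectionResult:
    """Kruskal–Wallis feature selection with Dunn's post hoc (Bonferroni).

    For k > 2 groups each feature gets pairwise Dunn z-tests Bonferroni-
    corrected over the number of pairs; a feature is selected when the
    adjusted p of the relevant pair (or, absent ``pair_of_interest``, of any
    pair) is < ``alpha``.  For k = 2 the KW p itself gates (Dunn's test
    degenerates and Bonferroni over one pair is the identity).
    """
    df = matrix.volumes if isinstance(matrix, FeatureMatrix) else pd.DataFrame(matrix)
    if isinstance(matrix, FeatureMatrix) and groups is None:
        groups = matrix.groups
    labels = np.asarray(groups)
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    for g in uniq:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 runs")
    pairs = list(combinations(uniq, 2))
    n_pairs = len(pairs)
    raw = {}
    adj = {p: {} for p in pairs}
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        samples = [x[labels == g] for g in uniq]
        try:
            raw[col] = sps.kruskal(*samples).pvalue
        except ValueError:  # all values identical
            raw[col] = 1.0
        if len(uniq) == 2:
            adj[pairs[0]][col] = raw[col]
        else:
            dunn = _dunn_pairwise(x, labels, uniq)
            for p in pairs:
                adj[p][col] = min(1.0, dunn[p] * n_pairs)
    pvalues = pd.Series(raw, index=df.columns)
    adjusted = pd.DataFrame({f"{a}|{b}": pd.Series(adj[(a, b)]) for a, b in pairs})
    if pair_of_interest is not None:
        a, b = sorted(pair_of_interest)
        gate = adjusted[f"{a}|{b}"]
    else:
        gate = adjusted.min(axis=1)
    selected = gate < alpha
    return SelectionResult(pvalues=pvalues, adjusted=adjusted, selected=selected,
                           alpha=alpha, groups=tuple(uniq))


@dataclass
class VipResult:
    vip: pd.Series
    n_components: int
    explained_y: np.ndarray           # fraction of Y variance per component

    def selected(self, gate: float = 1.0) -> pd.Series:
        return self.vip >= gate


def plsda_vip(matrix, labels, n_components: int = 2,
              scale: str = "autoscale") -> VipResult:
    """PLS-DA (NIPALS) with per-feature variable importance in projection.

    X is feature-scaled (``autoscale`` = unit variance, ``pareto`` = √sd, or
    ``none``), Y is the binary class indicator.  For feature j over A
    components with weights w_a and Y-variance shares SSY_a:

        VIP_j = sqrt( p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a )

    so mean_j VIP_j² = 1 by construction.
    """
    df = matrix.volumes if isinstance(matrix, FeatureMatrix) else pd.DataFrame(matrix)
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"PLS-DA contrast needs exactly 2 classes, got {classes}")
    y = (labels == classes[1]).astype(float)
    X = df.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    if scale == "autoscale":
        Xc = Xc / sd
    elif scale == "pareto":
        Xc = Xc / np.sqrt(sd)
    elif scale != "none":
        raise ValueError("scale must be autoscale, pareto or none")
    n_components = min(n_components, Xc.shape[1], Xc.shape[0] - 1)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xc, y - y.mean())
    W = pls.x_weights_                 # (p, A)
    T = pls.x_scores_                  # (n, A)
    Q = pls.y_loadings_                # (1, A)
    ssy = (T**2).sum(axis=0) * Q.ravel() ** 2
    ss_tot = ((y - y.mean()) ** 2).sum()
    p = Xc.shape[1]
    wnorm = W / np.linalg.norm(W, axis=0, keepdims=True)
    vip = np.sqrt(p * (wnorm**2 @ ssy) / ssy.sum())
    return VipResult(vip=pd.Series(vip, index=df.columns),
                     n_components=n_components,
                     explained_y=ssy / ss_tot if ss_tot > 0 else ssy * 0)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


def channel_regression(volumes_x, volumes_y) -> RegressionResult:
    """OLS of one channel's per-run responses against the 70 eV reference."""
    x = np.asarray(volumes_x, dtype=float)
    y = np.asarray(volumes_y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the reference (x) channel")
    fit = sps.linregress(x, y)
    ss_res = np.sum((y - (fit.slope * x + fit.intercept)) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            r_squared=float(r2))


def regress_channels(matrix_x, matrix_y) -> pd.DataFrame:
    """Per-feature :func:`channel_regression` over two aligned matrices."""
    dfx = matrix_x.volumes if isinstance(matrix_x, FeatureMatrix) else matrix_x
    dfy = matrix_y.volumes if isinstance(matrix_y, FeatureMatrix) else matrix_y
    rows = {}
    for col in dfx.columns.intersection(dfy.columns):
        try:
            r = channel_regression(dfx[col], dfy[col])
            rows[col] = (r.slope, r.intercept, r.r_squared)
        except ValueError:
            continue
    return pd.DataFrame(rows, index=["slope", "intercept", "r_squared"]).T


def rsd(values) -> float:
    """Percent relative standard deviation: 100 × sample SD / mean."""
    x = np.asarray(values, dtype=float)
    mean = x.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)
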