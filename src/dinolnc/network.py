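"""Signed weighted co-expression network (WGCNA-style).

Correlation is biweight midcorrelation (outlier quantile cap 0.1, per-
feature Pearson fallback when the MAD is zero); the signed adjacency is
a_ij = ((1 + cor)/2)^T with the soft power T picked by the scale-free
topology fit index (smallest T with I > 0.8, else the recommended default
18).  The topological overlap matrix blends direct adjacency with shared
neighbours; modules come from complete-linkage clustering of 1 - TOM with
a static height cut (a documented simplification of dynamic tree cut);
module eigengenes are first principal components, merged at correlation
>= 0.9, and correlated with numerically coded external factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._util import warn


@dataclass
class NetworkParams:
    power: int = 18
    min_module_size: int = 30
    merge_cor: float = 0.9
    cut_height_quantile: float = 0.99
    fit_indices: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError("power must be >= 1")


# ---------------------------------------------------------------------------
# Correlation


def bicor(X: np.ndarray, max_p_outliers: float = 0.1) -> np.ndarray:
    """Biweight midcorrelation between rows of X.

    Weights are Tukey biweights around the median with u = (x - med)/(9 MAD);
    the side quantiles at ``max_p_outliers`` are capped to |u| = 1 so at most
    that fraction of samples per side can be discarded as outliers.  Rows
    with MAD = 0 fall back to Pearson standardization individually.
    """
    X = np.asarray(X, dtype=float)
    n_feat, n_samp = X.shape
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    fallback = (mad[:, 0] == 0)
    standardized = np.empty_like(X)

    with np.errstate(invalid="ignore", divide="ignore"):
        u = (X - med) / (9.0 * mad)
    u[fallback] = 0.0
    # cap the side quantiles so no more than max_p_outliers per side are zeroed
    lo = np.quantile(u, max_p_outliers, axis=1, keepdims=True)
    hi = np.quantile(u, 1.0 - max_p_outliers, axis=1, keepdims=True)
    scale_lo = np.where(lo < -1.0, -lo, 1.0)
    scale_hi = np.where(hi > 1.0, hi, 1.0)
    u = np.where(u < 0, u / scale_lo, u / scale_hi)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    xw = (X - med) * w
    norm = np.sqrt((xw**2).sum(axis=1, keepdims=True))
    ok = norm[:, 0] > 0
    standardized[ok] = xw[ok] / norm[ok]
    fallback |= ~ok

    if fallback.any():
        sub = X[fallback]
        c = sub - sub.mean(axis=1, keepdims=True)
        nrm = np.sqrt((c**2).sum(axis=1, keepdims=True))
        bad = nrm[:, 0] == 0
        if bad.any():
            raise ValueError(
                f"non-finite correlations: {int(bad.sum())} constant feature(s)"
            )
        standardized[fallback] = c / nrm

    r = standardized @ standardized.T
    np.fill_diagonal(r, 1.0)
    return np.clip((r + r.T) / 2.0, -1.0, 1.0)


def signed_adjacency(cor: np.ndarray, power: int) -> np.ndarray:
    return ((1.0 + cor) / 2.0) ** power


# ---------------------------------------------------------------------------
# Soft-threshold selection


def scale_free_fit_index(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 (and slope) of log10 p(k) vs log10 k over connectivity bins."""
    k = k[k > 0]
    if len(k) < n_bins or k.min() == k.max():
        return 0.0, 0.0
    # equal-width bins over the connectivity range (quantile bins would make
    # p(k) constant by construction)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / len(k)))
    if len(xs) < 3 or np.std(ys) == 0:
        return 0.0, 0.0
    slope, _, r, *_ = stats.linregress(xs, ys)
    if not np.isfinite(r):
        return 0.0, float(slope)
    return float(r**2), float(slope)


def pick_soft_threshold(
    normalized: pd.DataFrame,
    powers: range = range(1, 31),
    rsq_cut: float = 0.8,
    default_power: int = 18,
    n_bins: int = 10,
) -> NetworkParams:
    """Smallest power with scale-free fit I > rsq_cut (negative slope), else 18."""
    X = normalized.to_numpy(dtype=float)
    if np.allclose(X.std(axis=1), 0):
        raise ValueError("degenerate (constant) expression matrix")
    if X.shape[1] < 8:
        warn("pick_soft_threshold: fewer than 8 samples; fit index is unreliable")
    cor = bicor(X)
    base = (1.0 + cor) / 2.0
    np.fill_diagonal(base, 0.0)
    fits: dict[int, float] = {}
    chosen = None
    a = np.ones_like(base)
    np.fill_diagonal(a, 0.0)
    prev_power = 0
    for T in powers:
        a = a * base ** (T - prev_power)
        prev_power = T
        k = a.sum(axis=1)
        rsq, slope = scale_free_fit_index(k, n_bins=n_bins)
        fits[T] = rsq if slope < 0 else 0.0
        if chosen is None and slope < 0 and rsq > rsq_cut:
            chosen = T
            break
    return NetworkParams(power=chosen if chosen is not None else default_power,
                         fit_indices=fits)


# ---------------------------------------------------------------------------
# Network and modules


def tom_from_adjacency(a: np.ndarray) -> np.ndarray:
    """Topological overlap: (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)."""
    a = np.asarray(a, dtype=float)
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / (kmin + 1.0 - a)
    tom = np.where(np.isfinite(tom), tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2.0, 0.0, 1.0)


def build_network(
    normalized: pd.DataFrame, params: NetworkParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signed adjacency and TOM for the expression matrix (features x samples)."""
    X = normalized.to_numpy(dtype=float)
    cor = bicor(X)
    adj = signed_adjacency(cor, params.power)
    np.fill_diagonal(adj, 1.0)
    tom = tom_from_adjacency(adj)
    idx = normalized.index
    return pd.DataFrame(adj, idx, idx), pd.DataFrame(tom, idx, idx)


def detect_modules(tom: pd.DataFrame, params: NetworkParams) -> pd.Series:
    """Complete-linkage clustering of 1 - TOM with a static height cut.

    Branches below the cut (height quantile of the merge heights) become
    candidate modules; branches smaller than ``min_module_size`` are left
    unassigned (label 0).  Modules are relabelled 1..m by decreasing size.
    """
    d = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.maximum((d + d.T) / 2.0, 0.0)
    Z = linkage(squareform(d, checks=False), method="complete")
    heights = Z[:, 2]
    cut = np.quantile(heights, params.cut_height_quantile)
    raw = fcluster(Z, t=cut, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= params.min_module_size].index
    if len(keep) == 0:
        warn("detect_modules: no branch reaches min_module_size; all unassigned")
    if len(keep) == 1 and len(sizes) == 1:
        warn("detect_modules: all features fall in a single module")
    order = sorted(keep, key=lambda lbl: (-sizes[lbl], lbl))
    relabel = {lbl: i + 1 for i, lbl in enumerate(order)}
    labels = np.array([relabel.get(lbl, 0) for lbl in raw])
    return pd.Series(labels, index=tom.index, name="module")


# ---------------------------------------------------------------------------
# Eigengenes


def _eigengene(sub: np.ndarray) -> np.ndarray:
    """First PC of the standardized module submatrix (unit-norm sample scores)."""
    sd = sub.std(axis=1, ddof=0)
    if np.all(sd == 0):
        raise ValueError("module of constant features has no eigengene")
    sub = sub[sd > 0]
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[sd > 0][:, None]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(e, mean_profile) < 0:
        e = -e
    return e / np.linalg.norm(e)


def module_eigengenes(
    normalized: pd.DataFrame,
    assignment: pd.Series,
    params: NetworkParams,
    traits: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame | None]:
    """Eigengenes, merged assignment and (optionally) module-trait correlations.

    Modules whose eigengenes correlate >= ``merge_cor`` (average-linkage
    clusters of eigengenes on 1 - cor) are merged iteratively until stable;
    eigengenes are recomputed after every merge round.  Trait correlation is
    Pearson r of each final eigengene against each numeric trait column.
    """
    if (assignment > 0).sum() == 0:
        raise ValueError("no assigned modules")
    assignment = assignment.copy()

    def compute(assign: pd.Series) -> pd.DataFrame:
        eg = {}
        for m in sorted(assign[assign > 0].unique()):
            feats = assign.index[assign == m]
            try:
                eg[m] = _eigengene(normalized.loc[feats].to_numpy(dtype=float))
            except ValueError:
                warn(f"module {m}: constant features, dropped")
                assign[assign == m] = 0
        return pd.DataFrame(eg, index=normalized.columns)

    eigengenes = compute(assignment)
    while eigengenes.shape[1] > 1:
        cor = np.corrcoef(eigengenes.to_numpy().T)
        d = 1.0 - cor
        np.fill_diagonal(d, 0.0)
        d = np.maximum((d + d.T) / 2.0, 0.0)
        Z = linkage(squareform(d, checks=False), method="average")
        groups = fcluster(Z, t=1.0 - params.merge_cor, criterion="distance")
        if len(set(groups)) == eigengenes.shape[1]:
            break
        mapping = {}
        for new, old in zip(groups, eigengenes.columns):
            mapping.setdefault(new, []).append(old)
        for new, olds in mapping.items():
            target = min(olds)
            for old in olds:
                assignment[assignment == old] = target
        # relabel contiguously 1..m by decreasing size
        sizes = assignment[assignment > 0].value_counts()
        relabel = {m: i + 1 for i, m in enumerate(
            sorted(sizes.index, key=lambda m: (-sizes[m], m)))}
        assignment = assignment.map(lambda m: relabel.get(m, 0))
        eigengenes = compute(assignment)

    trait_cor = None
    if traits is not None:
        coded = code_traits(traits.loc[normalized.columns])
        rows = []
        for m in eigengenes.columns:
            for trait in coded.columns:
                x = eigengenes[m].to_numpy()
                y = coded[trait].to_numpy(dtype=float)
                if np.std(y) == 0 or np.std(x) == 0:
                    r, p = 0.0, 1.0
                else:
                    res = stats.pearsonr(x, y)
                    r, p = float(res.statistic), float(res.pvalue)
                rows.append((m, trait, r, p))
        trait_cor = pd.DataFrame(rows, columns=["module", "trait", "r", "p"])
    return eigengenes, assignment, trait_cor


def code_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Numeric coding of factor columns: numeric kept as-is, binary -> {0,1}."""
    out = {}
    for col in traits.columns:
        vals = traits[col]
        numeric = pd.to_numeric(vals, errors="coerce")
        if numeric.notna().all():
            out[col] = numeric.astype(float)
        else:
            levels = sorted(vals.astype(str).unique())
            mapping = {lv: i for i, lv in enumerate(levels)}
            out[col] = vals.astype(str).map(mapping).astype(float)
    return pd.DataFrame(out, index=traits.index)
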