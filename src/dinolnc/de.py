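"""Count normalization, outlier flagging and differential expression.

Normalization uses median-of-ratios size factors (features containing any
zero are excluded from the reference) and a log2(count/sf + 1) transform.
Differential expression is a negative-binomial Wald test: per-feature
method-of-moments dispersion shrunk 50/50 toward a fitted mean-dispersion
trend, a Wald statistic on the log2 fold-change of normalized group means
(0.5 pseudocount), and BH adjustment.  A feature is called up/down only
when padj <= 0.01 AND |log2fc| >= 2; everything else is "ns".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from ._util import warn
from .genome_io import CountMatrix

LOG2 = np.log(2.0)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (features with any zero excluded)."""
    mat = counts.to_numpy(dtype=float)
    if mat.sum() == 0:
        raise ValueError("all-zero count matrix")
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no feature has non-zero counts in every sample")
    logref = np.log(mat[positive]).mean(axis=1)
    sf = np.exp(np.median(np.log(mat[positive]) - logref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(cm: CountMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """log2(count / size_factor + 1) matrix plus the size factors."""
    sf = size_factors(cm.counts)
    normalized = np.log2(cm.counts.to_numpy(dtype=float) / sf.to_numpy() + 1.0)
    return (
        pd.DataFrame(normalized, index=cm.counts.index, columns=cm.counts.columns),
        sf,
    )


def flag_outlier_samples(
    normalized: pd.DataFrame,
    metadata: pd.DataFrame,
    condition_cols: list[str] | None = None,
) -> list[str]:
    """Samples that do not cluster with any replicate of their condition.

    Average-linkage clustering of pairwise Euclidean distances between
    samples, cut into k = number of conditions flat clusters; a sample is
    an outlier iff its flat cluster contains no other sample of its own
    condition (singletons included).
    """
    if condition_cols is None:
        condition_cols = list(metadata.columns)
    meta = metadata.loc[normalized.columns]
    if condition_cols:
        condition = meta[condition_cols].astype(str).agg("|".join, axis=1)
    else:
        condition = pd.Series("all", index=meta.index)
    k = condition.nunique()
    if k == 1 and len(condition) < 3:
        warn("flag_outlier_samples: single condition with < 3 samples; no calls")
        return []
    X = normalized.to_numpy(dtype=float).T
    Z = linkage(pdist(X, metric="euclidean"), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    flags = []
    for i, sample in enumerate(normalized.columns):
        mates = [
            j for j in range(len(labels))
            if j != i and labels[j] == labels[i] and condition.iloc[j] == condition.iloc[i]
        ]
        if not mates:
            flags.append(sample)
    return flags


def _dispersion_estimates(q: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-feature NB dispersion: method of moments, 50/50 trend shrinkage.

    ``q`` are size-factor-normalized counts; residual variance is pooled
    around the per-group means, and the gene-wise alpha is averaged with a
    fitted trend alpha(mu) = a0 + a1/mu (non-negative least squares on the
    gene-wise estimates).
    """
    mu = q.mean(axis=1)
    ss = np.zeros(q.shape[0])
    dof = 0
    for idx in groups:
        sub = q[:, idx]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dof += len(idx) - 1
    var = ss / max(dof, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_mom = (var - mu) / mu**2
    alpha_mom = np.where(np.isfinite(alpha_mom), alpha_mom, 0.0)
    alpha_mom = np.clip(alpha_mom, 1e-8, 10.0)

    usable = mu > 0
    if usable.sum() >= 10:
        A = np.column_stack([np.ones(usable.sum()), 1.0 / mu[usable]])
        coef, *_ = np.linalg.lstsq(A, alpha_mom[usable], rcond=None)
        coef = np.clip(coef, 0.0, None)
        with np.errstate(divide="ignore"):
            trend = coef[0] + coef[1] / np.where(mu > 0, mu, np.inf)
        trend = np.clip(trend, 1e-8, 10.0)
    else:
        trend = np.full_like(alpha_mom, alpha_mom[usable].mean() if usable.any() else 1e-8)
    return 0.5 * alpha_mom + 0.5 * trend


def test_differential_expression(
    cm: CountMatrix,
    contrast: tuple[str, str, str],
    padj_threshold: float = 0.01,
    lfc_threshold: float = 2.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """NB Wald test for ``contrast = (factor, test_level, reference_level)``.

    Returns a frame with baseMean, log2fc, p, padj and status per feature.
    """
    factor, test_level, ref_level = contrast
    if factor not in cm.metadata.columns:
        raise ValueError(f"unknown factor {factor!r}")
    fac = cm.metadata[factor].astype(str)
    idx_test = np.flatnonzero((fac == str(test_level)).to_numpy())
    idx_ref = np.flatnonzero((fac == str(ref_level)).to_numpy())
    if len(idx_test) < 2 or len(idx_ref) < 2:
        raise ValueError("each contrast level needs >= 2 samples")

    sf = size_factors(cm.counts).to_numpy()
    counts = cm.counts.to_numpy(dtype=float)
    q = counts / sf
    alpha = _dispersion_estimates(q, [idx_test, idx_ref])

    m_test = q[:, idx_test].mean(axis=1)
    m_ref = q[:, idx_ref].mean(axis=1)
    # pseudocount only guards zero means: log2fc of strictly positive means
    # is then exactly invariant to rescaling all normalized counts
    pseudo = np.where((m_test > 0) & (m_ref > 0), 0.0, pseudocount)
    lfc = np.log2(m_test + pseudo) - np.log2(m_ref + pseudo)

    # Var(mean_g) under NB with size factors: (1/n^2) sum_j (m/sf_j + alpha m^2)
    def group_var(m: np.ndarray, idx: np.ndarray) -> np.ndarray:
        inv_sf = (1.0 / sf[idx]).sum()
        n = len(idx)
        return (m * inv_sf + alpha * m**2 * n) / n**2

    var_log2 = (
        group_var(m_test, idx_test) / ((m_test + pseudo + 1e-12) ** 2)
        + group_var(m_ref, idx_ref) / ((m_ref + pseudo + 1e-12) ** 2)
    ) / LOG2**2
    se = np.sqrt(var_log2)

    with np.errstate(invalid="ignore", divide="ignore"):
        wald = lfc / se
    p = 2.0 * stats.norm.sf(np.abs(wald))
    both_zero = (counts[:, idx_test].sum(axis=1) == 0) & (counts[:, idx_ref].sum(axis=1) == 0)
    p = np.where(both_zero | ~np.isfinite(p), 1.0, p)
    lfc = np.where(both_zero, 0.0, lfc)

    padj = multipletests(p, method="fdr_bh")[1]
    status = np.where(
        (padj <= padj_threshold) & (np.abs(lfc) >= lfc_threshold),
        np.where(lfc > 0, "up", "down"),
        "ns",
    )
    return pd.DataFrame(
        {
            "baseMean": q.mean(axis=1),
            "log2fc": lfc,
            "p": p,
            "padj": padj,
            "status": status,
        },
        index=cm.counts.index,
    )
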