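"""Alignment-free lncRNA comparison via normalized k-mer profiles.

Overlapping k-mer counts (windows containing N are skipped) are converted
to rates per 1000 nt and z-scored per k-mer against the full input set as
background, seekr-style.  Pairwise Pearson correlation of the profiles
gives the adjacency matrix; average-linkage hierarchical clustering of
1 - r cut into at most ``t`` flat clusters groups the lncRNAs.  Cluster
membership is compared with co-expression modules via per-pair Fisher
exact tests (BH, FDR <= 0.01) and a Monte-Carlo global association test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from ._util import warn

BASES = "ACGT"


@dataclass(frozen=True)
class KmerParams:
    k: int = 4
    n_clusters: int = 10
    log_transform: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")


def kmer_index(k: int) -> dict[str, int]:
    return {"".join(p): i for i, p in enumerate(product(BASES, repeat=k))}


def kmer_counts(sequence: str, k: int) -> np.ndarray:
    """Raw overlapping k-mer counts; windows containing N are skipped."""
    if len(sequence) < k:
        raise ValueError(f"sequence of length {len(sequence)} is shorter than k={k}")
    idx = kmer_index(k)
    counts = np.zeros(len(idx), dtype=float)
    for i in range(len(sequence) - k + 1):
        kmer = sequence[i : i + k]
        j = idx.get(kmer)
        if j is not None:
            counts[j] += 1
    return counts


def kmer_profile(
    sequences: dict[str, str], params: KmerParams = KmerParams()
) -> pd.DataFrame:
    """Z-scored k-mer rate profiles (rows: sequences, columns: 4^k k-mers).

    Rates are counts per 1000 nt of sequence; the background mean/sigma is
    computed once per k-mer over the full input set; sigma = 0 coordinates
    get z = 0.  With ``log_transform`` the rates are log2(rate + 1) first.
    """
    k = params.k
    too_short = [name for name, s in sequences.items() if len(s) < k]
    if too_short:
        raise ValueError(f"sequences shorter than k={k}: {too_short[:5]}")
    idx = kmer_index(k)
    mat = np.zeros((len(sequences), len(idx)))
    names = list(sequences)
    for row, name in enumerate(names):
        seq = sequences[name]
        mat[row] = kmer_counts(seq, k) / len(seq) * 1000.0
    if params.log_transform:
        mat = np.log2(mat + 1.0)
    mean = mat.mean(axis=0)
    sigma = mat.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (mat - mean) / sigma
    z[:, sigma == 0] = 0.0
    columns = sorted(idx, key=idx.get)
    return pd.DataFrame(z, index=names, columns=columns)


def profile_adjacency(profiles: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Pearson-r matrix over the 4^k coordinates."""
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    degenerate = sd == 0
    if degenerate.any():
        warn(f"profile_adjacency: {int(degenerate.sum())} zero-variance profile(s), "
             "correlations set to 0")
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    norms[degenerate] = 1.0
    Xn = Xc / norms[:, None]
    r = Xn @ Xn.T
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return pd.DataFrame(r, index=profiles.index, columns=profiles.index)


def cluster_profiles(
    adjacency: pd.DataFrame, params: KmerParams = KmerParams()
) -> pd.Series:
    """Average-linkage flat clusters (<= t) on the distance 1 - r."""
    n = len(adjacency)
    t = params.n_clusters
    if n < 2 or n <= t:
        if n <= t:
            warn(f"cluster_profiles: only {n} sequences for t={t}; singleton clusters")
        return pd.Series(range(1, n + 1), index=adjacency.index, name="cluster")
    dist = 1.0 - adjacency.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=t, criterion="maxclust")
    return pd.Series(labels, index=adjacency.index, name="cluster")


# ---------------------------------------------------------------------------
# Cluster vs co-expression module association


def fisher_enrichment(
    clusters: pd.Series, modules: pd.Series, fdr: float = 0.01
) -> pd.DataFrame:
    """Per (cluster, module) 2x2 Fisher exact tests with BH correction.

    For each pair the table is {in/out cluster} x {in/out module} over the
    common label universe; two-tailed exact hypergeometric p; significance
    at BH q <= ``fdr``; direction over/under by comparison with the
    expected overlap under independence.
    """
    if set(clusters.index) != set(modules.index):
        raise ValueError("clusters and modules must label the same universe")
    modules = modules.loc[clusters.index]
    n = len(clusters)
    rows = []
    for c in sorted(clusters.unique()):
        in_c = clusters == c
        for m in sorted(modules.unique()):
            in_m = modules == m
            a = int((in_c & in_m).sum())
            b = int((in_c & ~in_m).sum())
            cc = int((~in_c & in_m).sum())
            d = int((~in_c & ~in_m).sum())
            odds, p = stats.fisher_exact([[a, b], [cc, d]], alternative="two-sided")
            expected = in_c.sum() * in_m.sum() / n
            rows.append((c, m, a, b, cc, d, odds, p, a - expected))
    df = pd.DataFrame(
        rows, columns=["cluster", "module", "a", "b", "c", "d", "odds_ratio", "p", "excess"]
    )
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df["direction"] = np.where(
        df["q"] > fdr, "ns", np.where(df["excess"] > 0, "over", "under")
    )
    return df.drop(columns="excess")


def _chi2_stat(table: np.ndarray) -> float:
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        cells = (table - expected) ** 2 / expected
    return float(np.nansum(cells))


def global_association_test(
    clusters: pd.Series,
    modules: pd.Series,
    n_replicates: int = 10_000,
    seed: int | None = None,
) -> float:
    """Monte-Carlo p for cluster x module association.

    Statistic: Pearson chi-square on the r x c contingency table; the null
    distribution is generated by shuffling one label vector (which fixes
    both margins); p = (1 + #{sim >= obs}) / (1 + replicates).
    """
    if set(clusters.index) != set(modules.index):
        raise ValueError("clusters and modules must label the same universe")
    modules = modules.loc[clusters.index]
    c_codes = pd.factorize(clusters)[0]
    m_codes = pd.factorize(modules)[0]
    n_c, n_m = c_codes.max() + 1, m_codes.max() + 1
    obs = np.zeros((n_c, n_m))
    np.add.at(obs, (c_codes, m_codes), 1)
    observed = _chi2_stat(obs)
    rng = np.random.default_rng(seed)
    exceed = 0
    shuffled = m_codes.copy()
    for _ in range(n_replicates):
        rng.shuffle(shuffled)
        tab = np.zeros((n_c, n_m))
        np.add.at(tab, (c_codes, shuffled), 1)
        if _chi2_stat(tab) >= observed - 1e-12:
            exceed += 1
    return (1 + exceed) / (1 + n_replicates)


def cluster_module_enrichment(
    clusters: pd.Series,
    modules: pd.Series,
    fdr: float = 0.01,
    n_replicates: int = 10_000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, float]:
    """Fisher per-pair enrichment table plus the Monte-Carlo global p."""
    table = fisher_enrichment(clusters, modules, fdr=fdr)
    global_p = global_association_test(clusters, modules, n_replicates, seed)
    return table, global_p
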