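"""Summary-table builders for the pipeline report.

Shapes mirror the standard presentation of this analysis: a feature-summary
table (lncRNA vs gene statistics with ratios), a biotype breakdown, DE
counts per contrast, a module table (trait correlations with gene / lncRNA
membership and k-mer cluster composition), and the triplex interaction
accounting.  All printed percentages and ratios use round-half-away-from-
zero at 1 and 2 decimals respectively.
"""

from __future__ import annotations

import pandas as pd

from ._util import round_half_up
from .identify import printed_percent, printed_ratio


def interaction_table(
    category_counts: dict[str, int],
    n_interactions: int,
    n_genes_total: int,
    genes_with_interactions: int,
    n_de_genes: int | None = None,
    de_genes_with_interactions: int | None = None,
) -> pd.Series:
    """Triplex interaction accounting from the category counts upward.

    The total number of triplex-forming lncRNAs is the sum of the four
    specificity categories; the gene rows carry the printed percentage.
    """
    order = ("one_to_one", "one_to_many", "many_to_one", "many_to_many")
    total = sum(category_counts.get(c, 0) for c in order)
    rows = {"n_triplex_lncrnas": total}
    rows.update({c: category_counts.get(c, 0) for c in order})
    rows["n_interactions"] = n_interactions
    rows["n_genes_total"] = n_genes_total
    rows["genes_with_interacting_lncrnas"] = genes_with_interactions
    rows["genes_with_interacting_pct"] = (
        printed_percent(genes_with_interactions, n_genes_total) if n_genes_total else 0.0
    )
    if n_de_genes is not None:
        rows["n_de_genes"] = n_de_genes
        rows["de_genes_with_interacting_lncrnas"] = de_genes_with_interactions or 0
        rows["de_genes_with_interacting_pct"] = (
            printed_percent(de_genes_with_interactions or 0, n_de_genes)
            if n_de_genes else 0.0
        )
    return pd.Series(rows)


def de_count_table(de_results: pd.DataFrame, feature_classes: pd.Series) -> pd.DataFrame:
    """Up/down counts split by feature class (gene vs lncRNA)."""
    df = de_results.join(feature_classes.rename("feature_class"))
    out = (
        df[df["status"] != "ns"]
        .groupby(["feature_class", "status"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return out


def module_table(
    assignment: pd.Series,
    trait_cor: pd.DataFrame | None,
    feature_classes: pd.Series,
    kmer_clusters: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-module summary: trait correlations, membership, cluster mix."""
    rows = []
    for m in sorted(assignment[assignment > 0].unique()):
        members = assignment.index[assignment == m]
        classes = feature_classes.reindex(members)
        row: dict[str, object] = {
            "module": m,
            "n_features": len(members),
            "n_genes": int((classes == "gene").sum()),
            "n_lncrnas": int((classes == "lncRNA").sum()),
        }
        if trait_cor is not None:
            for _, t in trait_cor[trait_cor["module"] == m].iterrows():
                row[f"r_{t['trait']}"] = round_half_up(t["r"], 2)
        if kmer_clusters is not None:
            in_mod = kmer_clusters.reindex(members).dropna()
            for c, n in in_mod.value_counts().sort_index().items():
                row[f"cluster_{int(c)}"] = int(n)
        rows.append(row)
    return pd.DataFrame(rows)


def audit_printed_fraction(numerator: float, denominator: float, kind: str = "ratio") -> float:
    """Recompute a printed ratio (2 dp) or percentage (1 dp) from its parts."""
    if kind == "ratio":
        return printed_ratio(numerator, denominator)
    if kind == "percent":
        return printed_percent(numerator, denominator)
    raise ValueError(f"unknown kind {kind!r}")
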