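"""RNA-DNA triplex target prediction under Hoogsteen pairing rules.

A triplex-forming oligonucleotide (TFO) segment of a lncRNA binds a
purine-rich triplex target site (TTS) in the duplex major groove:

- pyrimidine motif {C,T}: parallel orientation, T.A:T and C.G:C;
- purine motif {G,A}: antiparallel orientation, G.G:C and A.A:T;
- mixed motif {G,T}: both orientations, G.G:C and T.A:T.

Both promoter strands are scanned.  A hit is an ungapped pairing of
length >= ``min_len`` with mismatch rate <= ``max_error_rate``, no run of
more than ``max_consecutive_errors`` mismatches, TTS guanine fraction >=
``min_guanine_rate``, and N never matching; hits begin and end on a
paired position, and only maximal hits (not contained in a longer valid
pairing on the same alignment diagonal) are reported.
Low-complexity tandem repeats are masked beforehand, and TFO segments
whose exact sequence recurs at more than ``duplicate_cutoff`` distinct
lncRNA loci are discarded.  The lncRNA is treated in the DNA alphabet
(U == T).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from ._util import revcomp, round_half_up, warn
from .genome_io import PromoterRegion

MOTIF_ORDER = ("pyrimidine", "purine", "mixed")

# Hoogsteen pairing per motif: (TFO base, TTS purine-strand base) pairs
MOTIF_PAIRS = {
    "pyrimidine": (("T", "A"), ("C", "G")),
    "purine": (("G", "G"), ("A", "A")),
    "mixed": (("G", "G"), ("T", "A")),
}
MOTIF_ORIENTATIONS = {
    "pyrimidine": ("parallel",),
    "purine": ("antiparallel",),
    "mixed": ("parallel", "antiparallel"),
}

@dataclass(frozen=True)
class TriplexParams:
    min_len: int = 20
    max_error_rate: float = 0.05
    repeat_filter: bool = True
    min_repeat_len: int = 7
    max_repeat_period: int = 3
    duplicate_cutoff: int = 5
    motifs: tuple[str, ...] = MOTIF_ORDER
    max_consecutive_errors: int = 1
    min_guanine_rate: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.max_error_rate < 1.0):
            raise ValueError("max_error_rate must be in (0,1)")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


@dataclass(frozen=True)
class TriplexHit:
    lncrna_id: str
    gene_id: str
    tfo_offset: int  # in lncRNA coordinates
    tts_offset: int  # in promoter (forward) coordinates
    length: int
    mismatches: int
    motif: str
    orientation: str
    tts_strand: str  # promoter strand carrying the purine tract

    @property
    def error_rate(self) -> float:
        return self.mismatches / self.length


def mask_low_complexity(sequence: str, mrl: int = 7, mrp: int = 3) -> str:
    """Replace maximal tandem repeats (period <= mrp, total length >= mrl) with N."""
    seq = sequence.upper().replace("U", "T")
    n = len(seq)
    mask = np.zeros(n, dtype=bool)
    for period in range(1, mrp + 1):
        i = period
        while i < n:
            if seq[i] == seq[i - period] and seq[i] != "N":
                start = i - period
                while i < n and seq[i] == seq[i - period] and seq[i] != "N":
                    i += 1
                if i - start >= mrl:
                    mask[start:i] = True
            else:
                i += 1
    return "".join("N" if m else b for m, b in zip(mask, seq))


def _min_seed_run(min_len: int, max_rate: float, max_len: int) -> int:
    """Lower bound on the longest all-match run inside any valid window.

    A window of length L with at most floor(max_rate*L) mismatches contains
    a match run of at least ceil((L - mm)/(mm + 1)); the minimum over
    feasible L is a safe pruning seed.
    """
    best = min_len
    for L in range(min_len, max(max_len, min_len) + 1):
        mm = int(max_rate * L)
        best = min(best, -(-(L - mm) // (mm + 1)))
    return max(best, 1)


def _maximal_windows(
    match: np.ndarray,
    g_mask: np.ndarray,
    params: TriplexParams,
) -> list[tuple[int, int, int]]:
    """Maximal valid (start, length, mismatches) windows on one diagonal.

    A valid window starts and ends on a paired position, has length >=
    min_len, mismatch rate <= max_error_rate, no mismatch run longer than
    max_consecutive_errors, and TTS guanine fraction >= min_guanine_rate.
    Maximal = not properly contained in another valid window.
    """
    n = len(match)
    l = params.min_len
    if n < l:
        return []
    mism = ~np.asarray(match, dtype=bool)
    mc = params.max_consecutive_errors

    # valid windows cannot contain (or abut into) a mismatch run longer than
    # mc, and never start/end on a mismatch: split into segments at long runs
    segments: list[tuple[int, int]] = []
    seg_start = 0
    i = 0
    while i < n:
        if mism[i]:
            j = i
            while j < n and mism[j]:
                j += 1
            if j - i > mc:
                if i - seg_start >= l:
                    segments.append((seg_start, i))
                seg_start = j
            i = j
        else:
            i += 1
    if n - seg_start >= l:
        segments.append((seg_start, n))
    if not segments:
        return []

    seed = _min_seed_run(l, params.max_error_rate, n)
    mm_prefix = np.concatenate([[0], np.cumsum(mism)])
    g_prefix = np.concatenate([[0], np.cumsum(np.asarray(g_mask, dtype=int))])

    def valid(a: int, b: int) -> bool:
        L = b - a
        if L < l or mism[a] or mism[b - 1]:
            return False
        if (mm_prefix[b] - mm_prefix[a]) > params.max_error_rate * L + 1e-12:
            return False
        if (g_prefix[b] - g_prefix[a]) < params.min_guanine_rate * L - 1e-12:
            return False
        return True

    out: list[tuple[int, int, int]] = []
    for (s0, s1) in segments:
        best_run, run = 0, 0
        for i in range(s0, s1):
            run = run + 1 if match[i] else 0
            best_run = max(best_run, run)
        if best_run < seed:
            continue
        windows = [
            (a, b)
            for a in range(s0, s1 - l + 1)
            if not mism[a]
            for b in range(a + l, s1 + 1)
            if valid(a, b)
        ]
        for (a, b) in windows:
            contained = any(
                (a2 <= a and b <= b2 and (a2, b2) != (a, b)) for a2, b2 in windows
            )
            if not contained:
                out.append((a, b - a, int(mm_prefix[b] - mm_prefix[a])))
    return out


def _hit_rank(h: "TriplexHit") -> tuple:
    """Collapse order for duplicate hits at identical coordinates."""
    return (h.mismatches, MOTIF_ORDER.index(h.motif), h.orientation != "parallel")


# each motif maps a TFO base to exactly one TTS purine-strand base, so a
# Hoogsteen match is literal string equality after translating the TFO
_MOTIF_TRANSLATE = {
    motif: str.maketrans(
        {b: "X" for b in "ACGTN"} | {a: b for (a, b) in pairs}
    )
    for motif, pairs in MOTIF_PAIRS.items()
}


def _scan_hits(
    lncrnas: dict[str, str],
    promoters: list[PromoterRegion],
    params: TriplexParams,
) -> list[TriplexHit]:
    """Seed-indexed scan shared by the single-pair and batch entry points.

    Every valid window contains a perfect match run of at least ``seed``
    positions, which after per-motif translation of the TFO is an exact
    common ``seed``-mer at the same alignment diagonal; a k-mer index over
    the promoter strands therefore enumerates every diagonal that can carry
    a hit, and only those diagonals are examined in full.
    """
    tfo_seqs = {}
    for lid, seq in lncrnas.items():
        s = seq.upper().replace("U", "T")
        if params.repeat_filter:
            s = mask_low_complexity(s, params.min_repeat_len, params.max_repeat_period)
        tfo_seqs[lid] = s
    proms = []
    for prom in promoters:
        s = prom.sequence.upper()
        if params.repeat_filter:
            s = mask_low_complexity(s, params.min_repeat_len, params.max_repeat_period)
        proms.append((prom, s))

    max_len = max(
        [len(s) for s in tfo_seqs.values()] + [len(s) for _, s in proms] + [params.min_len]
    )
    seed = _min_seed_run(params.min_len, params.max_error_rate, max_len)
    hits: dict[tuple, TriplexHit] = {}

    for tts_strand in ("+", "-"):
        # seed-mer index over all promoter target strands
        index: dict[str, list[tuple[int, int]]] = {}
        tts_cache: list[str] = []
        for pi, (prom, pseq) in enumerate(proms):
            tts = pseq if tts_strand == "+" else revcomp(pseq)
            tts_cache.append(tts)
            for j in range(len(tts) - seed + 1):
                index.setdefault(tts[j : j + seed], []).append((pi, j))

        for lid in sorted(tfo_seqs):
            tfo = tfo_seqs[lid]
            n_tfo = len(tfo)
            if n_tfo < params.min_len:
                continue
            for motif in params.motifs:
                for orientation in MOTIF_ORIENTATIONS[motif]:
                    q = tfo if orientation == "parallel" else tfo[::-1]
                    mapped = q.translate(_MOTIF_TRANSLATE[motif])
                    candidates: dict[int, set[int]] = {}
                    for i in range(len(mapped) - seed + 1):
                        sub = mapped[i : i + seed]
                        if "X" in sub:
                            continue
                        for (pi, j) in index.get(sub, ()):
                            candidates.setdefault(pi, set()).add(j - i)
                    for pi, offsets in candidates.items():
                        prom, _ = proms[pi]
                        tts = tts_cache[pi]
                        n_tts = len(tts)
                        for off in sorted(offsets):
                            i0 = max(0, -off)
                            j0 = max(0, off)
                            length = min(n_tfo - i0, n_tts - j0)
                            if length < params.min_len:
                                continue
                            qd = np.frombuffer(
                                mapped[i0 : i0 + length].encode(), dtype=np.uint8
                            )
                            td = np.frombuffer(
                                tts[j0 : j0 + length].encode(), dtype=np.uint8
                            )
                            diag = qd == td
                            g_diag = td == ord("G")
                            for (a, wlen, mm) in _maximal_windows(diag, g_diag, params):
                                qi = i0 + a
                                tj = j0 + a
                                tfo_off = (
                                    qi if orientation == "parallel"
                                    else n_tfo - (qi + wlen)
                                )
                                tts_off = tj if tts_strand == "+" else n_tts - (tj + wlen)
                                key = (lid, prom.gene_id, tfo_off, tts_off, wlen,
                                       tts_strand)
                                cand = TriplexHit(
                                    lid, prom.gene_id, tfo_off, tts_off, wlen,
                                    mm, motif, orientation, tts_strand,
                                )
                                prev = hits.get(key)
                                if prev is None or _hit_rank(cand) < _hit_rank(prev):
                                    hits[key] = cand
    return sorted(
        hits.values(),
        key=lambda h: (h.lncrna_id, h.gene_id, h.tts_offset, h.tfo_offset,
                       h.length, h.tts_strand, h.orientation),
    )


def find_triplex_hits(
    lncrna_id: str,
    lncrna_seq: str,
    promoter: PromoterRegion,
    params: TriplexParams = TriplexParams(),
) -> list[TriplexHit]:
    """All maximal triplex hits between one lncRNA and one promoter."""
    if not lncrna_seq or not promoter.sequence:
        return []
    return _scan_hits({lncrna_id: lncrna_seq}, [promoter], params)


def find_all_hits(
    lncrnas: dict[str, str],
    promoters: list[PromoterRegion],
    params: TriplexParams = TriplexParams(),
) -> list[TriplexHit]:
    """Genome-wide scan of every lncRNA against every promoter, deduplicated."""
    hits = _scan_hits(lncrnas, promoters, params)
    return deduplicate_features(hits, dc=params.duplicate_cutoff, lncrnas=lncrnas)


def deduplicate_features(
    hits: list[TriplexHit],
    dc: int = 5,
    lncrnas: dict[str, str] | None = None,
) -> list[TriplexHit]:
    """Drop hits whose exact TFO sequence recurs at > dc distinct lncRNA loci."""
    if lncrnas is None:
        return list(hits)
    tfo_seq = {}
    for h in hits:
        seq = lncrnas[h.lncrna_id].upper().replace("U", "T")
        tfo_seq[id(h)] = seq[h.tfo_offset : h.tfo_offset + h.length]
    loci: dict[str, set] = {}
    for h in hits:
        loci.setdefault(tfo_seq[id(h)], set()).add((h.lncrna_id, h.tfo_offset))
    return [h for h in hits if len(loci[tfo_seq[id(h)]]) <= dc]


# ---------------------------------------------------------------------------
# Interaction graph


@dataclass
class InteractionGraph:
    lnc_to_genes: dict[str, set[str]]
    gene_to_lncs: dict[str, set[str]]

    @classmethod
    def from_hits(cls, hits: list[TriplexHit]) -> "InteractionGraph":
        l2g: dict[str, set[str]] = {}
        g2l: dict[str, set[str]] = {}
        for h in hits:
            l2g.setdefault(h.lncrna_id, set()).add(h.gene_id)
            g2l.setdefault(h.gene_id, set()).add(h.lncrna_id)
        return cls(l2g, g2l)

    @property
    def n_edges(self) -> int:
        return sum(len(g) for g in self.lnc_to_genes.values())

    def edges(self) -> list[tuple[str, str]]:
        return sorted(
            (l, g) for l, genes in self.lnc_to_genes.items() for g in genes
        )


def categorize_interactions(graph: InteractionGraph) -> tuple[dict[str, str], pd.Series]:
    """Per-lncRNA interaction specificity category plus category counts.

    one_to_one: one gene, and that gene has only this lncRNA;
    one_to_many: several genes, all exclusive to this lncRNA;
    many_to_one: one gene that has several lncRNA partners;
    many_to_many: everything else.
    """
    categories = {}
    for l, genes in graph.lnc_to_genes.items():
        if len(genes) == 1:
            g = next(iter(genes))
            categories[l] = (
                "one_to_one" if len(graph.gene_to_lncs[g]) == 1 else "many_to_one"
            )
        else:
            if all(len(graph.gene_to_lncs[g]) == 1 for g in genes):
                categories[l] = "one_to_many"
            else:
                categories[l] = "many_to_many"
    counts = pd.Series(
        {c: sum(1 for v in categories.values() if v == c)
         for c in ("one_to_one", "one_to_many", "many_to_one", "many_to_many")},
        name="count",
    )
    return categories, counts


def interaction_summary(
    graph: InteractionGraph, n_genes_total: int, de_gene_ids: set[str] | None = None
) -> pd.Series:
    """Table-3-shaped accounting of the interaction graph."""
    _, counts = categorize_interactions(graph)
    genes_with = len(graph.gene_to_lncs)
    out = {
        "n_triplex_lncrnas": len(graph.lnc_to_genes),
        "n_interactions": graph.n_edges,
        **counts.to_dict(),
        "n_genes_total": n_genes_total,
        "genes_with_interacting_lncrnas": genes_with,
        "genes_with_interacting_pct": round_half_up(
            100.0 * genes_with / n_genes_total, 1
        ) if n_genes_total else 0.0,
    }
    if de_gene_ids is not None:
        de_with = len(de_gene_ids & set(graph.gene_to_lncs))
        out["n_de_genes"] = len(de_gene_ids)
        out["de_genes_with_interacting_lncrnas"] = de_with
        out["de_genes_with_interacting_pct"] = (
            round_half_up(100.0 * de_with / len(de_gene_ids), 1) if de_gene_ids else 0.0
        )
    return pd.Series(out)


# ---------------------------------------------------------------------------
# Expression correlation of interacting pairs


def correlate_interaction_expression(
    graph: InteractionGraph,
    de_results: pd.DataFrame,
    normalized: pd.DataFrame,
    rho_min: float = 0.8,
    p_max: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Spearman correlation for edges whose gene is differentially expressed.

    Retains |rho| >= rho_min AND p <= p_max; the summary reports the
    retained count and the fraction with negative rho.
    """
    de_genes = set(de_results.index[de_results["status"] != "ns"])
    rows = []
    for l, g in graph.edges():
        if g not in de_genes:
            continue
        if l not in normalized.index or g not in normalized.index:
            continue
        x = normalized.loc[l].to_numpy(dtype=float)
        y = normalized.loc[g].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        rho, p = stats.spearmanr(x, y)
        if np.isnan(rho):
            continue
        if abs(rho) >= rho_min and p <= p_max:
            rows.append((l, g, float(rho), float(p),
                         "negative" if rho < 0 else "positive"))
    df = pd.DataFrame(rows, columns=["lncrna_id", "gene_id", "spearman_rho", "p", "sign"])
    n = len(df)
    summary = pd.Series({
        "n_correlated_interactions": n,
        "fraction_negative": (df["sign"] == "negative").mean() if n else 0.0,
    })
    return df, summary


def group_target_genes(
    correlated: pd.DataFrame,
    min_multi: int = 2,
    n_groups: int = 3,
) -> pd.DataFrame:
    """Cluster multi-lncRNA target genes by their correlation fingerprints.

    Genes with >= ``min_multi`` correlated lncRNA interactions form a gene x
    lncRNA rho matrix (absent pairs 0); average-linkage Euclidean clustering
    cut to ``n_groups``; groups are ordered by ascending mean number of
    lncRNA interactions (group 1 = fewest).
    """
    per_gene = correlated.groupby("gene_id")["lncrna_id"].nunique()
    genes = sorted(per_gene.index[per_gene >= min_multi])
    if not genes:
        return pd.DataFrame(columns=["gene_id", "group", "n_interactions"])
    mat = correlated.pivot_table(
        index="gene_id", columns="lncrna_id", values="spearman_rho", fill_value=0.0
    ).loc[genes]
    k = min(n_groups, len(genes))
    if k < n_groups:
        warn(f"group_target_genes: only {len(genes)} genes for {n_groups} groups")
    if len(genes) == 1:
        labels = np.array([1])
    else:
        Z = linkage(pdist(mat.to_numpy(dtype=float), metric="euclidean"), method="average")
        labels = fcluster(Z, t=k, criterion="maxclust")
    df = pd.DataFrame({
        "gene_id": genes,
        "raw_group": labels,
        "n_interactions": per_gene.loc[genes].to_numpy(),
    })
    means = df.groupby("raw_group")["n_interactions"].mean().sort_values(kind="stable")
    order = {g: i + 1 for i, g in enumerate(means.index)}
    df["group"] = df["raw_group"].map(order)
    return df[["gene_id", "group", "n_interactions"]].sort_values(
        ["group", "gene_id"]
    ).reset_index(drop=True)
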