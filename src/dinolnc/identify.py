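"""The lncRNA identification cascade.

Transcript-to-genome alignments are filtered through five stages, in order:

1. alignment quality (identity >= 95%, query coverage >= 75%);
2. removal of transcripts overlapping (>= 1 bp) any annotated exon, on
   either strand — intronic-only overlap survives;
3. minimum length (> 200 nt) and intrinsic coding-potential consensus;
4. removal of transcripts with significant protein-domain hits
   (externally produced hit table, p <= 1e-5), identity when absent;
5. redundancy collapse by genomic-span overlap (longest representative)
   and expression support (>= min_reads uniquely mapped reads in
   >= min_samples samples).

Survivors are promoted to LncRNA records with intron counts and G+C
content, and summarized Table-2 style against the protein-coding genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._util import gc_fraction, round_half_up, warn
from .coding import score_coding_potential
from .genome_io import Annotation, CountMatrix, Genome, Interval

CASCADE_STAGES = ("alignment", "exon_overlap", "coding_potential",
                  "domain_hits", "redundancy", "expression_support")


# ---------------------------------------------------------------------------
# Records


@dataclass(frozen=True)
class TranscriptAlignment:
    transcript_id: str
    scaffold: str
    strand: str
    blocks: tuple[Interval, ...]
    identity: float
    query_coverage: float
    sequence: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.query_coverage <= 1.0):
            raise ValueError(f"{self.transcript_id}: identity/coverage must be in [0,1]")
        object.__setattr__(self, "blocks", tuple(sorted(tuple(b) for b in self.blocks)))
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: blocks overlap or unsorted")

    @property
    def span(self) -> Interval:
        return (self.blocks[0][0], self.blocks[-1][1])

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass
class LncRNACandidate:
    id: str
    scaffold: str
    strand: str
    blocks: tuple[Interval, ...]
    sequence: str
    stage_flags: dict[str, bool] = field(default_factory=dict)
    support_samples: int | None = None

    @property
    def span(self) -> Interval:
        return (self.blocks[0][0], self.blocks[-1][1])

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass(frozen=True)
class LncRNA:
    id: str
    scaffold: str
    strand: str
    blocks: tuple[Interval, ...]
    sequence: str
    support_samples: int
    intron_count: int
    gc_fraction: float

    @property
    def span(self) -> Interval:
        return (self.blocks[0][0], self.blocks[-1][1])

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


def candidates_from_alignments(alignments: list[TranscriptAlignment]) -> list[LncRNACandidate]:
    return [
        LncRNACandidate(a.transcript_id, a.scaffold, a.strand, a.blocks, a.sequence)
        for a in alignments
    ]


# ---------------------------------------------------------------------------
# Cascade stages


def filter_alignments(
    alignments: list[TranscriptAlignment],
    min_identity: float = 0.95,
    min_coverage: float = 0.75,
) -> list[TranscriptAlignment]:
    """Keep alignments with identity >= min_identity and coverage >= min_coverage."""
    return [
        a for a in alignments
        if a.identity >= min_identity and a.query_coverage >= min_coverage
    ]


def remove_exonic(
    candidates: list[LncRNACandidate],
    annotation: Annotation,
    genome: Genome | None = None,
    ignore_strand: bool = True,
) -> list[LncRNACandidate]:
    """Remove candidates whose blocks share >= 1 bp with any gene exon.

    The overlap test is strand-agnostic by default: dinoflagellate lncRNAs
    do not share exonic regions with genes on either strand.  Intronic-only
    overlap is kept (these become "sense genic" biotypes downstream).
    Passing the genome enables rejection of unknown candidate scaffolds.
    """
    kept = []
    for c in candidates:
        if genome is not None and c.scaffold not in genome:
            raise ValueError(f"candidate {c.id}: unknown scaffold {c.scaffold!r}")
        overlaps = False
        for g in annotation.overlapping(c.scaffold, *c.span):
            if not ignore_strand and g.strand != c.strand:
                continue
            for bs, be in c.blocks:
                for es, ee in g.exons:
                    if bs < ee and es < be:
                        overlaps = True
                        break
                if overlaps:
                    break
            if overlaps:
                break
        c.stage_flags["exon_overlap"] = not overlaps
        if not overlaps:
            kept.append(c)
    return kept


def filter_coding(
    candidates: list[LncRNACandidate],
    min_length: int = 200,
    min_orf_codons: int = 100,
    max_orf_fraction: float = 0.5,
    fickett_threshold: float = 0.95,
) -> list[LncRNACandidate]:
    """Keep candidates longer than ``min_length`` nt and called non-coding."""
    kept = []
    for c in candidates:
        if len(c.sequence) <= min_length:
            c.stage_flags["coding_potential"] = False
            continue
        cp = score_coding_potential(
            c.sequence, min_orf_codons, max_orf_fraction, fickett_threshold
        )
        c.stage_flags["coding_potential"] = cp.is_noncoding
        if cp.is_noncoding:
            kept.append(c)
    return kept


def filter_domain_hits(
    candidates: list[LncRNACandidate],
    hit_table: pd.DataFrame | None = None,
    max_p: float = 1e-5,
) -> list[LncRNACandidate]:
    """Remove candidates with >= 1 protein-domain hit at p <= max_p.

    ``hit_table`` columns: candidate id, p-value (first two columns used).
    Without a table this stage is the identity.
    """
    if hit_table is None or hit_table.empty:
        for c in candidates:
            c.stage_flags["domain_hits"] = True
        return list(candidates)
    ids = {c.id for c in candidates}
    idcol, pcol = hit_table.columns[0], hit_table.columns[1]
    unknown = set(hit_table[idcol]) - ids
    if unknown:
        warn(f"filter_domain_hits: ignoring hits for {len(unknown)} unknown candidate id(s)")
    significant = set(hit_table.loc[hit_table[pcol] <= max_p, idcol])
    kept = []
    for c in candidates:
        ok = c.id not in significant
        c.stage_flags["domain_hits"] = ok
        if ok:
            kept.append(c)
    return kept


def collapse_redundant(candidates: list[LncRNACandidate]) -> list[LncRNACandidate]:
    """One representative per chain of span-overlapping candidates.

    Connected components under "genomic span overlap >= 1 bp on the same
    scaffold and strand"; the representative maximizes total exonic length,
    ties broken by lexicographically smallest id.
    """
    by_group: dict[tuple[str, str], list[LncRNACandidate]] = {}
    for c in candidates:
        by_group.setdefault((c.scaffold, c.strand), []).append(c)
    representatives = []
    for group in by_group.values():
        group.sort(key=lambda c: (c.span[0], c.span[1], c.id))
        component: list[LncRNACandidate] = []
        comp_end = -1
        for c in group:
            s, e = c.span
            if component and s >= comp_end:
                representatives.append(_pick_representative(component))
                component = []
                comp_end = -1
            component.append(c)
            comp_end = max(comp_end, e)
        if component:
            representatives.append(_pick_representative(component))
    reps = {c.id for c in representatives}
    for c in candidates:
        c.stage_flags["redundancy"] = c.id in reps
    representatives.sort(key=lambda c: (c.scaffold, c.span[0], c.id))
    return representatives


def _pick_representative(component: list[LncRNACandidate]) -> LncRNACandidate:
    return min(component, key=lambda c: (-c.spliced_length, c.id))


def apply_expression_support(
    candidates: list[LncRNACandidate],
    counts: CountMatrix,
    min_samples: int = 10,
    min_reads: int = 10,
) -> list[LncRNA]:
    """Promote candidates supported by >= min_reads in >= min_samples samples."""
    missing = [c.id for c in candidates if c.id not in counts.counts.index]
    if missing:
        warn(f"apply_expression_support: {len(missing)} candidate(s) absent from "
             "counts, treated as all-zero")
    out = []
    for c in candidates:
        if c.id in counts.counts.index:
            support = int((counts.counts.loc[c.id] >= min_reads).sum())
        else:
            support = 0
        c.support_samples = support
        ok = support >= min_samples
        c.stage_flags["expression_support"] = ok
        if ok:
            out.append(
                LncRNA(
                    id=c.id, scaffold=c.scaffold, strand=c.strand, blocks=c.blocks,
                    sequence=c.sequence, support_samples=support,
                    intron_count=len(c.blocks) - 1, gc_fraction=gc_fraction(c.sequence),
                )
            )
    return out


def run_cascade(
    alignments: list[TranscriptAlignment],
    annotation: Annotation,
    counts: CountMatrix,
    hit_table: pd.DataFrame | None = None,
    min_identity: float = 0.95,
    min_coverage: float = 0.75,
    min_length: int = 200,
    min_samples: int = 10,
    min_reads: int = 10,
) -> tuple[list[LncRNA], pd.DataFrame]:
    """Run the full five-stage cascade; returns (lncRNAs, attrition table)."""
    attrition = []
    retained_aln = filter_alignments(alignments, min_identity, min_coverage)
    attrition.append(("alignment", len(alignments), len(retained_aln)))
    cands = candidates_from_alignments(retained_aln)
    for c in cands:
        c.stage_flags["alignment"] = True

    stage_in = len(cands)
    cands = remove_exonic(cands, annotation)
    attrition.append(("exon_overlap", stage_in, len(cands)))

    stage_in = len(cands)
    cands = filter_coding(cands, min_length=min_length)
    attrition.append(("coding_potential", stage_in, len(cands)))

    stage_in = len(cands)
    cands = filter_domain_hits(cands, hit_table)
    attrition.append(("domain_hits", stage_in, len(cands)))

    stage_in = len(cands)
    cands = collapse_redundant(cands)
    attrition.append(("redundancy", stage_in, len(cands)))

    stage_in = len(cands)
    lncrnas = apply_expression_support(cands, counts, min_samples, min_reads)
    attrition.append(("expression_support", stage_in, len(lncrnas)))

    table = pd.DataFrame(attrition, columns=["stage", "n_in", "n_out"])
    return lncrnas, table


# ---------------------------------------------------------------------------
# Feature summary (Table-2 shape)


@dataclass(frozen=True)
class FeatureSummary:
    """Per-set feature statistics and the lncRNA:gene ratios."""

    lncrna: dict[str, float]
    gene: dict[str, float]
    ratios: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = ["count", "mean_length_bp", "gc_percent", "mean_introns", "pct_with_introns"]
        return pd.DataFrame(
            {
                "lncRNA": [self.lncrna[r] for r in rows],
                "gene": [self.gene[r] for r in rows],
                "ratio": [self.ratios[r] for r in rows],
            },
            index=rows,
        )


def printed_ratio(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """A printed-table ratio, rounded half away from zero."""
    return round_half_up(numerator / denominator, ndigits)


def printed_percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    return round_half_up(100.0 * numerator / denominator, ndigits)


def _feature_stats(lengths, gcs, introns) -> dict[str, float]:
    n = len(lengths)
    return {
        "count": float(n),
        "mean_length_bp": sum(lengths) / n,
        "gc_percent": 100.0 * sum(g * l for g, l in zip(gcs, lengths)) / sum(lengths),
        "mean_introns": sum(introns) / n,
        "pct_with_introns": 100.0 * sum(1 for i in introns if i > 0) / n,
    }


def summarize_features(
    lncrnas: list[LncRNA], annotation: Annotation, genome: Genome
) -> FeatureSummary:
    """Table-2-style summary: counts, spliced length, G+C%, introns, ratios."""
    if not lncrnas or len(annotation) == 0:
        raise ValueError("summarize_features requires non-empty lncRNA and gene sets")
    l_stats = _feature_stats(
        [l.spliced_length for l in lncrnas],
        [l.gc_fraction for l in lncrnas],
        [l.intron_count for l in lncrnas],
    )
    genes = list(annotation)
    gseqs = [g.spliced_sequence(genome) for g in genes]
    g_stats = _feature_stats(
        [len(s) for s in gseqs],
        [gc_fraction(s) for s in gseqs],
        [g.intron_count for g in genes],
    )
    ratios = {}
    for key in l_stats:
        ndigits = 1 if key.startswith("pct") or key == "gc_percent" else 2
        # ratios are printed at 2 dp; the per-set % metrics at 1 dp
        ratios[key] = printed_ratio(l_stats[key], g_stats[key], 2)
        if key in ("gc_percent", "pct_with_introns"):
            l_stats[key] = round_half_up(l_stats[key], 1)
            g_stats[key] = round_half_up(g_stats[key], 1)
    return FeatureSummary(l_stats, g_stats, ratios)
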