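"""Biotype classification of lncRNAs relative to the nearest gene.

A lncRNA is paired with the closest gene within 5 kb up- or downstream
(span overlap takes precedence, distance 0) and labelled by the geometry:

- overlap, same strand          -> sense_genic (intronic by construction)
- overlap, opposite strand      -> antisense_genic
- no overlap, same strand       -> sense_intergenic
- no overlap, opposite strand   -> divergent if BOTH gap-adjacent transcript
  ends are 5' (head-to-head), convergent if both are 3' (tail-to-tail);
  configurations with one 5' and one 3' gap-adjacent end are labelled by
  the lncRNA's own gap-adjacent end and flagged ``mixed_ends``
- no qualifying gene            -> distant

Classification depends only on geometry and strand, never on identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up
from .genome_io import Annotation, GeneModel
from .identify import LncRNA

LABELS = (
    "sense_genic",
    "antisense_genic",
    "sense_intergenic",
    "antisense_intergenic_divergent",
    "antisense_intergenic_convergent",
    "distant",
)


@dataclass(frozen=True)
class BiotypeAssignment:
    lncrna_id: str
    gene_id: str | None
    distance_bp: int
    label: str
    mixed_ends: bool = False


def find_nearest_gene(
    lncrna: LncRNA, annotation: Annotation, window: int = 5000
) -> tuple[str | None, int, str]:
    """Closest gene within ``window`` bp either side, overlap preferred.

    Returns (gene_id or None, gap distance, relation in {overlap,left,right}).
    Among several overlapping genes the one with the largest span overlap is
    chosen (ties by id).  Equidistant left/right genes prefer the same-strand
    gene, then the left gene.
    """
    s, e = lncrna.span
    overlapping = annotation.overlapping(lncrna.scaffold, s, e)
    if overlapping:
        best = min(
            overlapping,
            key=lambda g: (-(min(e, g.end) - max(s, g.start)), g.gene_id),
        )
        return best.gene_id, 0, "overlap"
    near = annotation.overlapping(lncrna.scaffold, max(0, s - window - 1), e + window + 1)
    best_gene: GeneModel | None = None
    best_key = None
    for g in near:
        if g.end <= s:
            gap, side = s - g.end, "left"
        elif g.start >= e:
            gap, side = g.start - e, "right"
        else:  # pragma: no cover - overlap handled above
            continue
        if gap > window:
            continue
        same_strand = 0 if g.strand == lncrna.strand else 1
        side_pref = 0 if side == "left" else 1
        key = (gap, same_strand, side_pref, g.gene_id)
        if best_key is None or key < best_key:
            best_key, best_gene = key, g
            best_side = side
    if best_gene is None:
        return None, -1, "none"
    return best_gene.gene_id, best_key[0], best_side


def _gap_adjacent_end(strand: str, feature_is_left: bool) -> str:
    """Which transcript end (5'/3') of a feature faces the intergenic gap."""
    # the gap-adjacent genomic end is the feature's right edge if the feature
    # lies left of the gap, else its left edge
    if feature_is_left:
        return "3'" if strand == "+" else "5'"
    return "5'" if strand == "+" else "3'"


def classify_biotype(
    lncrna: LncRNA, annotation: Annotation, window: int = 5000
) -> BiotypeAssignment:
    gene_id, distance, relation = find_nearest_gene(lncrna, annotation, window)
    if gene_id is None:
        return BiotypeAssignment(lncrna.id, None, -1, "distant")
    gene = annotation[gene_id]
    same = gene.strand == lncrna.strand
    if relation == "overlap":
        label = "sense_genic" if same else "antisense_genic"
        return BiotypeAssignment(lncrna.id, gene_id, 0, label)
    if same:
        return BiotypeAssignment(lncrna.id, gene_id, distance, "sense_intergenic")
    # opposite strand, non-overlapping: inspect the two gap-adjacent ends
    gene_is_left = relation == "left"  # gene left of lncRNA -> gene faces gap on its right
    gene_end = _gap_adjacent_end(gene.strand, feature_is_left=gene_is_left)
    lnc_end = _gap_adjacent_end(lncrna.strand, feature_is_left=not gene_is_left)
    if gene_end == "5'" and lnc_end == "5'":
        return BiotypeAssignment(lncrna.id, gene_id, distance, "antisense_intergenic_divergent")
    if gene_end == "3'" and lnc_end == "3'":
        return BiotypeAssignment(lncrna.id, gene_id, distance, "antisense_intergenic_convergent")
    label = (
        "antisense_intergenic_divergent" if lnc_end == "5'"
        else "antisense_intergenic_convergent"
    )
    return BiotypeAssignment(lncrna.id, gene_id, distance, label, mixed_ends=True)


def classify_all(
    lncrnas: list[LncRNA], annotation: Annotation, window: int = 5000
) -> list[BiotypeAssignment]:
    return [classify_biotype(l, annotation, window) for l in lncrnas]


def summarize_biotypes(assignments: list[BiotypeAssignment]) -> pd.DataFrame:
    """Counts and percentages (1 dp) per label, plus a combined sense line."""
    total = len(assignments)
    counts = {label: 0 for label in LABELS}
    for a in assignments:
        counts[a.label] += 1
    rows = []
    for label in LABELS:
        rows.append((label, counts[label],
                     round_half_up(100.0 * counts[label] / total, 1) if total else 0.0))
    sense = counts["sense_genic"] + counts["sense_intergenic"]
    rows.append(("sense_combined", sense,
                 round_half_up(100.0 * sense / total, 1) if total else 0.0))
    return pd.DataFrame(rows, columns=["label", "count", "percent"]).set_index("label")


def pair_expression_correlation(
    assignments: list[BiotypeAssignment], normalized: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r between each lncRNA and its paired gene across samples.

    Pairs where either member is missing from the matrix or has zero
    variance are skipped.  Returns one row per retained pair with the
    biotype label carried along for per-biotype summaries.
    """
    rows = []
    for a in assignments:
        if a.gene_id is None:
            continue
        if a.lncrna_id not in normalized.index or a.gene_id not in normalized.index:
            continue
        x = normalized.loc[a.lncrna_id].to_numpy(dtype=float)
        y = normalized.loc[a.gene_id].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        r = float(stats.pearsonr(x, y).statistic)
        rows.append((a.lncrna_id, a.gene_id, a.label, r, len(x)))
    return pd.DataFrame(
        rows, columns=["lncrna_id", "gene_id", "label", "pearson_r", "n_samples"]
    )
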