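"""Intrinsic coding-potential scoring.

Two deterministic voters decide whether a transcript is protein-coding:

1. an ORF rule — longest forward-frame open reading frame (ATG..stop, or
   ATG to the transcript end if no stop follows) must be shorter than
   ``min_orf_codons`` codons AND cover less than ``max_orf_fraction`` of the
   transcript; and
2. the Fickett TESTCODE statistic, computed from positional nucleotide bias
   and base composition via the published lookup tables; scores below
   ``fickett_threshold`` indicate non-coding sequence.

A transcript is called non-coding only when BOTH voters agree.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._util import check_alphabet

STOP_CODONS = {"TAA", "TAG", "TGA"}

# Fickett TESTCODE lookup tables: probability of coding given the position
# parameter (max/min frame asymmetry) or the content parameter (base
# fraction), per base, with the corresponding decision thresholds.
_POSITION_PROB = {
    "A": (0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22),
    "C": (0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23),
    "G": (0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08),
    "T": (0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09),
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_THRESHOLDS = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)

_CONTENT_PROB = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.61, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_THRESHOLDS = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)


@dataclass(frozen=True)
class CodingPotential:
    label: str  # "coding" | "noncoding"
    orf_codons: int
    orf_fraction: float
    fickett: float

    @property
    def is_noncoding(self) -> bool:
        return self.label == "noncoding"


def longest_orf(sequence: str) -> tuple[int, int]:
    """Longest ORF over the three forward frames.

    Returns (codons, nucleotides).  An ORF runs from ATG to the first
    in-frame stop (stop included in the length) or to the last complete
    codon of the frame if no stop occurs.
    """
    best = 0
    n = len(sequence)
    for frame in range(3):
        open_from: int | None = None
        for i in range(frame, n - 2, 3):
            codon = sequence[i : i + 3]
            if open_from is None:
                if codon == "ATG":
                    open_from = i
            elif codon in STOP_CODONS:
                best = max(best, (i + 3 - open_from) // 3)
                open_from = None
        if open_from is not None:  # runs to the end of the frame
            last_full = frame + ((n - frame) // 3) * 3
            best = max(best, (last_full - open_from) // 3)
    return best, best * 3


def _lookup(value: float, thresholds, probs) -> float:
    for t, p in zip(thresholds, probs):
        if value >= t:
            return p
    return probs[-1]


def fickett_score(sequence: str) -> float:
    """Fickett TESTCODE statistic of a nucleotide sequence (N ignored)."""
    seq = sequence.upper().replace("N", "")
    if not seq:
        return 0.0
    score = 0.0
    total = len(seq)
    for base in "ACGT":
        counts = [seq[f::3].count(base) for f in range(3)]
        position = max(counts) / (min(counts) + 1)
        content = seq.count(base) / total
        score += _lookup(position, _POSITION_THRESHOLDS, _POSITION_PROB[base]) * _POSITION_WEIGHT[base]
        score += _lookup(content, _CONTENT_THRESHOLDS, _CONTENT_PROB[base]) * _CONTENT_WEIGHT[base]
    return score


def score_coding_potential(
    sequence: str,
    min_orf_codons: int = 100,
    max_orf_fraction: float = 0.5,
    fickett_threshold: float = 0.95,
) -> CodingPotential:
    """Consensus coding-potential call: non-coding only if all voters agree."""
    seq = sequence.upper()
    check_alphabet(seq)
    codons, orf_nt = longest_orf(seq)
    orf_fraction = orf_nt / len(seq) if seq else 0.0
    fickett = fickett_score(seq)
    orf_noncoding = codons < min_orf_codons and orf_fraction < max_orf_fraction
    fickett_noncoding = fickett < fickett_threshold
    label = "noncoding" if (orf_noncoding and fickett_noncoding) else "coding"
    return CodingPotential(label, codons, orf_fraction, fickett)
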