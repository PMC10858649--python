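"""Exhaustive triplex-search oracle: direct enumeration of every window.

Independent of the package's seed-indexed scanner: walks every (TFO
position, TTS position) start on every strand/motif/orientation, extends
one base at a time, and applies the hit definition literally.  Used to
verify the production scanner on small inputs.
"""

from dinolnc.genome_io import PromoterRegion
from dinolnc.triplex import (
    MOTIF_ORDER,
    MOTIF_ORIENTATIONS,
    MOTIF_PAIRS,
    TriplexHit,
    TriplexParams,
    mask_low_complexity,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def oracle_hits(
    lncrna_id: str,
    lncrna_seq: str,
    promoter: PromoterRegion,
    params: TriplexParams,
) -> list[TriplexHit]:
    tfo = lncrna_seq.upper().replace("U", "T")
    prom = promoter.sequence.upper()
    if params.repeat_filter:
        tfo = mask_low_complexity(tfo, params.min_repeat_len, params.max_repeat_period)
        prom = mask_low_complexity(prom, params.min_repeat_len, params.max_repeat_period)

    l = params.min_len
    e = params.max_error_rate
    mc = params.max_consecutive_errors
    gmin = params.min_guanine_rate
    best: dict[tuple, TriplexHit] = {}

    for tts_strand in ("+", "-"):
        tts = prom if tts_strand == "+" else _revcomp(prom)
        n2 = len(tts)
        for motif in params.motifs:
            pairs = set(MOTIF_PAIRS[motif])
            for orientation in MOTIF_ORIENTATIONS[motif]:
                q = tfo if orientation == "parallel" else tfo[::-1]
                n1 = len(q)
                windows = []
                for i in range(n1):
                    for j in range(n2):
                        if (q[i], tts[j]) not in pairs:
                            continue  # hits start on a paired position
                        mm = 0
                        g = 0
                        run = 0
                        L = 0
                        while i + L < n1 and j + L < n2:
                            paired = (q[i + L], tts[j + L]) in pairs
                            if paired:
                                run = 0
                            else:
                                mm += 1
                                run += 1
                                if run > mc:
                                    break
                            if tts[j + L] == "G":
                                g += 1
                            L += 1
                            if (
                                L >= l
                                and paired
                                and mm <= e * L + 1e-12
                                and g >= gmin * L - 1e-12
                            ):
                                windows.append((i, j, L, mm))
                # maximality: drop windows contained in a longer valid window
                # on the same diagonal
                maximal = []
                for (i, j, L, mm) in windows:
                    contained = any(
                        j2 - i2 == j - i and i2 <= i and i2 + L2 >= i + L
                        and (i2, L2) != (i, L)
                        for (i2, j2, L2, _) in windows
                    )
                    if not contained:
                        maximal.append((i, j, L, mm))
                for (i, j, L, mm) in maximal:
                    tfo_off = i if orientation == "parallel" else n1 - (i + L)
                    tts_off = j if tts_strand == "+" else n2 - (j + L)
                    key = (tfo_off, tts_off, L, tts_strand)
                    cand = TriplexHit(
                        lncrna_id, promoter.gene_id, tfo_off, tts_off, L, mm,
                        motif, orientation, tts_strand,
                    )
                    prev = best.get(key)
                    rank = (mm, MOTIF_ORDER.index(motif),
                            orientation != "parallel")
                    prev_rank = None if prev is None else (
                        prev.mismatches, MOTIF_ORDER.index(prev.motif),
                        prev.orientation != "parallel")
                    if prev is None or rank < prev_rank:
                        best[key] = cand
    return sorted(
        best.values(),
        key=lambda h: (h.lncrna_id, h.gene_id, h.tts_offset, h.tfo_offset,
                       h.length, h.tts_strand, h.orientation),
    )


def hit_tuple(h: TriplexHit) -> tuple:
    return (h.lncrna_id, h.gene_id, h.tfo_offset, h.tts_offset, h.length,
            h.mismatches, h.motif, h.orientation, h.tts_strand)
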