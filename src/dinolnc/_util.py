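"""Small shared helpers: rounding, sequences, warnings."""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_ALPHABET = frozenset("ACGTN")


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at `ndigits` decimals.

    Python's built-in round() is banker's rounding; printed summary tables
    use the conventional half-away-from-zero rule instead (0.125 -> 0.13).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def check_alphabet(seq: str, context: str = "sequence") -> None:
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise ValueError(f"{context} contains invalid characters: {sorted(bad)}")


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
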