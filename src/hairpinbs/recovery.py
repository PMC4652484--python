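"""Original-sequence recovery from hairpin bisulfite mate pairs.

Because the two mates of a hairpin pair read the two strands of the same
duplex, the pre-bisulfite sequence is recoverable position by position once
both mates are placed in Watson orientation:

=============  ==============  ==========================================
(T-read, A-read)  recovered     interpretation
=============  ==============  ==========================================
equal bases     that base      no conversion visible at this position
(T, C)          C              unmethylated Watson C (converted on T-read)
(G, A)          G              unmethylated Crick C (converted, seen as A)
anything else   error          PCR or sequencing error
=============  ==============  ==========================================

Matching (C, C) and (G, G) positions additionally reveal methylated Watson
and Crick cytosines, so recovery doubles as a double-strand methylation
caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .simulate import CRICK, WATSON, HairpinReadPair, revcomp

__all__ = [
    "MATCH",
    "BISULFITE_C",
    "BISULFITE_G",
    "ERROR",
    "MethCall",
    "RecoveredRead",
    "orient_pair",
    "classify_base_pair",
    "classify_positions",
    "recover",
    "error_offsets",
    "filter_exact",
    "mismatch_window_split",
]

MATCH = "match"
BISULFITE_C = "bisulfite_C"
BISULFITE_G = "bisulfite_G"
ERROR = "error"


@dataclass(frozen=True)
class MethCall:
    """One methylation call at a recovered-read offset."""

    offset: int
    strand: str  # watson or crick
    methylated: bool


@dataclass(frozen=True)
class RecoveredRead:
    pair_id: str
    sequence: str
    error_positions: tuple[int, ...]
    meth_calls: tuple[MethCall, ...]


def orient_pair(pair: HairpinReadPair, swap_mates: bool = False) -> tuple[str, str]:
    """Return (t_seq, a_seq) both in Watson orientation, truncated to the
    shorter mate from the shared 5' anchor.

    The A-read arrives reverse-complemented (delivered orientation); it is
    flipped back here.  ``swap_mates`` handles input with mislabeled mates.
    """
    t, a = pair.t_read, pair.a_read
    if swap_mates:
        t, a = a, t
    if not t or not a:
        raise ValueError("cannot orient a pair with an empty mate")
    a = revcomp(a)
    n = min(len(t), len(a))
    return t[:n], a[:n]


def classify_base_pair(t_base: str, a_base: str) -> str:
    """Rule table for one (T-read, A-read) base pair in Watson orientation."""
    if t_base == a_base:
        return MATCH
    if (t_base, a_base) == ("T", "C"):
        return BISULFITE_C
    if (t_base, a_base) == ("G", "A"):
        return BISULFITE_G
    return ERROR


def classify_positions(t_seq: str, a_seq: str) -> list[str]:
    """Per-offset labels over two Watson-oriented mates of equal length."""
    if len(t_seq) != len(a_seq):
        raise ValueError(f"oriented mates differ in length: {len(t_seq)} vs {len(a_seq)}")
    return [classify_base_pair(t, a) for t, a in zip(t_seq, a_seq)]


def recover(
    pair: HairpinReadPair, error_base: str = "N", swap_mates: bool = False
) -> RecoveredRead:
    """Reconstruct the original duplex sequence from a hairpin pair.

    Error positions are written as ``error_base`` ('N' by default, keeping
    downstream mapping honest; 't' takes the T-read base instead).
    Methylation calls: (C,C) -> methylated Watson C, (T,C) -> unmethylated
    Watson C, (G,G) -> methylated Crick C, (G,A) -> unmethylated Crick C.
    """
    if error_base not in ("N", "t"):
        raise ValueError("error_base must be 'N' or 't'")
    t_seq, a_seq = orient_pair(pair, swap_mates=swap_mates)
    out: list[str] = []
    errors: list[int] = []
    calls: list[MethCall] = []
    for i, (t, a) in enumerate(zip(t_seq, a_seq)):
        label = classify_base_pair(t, a)
        if label == MATCH:
            out.append(t)
            if t == "C":
                calls.append(MethCall(i, WATSON, True))
            elif t == "G":
                calls.append(MethCall(i, CRICK, True))
        elif label == BISULFITE_C:
            out.append("C")
            calls.append(MethCall(i, WATSON, False))
        elif label == BISULFITE_G:
            out.append("G")
            calls.append(MethCall(i, CRICK, False))
        else:
            out.append("N" if error_base == "N" else t)
            errors.append(i)
    return RecoveredRead(
        pair_id=pair.pair_id,
        sequence="".join(out),
        error_positions=tuple(errors),
        meth_calls=tuple(calls),
    )


def error_offsets(pair: HairpinReadPair, swap_mates: bool = False) -> tuple[int, ...]:
    """Offsets (Watson orientation) labeled as PCR/sequencing errors."""
    t_seq, a_seq = orient_pair(pair, swap_mates=swap_mates)
    return tuple(
        i for i, (t, a) in enumerate(zip(t_seq, a_seq)) if classify_base_pair(t, a) == ERROR
    )


def filter_exact(pairs: Iterable[HairpinReadPair]) -> list[HairpinReadPair]:
    """Pairs whose mates align exactly: no position is labeled an error."""
    return [p for p in pairs if not error_offsets(p)]


def mismatch_window_split(
    pairs: Sequence[HairpinReadPair], k: int, boundary: int = 25
) -> tuple[list[HairpinReadPair], list[HairpinReadPair]]:
    """Split pairs with exactly k inter-mate errors by error location.

    Returns (left_set, right_set): pairs whose k errors all fall at offsets
    < ``boundary`` (the 5' seed-region side) vs all at offsets >= boundary.
    Pairs with errors on both sides belong to neither.  k=0 pairs have no
    side: both returned sets are the exact pairs (report once).
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        exact = filter_exact(pairs)
        return exact, exact
    left: list[HairpinReadPair] = []
    right: list[HairpinReadPair] = []
    for p in pairs:
        errs = error_offsets(p)
        if len(errs) != k:
            continue
        if all(e < boundary for e in errs):
            left.append(p)
        elif all(e >= boundary for e in errs):
            right.append(p)
    return left, right
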