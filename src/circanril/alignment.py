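"""Global pairwise DNA alignment with affine gap penalties (Gotoh DP).

Used to decide whether two intronic repeats are (approximate) reverse
complements of one another: a repeat pair is called inverted when the global
alignment score of one repeat against the reverse complement of the other
clears a configurable minimum score.

Scoring model: a match scores ``match`` per base, a mismatch ``mismatch``
(``N`` against anything counts as a mismatch), and a gap of length ``L``
costs ``gap_open + L * gap_extend`` (both penalties are non-positive).  End
gaps are penalized like any other gap — the alignment is fully global.

The default scale (match +2, mismatch -6, gap open -10, gap extend -4) keeps
mismatches and gaps expensive relative to matches, in the spirit of
quality-weighted DNA alignment defaults; with the default acceptance
threshold of -200 a 300 bp repeat pair is accepted up to roughly one third
divergence, while unrelated random sequences of that length score far below
the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["AlignmentScoring", "align_global", "reverse_complement"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

NEG_INF = -1e30


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentScoring:
    """Scores per base (match/mismatch/gap_extend) and per gap (gap_open);
    ``min_score`` is the acceptance threshold for inverted-repeat calls."""

    match: float = 2.0
    mismatch: float = -6.0
    gap_open: float = -10.0
    gap_extend: float = -4.0
    min_score: float = -200.0

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise AlignmentError("gap penalties must be <= 0")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (incl. N) -> 4, which never matches."""
    table = np.full(256, 4, dtype=np.int8)
    for i, base in enumerate("ACGT"):
        table[ord(base)] = i
        table[ord(base.lower())] = i
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return table[arr]


@njit(cache=True)
def _gotoh(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = len(a), len(b)
    # M: a[i] aligned to b[j]; X: gap in b (a[i] unmatched); Y: gap in a.
    M = np.full(m + 1, NEG_INF)
    X = np.full(m + 1, NEG_INF)
    Y = np.full(m + 1, NEG_INF)
    M[0] = 0.0
    for j in range(1, m + 1):
        Y[j] = gap_open + j * gap_extend
    for i in range(1, n + 1):
        prev_M = M.copy()
        prev_X = X.copy()
        prev_Y = Y.copy()
        M[0] = NEG_INF
        Y[0] = NEG_INF
        X[0] = gap_open + i * gap_extend
        for j in range(1, m + 1):
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != 4) else mismatch
            best_prev = max(prev_M[j - 1], prev_X[j - 1], prev_Y[j - 1])
            M[j] = best_prev + s
            X[j] = max(
                prev_M[j] + gap_open + gap_extend,
                prev_X[j] + gap_extend,
                prev_Y[j] + gap_open + gap_extend,
            )
            Y[j] = max(
                M[j - 1] + gap_open + gap_extend,
                Y[j - 1] + gap_extend,
                X[j - 1] + gap_open + gap_extend,
            )
    return max(M[m], X[m], Y[m])


def align_global(a: str, b: str, scoring: AlignmentScoring | None = None) -> float:
    """Optimal global affine-gap alignment score of two DNA sequences.

    Deterministic dynamic programming over the three-state Gotoh recurrence;
    ``N`` (or any non-ACGT symbol) scores as a mismatch against everything.
    Raises :class:`AlignmentError` on an empty sequence.
    """
    if scoring is None:
        scoring = AlignmentScoring()
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    score = _gotoh(
        _encode(a),
        _encode(b),
        float(scoring.match),
        float(scoring.mismatch),
        float(scoring.gap_open),
        float(scoring.gap_extend),
    )
    return float(score)
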