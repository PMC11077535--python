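"""Ungapped window scoring under a standard substitution matrix.

Two fixed-length windows are compared position by position; the score is the
sum of substitution-matrix entries.  Gap characters (possible in internally
aligned families) contribute a fixed ``gap_score`` and out-of-range markers
contribute ``out_of_range_score``, which defaults to the matrix minimum so
that extreme shifts cannot win simply by sliding off the sequence end.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from .errors import HelixvoteError, ValidationError
from .families import GAP, OUT_OF_RANGE


@dataclass(frozen=True)
class ScoringScheme:
    """How a pair of equal-length windows is scored.

    ``matrix_name`` names any matrix shipped with Biopython (default
    BLOSUM62).  ``out_of_range_score`` defaults to the matrix minimum entry.
    """

    matrix_name: str = "BLOSUM62"
    out_of_range_score: float | None = None
    gap_score: float = 0.0

    @property
    def resolved_out_of_range_score(self) -> float:
        if self.out_of_range_score is not None:
            return self.out_of_range_score
        return float(np.min(np.asarray(_load_matrix(self.matrix_name))))


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    try:
        mat = substitution_matrices.load(name)
    except FileNotFoundError:
        raise ValidationError(f"unknown substitution matrix {name!r}") from None
    return mat


class EncodedScheme:
    """A scoring scheme compiled to an integer-coded lookup table.

    Characters are mapped to small integers; ``table[a, b]`` gives the score
    of aligning coded characters ``a`` and ``b``.  The gap and out-of-range
    sentinels get dedicated codes whose rows/columns hold the fixed scores
    (out-of-range takes precedence over gap).
    """

    def __init__(self, scheme: ScoringScheme):
        mat = _load_matrix(scheme.matrix_name)
        alphabet = str(mat.alphabet)
        n = len(alphabet)
        self.scheme = scheme
        self.gap_code = n
        self.oor_code = n + 1
        self.codes = np.full(128, -1, dtype=np.int16)
        for i, ch in enumerate(alphabet):
            self.codes[ord(ch)] = i
        self.codes[ord(GAP)] = self.gap_code
        self.codes[ord(OUT_OF_RANGE)] = self.oor_code
        table = np.zeros((n + 2, n + 2), dtype=np.float64)
        table[:n, :n] = np.asarray(mat)
        table[self.gap_code, :] = scheme.gap_score
        table[:, self.gap_code] = scheme.gap_score
        oor = scheme.resolved_out_of_range_score
        table[self.oor_code, :] = oor
        table[:, self.oor_code] = oor
        self.table = table

    def encode(self, window: str) -> np.ndarray:
        arr = self.codes[np.frombuffer(window.encode("ascii"), dtype=np.uint8)]
        if np.any(arr < 0):
            bad = window[int(np.argmin(arr))]
            raise ValidationError(
                f"character {bad!r} is not scorable under "
                f"{self.scheme.matrix_name}"
            )
        return arr.astype(np.intp)


@lru_cache(maxsize=8)
def encoded_scheme(scheme: ScoringScheme) -> EncodedScheme:
    return EncodedScheme(scheme)


def score_pair_at_offset(
    template_window: str, query_window: str, scheme: ScoringScheme | None = None
) -> float:
    """Score two equal-length windows: sum of per-position matrix entries.

    Out-of-range markers score ``out_of_range_score`` and gaps ``gap_score``
    regardless of the opposing character (out-of-range wins when both occur).
    """
    if scheme is None:
        scheme = ScoringScheme()
    if len(template_window) != len(query_window):
        raise HelixvoteError(
            f"window length mismatch: {len(template_window)} vs {len(query_window)}"
        )
    enc = encoded_scheme(scheme)
    t = enc.encode(template_window)
    q = enc.encode(query_window)
    return float(enc.table[t, q].sum())
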