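"""Offset voting: the multi-template helix alignment engine.

For a template family and a query family sharing one helix label, every
cross-family sequence pair is scored at every integer offset in a symmetric
range (default -25..+25).  Each pair casts one vote for its best-scoring
offset (split 1/k over k exact ties).  Voting is run twice — once sliding
the query windows, once sliding the template windows — and the
template-moved vector is re-indexed by negation onto the query-moved axis,
so a positive offset always means "the query helix moved right relative to
the template".  The per-offset mean of the two directions is the vote
profile for that (template, helix); scaled to [0, 1] it is the input to the
cross-template consensus product.

This plurality-of-pairs scheme is what makes the method robust in the
twilight zone (<~25% identity): any single pairwise comparison is noisy,
but hundreds or thousands of independent pairs voting for the same offset
give an unambiguous signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, HelixvoteError
from .families import ProfileFamily, extract_window
from .scoring import ScoringScheme, encoded_scheme


@dataclass(frozen=True)
class OffsetRange:
    """A symmetric-ish integer shift range including zero; default -25..+25."""

    min_shift: int = -25
    max_shift: int = 25

    def __post_init__(self) -> None:
        if not (self.min_shift <= 0 <= self.max_shift):
            raise ConfigurationError(
                f"offset range must contain 0: {self.min_shift}..{self.max_shift}"
            )

    @property
    def offsets(self) -> list[int]:
        return list(range(self.min_shift, self.max_shift + 1))

    def __contains__(self, shift: int) -> bool:
        return self.min_shift <= shift <= self.max_shift

    def index(self, shift: int) -> int:
        if shift not in self:
            raise ConfigurationError(f"shift {shift} outside range {self}")
        return shift - self.min_shift


def round_half_down(x: float) -> int:
    """Round to the nearest integer, halves toward negative infinity.

    Used only for displayed vote means (10332.5 prints as 10332); full
    precision is retained everywhere internally.
    """
    return math.ceil(x - 0.5)


@dataclass
class VoteTable:
    """Per-(template, query, helix) vote counts for every offset.

    ``votes_query_moved[i]`` is the number of pair-votes for offset
    ``offsets[i]`` when the query windows were slid; ``votes_template_moved``
    is the template-moved direction already re-indexed onto the same axis.
    Each direction sums to ``n_pairs``.
    """

    template_id: str
    query_id: str
    helix_id: str
    offsets: list[int]
    votes_query_moved: np.ndarray
    votes_template_moved: np.ndarray
    n_pairs: int
    mean_votes: np.ndarray = field(init=False)
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        vq = np.asarray(self.votes_query_moved, dtype=float)
        vt = np.asarray(self.votes_template_moved, dtype=float)
        if not (len(self.offsets) == vq.size == vt.size):
            raise HelixvoteError("vote vectors and offset axis differ in length")
        if (vq < 0).any() or (vt < 0).any():
            raise HelixvoteError("vote counts must be non-negative")
        self.votes_query_moved = vq
        self.votes_template_moved = vt
        self.mean_votes = (vq + vt) / 2.0
        self.normalized = normalize_votes(self.mean_votes)

    @property
    def winning_offset(self) -> int:
        return self.offsets[int(np.argmax(self.mean_votes))]

    def displayed_mean(self, offset: int) -> int:
        """The vote mean at an offset, rounded half-down for reporting."""
        return round_half_down(float(self.mean_votes[self.offsets.index(offset)]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "template_id": self.template_id,
                "query_id": self.query_id,
                "helix_id": self.helix_id,
                "offset": self.offsets,
                "votes_query_moved": self.votes_query_moved,
                "votes_template_moved": self.votes_template_moved,
                "mean": self.mean_votes,
                "normalized": self.normalized,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def normalize_votes(mean_votes) -> np.ndarray:
    """Scale a non-negative vote vector to [0, 1] by its maximum.

    An all-zero vector (possible for degenerate empty-overlap windows) maps
    to all zeros rather than raising.
    """
    v = np.asarray(mean_votes, dtype=float)
    if (v < 0).any():
        raise HelixvoteError("vote vector has negative entries")
    top = v.max() if v.size else 0.0
    if top == 0.0:
        return np.zeros_like(v)
    return v / top


def _window_codes(
    family: ProfileFamily, helix_id: str, shifts: list[int], scheme: ScoringScheme
) -> np.ndarray:
    """Integer-coded windows, shape (n_shifts, n_records, window_len)."""
    window = family.window(helix_id)
    enc = encoded_scheme(scheme)
    out = np.empty((len(shifts), len(family.records), len(window)), dtype=np.intp)
    for si, s in enumerate(shifts):
        for ri, rec in enumerate(family.records):
            out[si, ri] = enc.encode(extract_window(rec, window, s))
    return out


def _pair_scores(
    moved: np.ndarray, fixed: np.ndarray, scheme: ScoringScheme
) -> np.ndarray:
    """Scores of every (fixed-record, moved-record) pair at every shift.

    ``moved`` has shape (n_shifts, n_moved, L); ``fixed`` (n_fixed, L).
    Returns (n_fixed, n_moved, n_shifts).
    """
    table = encoded_scheme(scheme).table
    n_shifts, n_moved, L = moved.shape
    n_fixed = fixed.shape[0]
    scores = np.empty((n_fixed, n_moved, n_shifts), dtype=np.float64)
    for si in range(n_shifts):
        # (n_fixed, 1, L) x (1, n_moved, L) -> per-position table lookup
        scores[:, :, si] = table[fixed[:, None, :], moved[None, si, :, :]].sum(axis=2)
    return scores


def _votes_from_scores(scores: np.ndarray) -> np.ndarray:
    """Argmax votes with exact 1/k tie-splitting; sums to the pair count."""
    best = scores.max(axis=2, keepdims=True)
    ties = scores == best
    k = ties.sum(axis=2, keepdims=True)
    return (ties / k).sum(axis=(0, 1))


def cast_votes(
    template: ProfileFamily,
    query: ProfileFamily,
    helix_id: str,
    offset_range: OffsetRange | None = None,
    direction: str = "query_moved",
    scheme: ScoringScheme | None = None,
) -> tuple[np.ndarray, int]:
    """Vote vector for one direction of sliding, plus the pair count.

    For every ordered cross-family pair the window score is computed at each
    shift in ``offset_range``; the best shift receives one vote, split
    equally over exact ties.  ``direction`` selects which family's windows
    are slid; the returned vector is indexed by that family's shift (no
    re-indexing — :func:`tally` puts both directions on a common axis).
    """
    if offset_range is None:
        offset_range = OffsetRange()
    if scheme is None:
        scheme = ScoringScheme()
    if direction not in ("query_moved", "template_moved"):
        raise ConfigurationError(f"unknown direction {direction!r}")
    tw, qw = template.window(helix_id), query.window(helix_id)
    if len(tw) != len(qw):
        raise ConfigurationError(
            f"helix {helix_id}: window lengths differ between "
            f"{template.family_id!r} ({len(tw)}) and {query.family_id!r} ({len(qw)})"
        )
    shifts = offset_range.offsets
    if direction == "query_moved":
        moved = _window_codes(query, helix_id, shifts, scheme)
        fixed = _window_codes(template, helix_id, [0], scheme)[0]
    else:
        moved = _window_codes(template, helix_id, shifts, scheme)
        fixed = _window_codes(query, helix_id, [0], scheme)[0]
    scores = _pair_scores(moved, fixed, scheme)
    votes = _votes_from_scores(scores)
    return votes, len(template.records) * len(query.records)


def tally(
    template: ProfileFamily,
    query: ProfileFamily,
    helix_id: str,
    offset_range: OffsetRange | None = None,
    scheme: ScoringScheme | None = None,
) -> VoteTable:
    """Run both sliding directions and combine them into a :class:`VoteTable`.

    Template-moved votes are re-indexed by negation (sliding the template
    right by ``t`` is the same alignment as sliding the query left by ``t``)
    so both vectors share the query-moved axis: positive offset = query helix
    moved right.  The per-offset mean of the two directions and its [0, 1]
    scaling are computed on that common axis.
    """
    if offset_range is None:
        offset_range = OffsetRange()
    vq, n_pairs = cast_votes(template, query, helix_id, offset_range, "query_moved", scheme)
    vt_raw, _ = cast_votes(template, query, helix_id, offset_range, "template_moved", scheme)
    # re-index template shifts t onto query axis at offset -t
    vt = vt_raw[::-1].copy()
    if offset_range.min_shift != -offset_range.max_shift:
        # asymmetric range: map each template shift individually
        vt = np.zeros_like(vt_raw)
        for i, t in enumerate(offset_range.offsets):
            if -t in offset_range:
                vt[offset_range.index(-t)] += vt_raw[i]
    return VoteTable(
        template_id=template.family_id,
        query_id=query.family_id,
        helix_id=helix_id,
        offsets=offset_range.offsets,
        votes_query_moved=vq,
        votes_template_moved=vt,
        n_pairs=n_pairs,
    )


def tally_all(
    templates: list[ProfileFamily],
    query: ProfileFamily,
    helices: list[str],
    offset_range: OffsetRange | None = None,
    scheme: ScoringScheme | None = None,
) -> dict[str, dict[str, VoteTable]]:
    """Tally every (template, voted helix) combination.

    Returns ``{helix_id: {template_id: VoteTable}}``.
    """
    out: dict[str, dict[str, VoteTable]] = {}
    for helix_id in helices:
        out[helix_id] = {
            t.family_id: tally(t, query, helix_id, offset_range, scheme)
            for t in templates
        }
    return out
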