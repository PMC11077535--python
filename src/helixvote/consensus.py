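"""Cross-template consensus and alignment-derived summary statistics.

A single template family gives a noisy vote profile; multiplying the
[0, 1]-scaled profiles of several template families (alpha-Hb, beta-Hb,
cytoglobin, neuroglobin, myoglobin...) suppresses offsets that any template
disfavors and sharpens the offset all templates agree on.  The winning
offset per helix then feeds percent-identity summaries and the rendering of
the circularly permuted alignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .families import GAP, OUT_OF_RANGE, ProfileFamily, extract_window
from .voting import VoteTable

logger = logging.getLogger(__name__)


@dataclass
class ConsensusResult:
    """Product-of-votes consensus for one helix across templates."""

    helix_id: str
    templates_used: list[str]
    offsets: list[int]
    product_vector: np.ndarray
    winning_offset: int = field(init=False)
    runner_up_offset: int = field(init=False)
    dominance_ratio: float = field(init=False)

    def __post_init__(self) -> None:
        self.product_vector = np.asarray(self.product_vector, dtype=float)
        order = _tie_break_order(self.offsets, self.product_vector)
        self.winning_offset = self.offsets[order[0]]
        self.runner_up_offset = self.offsets[order[1]] if len(order) > 1 else self.winning_offset
        top = self.product_vector[order[0]]
        second = self.product_vector[order[1]] if len(order) > 1 else 0.0
        self.dominance_ratio = float("inf") if second == 0.0 else float(top / second)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "helix_id": self.helix_id,
                "offset": self.offsets,
                "product": self.product_vector,
                "winner": [o == self.winning_offset for o in self.offsets],
            }
        )


def _tie_break_order(offsets, values) -> list[int]:
    """Indices sorted by descending value; ties toward smallest |offset|,
    then the negative offset first."""
    return sorted(
        range(len(offsets)),
        key=lambda i: (-values[i], abs(offsets[i]), offsets[i]),
    )


def consensus(tables: list[VoteTable]) -> ConsensusResult:
    """Entrywise product of the normalized vote vectors of several templates.

    Templates whose vote vector is all zero (degenerate windows) are dropped
    with a warning rather than zeroing the whole consensus.
    """
    if not tables:
        raise ConfigurationError("consensus requires at least one vote table")
    helix = tables[0].helix_id
    offsets = tables[0].offsets
    for t in tables[1:]:
        if t.helix_id != helix:
            raise ConfigurationError(
                f"mixed helices in consensus: {helix!r} vs {t.helix_id!r}"
            )
        if t.offsets != offsets:
            raise ConfigurationError("vote tables have mismatched offset axes")
    used, dropped = [], []
    product = np.ones(len(offsets), dtype=float)
    for t in tables:
        if t.normalized.max() == 0.0:
            dropped.append(t.template_id)
            continue
        product *= t.normalized
        used.append(t.template_id)
    if dropped:
        logger.warning(
            "dropped zero-vote templates from consensus for helix %s: %s",
            helix, ", ".join(dropped),
        )
        warnings.warn(
            f"helix {helix}: zero-vote templates dropped from consensus: {dropped}",
            stacklevel=2,
        )
    if not used:
        raise ConfigurationError(
            f"helix {helix}: every template produced zero votes; no consensus"
        )
    return ConsensusResult(
        helix_id=helix, templates_used=used, offsets=list(offsets), product_vector=product
    )


def percent_identity(
    template: ProfileFamily,
    query: ProfileFamily,
    helix_id: str,
    offset: int = 0,
) -> float:
    """Mean percent identity over all cross-family pairs at a fixed offset.

    Each pair contributes (identical in-range positions) / (window length);
    out-of-range and gap positions count as non-identical.  Identity in the
    twilight zone is low even at the correct offset — the headline helix-A
    alignments run at 15-21% — which is exactly why voting, not identity,
    drives the alignment.
    """
    tw, qw = template.window(helix_id), query.window(helix_id)
    if len(tw) != len(qw):
        raise ConfigurationError(
            f"helix {helix_id}: window lengths differ between families"
        )
    t_wins = [extract_window(r, tw, 0) for r in template.records]
    q_wins = [extract_window(r, qw, offset) for r in query.records]
    length = len(tw)
    total = 0.0
    for t in t_wins:
        for q in q_wins:
            ident = sum(
                1
                for a, b in zip(t, q)
                if a == b and a not in (GAP, OUT_OF_RANGE)
            )
            total += ident / length
    return 100.0 * total / (len(t_wins) * len(q_wins))


def mean_helix_identity(per_helix: dict[str, float]) -> float:
    """Unweighted arithmetic mean of per-helix percent identities."""
    if not per_helix:
        raise ValidationError("mean_helix_identity requires at least one helix")
    return float(np.mean(list(per_helix.values())))


@dataclass(frozen=True)
class ColumnFrequencies:
    """Residue composition of one alignment column."""

    column: int
    fractions: dict[str, float]  # over non-gap residues; sums to 1 when any
    gap_fraction: float
    n_sequences: int


def column_frequencies(family: ProfileFamily, column: int) -> ColumnFrequencies:
    """Residue frequencies at a 1-based column of an aligned family.

    Fractions are taken over non-gap residues (so a column that is 41/50 Tyr
    with no gaps reports Tyr 0.82); the gap fraction is reported separately.
    """
    if not family.is_aligned:
        raise ConfigurationError(
            f"family {family.family_id!r} is not aligned; columns are undefined"
        )
    if not (1 <= column <= family.alignment_width):
        raise ValidationError(
            f"column {column} outside alignment width {family.alignment_width}"
        )
    chars = [r.residues[column - 1] for r in family.records]
    n = len(chars)
    gaps = chars.count(GAP)
    non_gap = n - gaps
    fractions: dict[str, float] = {}
    if non_gap:
        for ch in sorted(set(chars) - {GAP}):
            fractions[ch] = chars.count(ch) / non_gap
    return ColumnFrequencies(
        column=column, fractions=fractions, gap_fraction=gaps / n, n_sequences=n
    )
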