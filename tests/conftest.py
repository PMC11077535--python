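"""Shared fixtures and independent oracles for the helixvote test suite."""

from __future__ import annotations

from fractions import Fraction

import pytest

from helixvote import (
    HelixWindow,
    OffsetRange,
    ProfileFamily,
    ScoringScheme,
    SequenceRecord,
    SyntheticSpec,
    default_windows,
    extract_window,
    generate_family,
    random_seed_sequence,
    score_pair_at_offset,
)
from helixvote.synthetic import DEFAULT_CHAIN_LENGTH


def naive_cast_votes(
    template: ProfileFamily,
    query: ProfileFamily,
    helix_id: str,
    offset_range: OffsetRange,
    direction: str,
    scheme: ScoringScheme | None = None,
) -> dict[int, Fraction]:
    """Brute-force reference: a plain triple loop with exact tie fractions.

    Deliberately shares no code path with voting._pair_scores: windows are
    re-extracted per (pair, shift) and scored one at a time.
    """
    scheme = scheme or ScoringScheme()
    tw, qw = template.window(helix_id), query.window(helix_id)
    votes = {s: Fraction(0) for s in offset_range.offsets}
    for t_rec in template.records:
        for q_rec in query.records:
            scores = []
            for s in offset_range.offsets:
                if direction == "query_moved":
                    a = extract_window(t_rec, tw, 0)
                    b = extract_window(q_rec, qw, s)
                else:
                    a = extract_window(t_rec, tw, s)
                    b = extract_window(q_rec, qw, 0)
                scores.append(score_pair_at_offset(a, b, scheme))
            best = max(scores)
            tied = [s for s, sc in zip(offset_range.offsets, scores) if sc == best]
            for s in tied:
                votes[s] += Fraction(1, len(tied))
    return votes


def make_family(
    family_id: str,
    n: int = 10,
    identity: float = 0.4,
    rng_seed: int = 0,
    seed_sequence: str | None = None,
) -> ProfileFamily:
    """A synthetic family with the default six-helix window layout."""
    if seed_sequence is None:
        seed_sequence = random_seed_sequence(DEFAULT_CHAIN_LENGTH, rng_seed + 101)
    spec = SyntheticSpec(
        seed_sequence=seed_sequence,
        n_sequences=n,
        target_identity=identity,
        rng_seed=rng_seed,
        family_id=family_id,
    )
    return generate_family(spec, windows=default_windows(family_id))


def make_homologous_pair(
    n: int = 10,
    identity: float = 0.4,
    rng_seed: int = 0,
    length: int = DEFAULT_CHAIN_LENGTH,
) -> tuple[ProfileFamily, ProfileFamily]:
    """Template and query families descended from one common seed sequence."""
    seed = random_seed_sequence(length, rng_seed + 7)
    t = generate_family(
        SyntheticSpec(seed_sequence=seed, n_sequences=n, target_identity=identity,
                      rng_seed=rng_seed * 2 + 1, family_id="tmpl"),
        windows=default_windows("tmpl"),
    )
    q = generate_family(
        SyntheticSpec(seed_sequence=seed, n_sequences=n, target_identity=identity,
                      rng_seed=rng_seed * 2 + 2, family_id="qry"),
        windows=default_windows("qry"),
    )
    return t, q


def tiny_family(family_id: str, residues: list[str], start: int = 2, end: int = 5,
                helix_id: str = "A") -> ProfileFamily:
    """A hand-built family with one helix window over explicit sequences."""
    return ProfileFamily(
        family_id=family_id,
        records=[SequenceRecord(f"{family_id}{i}", r) for i, r in enumerate(residues)],
        windows={helix_id: HelixWindow(helix_id, family_id, start, end,
                                       coordinate_space="sequence")},
    )


@pytest.fixture
def small_pair():
    return make_homologous_pair(n=5, identity=0.5, rng_seed=3)
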