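"""Consensus products, percent identity, column frequencies."""

import numpy as np
import pytest

from helixvote import (
    ConfigurationError,
    OffsetRange,
    ValidationError,
    VoteTable,
    column_frequencies,
    consensus,
    mean_helix_identity,
    percent_identity,
    plant_offset,
    tally,
)
from helixvote.families import ProfileFamily, SequenceRecord

from conftest import make_homologous_pair, tiny_family


def _table(template_id, normalized_target, offsets=(0, 4)):
    """Build a VoteTable whose normalized vector equals the given values."""
    v = np.asarray(normalized_target, dtype=float)
    return VoteTable(template_id, "q", "A", list(offsets), v, v, n_pairs=1)


class TestConsensus:
    def test_product_of_two_profiles(self):
        r = consensus([_table("t1", [1.0, 0.5]), _table("t2", [1.0, 0.2])])
        np.testing.assert_allclose(r.product_vector, [1.0, 0.1])
        assert r.winning_offset == 0
        assert r.runner_up_offset == 4
        assert r.dominance_ratio == pytest.approx(10.0)

    def test_five_templates_agreeing_on_zero(self):
        tables = [_table(f"t{i}", [1.0, 0.3 + 0.05 * i]) for i in range(5)]
        assert consensus(tables).winning_offset == 0

    def test_single_template_equals_its_normalized_vector(self):
        t = _table("only", [0.4, 1.0])
        r = consensus([t])
        np.testing.assert_allclose(r.product_vector, t.normalized)
        assert r.winning_offset == 4

    def test_product_bounded_by_factors(self):
        a, b = _table("a", [0.9, 0.7]), _table("b", [0.8, 1.0])
        r = consensus([a, b])
        assert np.all(r.product_vector <= np.minimum(a.normalized, b.normalized) + 1e-12)
        assert np.all((0 <= r.product_vector) & (r.product_vector <= 1))

    def test_tie_breaks_toward_smallest_absolute_offset_then_negative(self):
        r = consensus([_table("t", [1.0, 1.0, 1.0], offsets=(-2, 0, 2))])
        assert r.winning_offset == 0
        r = consensus([_table("t", [1.0, 0.0, 1.0], offsets=(-2, 0, 2))])
        assert r.winning_offset == -2

    def test_zero_vote_template_dropped_with_warning(self):
        live = _table("live", [1.0, 0.5])
        dead = VoteTable("dead", "q", "A", [0, 4], np.zeros(2), np.zeros(2), n_pairs=1)
        with pytest.warns(UserWarning, match="dead"):
            r = consensus([live, dead])
        assert r.templates_used == ["live"]
        np.testing.assert_allclose(r.product_vector, live.normalized)

    def test_mismatched_axes_or_empty_list_rejected(self):
        with pytest.raises(ConfigurationError):
            consensus([])
        with pytest.raises(ConfigurationError):
            consensus([_table("a", [1.0, 0.5]), _table("b", [1.0, 0.5], offsets=(0, 5))])

    def test_consensus_dominance_exceeds_single_template(self):
        """When every template prefers the planted offset, multiplying the
        profiles sharpens the winner at least as much as the best single
        template."""
        from helixvote import SyntheticSpec, default_windows, generate_family, random_seed_sequence

        improved = 0
        total = 0
        for rep in range(25):
            seed = random_seed_sequence(140, 2000 + rep)
            qry = generate_family(
                SyntheticSpec(seed_sequence=seed, n_sequences=8, target_identity=0.3,
                              rng_seed=300 + rep, family_id="qry"),
                windows=default_windows("qry"))
            qry = plant_offset(qry, "G", 3, rng_seed=rep)
            tables = []
            for k in range(5):
                t = generate_family(
                    SyntheticSpec(seed_sequence=seed, n_sequences=8, target_identity=0.3,
                                  rng_seed=5000 + 10 * rep + k, family_id=f"t{k}"),
                    windows=default_windows(f"t{k}"))
                tables.append(tally(t, qry, "G", OffsetRange(-6, 6)))
            if not all(t.winning_offset == 3 for t in tables):
                continue  # the guarantee applies when all templates agree
            total += 1
            r = consensus(tables)
            best_single = max(
                consensus([t]).dominance_ratio for t in tables
            )
            if r.dominance_ratio >= best_single:
                improved += 1
        assert total >= 15  # the planted signal is strong enough to compare
        assert improved == total


class TestPercentIdentity:
    def test_identical_single_sequence_families_score_100(self):
        fam = tiny_family("f", ["MVLSPADK"])
        assert percent_identity(fam, fam, "A", 0) == pytest.approx(100.0)

    def test_four_of_five_positions(self):
        a = tiny_family("a", ["ACDEF"], start=1, end=5)
        b = tiny_family("b", ["ACDQF"], start=1, end=5)
        assert percent_identity(a, b, "A", 0) == pytest.approx(80.0)

    def test_matches_brute_force_pair_mean(self):
        a = tiny_family("a", ["ACDEFG", "AWDEFG", "ACDEYG"], start=2, end=6)
        b = tiny_family("b", ["ACDEFG", "HCDEFH", "ACKEFG"], start=2, end=6)
        expected = 0.0
        for ra in a.records:
            for rb in b.records:
                wa, wb = ra.residues[1:6], rb.residues[1:6]
                expected += sum(x == y for x, y in zip(wa, wb)) / 5
        expected *= 100.0 / 9
        assert percent_identity(a, b, "A", 0) == pytest.approx(expected)

    def test_out_of_range_counts_as_mismatch(self):
        fam = tiny_family("f", ["MVLSPADK"])
        # offset pushes two positions past the end: at most 2/4 can match
        assert percent_identity(fam, fam, "A", 6) <= 50.0

    def test_identity_peaks_at_planted_offset(self):
        """Mean identity at the planted offset beats other offsets (trend)."""
        hits = 0
        for rep in range(20):
            tmpl, qry = make_homologous_pair(n=6, identity=0.35, rng_seed=900 + rep)
            qry = plant_offset(qry, "F", 2, rng_seed=rep)
            at_plant = percent_identity(tmpl, qry, "F", 2)
            others = [percent_identity(tmpl, qry, "F", s) for s in (-4, -2, 0, 4)]
            if at_plant >= max(others):
                hits += 1
        assert hits >= 18


class TestMeanHelixIdentity:
    def test_arithmetic_mean(self):
        assert mean_helix_identity({"A": 10.0, "B": 20.0}) == pytest.approx(15.0)

    def test_constant_map(self):
        assert mean_helix_identity({h: 17.8 for h in "ABEFGH"}) == pytest.approx(17.8)

    def test_six_helices_match_hand_mean(self):
        vals = {"A": 15.3, "B": 11.2, "E": 18.0, "F": 26.0, "G": 13.9, "H": 7.8}
        assert mean_helix_identity(vals) == pytest.approx(sum(vals.values()) / 6)

    def test_empty_map_rejected(self):
        with pytest.raises(ValidationError):
            mean_helix_identity({})


class TestColumnFrequencies:
    def _aligned(self, columns):
        recs = [
            SequenceRecord(f"s{i}", "".join(row))
            for i, row in enumerate(zip(*columns))
        ]
        return ProfileFamily("f", recs, is_aligned=True)

    def test_counts_fractions(self):
        fam = self._aligned([["Y", "Y", "F", "Y"]])
        f = column_frequencies(fam, 1)
        assert f.fractions == {"F": 0.25, "Y": 0.75}
        assert f.gap_fraction == 0.0

    def test_all_gap_column(self):
        fam = self._aligned([["-", "-", "-"], ["A", "C", "D"]])
        f = column_frequencies(fam, 1)
        assert f.fractions == {} and f.gap_fraction == 1.0

    def test_fractions_sum_to_one_over_non_gap(self):
        fam = self._aligned([["Y", "-", "F", "Y", "W"], ["A", "A", "A", "A", "A"]])
        f = column_frequencies(fam, 1)
        assert sum(f.fractions.values()) == pytest.approx(1.0)
        assert f.gap_fraction == pytest.approx(0.2)

    def test_column_out_of_range(self):
        fam = self._aligned([["Y", "Y"]])
        with pytest.raises(ValidationError):
            column_frequencies(fam, 2)

    def test_unaligned_family_rejected(self):
        fam = ProfileFamily("f", [SequenceRecord("a", "MV"), SequenceRecord("b", "MVL")])
        with pytest.raises(ConfigurationError):
            column_frequencies(fam, 1)
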