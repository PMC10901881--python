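"""ASRT stimulus structure: patterns, alternation, triplet statistics."""

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import triplet_lookup_table
from tacstrial.sequence import (
    PatternSequence,
    all_patterns,
    classify_triplet,
    generate_pattern,
    generate_session,
    triplet_probability,
)


class TestPattern:
    def test_example_pattern_is_valid(self):
        p = PatternSequence((3, 2, 4, 1))
        assert p.successor(3) == 2 and p.successor(1) == 3

    @pytest.mark.parametrize("bad", [(1, 2, 3, 3), (1, 2, 3), (0, 1, 2, 3)])
    def test_non_permutations_rejected(self, bad):
        with pytest.raises(ValueError):
            PatternSequence(bad)

    def test_generated_patterns_are_permutations(self):
        for seed in range(200):
            p = generate_pattern(seed)
            assert sorted(p.positions) == [1, 2, 3, 4]
        assert generate_pattern(7).positions == generate_pattern(7).positions

    def test_pattern_sampling_uniform_over_24_permutations(self):
        counts = {}
        n = 24_000
        for seed in range(n):
            key = generate_pattern(seed).positions
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 24
        stat, p = sps.chisquare(list(counts.values()))
        assert p > 1e-4  # uniform to within sampling error


class TestSessionProperties:
    """Structural invariants that must hold for any seed and layout."""

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n_blocks=st.integers(1, 6),
        trials_per_block=st.sampled_from([8, 16, 40, 80]),
    )
    def test_any_layout_preserves_alternation_and_annotation(
        self, seed, n_blocks, trials_per_block
    ):
        pattern = generate_pattern(seed)
        s = generate_session(
            pattern,
            n_blocks=n_blocks,
            trials_per_block=trials_per_block,
            rng_seed=seed,
        )
        assert len(s) == (n_blocks + 2) * trials_per_block
        test = s[~s["is_practice"]]
        odd = test["trial_index_in_block"] % 2 == 1
        assert (test.loc[odd, "trial_type"] == "pattern").all()
        assert (test.loc[~odd, "trial_type"] == "random").all()
        assert ((s["triplet_class"] == "undefined")
                == (s["trial_index_in_block"] <= 2)).all()
        assert not (s["is_trill"] & s["is_repetition"]).any()


class TestClassify:
    def test_pattern_transition_is_high_for_any_middle(self, pattern3241):
        for x in (1, 2, 3, 4):
            assert classify_triplet(3, x, 2, pattern3241).high

    def test_trill_and_repetition_flags(self, pattern3241):
        t = classify_triplet(1, 2, 1, pattern3241)
        assert t.trill and not t.repetition
        r = classify_triplet(3, 3, 3, pattern3241)
        assert r.repetition and not r.trill

    def test_exactly_16_high_triplets_of_64(self, pattern3241):
        n_high = sum(
            classify_triplet(e1, e2, e3, pattern3241).high
            for e1 in range(1, 5)
            for e2 in range(1, 5)
            for e3 in range(1, 5)
        )
        assert n_high == 16

    def test_agrees_with_lookup_oracle_for_all_patterns(self):
        for pattern in all_patterns():
            lookup = triplet_lookup_table(pattern.positions)
            for (e1, e2, e3), expect in lookup.items():
                got = classify_triplet(e1, e2, e3, pattern)
                assert got.high == expect["high"]
                assert got.trill == expect["trill"]
                assert got.repetition == expect["repetition"]

    def test_invalid_positions_rejected(self, pattern3241):
        with pytest.raises(ValueError):
            classify_triplet(0, 1, 2, pattern3241)


class TestTripletProbability:
    def test_analytic_values(self, pattern3241):
        assert triplet_probability(pattern3241, "high") == pytest.approx(0.625)
        assert triplet_probability(pattern3241, "low") == pytest.approx(0.375)
        assert (
            triplet_probability(pattern3241, "high")
            + triplet_probability(pattern3241, "low")
            == 1.0
        )


class TestSession:
    def test_default_layout(self, single_session):
        s = single_session
        assert len(s) == 1760
        assert s["block"].nunique() == 22
        assert (~s["is_practice"]).sum() == 1600
        assert s.loc[s["is_practice"], "block"].nunique() == 2

    def test_pattern_trials_follow_pattern_cyclically(self, single_session):
        test = single_session[~single_session["is_practice"]]
        pattern_pos = test.loc[test["trial_type"] == "pattern", "stimulus_position"]
        expected = np.resize([3, 2, 4, 1], len(pattern_pos))
        assert np.array_equal(pattern_pos.to_numpy(), expected)

    def test_strict_alternation_starting_with_pattern(self, single_session):
        test = single_session[~single_session["is_practice"]]
        for _, block in test.groupby("block"):
            types = block.sort_values("trial_index_in_block")["trial_type"].to_numpy()
            assert np.array_equal(
                types, np.where(np.arange(len(types)) % 2 == 0, "pattern", "random")
            )

    def test_half_of_test_trials_are_pattern(self, single_session):
        test = single_session[~single_session["is_practice"]]
        assert (test["trial_type"] == "pattern").mean() == 0.5

    def test_triplet_undefined_iff_first_two_of_block(self, single_session):
        undef = single_session["triplet_class"] == "undefined"
        first_two = single_session["trial_index_in_block"] <= 2
        assert (undef == first_two).all()

    def test_trill_and_repetition_disjoint(self, single_session):
        both = single_session["is_trill"] & single_session["is_repetition"]
        assert not both.any()

    @pytest.mark.parametrize(
        "kwargs", [{"trials_per_block": 81}, {"n_blocks": 0}]
    )
    def test_invalid_layout_rejected(self, pattern3241, kwargs):
        with pytest.raises(ValueError):
            generate_session(pattern3241, rng_seed=0, **kwargs)


class TestEmpiricalTripletRates:
    """Monte-Carlo agreement with the analytic triplet probabilities."""

    @pytest.fixture(scope="class")
    def big_stream(self, pattern3241):
        # 70 sessions x 1,560 classifiable trials > 1e5
        import pandas as pd

        frames = [
            generate_session(pattern3241, rng_seed=seed, session=seed + 1)
            for seed in range(70)
        ]
        df = pd.concat(frames, ignore_index=True)
        return df[(~df["is_practice"]) & (df["triplet_class"] != "undefined")]

    def test_high_probability_frequency_is_0625(self, big_stream):
        n = len(big_stream)
        assert n >= 100_000
        p_hat = (big_stream["triplet_class"] == "high").mean()
        se = np.sqrt(0.625 * 0.375 / n)
        assert abs(p_hat - 0.625) < 3 * se

    def test_trill_and_repetition_rates_among_random_endings(self, big_stream):
        rnd = big_stream[big_stream["trial_type"] == "random"]
        n = len(rnd)
        for col, expect in (("is_trill", 3 / 16), ("is_repetition", 1 / 16)):
            p_hat = rnd[col].mean()
            se = np.sqrt(expect * (1 - expect) / n)
            assert abs(p_hat - expect) < 4 * se

    def test_pattern_endings_never_trill_or_repetition(self, big_stream):
        pat = big_stream[big_stream["trial_type"] == "pattern"]
        assert not pat["is_trill"].any()
        assert not pat["is_repetition"].any()
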