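"""Pair enumeration rules, Fisher-z similarity, condition means."""

import numpy as np
import pytest

import memorsa as m
from conftest import brute_force_ers, brute_force_rrs, random_toy_design
from memorsa.rsa import (CELLS, DegeneratePairError, PairSet, bilateral_means,
                         cell_means, fisher_z)


class TestFisherZ:
    def test_closed_form_values(self):
        assert fisher_z(0.0) == 0.0
        assert abs(fisher_z(0.5) - 0.5493) < 1e-4
        assert abs(fisher_z(-0.5) + 0.5493) < 1e-4

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(DegeneratePairError):
            fisher_z(1.0)
        with pytest.raises(DegeneratePairError):
            fisher_z(-1.0 + 1e-9)
        with pytest.raises(ValueError):
            fisher_z(1.5)


class TestPairEnumeration:
    def test_matches_exhaustive_oracle_on_random_designs(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            enc, ret = random_toy_design(rng)
            ers = m.enumerate_ers_pairs(enc, ret)
            got = set(zip(ers.a_idx.tolist(), ers.b_idx.tolist(),
                          ers.cell.tolist()))
            assert got == brute_force_ers(enc, ret)
            rrs = m.enumerate_rrs_pairs(ret, enc)
            got = set(zip(rrs.a_idx.tolist(), rrs.b_idx.tolist(),
                          rrs.cell.tolist()))
            assert got == brute_force_rrs(ret, enc)

    def test_incorrect_encoding_excludes_object_everywhere(self):
        enc, ret = m.make_design(16, 4, 2, 2, seed=5)
        truth = m.truth_for_profile("null", p_encoding_correct=1.0,
                                    p_remember_high=1.0, p_remember_low=1.0)
        enc, ret = m.simulate_behavior(enc, ret, truth, seed=6)
        bad_obj = int(enc.object_id[0])
        bad_rep = np.flatnonzero(enc.object_id == bad_obj)[1]
        enc.correct[bad_rep] = False
        ers = m.enumerate_ers_pairs(enc, ret)
        assert not np.isin(enc.object_id[ers.a_idx], bad_obj).any()
        assert not np.isin(ret.object_id[ers.b_idx], bad_obj).any()
        rrs = m.enumerate_rrs_pairs(ret, enc)
        assert not np.isin(ret.object_id[rrs.a_idx], bad_obj).any()
        assert not np.isin(ret.object_id[rrs.b_idx], bad_obj).any()

    def test_same_object_pairs_absent(self, default_design):
        enc, ret = default_design
        truth = m.truth_for_profile("null", p_encoding_correct=1.0)
        enc, ret = m.simulate_behavior(enc, ret, truth, seed=7)
        ers = m.enumerate_ers_pairs(enc, ret)
        assert (enc.object_id[ers.a_idx] != ret.object_id[ers.b_idx]).all()

    def test_single_run_rrs_is_empty(self):
        enc, ret = m.make_design(16, 4, 1, 2, seed=8)
        enc, ret = m.simulate_behavior(enc, ret, m.truth_for_profile("null"),
                                       seed=9)
        assert len(m.enumerate_rrs_pairs(ret, enc)) == 0

    def test_rrs_pairs_unordered_once(self, toy_subject):
        rrs = m.enumerate_rrs_pairs(toy_subject.retrieval,
                                    toy_subject.encoding)
        assert (rrs.a_idx < rrs.b_idx).all()
        keys = set(zip(rrs.a_idx.tolist(), rrs.b_idx.tolist()))
        assert len(keys) == len(rrs)

    def test_same_scene_implies_same_reward(self, toy_subject):
        for pairs, ta, tb in (
            (m.enumerate_ers_pairs(toy_subject.encoding,
                                   toy_subject.retrieval),
             toy_subject.encoding, toy_subject.retrieval),
            (m.enumerate_rrs_pairs(toy_subject.retrieval,
                                   toy_subject.encoding),
             toy_subject.retrieval, toy_subject.retrieval),
        ):
            same = pairs.cell % 2 == 0
            np.testing.assert_array_equal(
                ta.scene_id[pairs.a_idx[same]] == tb.scene_id[pairs.b_idx[same]],
                True)
            np.testing.assert_array_equal(
                ta.reward_high[pairs.a_idx], tb.reward_high[pairs.b_idx])


class TestPairProperties:
    """Hypothesis-driven invariants of the pair rules."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(n_scenes=st.sampled_from([2, 4]), n_runs=st.integers(1, 2),
           per=st.integers(1, 2), seed=st.integers(0, 2 ** 20),
           p_enc=st.floats(0.3, 1.0), p_rem=st.floats(0.1, 0.9))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_rules_hold_on_arbitrary_designs(self, n_scenes, n_runs, per,
                                             seed, p_enc, p_rem):
        n_objects = n_scenes * n_runs * per * 2
        enc, ret = m.make_design(n_objects, n_scenes, n_runs, 2, seed=seed)
        truth = m.truth_for_profile("null", p_encoding_correct=p_enc,
                                    p_remember_high=p_rem,
                                    p_remember_low=p_rem)
        enc, ret = m.simulate_behavior(enc, ret, truth, seed=seed + 1)
        ok = m.encoding_all_correct(enc)

        ers = m.enumerate_ers_pairs(enc, ret)
        assert (enc.object_id[ers.a_idx] != ret.object_id[ers.b_idx]).all()
        assert ok[enc.object_id[ers.a_idx]].all()
        assert ok[ret.object_id[ers.b_idx]].all()
        same = ers.cell % 2 == 0
        assert (enc.scene_id[ers.a_idx[same]]
                == ret.scene_id[ers.b_idx[same]]).all()
        assert (enc.scene_id[ers.a_idx[~same]]
                != ret.scene_id[ers.b_idx[~same]]).all()
        # same condition cell implies same reward level on both members
        assert (enc.reward_high[ers.a_idx]
                == ret.reward_high[ers.b_idx]).all()

        rrs = m.enumerate_rrs_pairs(ret, enc)
        assert (ret.run[rrs.a_idx] != ret.run[rrs.b_idx]).all()
        assert (rrs.a_idx < rrs.b_idx).all()
        assert ok[ret.object_id[rrs.a_idx]].all()
        assert ok[ret.object_id[rrs.b_idx]].all()
        assert (ret.remembered[rrs.a_idx] == ret.remembered[rrs.b_idx]).all()


class TestConditionMeans:
    def test_hand_computed_toy_example(self):
        # three pairs, 3x4 pattern matrices, hand-computed correlations
        a = np.array([[1.0, 2.0, 3.0, 4.0],
                      [2.0, 1.0, 4.0, 3.0],
                      [1.0, 0.0, 1.0, 0.0]])
        b = np.array([[3.0, 1.0, 4.0, 2.0],
                      [1.0, 2.0, 4.0, 3.0],
                      [0.0, 1.0, 1.0, 0.0]])
        pairs = PairSet("ERS", np.array([0, 1, 2]), np.array([0, 1, 2]),
                        np.array([0, 0, 1]))
        m.pair_similarities(pairs, a, b)

        def r(x, y):
            x = x - x.mean()
            y = y - y.mean()
            return (x @ y) / np.sqrt((x @ x) * (y @ y))

        z = [np.arctanh(r(a[i], b[i])) for i in range(3)]
        means, counts = cell_means(pairs)
        assert counts[0] == 2 and counts[1] == 1
        assert abs(means[0] - (z[0] + z[1]) / 2) < 1e-12
        assert abs(means[1] - z[2]) < 1e-12
        assert np.isnan(means[2:]).all()

    def test_trial_order_permutation_invariance(self, toy_subject):
        s = toy_subject
        base = m.roi_similarity(s.encoding, s.retrieval, s.enc_patterns,
                                s.ret_patterns)
        rng = np.random.default_rng(10)
        perm_e = rng.permutation(len(s.encoding))
        perm_r = rng.permutation(len(s.retrieval))
        enc2 = s.encoding.copy()
        ret2 = s.retrieval.copy()
        for name in ("object_id", "scene_id", "reward_high", "run", "onset",
                     "duration", "repetition", "correct", "rt"):
            arr = getattr(enc2, name)
            if arr is not None:
                setattr(enc2, name, arr[perm_e])
        for name in ("object_id", "scene_id", "reward_high", "run", "onset",
                     "duration", "recall_response", "remembered",
                     "confidence", "rt"):
            arr = getattr(ret2, name)
            if arr is not None:
                setattr(ret2, name, arr[perm_r])
        shuffled = m.roi_similarity(enc2, ret2, s.enc_patterns[perm_e],
                                    s.ret_patterns[perm_r])
        for k in ("ERS", "RRS"):
            np.testing.assert_allclose(base[k][0], shuffled[k][0],
                                       atol=1e-12)
            np.testing.assert_array_equal(base[k][1], shuffled[k][1])

    def test_bilateral_average_exact(self):
        mL = np.arange(8.0)
        mR = np.arange(8.0) * 3
        np.testing.assert_array_equal(bilateral_means(mL, mR), 2 * np.arange(8.0))

    def test_constant_row_rejected(self, toy_subject):
        pat = toy_subject.ret_patterns.copy()
        pat[3] = 5.0
        pairs = m.enumerate_rrs_pairs(toy_subject.retrieval,
                                      toy_subject.encoding)
        with pytest.raises(DegeneratePairError, match="3"):
            m.pair_similarities(pairs, pat)


class TestSingleTrialIndices:
    def test_oracle_recomputation(self, toy_subject):
        ers = m.pair_similarities(
            m.enumerate_ers_pairs(toy_subject.encoding, toy_subject.retrieval),
            toy_subject.enc_patterns, toy_subject.ret_patterns)
        idx = m.single_trial_reinstatement(ers, len(toy_subject.retrieval))
        for t in range(len(toy_subject.retrieval)):
            mine = ers.b_idx == t
            same = mine & (ers.cell % 2 == 0)
            diff = mine & (ers.cell % 2 == 1)
            if same.any() and diff.any():
                expected = ers.z[same].mean() - ers.z[diff].mean()
                assert abs(idx[t] - expected) < 1e-12
            else:
                assert np.isnan(idx[t])

        rrs = m.pair_similarities(
            m.enumerate_rrs_pairs(toy_subject.retrieval,
                                  toy_subject.encoding),
            toy_subject.ret_patterns)
        idx = m.single_trial_overlap(rrs, len(toy_subject.retrieval))
        for t in range(len(toy_subject.retrieval)):
            mine = (rrs.a_idx == t) | (rrs.b_idx == t)
            same = mine & (rrs.cell % 2 == 0)
            diff = mine & (rrs.cell % 2 == 1)
            if same.any() and diff.any():
                expected = rrs.z[same].mean() - rrs.z[diff].mean()
                assert abs(idx[t] - expected) < 1e-12

    def test_noiseless_planted_trials_positive(self):
        enc, ret = m.make_design(32, 4, 2, 2, seed=11)
        truth = m.truth_for_profile("phc_like", noise_sd=0.0,
                                    reinstatement_gain_remembered=0.3,
                                    p_encoding_correct=1.0)
        enc, ret = m.simulate_behavior(enc, ret, truth, seed=12)
        ep, rp, _ = m.simulate_patterns(enc, ret, truth, 60, seed=13)
        ers = m.pair_similarities(m.enumerate_ers_pairs(enc, ret), ep, rp)
        idx = m.single_trial_reinstatement(ers, len(ret))
        rem = ret.remembered & np.isfinite(idx)
        assert rem.any()
        assert (idx[rem] > 0).all()

    def test_null_profile_mean_near_zero(self):
        enc, ret = m.make_design(160, 4, 4, 2, seed=14)
        truth = m.truth_for_profile("null", p_encoding_correct=1.0)
        enc, ret = m.simulate_behavior(enc, ret, truth, seed=15)
        ep, rp, _ = m.simulate_patterns(enc, ret, truth, 100, seed=16)
        ers = m.pair_similarities(m.enumerate_ers_pairs(enc, ret), ep, rp)
        idx = m.single_trial_reinstatement(ers, len(ret))
        vals = idx[np.isfinite(idx)]
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean()) < 3 * se + 1e-12
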