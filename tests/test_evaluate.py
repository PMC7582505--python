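"""Session aggregation, MAE, TOST, t-tests, and evaluation protocols."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eegmotor.evaluate import (EquivalenceSpec, LeakageError, SessionScore,
                               aggregate_sessions, cross_participant_eval,
                               mae, pearson, tost, ttests,
                               within_participant_eval)
from eegmotor.features import LabeledDataset


def _index(pids, sids, fmas):
    return pd.DataFrame({"participant_id": pids, "session_id": sids,
                         "fma_ue": fmas})


class TestAggregation:
    def test_session_mean(self):
        idx = _index(["P1"] * 2, ["s1"] * 2, [45.0] * 2)
        out = aggregate_sessions([40.0, 50.0], idx)
        assert len(out) == 1
        assert out[0].predicted == 45.0
        assert out[0].n_trials == 2

    def test_six_sessions_of_140_trials(self, rng):
        n = 6 * 140
        idx = _index(["P1"] * n, np.repeat([f"s{k}" for k in range(6)], 140),
                     [45.0] * n)
        out = aggregate_sessions(rng.normal(45, 3, n), idx)
        assert len(out) == 6
        assert all(s.n_trials == 140 for s in out)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_sessions([], _index([], [], []))

    def test_mae_examples(self):
        def sess(diffs):
            return [SessionScore("P", f"s{i}", 45.0 + d, 10, 45.0)
                    for i, d in enumerate(diffs)]
        assert mae(sess([0.0, 0.0])) == 0.0
        assert mae(sess([1.0, -2.0, 3.0])) == 2.0
        assert mae(sess([-4.0])) == 4.0

    def test_mae_invariant_to_order_and_equals_precomputed_means(self, rng):
        diffs = rng.normal(0, 2, 8)
        def sess(ds):
            return [SessionScore("P", f"s{i}", 45.0 + d, 10, 45.0)
                    for i, d in enumerate(ds)]
        assert mae(sess(diffs)) == pytest.approx(mae(sess(diffs[::-1])))
        assert mae(sess(diffs)) == pytest.approx(np.mean(np.abs(diffs)))


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(5.0)
        assert pearson(2 * x + 1, x) == pytest.approx(1.0)
        assert pearson(-x, x) == pytest.approx(-1.0)

    def test_toy_set_matches_hand_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 3.0, 3.0, 6.0, 7.0])
        xc, yc = x - x.mean(), y - y.mean()
        expect = np.sum(xc * yc) / np.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2))
        assert pearson(x, y) == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1.0, 1.0], [1.0, 2.0])


class TestTost:
    def test_zero_differences_strongly_equivalent(self):
        res = tost(np.zeros(6))
        assert res.zero_variance
        assert res.p < 0.001

    def test_near_zero_variance_matches_reference(self):
        d = np.full(6, 1e-9)
        d[0] += 1e-12
        res = tost(d)
        assert res.p < 1e-10

    def test_mean_far_outside_bounds_not_equivalent(self, rng):
        d = rng.normal(30.0, 1.0, 6)
        assert tost(d).p > 0.999

    def test_matches_statsmodels_on_100_seeded_datasets(self):
        from statsmodels.stats.weightstats import DescrStatsW
        spec = EquivalenceSpec()
        for seed in range(100):
            rng = np.random.default_rng(seed)
            d = rng.normal(rng.uniform(-8, 8), rng.uniform(0.5, 5),
                           rng.integers(3, 25))
            ours = tost(d, spec)
            ref_p, (ref_t1, ref_p1, _), (ref_t2, ref_p2, _) = \
                DescrStatsW(d).ttost_mean(spec.lower_bound, spec.upper_bound)
            assert ours.p == pytest.approx(ref_p, abs=1e-8)
            assert ours.p_lower == pytest.approx(ref_p1, abs=1e-8)
            assert ours.p_upper == pytest.approx(ref_p2, abs=1e-8)

    def test_asymmetric_bounds_applied_as_given(self):
        # a mean of +5.8 sits inside (-5, 6.6) but outside (-5, 5)
        rng = np.random.default_rng(0)
        d = rng.normal(5.8, 0.1, 30)
        assert tost(d, EquivalenceSpec()).p < 0.05
        assert tost(d, EquivalenceSpec(upper_bound=5.0)).p > 0.5

    def test_too_few_differences_rejected(self):
        with pytest.raises(ValueError):
            tost([1.0])


class TestTTests:
    def test_identical_vectors_flagged_degenerate(self):
        res = ttests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.paired_p == 1.0
        assert res.degenerate

    def test_matches_closed_form(self):
        rng = np.random.default_rng(42)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
        res = ttests(a, b)
        # textbook paired t
        d = a - b
        t_p = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_paired = 2 * stats.t.sf(abs(t_p), len(d) - 1)
        assert res.paired_p == pytest.approx(p_paired, abs=1e-10)
        # Welch two-sample t
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_w = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_w = (va + vb) ** 2 / (va ** 2 / (len(a) - 1)
                                 + vb ** 2 / (len(b) - 1))
        p_welch = 2 * stats.t.sf(abs(t_w), df_w)
        assert res.unpaired_p == pytest.approx(p_welch, abs=1e-10)

    def test_large_shift_tiny_noise_significant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(50, 0.1, 6)
        b = rng.normal(40, 0.1, 6)
        res = ttests(a, b)
        assert res.paired_p < 1e-6

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            ttests([1.0, 2.0], [1.0, 2.0, 3.0])


class _StubModel:
    """Predicts true score + fixed offset; stands in for a trained net."""

    def __init__(self, dataset, offset=0.0, constant=None):
        self._table = dict(zip(dataset.trial_ids, dataset.scores))
        self._order = list(dataset.trial_ids)
        self.offset = offset
        self.constant = constant

    def predict(self, tensors, clip=False):
        n = len(tensors)
        if self.constant is not None:
            return np.full(n, self.constant)
        return np.array([self._table[t] + self.offset
                         for t in self._order[:n]])


def _longitudinal_dataset(rng, score=45.0, n_sessions=6, trials=10):
    n = n_sessions * trials
    feats = rng.standard_normal((n, 270, 32, 2)).astype(np.float32)
    sessions = np.repeat([f"s{k}" for k in range(n_sessions)], trials)
    return LabeledDataset(
        feats, np.full(n, score), np.array(["P1"] * n), sessions,
        np.array(["stroke"] * n),
        np.array([f"P1/{s}/e{i}" for i, s in enumerate(sessions)]))


class TestWithinParticipant:
    def test_perfect_model_zero_mae_equivalent(self, rng):
        ds = _longitudinal_dataset(rng)
        report = within_participant_eval(_StubModel(ds), ds)
        assert report.mae == 0.0
        assert report.tost_p < report.spec.alpha

    def test_constant_offset_model_mae_equals_offset(self, rng):
        ds = _longitudinal_dataset(rng)
        report = within_participant_eval(_StubModel(ds, offset=3.0), ds)
        assert report.mae == pytest.approx(3.0)

    def test_wildly_wrong_model_not_equivalent(self, rng):
        ds = _longitudinal_dataset(rng, score=45.0)
        report = within_participant_eval(_StubModel(ds, constant=0.0), ds)
        assert report.tost_p > 0.99
        assert not report.equivalent

    def test_report_serialises(self, rng, tmp_path):
        ds = _longitudinal_dataset(rng)
        report = within_participant_eval(_StubModel(ds, offset=1.0), ds)
        text = report.to_json(tmp_path / "report.json")
        assert '"mae"' in text
        assert "MAE" in report.to_table()


class TestCrossParticipant:
    def test_exclusion_and_leakage_guard(self, tiny_train, tiny_test, rng):
        from eegmotor.models import CnnConfig
        target = tiny_train.participants[0]
        target_ds = tiny_test.subset(
            np.flatnonzero(tiny_test.participants == target))
        # verify_no_leakage path: relabel one target trial as another
        # participant and keep it in the pool -> hard error
        poisoned = LabeledDataset(
            tiny_train.features.copy(), tiny_train.scores.copy(),
            tiny_train.participants.copy(), tiny_train.sessions.copy(),
            tiny_train.groups.copy(), tiny_train.trial_ids.copy())
        victim = np.flatnonzero(poisoned.participants == target)[0]
        poisoned.participants[victim] = "MOLE"
        poisoned.trial_ids[victim] = target_ds.trial_ids[0]
        with pytest.raises(LeakageError):
            cross_participant_eval(poisoned, target_ds, target,
                                   CnnConfig(), seed=0)

    def test_training_pool_excludes_target(self, tiny_train):
        target = tiny_train.participants[0]
        reduced = tiny_train.exclude_participant(target)
        assert target not in set(reduced.participants)
        assert len(set(reduced.participants)) \
            == len(set(tiny_train.participants)) - 1

    def test_target_absent_from_longitudinal_rejected(self, tiny_train,
                                                      tiny_test):
        from eegmotor.models import CnnConfig
        with pytest.raises(ValueError, match="absent"):
            cross_participant_eval(tiny_train, tiny_test, "NOBODY",
                                   CnnConfig(), seed=0)
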