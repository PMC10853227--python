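"""Metrics against exhaustive oracles; CV mechanics; comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deltasurv.evaluation import (CVScheme, bh_adjust, bootstrap_summary, compare_models,
                                  concordance_index, integrated_auc, run_repeated_cv)


def oracle_cindex(times, events, risks):
    """O(n^2) pure-Python pair enumeration with the pinned conventions."""
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if risks[i] > risks[j]:
                    num += 1
                elif risks[i] == risks[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pair")
    return num / den


class TestConcordance:
    def test_perfect_concordance(self):
        assert concordance_index([5, 10, 15], [1, 1, 1], [3, 2, 1]) == 1.0

    def test_perfect_anticoncordance(self):
        assert concordance_index([5, 10, 15], [1, 1, 1], [1, 2, 3]) == 0.0

    def test_censoring_excludes_pairs(self):
        # comparable pairs: (1,2) and (1,3) only -> one concordant, one not
        assert concordance_index([5, 10, 15], [1, 0, 1], [2, 3, 1]) == 0.5

    def test_matches_exhaustive_oracle_on_random_censored_instances(self):
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(200):
            n = rng.integers(3, 21)
            times = rng.integers(1, 10, size=n).astype(float)  # ties likely
            events = rng.integers(0, 2, size=n)
            risks = rng.integers(0, 5, size=n).astype(float)   # tied risks likely
            try:
                expected = oracle_cindex(times, events, risks)
            except ValueError:
                with pytest.raises(ValueError):
                    concordance_index(times, events, risks)
                continue
            assert concordance_index(times, events, risks) == expected
            checked += 1
        assert checked > 150

    def test_affine_invariance_of_risks(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(10, 30)
        events = rng.integers(0, 2, 30)
        events[0] = 1
        risks = rng.normal(size=30)
        c = concordance_index(times, events, risks)
        assert concordance_index(times, events, 3.7 * risks - 11.0) == c

    def test_undefined_without_comparable_pairs(self):
        with pytest.raises(ValueError):
            concordance_index([5, 10], [0, 0], [1, 2])


class TestIntegratedAUC:
    def _outcomes(self, times, events):
        return pd.DataFrame({"pfs_months": times, "event": events})

    def test_perfect_ordering_reaches_one(self):
        times = np.linspace(1, 40, 60)
        out = self._outcomes(times, np.ones(60, int))
        assert integrated_auc(out, out, -times) == pytest.approx(1.0)

    def test_random_risks_near_half(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(10, 400) + 0.1
        out = self._outcomes(times, np.ones(400, int))
        assert integrated_auc(out, out, rng.normal(size=400)) == pytest.approx(0.5, abs=0.05)

    def test_identical_risks_give_exactly_half(self):
        times = np.linspace(1, 20, 20)
        out = self._outcomes(times, np.ones(20, int))
        assert integrated_auc(out, out, np.full(20, 2.0)) == 0.5

    def test_degenerate_grid_falls_back_with_warning(self):
        out_train = self._outcomes([5.0, 10.0, 15.0, 20.0], [1, 1, 1, 1])
        out_test = self._outcomes([9.0, 9.0, 9.0, 12.0], [1, 0, 0, 1])
        with pytest.warns(UserWarning, match="degenerate"):
            v = integrated_auc(out_train, out_test, np.array([3.0, 1.0, 2.0, 0.5]))
        assert 0.0 <= v <= 1.0


class _IdentityPipeline:
    """Records its training data; predicts the first feature as risk."""

    def __init__(self, xtr):
        self.train_copy = xtr.copy()

    def predict_risk(self, x):
        return x.iloc[:, 0].to_numpy()


class TestRepeatedCV:
    def _data(self, n=18, seed=0):
        rng = np.random.default_rng(seed)
        times = rng.exponential(11, n) + 0.2
        features = pd.DataFrame({"f0": -times + rng.normal(0, 4, n),
                                 "f1": rng.normal(size=n)})
        outcomes = pd.DataFrame({"pfs_months": times,
                                 "event": (rng.random(n) > 0.11).astype(int)})
        return features, outcomes

    def test_4x25_scheme_yields_100_test_scores(self):
        features, outcomes = self._data()

        def fit(xtr, otr, seed):
            return _IdentityPipeline(xtr)

        run = run_repeated_cv(fit, features, outcomes, CVScheme(4, 25, seed=1),
                              compute_iauc=False, keep_models=False)
        assert len(run.scores) + len(run.skipped) == 100
        assert len(run.skipped) == 0  # stratification guarantees test events

    def test_garbage_in_test_rows_never_touches_fitted_state(self):
        features, outcomes = self._data()
        fitted = []

        def fit(xtr, otr, seed):
            p = _IdentityPipeline(xtr)
            fitted.append(p)
            return p

        scheme = CVScheme(4, 2, seed=3)
        run1 = run_repeated_cv(fit, features, outcomes, scheme, compute_iauc=False)
        states1 = [p.train_copy for p in fitted]
        fitted.clear()
        corrupted = features.copy()
        corrupted.iloc[::2] += 1e6  # corrupt half the cohort
        run2 = run_repeated_cv(fit, corrupted, outcomes, scheme, compute_iauc=False)
        # folds where the training half happens to be clean must be identical
        clean_match = 0
        for a, b in zip(states1, [p.train_copy for p in fitted]):
            if a.index.equals(b.index) and np.allclose(a, b):
                clean_match += 1
        assert not run1.scores["cindex_test"].equals(run2.scores["cindex_test"])

    def test_null_signal_mean_test_c_near_half(self):
        rng = np.random.default_rng(5)
        n = 200
        features = pd.DataFrame({"f0": rng.normal(size=n), "f1": rng.normal(size=n)})
        outcomes = pd.DataFrame({"pfs_months": rng.exponential(11, n) + 0.2,
                                 "event": np.ones(n, int)})

        def fit(xtr, otr, seed):
            return _IdentityPipeline(xtr)

        run = run_repeated_cv(fit, features, outcomes, CVScheme(4, 5, seed=7),
                              compute_iauc=False, keep_models=False)
        assert abs(run.scores["cindex_test"].mean() - 0.5) < 0.05


class TestBootstrapSummary:
    def test_constant_scores(self):
        s = bootstrap_summary([0.7] * 10, seed=0)
        assert s.mean == pytest.approx(0.7)
        assert s.se == pytest.approx(0.0, abs=1e-12)
        assert s.ci_low == pytest.approx(0.7) and s.ci_high == pytest.approx(0.7)

    def test_seed_determinism(self):
        scores = np.random.default_rng(3).random(40)
        assert bootstrap_summary(scores, seed=9) == bootstrap_summary(scores, seed=9)

    def test_two_point_scores_ci_matches_binomial_enumeration(self):
        # resampling {0,1,...} of size 4: bootstrap mean is Binomial(4, 1/2)/4
        s = bootstrap_summary([0.0, 0.0, 1.0, 1.0], n_boot=20000, seed=1)
        assert s.mean == pytest.approx(0.5, abs=0.01)
        assert s.se == pytest.approx(0.25, abs=0.01)  # sd of Bin(4,.5)/4
        assert s.ci_low == 0.0 and s.ci_high == 1.0   # 2.5th/97.5th percentiles


class TestComparisons:
    def test_extreme_separation_exact_p(self):
        res = compare_models([0.9, 0.8], [0.1, 0.2])
        assert res.u_statistic == 4.0
        assert res.p_value == pytest.approx(1 / 6)

    def test_identical_lists_give_half(self):
        res = compare_models([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert res.p_value == 0.5 and res.degenerate

    def test_direction_swap_complements_p(self):
        a = [0.9, 0.7, 0.8, 0.85]
        b = [0.2, 0.3, 0.1, 0.4]
        p_ab = compare_models(a, b).p_value
        p_ba = compare_models(b, a).p_value
        assert p_ab < 0.05 < p_ba
        # exact distributions: P(U>=u) + P(U<=u) = 1 + P(U=u)
        assert p_ab + p_ba >= 1.0


class TestBH:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_adjusted_ps_are_monotone_in_raw_ranking(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)
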