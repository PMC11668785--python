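"""Competing-risk forest: Gray splitting, Aalen–Johansen leaves, ensemble,
OOB machinery, tuning and variable importance — checked against independent
enumeration and one-cause reduction oracles."""

import numpy as np
import pandas as pd
import pytest

from crlandmark import (CompetingRiskForest, gray_split_statistic,
                        aalen_johansen, tune, vimp,
                        simulate_competing_dataset, two_group_true_cif,
                        NODESIZE_GRID)
from crlandmark.forest import _grow_tree, _combo_seed


# ---------------------------------------------------------------------------
# independent oracles

def gray_oracle(time, status, left, cause):
    """Loop-based subdistribution log-rank score (extended risk set)."""
    time = list(time)
    status = list(status)
    other = 2 if cause == 1 else 1
    n = len(time)
    U = V = 0.0
    for tau in sorted({t for t, s in zip(time, status) if s == cause}):
        risk = [i for i in range(n)
                if time[i] >= tau or (status[i] == other and time[i] < tau)]
        d = sum(1 for i in range(n) if time[i] == tau and status[i] == cause)
        dL = sum(1 for i in range(n)
                 if time[i] == tau and status[i] == cause and left[i])
        Y = len(risk)
        YL = sum(1 for i in risk if left[i])
        p = YL / Y
        U += dL - d * p
        if Y > 1:
            V += d * p * (1 - p) * (Y - d) / (Y - 1)
    return U / np.sqrt(V) if V > 0 else 0.0


def _rand_cr(n, seed, p=3, censor=0.3):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"x{i}" for i in range(p)])
    time = rng.exponential(5.0, n).round(3) + 0.01
    status = rng.choice([0, 1, 2], n, p=[censor, (1 - censor) * 0.6,
                                         (1 - censor) * 0.4])
    return X, time, status


# ---------------------------------------------------------------------------
# Gray split statistic

class TestGrayStatistic:
    def test_symmetric_duplicate_halves_score_zero(self):
        time = np.array([1, 2, 3, 4.0] * 2)
        status = np.array([1, 0, 2, 1] * 2)
        left = np.array([True] * 4 + [False] * 4)
        assert gray_split_statistic(time, status, left, cause=1) == pytest.approx(0.0)

    def test_reduces_to_logrank_without_competing_events(self):
        from lifelines.statistics import logrank_test
        rng = np.random.default_rng(5)
        tA = rng.exponential(1.0, 20).round(2) + 0.01
        tB = rng.exponential(2.0, 15).round(2) + 0.01
        eA = rng.uniform(size=20) < 0.8
        eB = rng.uniform(size=15) < 0.8
        time = np.concatenate([tA, tB])
        status = np.concatenate([eA, eB]).astype(int)  # only cause 1
        left = np.array([True] * 20 + [False] * 15)
        z = gray_split_statistic(time, status, left, cause=1)
        ref = logrank_test(tA, tB, event_observed_A=eA, event_observed_B=eB)
        assert z ** 2 == pytest.approx(ref.test_statistic, rel=1e-9)

    def test_six_subject_enumeration_oracle(self):
        time = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        status = [1, 2, 1, 0, 1, 2]
        left = [True, False, True, True, False, False]
        got = gray_split_statistic(time, status, left, cause=1)
        assert got == pytest.approx(gray_oracle(time, status, left, 1), abs=1e-12)
        got2 = gray_split_statistic(time, status, left, cause=2)
        assert got2 == pytest.approx(gray_oracle(time, status, left, 2), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_nodes_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        time = rng.exponential(3, n).round(2) + 0.01
        status = rng.choice([0, 1, 2], n)
        left = rng.uniform(size=n) < 0.5
        if left.all() or not left.any():
            left[0] = ~left[0]
        for cause in (1, 2):
            assert gray_split_statistic(time, status, left, cause) == \
                pytest.approx(gray_oracle(time, status, left, cause), abs=1e-10)

    def test_one_sided_split_rejected(self):
        with pytest.raises(ValueError, match="one-sided"):
            gray_split_statistic([1, 2], [1, 1], [True, True], 1)


# ---------------------------------------------------------------------------
# Aalen–Johansen

class TestAalenJohansen:
    def test_no_censoring_equals_empirical_fraction(self):
        time = np.array([1, 2, 3, 4, 5, 6.0])
        status = np.array([1, 2, 1, 1, 2, 1])
        cifs = aalen_johansen(time, status)
        for t in (2.5, 4.5, 6.0):
            assert cifs[1].at(t) == pytest.approx(
                np.mean((status == 1) & (time <= t)))
            assert cifs[2].at(t) == pytest.approx(
                np.mean((status == 2) & (time <= t)))

    def test_single_subject_jump(self):
        cifs = aalen_johansen([2.0], [1])
        assert cifs[1].at(1.9) == 0.0
        assert cifs[1].at(2.0) == 1.0
        assert cifs[2].at(10.0) == 0.0

    def test_ten_subject_product_limit_oracle(self):
        """Hand-computed product-limit values (exact fractions)."""
        time = [1, 2, 2, 3, 4, 5, 6, 7, 8, 9.0]
        status = [1, 2, 0, 1, 1, 0, 2, 1, 0, 0]
        cifs = aalen_johansen(time, status)
        assert cifs[1].at(1) == pytest.approx(7 / 70)
        assert cifs[1].at(3) == pytest.approx(15 / 70)
        assert cifs[1].at(4) == pytest.approx(23 / 70)
        assert cifs[1].at(7) == pytest.approx(33 / 70)
        assert cifs[2].at(2) == pytest.approx(7 / 70)
        assert cifs[2].at(6) == pytest.approx(17 / 70)
        assert cifs[1].at(100) == pytest.approx(33 / 70)

    def test_one_cause_reduces_to_one_minus_km(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(7)
        time = rng.exponential(2, 40).round(2) + 0.01
        status = (rng.uniform(size=40) < 0.7).astype(int)
        cifs = aalen_johansen(time, status)
        km = KaplanMeierFitter().fit(time, status)
        for t in (0.5, 1.0, 2.0, 4.0):
            assert cifs[1].at(t) == pytest.approx(
                1 - km.predict(t), abs=1e-10)
        assert np.all(cifs[2].values == 0)


# ---------------------------------------------------------------------------
# tree growth

class TestTreeGrowth:
    def test_stump_limit_equals_full_sample_aj(self):
        X, time, status = _rand_cr(30, 1)
        f = CompetingRiskForest(ntree=1, nodesize=30, bootstrap=False,
                                seed=0).fit(X, time, status)
        tree = f.trees_[0]
        assert len(tree.feature) == 1 and tree.feature[0] == -1
        cifs = aalen_johansen(time, status)
        pred = f.predict_cif(X.iloc[[0]])
        np.testing.assert_allclose(pred[1][0],
                                   cifs[1].at(f.time_grid_), atol=1e-12)
        np.testing.assert_allclose(pred[2][0],
                                   cifs[2].at(f.time_grid_), atol=1e-12)

    def test_dominant_binary_predictor_chosen_at_root(self):
        rng = np.random.default_rng(2)
        n = 60
        grp = np.repeat([0.0, 1.0], n // 2)
        time = np.where(grp == 1, rng.uniform(0.2, 1.0, n), 5.0)
        status = np.where(grp == 1, 1, 0)
        X = pd.DataFrame({"flag": grp, "noise": rng.normal(size=n)})
        f = CompetingRiskForest(ntree=5, mtry=2, nodesize=5, bootstrap=False,
                                seed=3).fit(X, time, status.astype(int))
        assert all(t.feature[0] == 0 for t in f.trees_)

    def test_root_split_matches_exhaustive_oracle(self):
        """n=8, all variables, all midpoints: the chosen root split maximises
        the summed squared Gray statistics over every (variable, midpoint)."""
        rng = np.random.default_rng(4)
        n = 8
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        time = rng.exponential(2, n).round(2) + 0.05
        status = np.array([1, 2, 0, 1, 1, 2, 0, 1])
        f = CompetingRiskForest(ntree=1, mtry=2, nodesize=2, nsplit=None,
                                bootstrap=False, seed=9).fit(X, time, status)
        tree = f.trees_[0]
        best_score, best = -1.0, None
        for v, col in enumerate(X.columns):
            vals = np.sort(np.unique(X[col]))
            for cut in (vals[:-1] + vals[1:]) / 2:
                left = X[col].to_numpy() <= cut
                if left.sum() < 2 or (~left).sum() < 2:
                    continue
                score = sum(gray_split_statistic(time, status, left, k) ** 2
                            for k in (1, 2))
                if score > best_score:
                    best_score, best = score, (v, cut)
        assert tree.feature[0] == best[0]
        assert tree.threshold[0] == pytest.approx(best[1])

    def test_terminal_nodes_respect_nodesize(self):
        X, time, status = _rand_cr(200, 3)
        f = CompetingRiskForest(ntree=3, nodesize=25, seed=0).fit(X, time, status)
        for tree in f.trees_:
            # count in-bag members per leaf
            slots = tree.apply(X.to_numpy())
            # leaves exist and tree is binary
            internal = tree.feature >= 0
            assert np.all(tree.children_left[internal] >= 0)
            assert np.all(tree.children_right[internal] >= 0)


# ---------------------------------------------------------------------------
# forest ensemble

class TestForest:
    def test_ntree_one_equals_tree_prediction(self):
        X, time, status = _rand_cr(50, 5)
        f = CompetingRiskForest(ntree=1, seed=1).fit(X, time, status)
        tree = f.trees_[0]
        pred = f.predict_cif(X)
        slots = tree.apply(X.to_numpy())
        np.testing.assert_allclose(pred[1], tree.leaf_cif[slots][:, 0, :])

    def test_same_seed_identical_forests(self):
        X, time, status = _rand_cr(60, 6)
        a = CompetingRiskForest(ntree=4, seed=7).fit(X, time, status)
        b = CompetingRiskForest(ntree=4, seed=7).fit(X, time, status)
        np.testing.assert_array_equal(a.predict_cif(X)[1], b.predict_cif(X)[1])
        for ta, tb in zip(a.trees_, b.trees_):
            np.testing.assert_array_equal(ta.feature, tb.feature)

    def test_ensemble_is_mean_of_tree_cifs(self):
        X, time, status = _rand_cr(60, 8)
        f = CompetingRiskForest(ntree=6, seed=2).fit(X, time, status)
        manual = np.mean([t.leaf_cif[t.apply(X.to_numpy())][:, 0, :]
                          for t in f.trees_], axis=0)
        np.testing.assert_allclose(f.predict_cif(X)[1], manual, atol=1e-12)

    def test_prediction_row_order_invariance(self):
        X, time, status = _rand_cr(40, 9)
        f = CompetingRiskForest(ntree=5, seed=3).fit(X, time, status)
        perm = np.random.default_rng(0).permutation(len(X))
        a = f.predict_cif(X)[1]
        b = f.predict_cif(X.iloc[perm])[1]
        np.testing.assert_allclose(a[perm], b)

    def test_cif_invariants_on_random_inputs(self):
        X, time, status = _rand_cr(120, 10)
        f = CompetingRiskForest(ntree=20, nodesize=10, seed=4).fit(X, time, status)
        Xq = pd.DataFrame(np.random.default_rng(1).normal(size=(100, 3)),
                          columns=X.columns)
        cifs = f.predict_cif(Xq)
        assert (np.diff(cifs[1], axis=1) >= -1e-10).all()
        assert (np.diff(cifs[2], axis=1) >= -1e-10).all()
        assert (cifs[1] >= -1e-12).all()
        assert (cifs[1] + cifs[2] <= 1 + 1e-9).all()

    def test_unknown_column_raises_schema_error(self):
        X, time, status = _rand_cr(30, 11)
        f = CompetingRiskForest(ntree=2, seed=0).fit(X, time, status)
        with pytest.raises(ValueError, match="columns"):
            f.predict_cif(X.rename(columns={"x0": "bad"}))

    def test_group_cif_recovery_two_group_cohort(self):
        """Mean predicted CIF per group approaches the closed-form group CIF
        (constant hazards) within 3 Monte-Carlo standard errors."""
        gh = {0: (0.05, 0.05), 1: (0.30, 0.10)}
        X, time, status = simulate_competing_dataset(
            1200, seed=12, group_hazards=gh, censor_rate=0.03)
        f = CompetingRiskForest(ntree=100, nodesize=40, seed=5).fit(
            X, time, status, horizon=5.0)
        cifs = f.predict_cif(X)
        idx = np.searchsorted(f.time_grid_, 5.0, side="right") - 1
        for g in (0, 1):
            sel = X["group"] == g
            truth = two_group_true_cif(*gh[g], t=5.0, cause=1)
            se = np.sqrt(truth * (1 - truth) / sel.sum())
            got = cifs[1][sel.to_numpy(), idx].mean()
            assert abs(got - truth) < 3 * se, (g, got, truth, 3 * se)

    def test_oob_cif_rmse_decreases_with_more_trees(self):
        gh = {0: (0.05, 0.05), 1: (0.30, 0.10)}
        X, time, status = simulate_competing_dataset(
            400, seed=13, group_hazards=gh, censor_rate=0.03)
        truth = np.where(X["group"] == 1,
                         two_group_true_cif(*gh[1], 5.0, 1),
                         two_group_true_cif(*gh[0], 5.0, 1))

        def rmse(ntree):
            f = CompetingRiskForest(ntree=ntree, nodesize=40, seed=6).fit(
                X, time, status, horizon=5.0)
            cifs, count = f.oob_cif()
            idx = np.searchsorted(f.time_grid_, 5.0, side="right") - 1
            ok = count > 0
            return np.sqrt(np.mean((cifs[1][ok, idx] - truth[ok]) ** 2))

        assert rmse(200) < rmse(10)


class TestOob:
    def test_random_predictors_give_error_near_half(self):
        X, time, status = _rand_cr(250, 14)
        f = CompetingRiskForest(ntree=80, nodesize=20, seed=7).fit(
            X, time, status, horizon=5.0)
        err = f.oob_error()
        for k in (1, 2):
            assert 0.40 < err[k] < 0.60

    def test_strong_continuous_signal_gives_low_error(self):
        # steep log-linear cause-1 hazard in a continuous covariate: the
        # forest should rank OOB subjects far better than chance
        rng = np.random.default_rng(15)
        n = 400
        x = rng.normal(size=n)
        l1 = np.exp(-1.0 + 3.0 * x)
        l2 = np.full(n, 0.03)
        lam = l1 + l2
        t_ev = rng.exponential(1 / lam)
        cause = np.where(rng.uniform(size=n) < l1 / lam, 1, 2)
        cens = np.minimum(rng.exponential(1 / 0.02, n), 10.0)
        time = np.minimum(t_ev, cens)
        status = np.where(t_ev <= cens, cause, 0)
        X = pd.DataFrame({"x": x, "noise": rng.normal(size=n)})
        f = CompetingRiskForest(ntree=80, nodesize=15, seed=8).fit(
            X, time, status, horizon=5.0)
        assert f.oob_error()[1] < 0.2

    def test_oob_masking_contract(self):
        """A subject's OOB prediction uses only trees where it is out of bag."""
        X, time, status = _rand_cr(80, 16)
        f = CompetingRiskForest(ntree=12, seed=9).fit(X, time, status)
        cifs, count = f.oob_cif()
        i = 3
        acc = np.zeros(len(f.time_grid_))
        c = 0
        for tree in f.trees_:
            if tree.inbag_count[i] == 0:
                acc += tree.leaf_cif[tree.apply(X.to_numpy()[[i]])[0], 0, :]
                c += 1
        assert c == count[i]
        np.testing.assert_allclose(cifs[1][i], acc / max(c, 1), atol=1e-12)


class TestTune:
    def test_p1_fixes_mtry(self):
        X, time, status = _rand_cr(80, 17, p=1)
        from crlandmark.landmark import LandmarkDataset
        data = X.assign(patient_id=np.arange(len(X)), time=time, status=status)
        ld = LandmarkDataset(s=0.5, horizon=5.0, features=list(X.columns),
                             data=data)
        m, ns = tune(ld, seed=0, ntree=10, nodesize_grid=(5, 20))
        assert m == 1
        assert ns in (5, 20)

    def test_nodesize_grid_has_28_values(self):
        assert len(NODESIZE_GRID) == 28
        assert NODESIZE_GRID[:10] == (1, 2, 3, 4, 5, 6, 7, 8, 9, 10)
        assert NODESIZE_GRID[-1] == 100

    def test_matches_exhaustive_oracle_on_tiny_grid(self):
        gh = {0: (0.05, 0.05), 1: (0.5, 0.1)}
        X, time, status = simulate_competing_dataset(
            100, seed=18, group_hazards=gh, n_noise=1)
        from crlandmark.landmark import LandmarkDataset
        data = X.assign(patient_id=np.arange(len(X)), time=time, status=status)
        ld = LandmarkDataset(s=0.5, horizon=5.0, features=list(X.columns),
                             data=data)
        grid = (5, 15, 30)
        got = tune(ld, seed=1, ntree=10, nodesize_grid=grid)
        # exhaustive oracle over all mtry x the same nodesize list,
        # using identical per-combination forest seeds
        best = None
        p = len(X.columns)
        for ns in grid:
            for m in range(1, p + 1):
                f = CompetingRiskForest(ntree=10, mtry=m, nodesize=ns,
                                        seed=_combo_seed(1, ns, m)).fit(
                    X, time, status, horizon=5.0)
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    e = f.oob_error()
                err = 0.5 * (e[1] + e[2])
                if best is None or err < best[0]:
                    best = (err, m, ns)
        assert got == (best[1], best[2])


@pytest.fixture(scope="module")
def planted():
    gh = {0: (0.04, 0.06), 1: (0.6, 0.06)}
    X, time, status = simulate_competing_dataset(
        400, seed=19, group_hazards=gh, censor_rate=0.03, n_noise=2)
    X = X.assign(constant=1.0)
    f = CompetingRiskForest(ntree=60, nodesize=20, seed=10).fit(
        X, time, status, horizon=5.0)
    return X, f


class TestVimp:
    def test_planted_signal_ranks_first_for_cause_1(self, planted):
        X, f = planted
        table = vimp(f, seed=0)
        assert table["vimp_eskd"].idxmax() == "group"

    def test_noise_variable_importance_near_zero(self, planted):
        X, f = planted
        table = vimp(f, seed=0)
        assert abs(table.loc["noise0", "vimp_eskd"]) < 0.05

    def test_never_split_variable_has_exactly_zero_importance(self, planted):
        X, f = planted
        const_idx = list(f.columns_).index("constant")
        assert all(const_idx not in t.split_features for t in f.trees_)
        table = vimp(f, seed=0)
        assert table.loc["constant", "vimp_eskd"] == 0.0
        assert table.loc["constant", "vimp_death"] == 0.0
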