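import numpy as np
import pytest

from dateqi.chemometrics import (
    DegenerateResponseError,
    InfeasibleSplitError,
    aggregate_combined,
    compute_metrics,
    cross_validate_lv,
    make_group_folds,
    plsr_fit,
    plsr_predict,
    r_squared,
    round_half_up,
    split_dataset,
)


class TestSplitDataset:
    def test_singleton_groups_exact_partition_counts(self):
        ids = [f"s{i}" for i in range(1000)]
        plan = split_dataset(ids, ids, (0.70, 0.20, 0.10), seed=3)
        assert len(plan.train_ids) == 700
        assert len(plan.test_ids) == 200
        assert len(plan.validation_ids) == 100

    def test_group_integrity(self):
        ids = [f"s{i}" for i in range(12)]
        groups = [f"g{i // 3}" for i in range(12)]  # 4 groups of 3
        plan = split_dataset(ids, groups, (0.5, 0.25, 0.25), seed=0)
        part = plan.partition_of()
        for g in set(groups):
            members = [part[s] for s, gg in zip(ids, groups) if gg == g]
            assert len(set(members)) == 1

    def test_deterministic_under_seed(self):
        ids = [f"s{i}" for i in range(200)]
        groups = [f"g{i // 2}" for i in range(200)]
        assert split_dataset(ids, groups, seed=7) == split_dataset(ids, groups, seed=7)
        assert split_dataset(ids, groups, seed=7) != split_dataset(ids, groups, seed=8)

    def test_partition_property_over_seed_sweep(self):
        ids = [f"s{i}" for i in range(90)]
        groups = [f"g{i // 3}" for i in range(90)]
        for seed in range(100):
            plan = split_dataset(ids, groups, seed=seed)
            a, b, c = set(plan.train_ids), set(plan.test_ids), set(plan.validation_ids)
            assert a | b | c == set(ids)
            assert not (a & b or a & c or b & c)
            part = plan.partition_of()
            for g in set(groups):
                assert len({part[s] for s, gg in zip(ids, groups) if gg == g}) == 1

    def test_oversized_group_is_infeasible(self):
        ids = [f"s{i}" for i in range(10)]
        groups = ["big"] * 5 + [f"g{i}" for i in range(5)]
        with pytest.raises(InfeasibleSplitError):
            split_dataset(ids, groups, (0.6, 0.2, 0.2), seed=0)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(["a"], ["a"], (0.5, 0.3, 0.3), seed=0)


class TestPlsr:
    def test_single_informative_column_matches_univariate_regression(self, rng):
        n = 60
        x = rng.normal(size=n)
        y = 2.0 * x + 0.5 + rng.normal(0, 0.01, n)
        X = np.column_stack([x, rng.normal(0, 1e-12, (n, 4))])  # inert columns
        model = plsr_fit(X, y, 1)
        # closed-form univariate least squares oracle
        xc, yc = x - x.mean(), y - y.mean()
        slope = float(xc @ yc / (xc @ xc))
        pred_oracle = slope * xc + y.mean()
        assert np.allclose(plsr_predict(model, X), pred_oracle, atol=1e-8)

    def test_scores_are_orthogonal(self, rng):
        X = rng.normal(size=(30, 12))
        y = rng.normal(size=30)
        model = plsr_fit(X, y, 5)
        Xc = X - model.x_mean
        T = np.zeros((30, 5))
        for a in range(5):
            t = Xc @ model.weights[:, a]
            Xc = Xc - np.outer(t, model.x_loadings[:, a])
            T[:, a] = t
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8

    def test_full_rank_equals_ols(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        model = plsr_fit(X, y, 5)
        Xd = np.column_stack([np.ones(20), X])
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        assert np.allclose(plsr_predict(model, X), Xd @ beta, atol=1e-6)

    def test_against_reference_implementation(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(40, 15))
        y = X @ rng.normal(size=15) + rng.normal(0, 0.1, 40)
        model = plsr_fit(X, y, 4)
        ref = sklearn.PLSRegression(n_components=4, scale=False).fit(X, y)
        assert np.allclose(
            plsr_predict(model, X), ref.predict(X).ravel(), atol=1e-8
        )

    def test_centering_and_row_permutation(self, rng):
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        model = plsr_fit(X, y, 3)
        assert plsr_predict(model, model.x_mean[None, :])[0] == pytest.approx(
            model.y_mean
        )
        perm = rng.permutation(25)
        assert np.allclose(
            plsr_predict(model, X[perm]), plsr_predict(model, X)[perm]
        )

    def test_degenerate_response_rejected(self, rng):
        with pytest.raises(DegenerateResponseError):
            plsr_fit(rng.normal(size=(10, 3)), np.ones(10), 1)

    def test_json_round_trip(self, rng, tmp_path):
        from dateqi.chemometrics import PLSRModel

        X = rng.normal(size=(20, 8))
        y = rng.normal(size=20)
        model = plsr_fit(X, y, 3)
        path = tmp_path / "plsr.json"
        model.to_json(path)
        back = PLSRModel.from_json(path)
        assert np.allclose(plsr_predict(back, X), plsr_predict(model, X))


class TestCrossValidation:
    def test_noiseless_low_rank_relation_selects_true_rank(self, rng):
        n, p, rank = 60, 15, 2
        T = rng.normal(size=(n, rank))
        P = rng.normal(size=(rank, p))
        X = T @ P
        y = T @ np.array([1.5, -0.7])
        sel = cross_validate_lv(X, y, [f"g{i}" for i in range(n)], 6, 5, seed=0)
        assert sel.selected_lv == rank
        assert sel.rmsecv_per_lv[rank - 1] < 1e-8

    def test_grouped_loo_matches_brute_force(self, rng):
        n = 12
        X = rng.normal(size=(n, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + rng.normal(0, 0.1, n)
        groups = [f"g{i}" for i in range(n)]
        sel = cross_validate_lv(X, y, groups, max_components=3, k_folds=n, seed=1)
        # brute-force leave-one-out oracle, independent of the fold machinery
        preds = np.empty(n)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            m = plsr_fit(X[mask], y[mask], sel.selected_lv)
            preds[i] = plsr_predict(m, X[i : i + 1])[0]
        rmse_oracle = float(np.sqrt(np.mean((preds - y) ** 2)))
        assert sel.rmsecv_per_lv[sel.selected_lv - 1] == pytest.approx(
            rmse_oracle, rel=1e-10
        )

    def test_overfit_prone_noise_prefers_few_components(self, rng):
        n, p = 40, 30
        x = rng.normal(size=n)
        X = np.column_stack([x, rng.normal(size=(n, p - 1))])
        y = x + rng.normal(0, 0.3, n)
        sel = cross_validate_lv(X, y, [f"g{i}" for i in range(n)], 10, 5, seed=2)
        assert sel.selected_lv <= 3
        assert sel.rmsecv_per_lv[-1] > sel.rmsecv_per_lv[sel.selected_lv - 1]

    def test_fewer_groups_than_folds_raises(self, rng):
        X = rng.normal(size=(6, 3))
        y = rng.normal(size=6)
        with pytest.raises(ValueError):
            cross_validate_lv(X, y, ["g1", "g1", "g1", "g2", "g2", "g2"], 2, 5)

    def test_folds_respect_groups(self):
        groups = [f"g{i // 4}" for i in range(40)]
        folds = make_group_folds(groups, 5, seed=9)
        assert sorted(np.concatenate(folds).tolist()) == list(range(40))
        for fold in folds:
            gset = {groups[i] for i in fold}
            for other in folds:
                if other is fold:
                    continue
                assert gset.isdisjoint({groups[i] for i in other})


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0.1, 0.5, 0.9])
        with pytest.warns(UserWarning):
            rep = compute_metrics(y, y, y, y, y, y)
        assert rep.r_squared == 1.0
        assert rep.rmsec == 0.0 and rep.rmsep == 0.0
        assert np.isinf(rep.rer) and np.isinf(rep.rep_percent)

    def test_relative_error_arithmetic(self, rng):
        y = np.array([4.5, 5.5, 4.0, 6.0])  # mean 5.0, range 2.0
        pred = y + np.array([0.5, -0.5, 0.5, -0.5])  # RMSEP 0.5
        rep = compute_metrics(y, pred, y, pred, y, pred)
        assert rep.rmsep == pytest.approx(0.5)
        assert rep.rep_percent == pytest.approx(10.0)
        assert rep.rer == pytest.approx(4.0)

    def test_identities_hold_exactly(self, rng):
        y = rng.uniform(0, 1, 50)
        pred = y + rng.normal(0, 0.05, 50)
        rep = compute_metrics(y, pred, y, pred, y, pred)
        assert rep.rer * rep.rmsep == pytest.approx(rep.y_range, rel=1e-10)
        assert rep.rep_percent * rep.y_mean == pytest.approx(
            100.0 * rep.rmsep, rel=1e-10
        )


class TestAggregateCombined:
    def test_reproduces_printed_summary_row(self):
        per = [
            {"rmsep": 0.256, "rep_percent": 8.12, "rer": 10.6},
            {"rmsep": 0.266, "rep_percent": 8.75, "rer": 9.8},
        ]
        combined = aggregate_combined(per)
        assert combined == {"rmsep": 0.261, "rep_percent": 8.44, "rer": 10.2}

    def test_idempotent_on_identical_inputs(self):
        per = [{"rmsep": 0.3, "rep_percent": 6.0, "rer": 12.0}] * 2
        assert aggregate_combined(per) == {
            "rmsep": 0.3,
            "rep_percent": 6.0,
            "rer": 12.0,
        }

    def test_half_up_rounding(self):
        assert round_half_up(8.435, 2) == 8.44
        assert round_half_up(0.2605, 3) == 0.261
        assert round_half_up(12.95, 1) == 13.0


def test_r_squared_basics(rng):
    y = rng.uniform(size=30)
    assert r_squared(y, y) == 1.0
    assert r_squared(y, np.full(30, y.mean())) == pytest.approx(0.0)
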