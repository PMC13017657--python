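"""Median split, fold plans, elastic net oracles, metrics, regime machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agemod.crossage import (
    REGIMES,
    ElasticNetSpec,
    _prepare_fold,
    compare_regimes,
    evaluate_predictions,
    fisher_z_mean,
    fit_elastic_net,
    make_fold_plan,
    relative_reduction,
    run_generalization,
    split_median,
    subsample_pooled,
    summarize_coefficients_by_category,
    train_elastic_net_nested,
)
from agemod.synthdata import CohortConfig, generate_cohort


class TestSplitMedian:
    def test_four_subjects(self):
        assert split_median(np.array([1.0, 2, 3, 4])).tolist() == [
            "young", "young", "old", "old",
        ]

    def test_odd_n_young_gets_ceiling(self):
        labels = split_median(np.array([10.0, 20, 30, 40, 50]))
        assert (labels == "young").sum() == 3  # ceil(5/2); median tie goes young

    def test_permutation_invariance(self, rng):
        ages = rng.uniform(47, 83, 31)
        perm = rng.permutation(31)
        assert np.array_equal(split_median(ages)[perm], split_median(ages[perm]))

    def test_constant_ages_rejected(self):
        with pytest.raises(ValueError):
            split_median(np.full(10, 60.0))


class TestFoldPlan:
    def test_ten_by_ten_yields_hundred_splits(self, rng):
        groups = split_median(rng.uniform(47, 83, 400))
        plan = make_fold_plan(groups, k=10, repeats=10, seed=0)
        n_splits = sum(
            1 for rep in range(plan.repeats) for _ in range(plan.k)
        )
        assert n_splits == 100
        assert plan.fold_ids["young"].shape == (10, (groups == "young").sum())

    def test_folds_partition_each_group(self, rng):
        groups = split_median(rng.uniform(47, 83, 103))
        plan = make_fold_plan(groups, k=5, repeats=3, seed=1)
        for g in ("young", "old"):
            for rep in range(3):
                seen = np.concatenate(
                    [plan.test_rows(g, rep, f) for f in range(5)]
                )
                assert sorted(seen) == sorted(plan.group_rows[g])
                assert len(set(seen)) == len(seen)

    def test_deterministic_under_seed(self, rng):
        groups = split_median(rng.uniform(47, 83, 60))
        a = make_fold_plan(groups, k=4, repeats=2, seed=9)
        b = make_fold_plan(groups, k=4, repeats=2, seed=9)
        for g in ("young", "old"):
            assert np.array_equal(a.fold_ids[g], b.fold_ids[g])

    def test_group_smaller_than_k(self, rng):
        groups = split_median(np.array([1.0, 2, 3, 4, 5, 6]))
        with pytest.raises(ValueError):
            make_fold_plan(groups, k=10, repeats=1, seed=0)


class TestSubsamplePooled:
    def test_full_and_empty(self):
        pool = np.arange(10)
        assert sorted(subsample_pooled(pool, 10, 0)) == list(range(10))
        assert len(subsample_pooled(pool, 0, 0)) == 0

    def test_target_exceeds_pool(self):
        with pytest.raises(ValueError):
            subsample_pooled(np.arange(3), 4, 0)

    def test_uniform_inclusion_frequency(self):
        pool = np.arange(10)
        counts = np.zeros(10)
        n = 2000
        for seed in range(n):
            counts[subsample_pooled(pool, 5, seed)] += 1
        # each member included ~n/2 times; 4-sigma binomial band
        half = 4 * np.sqrt(0.25 * n)
        assert np.all(np.abs(counts - n / 2) < half)


class TestElasticNetOracles:
    def test_tiny_alpha_recovers_ols(self, rng):
        n, p = 200, 5
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + 0.1 * rng.normal(size=n)
        spec = ElasticNetSpec(alpha_grid=np.array([1e-8]), rho_grid=(0.5,), inner_folds=3)
        fitted = train_elastic_net_nested(X, y, spec, seed=0)
        Xc = np.column_stack([np.ones(n), X])
        ols = np.linalg.lstsq(Xc, y, rcond=None)[0]
        assert np.max(np.abs(fitted.coef - ols[1:])) < 1e-3

    def test_huge_alpha_zeroes_coefficients(self, rng):
        X = rng.normal(size=(100, 4))
        y = rng.normal(size=100)
        model = fit_elastic_net(X, y, alpha=1e6, rho=0.5)
        assert np.allclose(model.coef_, 0.0)

    def test_ridge_closed_form(self, rng):
        # rho=0 with centered data matches (X'X + n alpha I)^-1 X'y
        n, p = 150, 4
        X = rng.normal(size=(n, p))
        X -= X.mean(axis=0)
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        y -= y.mean()
        alpha = 0.3
        model = fit_elastic_net(X, y, alpha, 0.0, fit_intercept=False, tol=1e-12)
        closed = np.linalg.solve(X.T @ X + n * alpha * np.eye(p), X.T @ y)
        assert np.max(np.abs(model.coef_ - closed)) < 1e-6

    def test_objective_never_worse_than_zero_vector(self, rng):
        n, p = 80, 6
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        for alpha, rho in [(0.01, 0.5), (1.0, 0.0), (0.5, 1.0)]:
            m = fit_elastic_net(X, y, alpha, rho, fit_intercept=False)
            b = m.coef_

            def obj(beta):
                return (
                    np.sum((y - X @ beta) ** 2) / (2 * n)
                    + alpha * (rho * np.abs(beta).sum() + (1 - rho) / 2 * beta @ beta)
                )

            assert obj(b) <= obj(np.zeros(p)) + 1e-12

    def test_empty_grid_rejected(self, rng):
        spec = ElasticNetSpec(alpha_grid=np.array([]), rho_grid=())
        with pytest.raises(ValueError):
            train_elastic_net_nested(rng.normal(size=(20, 2)), rng.normal(size=20), spec)


class TestMetrics:
    def test_mean_predictor_zero_gain(self, rng):
        y = rng.normal(size=50)
        m = evaluate_predictions(y, np.full(50, y.mean()))
        assert m["pct_delta_rmse"] == pytest.approx(0.0)

    def test_perfect_prediction(self, rng):
        y = rng.normal(size=50)
        m = evaluate_predictions(y, y)
        assert m["r"] == pytest.approx(1.0)
        assert m["pct_delta_rmse"] == pytest.approx(100.0)

    def test_anticorrelated(self, rng):
        y = rng.normal(size=50)
        y = y - y.mean()
        assert evaluate_predictions(y, -y)["r"] == pytest.approx(-1.0)

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError):
            evaluate_predictions(np.ones(10), np.zeros(10))

    def test_bounds(self, rng):
        for _ in range(10):
            y = rng.normal(size=30)
            pred = rng.normal(size=30)
            m = evaluate_predictions(y, pred)
            assert -1 <= m["r"] <= 1
            assert m["pct_delta_rmse"] <= 100


class TestFisherZ:
    def test_equal_inputs_identity(self):
        assert fisher_z_mean([0.5, 0.5]) == pytest.approx(0.5)

    def test_formula_example(self):
        assert fisher_z_mean([0.0, 0.6]) == pytest.approx(np.tanh(np.arctanh(0.6) / 2))
        assert fisher_z_mean([0.0, 0.6]) == pytest.approx(0.3333, abs=1e-4)

    @settings(max_examples=40, deadline=None)
    @given(
        rs=st.lists(st.floats(-0.99, 0.99), min_size=2, max_size=6),
        idx=st.integers(0, 5),
        bump=st.floats(0.001, 0.05),
    )
    def test_monotone_in_each_element(self, rs, idx, bump):
        idx = idx % len(rs)
        raised = list(rs)
        raised[idx] = min(0.999, raised[idx] + bump)
        assert fisher_z_mean(raised) >= fisher_z_mean(rs) - 1e-12


def _fake_outcomes(r_by_regime: dict, repeats: int = 10, jitter: float = 0.0, seed: int = 0):
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(repeats):
        for (tr, te) in REGIMES:
            name = f"{tr}:{te}"
            rows.append({
                "repeat": rep, "regime": name, "train": tr, "test": te,
                "r": r_by_regime[name] + jitter * rng.normal(),
            })
    return pd.DataFrame(rows)


class TestCompareRegimes:
    def test_all_positive_differences_exact_p(self):
        base = {f"{tr}:{te}": 0.2 for tr, te in REGIMES}
        out = _fake_outcomes(base, jitter=0.01, seed=3)
        out.loc[out.regime == "young:young", "r"] += 0.5  # YY always wins
        res = compare_regimes(out, contrasts=[("young:young", "old:young")])
        assert res["p"].iloc[0] == pytest.approx(0.001953125)  # 2/2^10

    def test_all_zero_differences_p_one(self):
        out = _fake_outcomes({f"{tr}:{te}": 0.2 for tr, te in REGIMES})
        res = compare_regimes(out, contrasts=[("within", "pooled")])
        assert res["p"].iloc[0] == 1.0

    def test_bh_over_contrasts(self):
        # four contrasts engineered so raw p's adjust to a common value
        out = _fake_outcomes({f"{tr}:{te}": 0.2 for tr, te in REGIMES})
        res = compare_regimes(out)
        assert np.all(res["p_bh"] >= res["p"])
        assert list(res["contrast"]) == [
            "within vs pooled", "within vs across", "pooled vs across",
            "young:young vs old:young", "young:old vs old:old",
        ]


class TestCoefficientSummary:
    def test_zero_coefficients(self):
        out = summarize_coefficients_by_category(np.zeros((3, 4)), ["a", "a", "b", "b"])
        assert (out == 0).all()

    def test_relative_reduction_formula(self):
        assert relative_reduction(1.0, 0.683) == pytest.approx(31.7, abs=0.01)

    def test_column_order_invariance(self, rng):
        coefs = rng.normal(size=(5, 6))
        cats = ["a", "b", "a", "b", "a", "b"]
        base = summarize_coefficients_by_category(coefs, cats)
        perm = rng.permutation(6)
        again = summarize_coefficients_by_category(coefs[:, perm], [cats[i] for i in perm])
        assert np.allclose(base.sort_index(), again.sort_index())

    def test_misaligned_labels_rejected(self):
        with pytest.raises(ValueError):
            summarize_coefficients_by_category(np.zeros((2, 4)), ["a", "b"])


@pytest.fixture(scope="module")
def gen_cohort():
    cfg = CohortConfig(
        n_subjects=400,
        n_nuisance_confounds=10,
        idp_category_sizes={"volume": 8, "area": 4},
        trait_count=4,
        base_slope=0.3,
        idp_missing_rate=0.01,
        seed=11,
    )
    return generate_cohort(cfg)


FAST_ENET = ElasticNetSpec(
    alpha_grid=np.logspace(-2, 1, 4), rho_grid=(0.0, 0.5), inner_folds=3
)


class TestRunGeneralization:
    def test_six_regimes_per_repetition_and_pairing(self, gen_cohort):
        groups = split_median(gen_cohort.ages)
        plan = make_fold_plan(groups, k=3, repeats=2, seed=4)
        res = run_generalization(gen_cohort, plan, enet=FAST_ENET, seed=4)
        out = res["outcomes"]
        assert len(out) == 2 * 6
        assert set(out["regime"]) == {f"{a}:{b}" for a, b in REGIMES}
        log = res["fold_log"]
        # pairing contract: same test folds across regimes within a repetition
        for (rep, te), grp in log.groupby(["repeat", "test"]):
            assert grp.groupby("train")["n_test"].apply(tuple).nunique() == 1

    def test_size_matching(self, gen_cohort):
        groups = split_median(gen_cohort.ages)
        plan = make_fold_plan(groups, k=4, repeats=1, seed=2)
        res = run_generalization(gen_cohort, plan, enet=FAST_ENET, seed=2)
        log = res["fold_log"]
        for (rep, fold, te), grp in log.groupby(["repeat", "fold", "test"]):
            pooled_n = grp.loc[grp.train == "pooled", "n_train"].iloc[0]
            within_n = grp.loc[grp.train == te, "n_train"].iloc[0]
            assert pooled_n == within_n

    def test_leakage_guard_bitwise(self, gen_cohort):
        # corrupting test-fold data must leave every training artifact untouched
        groups = split_median(gen_cohort.ages)
        plan = make_fold_plan(groups, k=3, repeats=1, seed=7)
        train_rows = plan.train_rows("young", 0, 0)
        test_rows = plan.test_rows("young", 0, 0)
        traits = list(gen_cohort.traits.columns)
        _, _, _, _, art1 = _prepare_fold(gen_cohort, train_rows, test_rows, 0.85, 4, traits)

        corrupted = gen_cohort
        corrupted.traits.iloc[test_rows] = 999.0
        corrupted.idps.iloc[test_rows] = -999.0
        try:
            _, _, _, _, art2 = _prepare_fold(
                corrupted, train_rows, test_rows, 0.85, 4, traits
            )
        finally:
            # regenerate unharmed fixture state for other tests
            fresh = generate_cohort(gen_cohort.config)
            gen_cohort.traits.iloc[:, :] = fresh.traits
            gen_cohort.idps.iloc[:, :] = fresh.idps

        assert art1["deconfound_idp"].coef.tobytes() == art2["deconfound_idp"].coef.tobytes()
        assert art1["deconfound_traits"].coef.tobytes() == art2["deconfound_traits"].coef.tobytes()
        assert art1["composite"].to_json() == art2["composite"].to_json()
        assert art1["x_mean"].tobytes() == art2["x_mean"].tobytes()
        assert art1["idp_means"].tobytes() == art2["idp_means"].tobytes()

    def test_no_signal_cohort_r_near_zero(self):
        cfg = CohortConfig(
            n_subjects=500,
            n_nuisance_confounds=8,
            idp_category_sizes={"volume": 6},
            trait_count=4,
            base_slope=0.0,  # IDPs carry no cognitive signal
            idp_missing_rate=0.0,
            seed=13,
        )
        cohort = generate_cohort(cfg)
        plan = make_fold_plan(split_median(cohort.ages), k=4, repeats=2, seed=13)
        res = run_generalization(cohort, plan, enet=FAST_ENET, seed=13)
        log = res["fold_log"]
        for regime, grp in log.groupby("regime"):
            rs = grp["r"].to_numpy()
            se = rs.std(ddof=1) / np.sqrt(len(rs))
            assert abs(rs.mean()) < max(2 * se, 0.05)
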