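import itertools

import numpy as np
import pandas as pd
import pytest

from dyadpred import (ModelSpec, Predictor, build_design, build_universe,
                      enumerate_models, fit_lmm, loocv_r2, predict,
                      select_model)
from dyadpred.model_search import (CandidateScore, CapacityError,
                                   choose_candidate, count_subsets,
                                   satisfies_heredity)
from dyadpred.terms import ModelTerm as T


def preds(n_cont, n_bin):
    out = [Predictor(f"x{i+1}", "continuous") for i in range(n_cont)]
    out += [Predictor(f"g{i+1}", "binary") for i in range(n_bin)]
    return out


class TestUniverse:
    def test_counting_formula(self):
        uni = build_universe(preds(4, 2))
        # 6 linear + 4 quadratic + C(6,2)=15 interactions
        assert uni.size == 25

    def test_single_continuous(self):
        uni = build_universe(preds(1, 0))
        assert [t.name for t in uni.terms] == ["x1", "x1^2"]

    def test_exclusions(self):
        ps = preds(4, 2)
        names = [p.name for p in ps]
        excl = [T.interaction("x1", other) for other in names if other != "x1"]
        uni = build_universe(ps, exclusions=excl)
        n_inter = sum(1 for t in uni.terms if t.kind == "interaction")
        assert n_inter == 15 - 5

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_universe([Predictor("x", "continuous"),
                            Predictor("x", "binary")])


class TestEnumeration:
    def test_binomial_count(self):
        uni = build_universe(preds(0, 5))  # 5 linear + 10 interactions... no
        # restrict to 5 linear terms only: binary predictors, no interactions
        uni = build_universe(preds(0, 5),
                             exclusions=[t for t in uni.terms
                                         if t.kind == "interaction"])
        assert uni.size == 5
        specs = list(enumerate_models(uni, "y", max_terms=2,
                                      heredity_interactions=False))
        assert len(specs) == 16  # C(5,0)+C(5,1)+C(5,2)

    def test_heredity_matches_brute_force(self):
        uni = build_universe(preds(1, 1))  # x1, x1^2, g1, x1:g1
        assert uni.size == 4
        specs = {frozenset(s.terms)
                 for s in enumerate_models(uni, "y", max_terms=3,
                                           heredity_interactions=True)}
        brute = set()
        for k in range(4):
            for combo in itertools.combinations(uni.terms, k):
                inter = T.interaction("g1", "x1")
                if inter in combo and not (T.linear("x1") in combo
                                           and T.linear("g1") in combo):
                    continue
                brute.add(frozenset(combo))
        assert specs == brute
        for s in specs:
            assert satisfies_heredity(s)

    def test_max_terms_zero(self):
        uni = build_universe(preds(2, 0))
        specs = list(enumerate_models(uni, "y", max_terms=0))
        assert len(specs) == 1 and specs[0].terms == ()

    def test_budget_capacity_error(self):
        uni = build_universe(preds(10, 10))
        with pytest.raises(CapacityError) as exc:
            list(enumerate_models(uni, "y", max_terms=9, budget=1000))
        assert exc.value.count == count_subsets(uni.size, 9)

    def test_quadratic_heredity_flag(self):
        uni = build_universe(preds(1, 0))
        specs = {frozenset(s.terms)
                 for s in enumerate_models(uni, "y", max_terms=1,
                                           heredity_quadratics=True)}
        assert frozenset({T.quadratic("x1")}) not in specs
        specs2 = {frozenset(s.terms)
                  for s in enumerate_models(uni, "y", max_terms=1)}
        assert frozenset({T.quadratic("x1")}) in specs2


class TestLoocv:
    def test_perfect_linear(self):
        n = 12
        x = np.linspace(-2, 2, n)
        df = pd.DataFrame({"x1": x, "y": 1.0 + 2.0 * x,
                           "therapist_id": [f"T{i}" for i in range(n)]})
        r2, preds_, ok = loocv_r2(df, ModelSpec("y", (T.linear("x1"),)))
        assert ok
        assert r2 == pytest.approx(1.0, abs=1e-8)

    def test_hand_computed_press(self):
        df = pd.DataFrame({"y": [0.0, 0.0, 3.0],
                           "therapist_id": ["a", "b", "c"]})
        r2, preds_, ok = loocv_r2(df, ModelSpec("y"))
        assert ok
        np.testing.assert_allclose(preds_, [1.5, 1.5, 0.0])
        assert r2 == pytest.approx(-1.25)

    def test_matches_naive_refit_oracle(self):
        spec = ModelSpec("y", (T.linear("x1"), T.quadratic("x1")))
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_groups = 8
            df = pd.DataFrame({
                "therapist_id": np.repeat([f"T{j}" for j in range(n_groups)], 2),
                "x1": rng.standard_normal(2 * n_groups)})
            df["y"] = (0.4 * df.x1 - 0.3 * df.x1 ** 2
                       + rng.standard_normal(2 * n_groups))
            r2, got, ok = loocv_r2(df, spec)
            assert ok
            naive = np.empty(len(df))
            for i in range(len(df)):
                train = df.drop(index=i)
                fit = fit_lmm(build_design(train, spec))
                naive[i] = predict(fit, df.iloc[[i]],
                                   "with_group_effects")[0]
            np.testing.assert_allclose(got, naive, atol=1e-10)
            press = np.sum((df.y.to_numpy() - naive) ** 2)
            tss = np.sum((df.y - df.y.mean()) ** 2)
            assert r2 == pytest.approx(1 - press / tss, abs=1e-12)


def _mk_score(terms, aic, r2_train, r2_cv):
    sc = CandidateScore(ModelSpec("y", terms), aic=aic, r2_train=r2_train,
                        r2_cv=r2_cv, converged=True, in_cv_pool=True)
    sc.admissible = (r2_train - r2_cv) <= 0.10
    return sc


class TestSelectionRule:
    def test_second_best_when_first_overfits(self):
        pool = [_mk_score((T.linear("x1"),), aic=100.0, r2_train=0.60,
                          r2_cv=0.45),   # drop 0.15 -> inadmissible
                _mk_score((T.linear("x2"),), aic=105.0, r2_train=0.55,
                          r2_cv=0.50)]   # drop 0.05 -> admissible
        best, note = choose_candidate(pool, 0.10, "absolute")
        assert best.spec.terms == (T.linear("x2"),)
        assert "drop rule" in note

    def test_fallback_when_none_pass(self):
        pool = [_mk_score((T.linear("x1"),), 100.0, 0.6, 0.3),
                _mk_score((T.linear("x2"),), 90.0, 0.7, 0.4)]
        best, note = choose_candidate(pool, 0.10, "absolute")
        assert best.spec.terms == (T.linear("x2"),)  # max r2_cv
        assert "fallback" in note

    def test_aic_tie_broken_by_parsimony(self):
        pool = [_mk_score((T.linear("x1"), T.linear("x2")), 100.0, 0.5, 0.5),
                _mk_score((T.linear("x1"),), 100.0, 0.5, 0.5)]
        best, _ = choose_candidate(pool, 0.10, "absolute")
        assert best.spec.n_terms == 1


@pytest.fixture(scope="module")
def search_frame():
    from dyadpred import generate_prediction_frame
    from dyadpred.synthetic_study import CovariateSpec
    covs = {"x1": CovariateSpec("continuous", "client"),
            "x2": CovariateSpec("continuous", "client"),
            "g1": CovariateSpec("binary", "therapist")}
    true = [(T.linear("x1"), 0.6), (T.quadratic("x2"), 0.5),
            (T.interaction("g1", "x1"), 0.6)]
    frame, truth = generate_prediction_frame(
        true, n_therapists=60, covariates=covs,
        therapist_intercept_sd=0.3, residual_sd=np.sqrt(0.5), seed=5)
    return frame


@pytest.fixture(scope="module")
def small_universe():
    return build_universe([Predictor("x1", "continuous"),
                           Predictor("x2", "continuous"),
                           Predictor("g1", "binary", "therapist")])


class TestSelectModel:
    def test_exhaustive_mode_and_recovery(self, search_frame, small_universe):
        res = select_model(search_frame, small_universe, "y",
                          cv_pool_size=10, seed=0)
        assert res.search_mode == "exhaustive"
        sel = set(res.selected.terms)
        assert {T.linear("x1"), T.quadratic("x2"),
                T.interaction("g1", "x1")} <= sel

    def test_determinism(self, search_frame, small_universe):
        r1 = select_model(search_frame, small_universe, "y",
                          cv_pool_size=5, seed=3)
        r2 = select_model(search_frame, small_universe, "y",
                          cv_pool_size=5, seed=3)
        pd.testing.assert_frame_equal(r1.ledger, r2.ledger)
        assert r1.selected == r2.selected

    def test_guard_consistency(self, search_frame, small_universe):
        res = select_model(search_frame, small_universe, "y",
                          cv_pool_size=10, seed=0)
        sc = res.selected_score()
        if "fallback" not in res.selection_note:
            assert sc.r2_train - sc.r2_cv <= res.drop_threshold + 1e-12

    def test_stepwise_mode_triggered(self, search_frame, small_universe):
        res = select_model(search_frame, small_universe, "y",
                          budget=10, beam_width=8, cv_pool_size=5, seed=0)
        assert res.search_mode == "stepwise"
        sel = set(res.selected.terms)
        assert {T.linear("x1"), T.quadratic("x2"),
                T.interaction("g1", "x1")} <= sel

    def test_empty_universe_rejected(self, search_frame):
        from dyadpred.model_search import TermUniverse
        uni = TermUniverse((), ())
        with pytest.raises(ValueError, match="empty"):
            select_model(search_frame, uni, "y")

    def test_missing_cells_rejected(self, search_frame, small_universe):
        frame = search_frame.copy()
        frame.loc[0, "x1"] = np.nan
        with pytest.raises(ValueError, match="impute"):
            select_model(frame, small_universe, "y")

    def test_train_r2_ge_cv_on_average(self, small_universe):
        from dyadpred import generate_prediction_frame
        from dyadpred.synthetic_study import CovariateSpec
        covs = {"x1": CovariateSpec("continuous", "client"),
                "x2": CovariateSpec("continuous", "client"),
                "g1": CovariateSpec("binary", "therapist")}
        diffs = []
        spec = ModelSpec("y", (T.linear("x1"),))
        for seed in range(50):
            frame, _ = generate_prediction_frame(
                [(T.linear("x1"), 0.5)], n_therapists=25, covariates=covs,
                residual_sd=1.0, seed=seed)
            fit = fit_lmm(build_design(frame, spec))
            r2cv, _, _ = loocv_r2(frame, spec)
            diffs.append(fit.r2_marginal - r2cv)
        assert np.mean(diffs) >= 0.0
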