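import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gutstress as gs
from gutstress.preprocess import ClrEnsemble, abundance_filter, dirichlet_clr
from gutstress.plsda_biomarkers import (
    bh_adjust,
    fit_plsda,
    loo_error,
    loo_select_components,
    sequential_elimination,
    vip_scores,
    welch_enrichment,
)


def make_xy(n=38, p=10, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = (np.arange(n) % 2).astype(float)
    return X, y


class TestFitPlsda:
    def test_first_component_weights_match_closed_form(self):
        X, y = make_xy(p=2, seed=1)
        model = fit_plsda(X, y, A=1)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        assert np.abs(model.weights[:, 0] - w).max() < 1e-8

    def test_perfect_predictor_zero_training_error(self):
        X, y = make_xy(seed=2)
        X *= 0.05  # weak noise background
        X[:, 3] = y  # plant the response as a column
        model = fit_plsda(X, y, A=1)
        assert (model.classify(X) == y).all()

    def test_scores_orthogonal(self):
        X, y = make_xy(p=8, seed=3)
        model = fit_plsda(X, y, A=4)
        T = model.scores
        off = T.T @ T - np.diag(np.diag(T.T @ T))
        assert np.abs(off).max() < 1e-6

    def test_zero_variance_column_dropped_with_warning(self):
        X, y = make_xy(seed=4)
        X[:, 5] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            model = fit_plsda(X, y, A=1)
        assert 5 in model.dropped

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="4 samples"):
            fit_plsda(np.ones((3, 2)), np.array([0, 1, 0]), A=1)

    def test_null_loo_error_near_half(self):
        rng = np.random.default_rng(5)
        errs = []
        for r in range(200):
            X = rng.normal(size=(38, 10))
            y = (np.arange(38) % 2).astype(float)
            errs.append(loo_error(X, y, A=1))
        assert 0.35 <= np.mean(errs) <= 0.65


class TestVip:
    def test_equal_weights_give_unit_vip(self):
        X, y = make_xy(p=2, seed=6)
        model = fit_plsda(X, y, A=1)
        model.weights = np.array([[np.sqrt(0.5)], [np.sqrt(0.5)]])
        vip = vip_scores(model)
        assert np.allclose(vip, 1.0)

    def test_hand_computed_one_component(self):
        X, y = make_xy(p=2, seed=7)
        model = fit_plsda(X, y, A=1)
        model.weights = np.array([[0.6], [0.8]])
        vip = vip_scores(model)
        assert vip.to_numpy() == pytest.approx([0.8485, 1.1314], abs=1e-4)

    def test_normalization_identity(self):
        X, y = make_xy(p=12, seed=8)
        model = fit_plsda(X, y, A=3)
        vip = vip_scores(model)
        assert (vip**2).sum() == pytest.approx(12, abs=1e-6)

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 10_000))
    def test_normalization_property(self, seed):
        X, y = make_xy(p=6, seed=seed)
        model = fit_plsda(X, y, A=2)
        assert (vip_scores(model) ** 2).sum() == pytest.approx(6, abs=1e-6)


class TestLooSelect:
    def test_perfect_predictor_selects_one_component(self):
        X, y = make_xy(seed=9)
        X *= 0.05
        X[:, 0] = y + 0.01 * np.random.default_rng(9).normal(size=38)
        a_star, errs = loo_select_components(X, y, A_max=3)
        assert a_star == 1 and errs[1] == 0.0

    def test_tie_goes_to_smallest(self):
        X, y = make_xy(seed=10)
        X *= 0.05
        X[:, 0] = y  # every A achieves 0 error
        a_star, errs = loo_select_components(X, y, A_max=3)
        assert a_star == min(a for a, e in errs.items() if e == min(errs.values()))
        assert a_star == 1


class TestSequentialElimination:
    def test_all_high_vip_stops_immediately(self):
        # 3 equally informative predictors: VIPs all ~1 >= 0.8
        rng = np.random.default_rng(11)
        y = (np.arange(38) % 2).astype(float)
        X = np.column_stack([y * 2 - 1 + 0.3 * rng.normal(size=38) for _ in range(3)])
        res = sequential_elimination(pd.DataFrame(X), y)
        assert len(res.rounds) == 1
        assert res.final_genera == [0, 1, 2]
        assert res.stop_reason == "no genus below VIP cut"

    def test_all_noise_terminates_without_spurious_discrimination(self):
        X, y = make_xy(n=38, p=30, seed=12)
        res = sequential_elimination(pd.DataFrame(X), y)
        assert len(res.rounds) <= 30
        assert res.final_loo_error >= 0.35

    def test_too_few_genera_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            sequential_elimination(pd.DataFrame(np.ones((5, 1))), np.zeros(5))

    def test_recovery_of_planted_genera(self):
        hits = 0
        n_rep = 10
        for r in range(n_rep):
            design = gs.CohortDesign(seed=2000 + r, sites=("caecum",), n_genera=50)
            truth = gs.default_truth(design, n_enriched=3, n_depleted=2, effect_size=1.5)
            counts, meta = gs.generate_counts(design, truth)
            labels = meta[meta.site == "caecum"]["treatment"].to_numpy()
            tab, _ = abundance_filter(counts["caecum"])
            ens = dirichlet_clr(tab, K=32, seed=r)
            res = sequential_elimination(ens.mean, (labels == "stress").astype(float))
            planted = set(truth.enriched) | set(truth.depleted)
            hits += len(planted & set(res.final_genera)) >= 4
        assert hits / n_rep >= 0.8


def single_instance_ensemble(matrix, genera):
    inst = np.asarray(matrix, dtype=float)[None, :, :]
    samples = [f"s{i}" for i in range(inst.shape[1])]
    return ClrEnsemble(inst, samples, genera)


class TestWelchEnrichment:
    def test_hand_computed_welch(self):
        # groups {1,2,3} vs {4,5,6}: t = -3.674, df = 4, p = 0.0214
        vals = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        mat = np.column_stack([vals, -vals / 2, -vals / 2])  # rows sum to 0
        ens = single_instance_ensemble(mat, ["g0", "g1", "g2"])
        labels = ["stress"] * 3 + ["control"] * 3
        rep = welch_enrichment(ens, labels, ["g0"])
        assert rep.loc["g0", "p_welch"] == pytest.approx(0.0214, abs=2e-4)
        assert rep.loc["g0", "direction"] == "depleted"

    def test_zero_difference_direction_none(self):
        mat = np.array([[1, -1, 0], [0, 1, -1], [1, 0, -1], [0, -1, 1]], dtype=float)
        ens = single_instance_ensemble(mat, ["g0", "g1", "g2"])
        labels = ["stress", "stress", "control", "control"]
        rep = welch_enrichment(ens, labels, ["g0"])
        assert rep.loc["g0", "effect_sd"] == 0.0
        assert rep.loc["g0", "direction"] == "none"

    def test_direction_consistent_with_sign(self, caecum):
        table, meta = caecum
        tab, _ = abundance_filter(table)
        ens = dirichlet_clr(tab, K=8, seed=0)
        labels = meta["treatment"].to_numpy()
        rep = welch_enrichment(ens, labels)
        s = ens.mean.loc[:, rep.index][labels == "stress"].mean()
        c = ens.mean.loc[:, rep.index][labels == "control"].mean()
        signs = np.sign(s - c)
        enriched = rep["direction"] == "enriched"
        assert (signs[enriched.to_numpy()] > 0).all()

    def test_small_group_rejected(self):
        mat = np.zeros((3, 2))
        ens = single_instance_ensemble(mat, ["g0", "g1"])
        with pytest.raises(ValueError, match="at least 2"):
            welch_enrichment(ens, ["stress", "control", "control"], ["g0"])

    def test_unknown_genus_rejected(self, caecum):
        table, meta = caecum
        ens = dirichlet_clr(table, K=2, seed=0)
        with pytest.raises(ValueError, match="not in ensemble"):
            welch_enrichment(ens, meta["treatment"].to_numpy(), ["NotAGenus"])


def test_bh_adjust_matches_definition():
    p = np.array([0.01, 0.02, 0.03, 0.5])
    q = bh_adjust(p)
    assert q == pytest.approx([0.04, 0.04, 0.04, 0.5])
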