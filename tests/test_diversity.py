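import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gutstress.diversity import (
    alpha_diversity,
    bray_curtis,
    mixed_contrast,
    permanova,
    within_group_dissimilarity,
)


class TestAlphaDiversity:
    def test_uniform_counts_give_evenness_one(self):
        df = pd.DataFrame([[3] * 10], index=["s"])
        out = alpha_diversity(df)
        assert out.loc["s", "adjusted_shannon"] == pytest.approx(1.0)
        assert out.loc["s", "observed_genera"] == 10

    def test_single_genus_degenerate(self):
        out = alpha_diversity(pd.DataFrame([[9, 0, 0]], index=["s"]))
        assert out.loc["s", "observed_genera"] == 1
        assert out.loc["s", "adjusted_shannon"] == 0.0

    def test_hand_computed_shannon(self):
        out = alpha_diversity(pd.DataFrame([[2, 2, 4]], index=["s"]))
        assert out.loc["s", "adjusted_shannon"] == pytest.approx(0.9464, abs=1e-4)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            alpha_diversity(pd.DataFrame([[0, 0]], index=["s"]))

    def test_bounds(self, caecum):
        table, _ = caecum
        out = alpha_diversity(table.counts)
        assert ((out["adjusted_shannon"] >= 0) & (out["adjusted_shannon"] <= 1)).all()
        assert (out["observed_genera"] <= table.n_genera).all()


class TestMixedContrast:
    def test_zero_litter_variance_collapses_to_ols(self):
        rng = np.random.default_rng(1)
        n = 38
        grp = np.where(np.arange(n) % 2 == 0, "stress", "control")
        lit = np.array([f"L{i % 9}" for i in range(n)])
        y = 2.0 * (grp == "control") + rng.normal(0, 1, n)
        mc = mixed_contrast(y, grp, lit)
        ols = y[grp == "control"].mean() - y[grp == "stress"].mean()
        assert mc.estimate == pytest.approx(ols, abs=1e-6)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(2)
        n, q = 38, 9
        grp = np.where(np.arange(n) % 2 == 0, "stress", "control")
        lit = np.array([f"L{i % q}" for i in range(n)])
        ests = []
        for _ in range(200):
            u = rng.normal(0, 1, q)
            y = 1.0 * (grp == "control") + u[np.arange(n) % q] + rng.normal(0, 1, n)
            ests.append(mixed_contrast(y, grp, lit).estimate)
        assert np.mean(ests) == pytest.approx(1.0, abs=0.15)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(3)
        n, q = 38, 9
        grp = np.where(np.arange(n) % 2 == 0, "stress", "control")
        lit = np.array([f"L{i % q}" for i in range(n)])
        rej = 0
        n_rep = 200
        for _ in range(n_rep):
            y = rng.normal(0, 1, q)[np.arange(n) % q] + rng.normal(0, 1, n)
            rej += mixed_contrast(y, grp, lit).pvalue < 0.05
        assert 0.02 <= rej / n_rep <= 0.09

    def test_single_litter_falls_back_to_ols(self):
        rng = np.random.default_rng(4)
        n = 10
        grp = np.repeat(["stress", "control"], 5)
        y = rng.normal(0, 1, n)
        mc = mixed_contrast(y, grp, np.repeat("L1", n))
        assert mc.method == "ols"

    def test_lsmeans_match_estimate(self):
        rng = np.random.default_rng(5)
        n = 20
        grp = np.repeat(["stress", "control"], 10)
        lit = np.array([f"L{i % 4}" for i in range(n)])
        mc = mixed_contrast(rng.normal(0, 1, n), grp, lit)
        assert mc.lsmeans["control"][0] - mc.lsmeans["stress"][0] == pytest.approx(mc.estimate)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        d = bray_curtis(np.array([[0.2, 0.8], [0.2, 0.8]]))
        assert d.iloc[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        d = bray_curtis(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_hand_computed(self):
        d = bray_curtis(np.array([[6.0, 2.0], [2.0, 2.0]]))
        assert d.iloc[0, 1] == pytest.approx(4 / 12)

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.lists(st.floats(0, 10), min_size=3, max_size=3).filter(lambda r: sum(r) > 0),
            min_size=2,
            max_size=6,
        )
    )
    def test_symmetry_range_zero_diagonal(self, rows):
        d = bray_curtis(np.asarray(rows)).to_numpy()
        assert np.allclose(d, d.T)
        assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()
        assert np.allclose(np.diag(d), 0.0)


class TestPermanova:
    def brute_force_single_factor(self, D, labels):
        # independent oracle: classical within/between partition from pairwise distances
        D = np.asarray(D, dtype=float)
        n = D.shape[0]
        iu = np.triu_indices(n, 1)
        ss_total = (D[iu] ** 2).sum() / n
        ss_within = 0.0
        for g in np.unique(labels):
            idx = np.where(labels == g)[0]
            sub = D[np.ix_(idx, idx)]
            ss_within += (sub[np.triu_indices(idx.size, 1)] ** 2).sum() / idx.size
        a = np.unique(labels).size
        ss_between = ss_total - ss_within
        return (ss_between / (a - 1)) / (ss_within / (n - a))

    def test_matches_independent_formula(self):
        rng = np.random.default_rng(6)
        X = np.abs(rng.normal(size=(10, 4)))
        labels = np.repeat(["a", "b"], 5)
        D = bray_curtis(X).to_numpy()
        res = permanova(D, labels, n_perm=9, seed=0)
        assert res.pseudo_f("treatment") == pytest.approx(
            self.brute_force_single_factor(D, labels), rel=1e-10
        )

    def test_exhaustive_duplicated_points(self):
        # two groups of duplicated identical points: F is maximal, p = m/n! with
        # m = 8 label-preserving permutations of 4 samples
        D = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], dtype=float
        )
        labels = np.array(["a", "a", "b", "b"])
        res = permanova(D, labels, permutations="exhaustive")
        assert res.pvalue("treatment") == pytest.approx(8 / 24)

    def test_exhaustive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        X = np.abs(rng.normal(size=(4, 3)))
        labels = np.array(["a", "a", "b", "b"])
        D = bray_curtis(X).to_numpy()
        res = permanova(D, labels, permutations="exhaustive")
        f_obs = self.brute_force_single_factor(D, labels)
        count = sum(
            self.brute_force_single_factor(D, labels[list(p)]) >= f_obs - 1e-12
            for p in itertools.permutations(range(4))
        )
        assert res.pvalue("treatment") == pytest.approx(count / 24)

    def test_ss_partition_exact(self, caecum):
        table, meta = caecum
        D = bray_curtis(table.relative_abundance()).to_numpy()
        res = permanova(D, meta["treatment"], meta["litter"], n_perm=49, seed=0)
        t = res.table
        parts = t.loc[["litter", "treatment", "Residual"], "ss"].sum()
        assert parts == pytest.approx(t.loc["Total", "ss"], rel=1e-10)

    def test_null_calibration(self):
        rng = np.random.default_rng(8)
        rej = 0
        n_rep = 100
        for r in range(n_rep):
            X = np.abs(rng.normal(size=(20, 8)))
            labels = np.repeat(["a", "b"], 10)
            res = permanova(bray_curtis(X).to_numpy(), labels, n_perm=199, seed=r)
            rej += res.pvalue("treatment") <= 0.05
        assert 0.01 <= rej / n_rep <= 0.10

    def test_planted_effect_detected(self):
        import gutstress as gs

        hits = 0
        n_rep = 10
        for r in range(n_rep):
            design = gs.CohortDesign(seed=40 + r, sites=("caecum",))
            truth = gs.default_truth(design, effect_size=3.0)  # large clr shift
            counts, meta = gs.generate_counts(design, truth)
            m = meta[meta.site == "caecum"]
            D = bray_curtis(counts["caecum"].relative_abundance()).to_numpy()
            res = permanova(D, m["treatment"], m["litter"], n_perm=199, seed=r)
            hits += res.pvalue("treatment") <= 0.05
        assert hits / n_rep >= 0.9

    def test_fixed_seed_identical_p(self, caecum):
        table, meta = caecum
        D = bray_curtis(table.relative_abundance()).to_numpy()
        a = permanova(D, meta["treatment"], n_perm=99, seed=12)
        b = permanova(D, meta["treatment"], n_perm=99, seed=12)
        assert a.pvalue("treatment") == b.pvalue("treatment")

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            permanova(np.array([[0, 1.0], [0.5, 0]]), ["a", "b"])

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            permanova(np.zeros((2, 3)), ["a", "b"])


class TestWithinGroupDissimilarity:
    def test_identical_points_zero(self):
        D = np.zeros((4, 4))
        out = within_group_dissimilarity(D, ["a", "a", "b", "b"])
        assert (out == 0).all()

    def test_hand_computed_three_samples(self):
        D = np.array([[0, 0.2, 0.4], [0.2, 0, 0.6], [0.4, 0.6, 0]])
        out = within_group_dissimilarity(D, ["g", "g", "g"])
        assert out["g"] == pytest.approx((0.2 + 0.4 + 0.6) / 3)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            within_group_dissimilarity(np.zeros((3, 3)), ["a", "a", "b"])
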