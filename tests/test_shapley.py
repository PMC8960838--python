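"""Shapley attribution: efficiency, oracle equivalence, pruning, aggregation."""

import numpy as np
import pandas as pd
import pytest

from evlock import decoding as dec
from evlock import shapley as shp
from evlock import simulate as sim
from oracles import brute_force_tree_shapley


def toy_feature_matrix(rng, n=300, m=8, signal_cols=(0, 1, 2)):
    X = rng.normal(size=(n, m))
    logits = sum(X[:, j] for j in signal_cols)
    y = (logits + 0.5 * rng.normal(size=n) > 0).astype(int)
    cols = [(f"R{j:03d}", 0) for j in range(m)]
    return dec.FeatureMatrix(X=X, y=y, columns=cols, classes=("a", "b"))


@pytest.fixture(scope="module")
def toy_model():
    rng = np.random.default_rng(0)
    feats = toy_feature_matrix(rng)
    model = shp.fit_gbdt(feats, seed=0, n_estimators=15, num_leaves=7, n_jobs=1)
    return model, feats


class TestTreeExact:
    def test_efficiency_row_sums(self, toy_model):
        model, feats = toy_model
        sh = shp.shapley_values(model, feats, "tree-exact")
        assert sh.efficiency_gap < 1e-6

    def test_matches_exhaustive_coalition_enumeration(self, toy_model):
        """Tree-exact contributions equal the 2^M brute force on the dumped
        trees (same cover-weighted value function), near machine precision;
        summing per-tree oracles also exercises the additivity property."""
        model, feats = toy_model
        sh = shp.shapley_values(model, feats, "tree-exact")
        for i in (0, 3, 11):
            phi, base = brute_force_tree_shapley(model.booster_, feats.X[i])
            np.testing.assert_allclose(sh.values[i], phi, atol=1e-9)
            assert sh.base_values[i] == pytest.approx(base, abs=1e-9)

    def test_unused_feature_has_zero_contribution(self, rng):
        feats = toy_feature_matrix(rng, m=6, signal_cols=(0,))
        feats.X[:, 5] = 0.0  # constant: no split can use it
        model = shp.fit_gbdt(feats, seed=1, n_estimators=10, n_jobs=1)
        sh = shp.shapley_values(model, feats)
        assert np.abs(sh.values[:, 5]).max() == 0.0

    def test_non_tree_model_rejected(self, rng):
        from sklearn.linear_model import LogisticRegression

        feats = toy_feature_matrix(rng, n=60, m=4)
        lr = LogisticRegression().fit(feats.X, feats.y)
        with pytest.raises(TypeError):
            shp.shapley_values(lr, feats, "tree-exact")


class TestSamplingAndBruteForce:
    def test_linear_model_closed_form(self, rng):
        """For f = theta0 + theta.x the Shapley value of feature j is
        theta_j (x_j - E X_j)."""
        theta = np.array([1.5, -2.0, 0.7])
        background = rng.normal(size=(200, 3))

        class Linear:
            def predict(self, X):
                return 0.3 + np.asarray(X) @ theta

        X = rng.normal(size=(5, 3))
        sh = shp.shapley_values(
            Linear(), X, "sampling", n_samples=1500, background=background,
            seed=0,
        )
        # Monte-Carlo error ~ |theta_j| / sqrt(n_samples)
        expected = theta * (X - background.mean(axis=0))
        np.testing.assert_allclose(sh.values, expected, atol=0.2)

    def test_sampling_efficiency_exact_per_row(self, rng):
        class Nonlinear:
            def predict(self, X):
                X = np.asarray(X)
                return np.tanh(X[:, 0]) * X[:, 1] + X[:, 2] ** 2

        X = rng.normal(size=(4, 3))
        sh = shp.shapley_values(
            Nonlinear(), X, "sampling", n_samples=100,
            background=rng.normal(size=(50, 3)), seed=1,
        )
        assert sh.efficiency_gap < 1e-10

    def test_bruteforce_symmetry_and_efficiency(self, rng):
        def f(X):
            X = np.asarray(X)
            return X[:, 0] + X[:, 1] + 0.5 * X[:, 2] * X[:, 3]

        # symmetry needs exchangeable marginals: center the background so
        # features 0 and 1 see identical value functions
        background = rng.normal(size=(64, 4))
        background[:, :2] -= background[:, :2].mean(axis=0)
        x = np.array([1.0, 1.0, 0.5, -0.3])
        phi = shp.exact_shapley_bruteforce(f, x, background)
        # features 0 and 1 enter identically and share the same value here
        assert phi[0] == pytest.approx(phi[1], abs=1e-9)
        v_full = f(x[None, :])[0]
        v_base = f(background).mean()
        assert phi.sum() == pytest.approx(v_full - v_base, abs=1e-9)

    def test_bruteforce_single_feature_and_constant_model(self, rng):
        background = rng.normal(size=(32, 1))
        phi = shp.exact_shapley_bruteforce(
            lambda X: 3.0 * np.asarray(X)[:, 0], np.array([2.0]), background
        )
        assert phi[0] == pytest.approx(6.0 - 3.0 * background.mean(), abs=1e-9)
        const = shp.exact_shapley_bruteforce(
            lambda X: np.full(len(X), 1.7), np.array([0.5]), background
        )
        assert const[0] == pytest.approx(0.0, abs=1e-12)

    def test_sampling_matches_bruteforce_oracle(self, rng):
        def f(X):
            X = np.asarray(X)
            return X[:, 0] * X[:, 1] + 2.0 * X[:, 2]

        background = rng.normal(size=(40, 3))
        x = rng.normal(size=3)

        class M:
            predict = staticmethod(f)

        sh = shp.shapley_values(
            M(), x[None, :], "sampling", n_samples=2000,
            background=background, seed=2,
        )
        oracle = shp.exact_shapley_bruteforce(f, x, background)
        np.testing.assert_allclose(sh.values[0], oracle, atol=0.08)

    def test_too_many_features_rejected(self, rng):
        with pytest.raises(ValueError):
            shp.exact_shapley_bruteforce(
                lambda X: np.zeros(len(X)), np.zeros(13), rng.normal(size=(4, 13))
            )


class TestRankingAndPruning:
    def test_keep_fraction_one_is_identity(self, toy_model):
        model, feats = toy_model
        sh = shp.shapley_values(model, feats)
        ranking = shp.rank_features(sh)
        res = shp.prune_and_retrain(
            {"name": "gbdt", "n_estimators": 15}, feats, ranking, 1.0,
            dec.CVConfig(tune="none", seed=0),
        )
        assert len(res.kept_columns) == feats.n_features
        np.testing.assert_array_equal(res.kept_columns, np.arange(feats.n_features))

    def test_zero_retention_rejected(self, toy_model):
        model, feats = toy_model
        ranking = shp.rank_features(shp.shapley_values(model, feats))
        with pytest.raises(ValueError):
            shp.prune_and_retrain("gbdt", feats, ranking, 0.01)

    def test_ranking_descending_with_stable_ties(self, rng):
        sh = shp.ShapleyMatrix(
            values=np.array([[0.5, -0.5, 0.2, 0.0]]),
            base_values=np.zeros(1),
            raw_output=np.array([0.2]),
            columns=[("R", i) for i in range(4)],
        )
        ranking = shp.rank_features(sh)
        assert list(ranking.index[:2]) == [0, 1]  # tie 0.5 broken by column
        assert list(ranking["mean_abs_phi"]) == sorted(
            ranking["mean_abs_phi"], reverse=True
        )

    def test_keep_sweep_auc_curve(self, toy_model):
        """AUC as a function of retained-feature fraction is reported for
        each sweep point (pruning-curve export)."""
        model, feats = toy_model
        ranking = shp.rank_features(shp.shapley_values(model, feats))
        rows = []
        for frac in (0.25, 0.5, 1.0):
            res = shp.prune_and_retrain(
                {"name": "gbdt", "n_estimators": 15}, feats, ranking, frac,
                dec.CVConfig(tune="none", seed=0),
            )
            rows.append((frac, res.post.mean_auc))
        assert all(0.0 <= auc <= 1.0 for _, auc in rows)
        assert len({len(r) for r in rows}) == 1

    def test_signal_features_ranked_first(self, rng):
        feats = toy_feature_matrix(rng, n=500, m=10, signal_cols=(2, 7))
        model = shp.fit_gbdt(feats, seed=2, n_estimators=40, n_jobs=1)
        ranking = shp.rank_features(shp.shapley_values(model, feats))
        assert set(ranking.index[:2]) == {2, 7}


class TestAggregation:
    def make_matrix(self, values, regions=("Ra", "Rb"), offsets=(0, 5)):
        cols = [(r, o) for r in regions for o in offsets]
        values = np.asarray(values, dtype=float)
        return shp.ShapleyMatrix(
            values=values,
            base_values=np.zeros(len(values)),
            raw_output=values.sum(axis=1),
            columns=cols,
        )

    def test_zero_matrix_aggregates_to_zero(self):
        sh = self.make_matrix(np.zeros((3, 4)))
        by_tr = shp.aggregate_shapley(sh, by="tr")
        assert (by_tr["weight"] == 0).all()

    def test_single_active_column_localized(self):
        vals = np.zeros((4, 4))
        vals[:, 1] = 2.0  # (Ra, offset 5)
        sh = self.make_matrix(vals)
        by_tr = shp.aggregate_shapley(sh, by="tr")
        active = by_tr[by_tr["weight"] > 0]
        assert len(active) == 1
        assert (active.iloc[0]["tr_offset"], active.iloc[0]["region"]) == (5, "Ra")
        sums = shp.aggregate_shapley(sh, by="region", window=(5, 5))
        assert sums["Ra"] == pytest.approx(2.0)
        assert sums["Rb"] == pytest.approx(0.0)

    def test_window_restricts_region_sums(self):
        vals = np.ones((2, 4))
        sh = self.make_matrix(vals)
        early = shp.aggregate_shapley(sh, by="region", window=(0, 4))
        assert early["Ra"] == pytest.approx(1.0)  # only offset 0 in window

    def test_window_outside_offsets_rejected(self):
        sh = self.make_matrix(np.ones((2, 4)))
        with pytest.raises(ValueError):
            shp.aggregate_shapley(sh, by="region", window=(6, 11))

    def test_normalized_weights_sum_to_one(self, rng):
        sh = self.make_matrix(rng.normal(size=(10, 4)))
        by_tr = shp.aggregate_shapley(sh, by="tr", normalize=True)
        assert by_tr["weight"].sum() == pytest.approx(1.0, abs=1e-12)


class TestShapleyVsArea:
    def area_table(self, regions, areas, maxima):
        return pd.DataFrame(
            {"delta_area": areas, "has_maxima": maxima},
            index=pd.Index(regions, name="region"),
        )

    def test_quadrant_flags(self):
        sums = pd.Series([0.4, 0.1], index=["Ra", "Rb"])
        table = shp.shapley_vs_area(
            sums, self.area_table(["Ra", "Rb"], [0.9, 0.2], [True, False]),
            critical=0.5,
        )
        assert bool(table.loc["Ra", "exceeds_critical"])
        assert bool(table.loc["Ra", "has_maxima"])
        assert not bool(table.loc["Rb", "exceeds_critical"])
        assert not bool(table.loc["Rb", "has_maxima"])

    def test_trough_contrast_high_shapley_without_maxima(self):
        """A late trough-depth contrast drives the classifier (high Shapley)
        but fails the two-maxima requirement of the mean-signal screen."""
        classes = ("POScorr", "LURfalse")
        noise = sim.NoiseSpec(0.3, 1.0, 0.0)
        mean_a = np.zeros((2, 12))
        mean_b = np.zeros((2, 12))
        mean_b[0, 9:] = -0.8  # deeper late trough in region 0, no peak
        t = sim.sample_trials(
            {classes[0]: mean_a, classes[1]: mean_b},
            {c: 300 for c in classes}, noise, 0,
        )
        feats = dec.build_features(t, classes)
        model = shp.fit_gbdt(feats, seed=0, n_estimators=40, n_jobs=1)
        sh = shp.shapley_values(model, feats)
        sums = shp.aggregate_shapley(sh, by="region", window=(5, 9))
        assert sums.idxmax() == "R000"
        assert sums["R000"] > 2 * sums["R001"]

        from evlock import curves, inference as inf

        # the mean-signal screen uses the noise-free class patterns: a
        # trough has no in-window maximum by construction
        times = np.arange(-2.0, 10.0)
        pairs = {
            rid: (
                curves.interpolate(times, mean_a[i]),
                curves.interpolate(times, mean_b[i]),
            )
            for i, rid in enumerate(t.region_ids)
        }
        criteria = inf.SelectionCriteria(maxima_window=(5, 9), area_window=(5, 9))
        area = inf.select_area_regions(pairs, 0.05, criteria)
        paired = shp.shapley_vs_area(sums, area[["delta_area", "has_maxima"]],
                                     critical=0.05)
        assert not bool(paired.loc["R000", "has_maxima"])
        assert bool(paired.loc["R000", "exceeds_critical"])

    def test_empty_input_gives_empty_table(self):
        table = shp.shapley_vs_area(
            pd.Series(dtype=float), self.area_table([], [], []), 0.5
        )
        assert len(table) == 0

    def test_region_mismatch_rejected(self):
        with pytest.raises(ValueError):
            shp.shapley_vs_area(
                pd.Series([1.0], index=["Ra"]),
                self.area_table(["Rb"], [0.1], [True]),
                0.5,
            )
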