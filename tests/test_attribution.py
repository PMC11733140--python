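import numpy as np
import pytest

from chemxplain import (
    FeatureCatalog,
    LocalAttribution,
    SyntheticSpec,
    exact_shapley,
    fit_surrogate,
    generate_synthetic,
    global_importance,
    globalize,
    lime_sample,
    local_lime,
    local_tree_shap,
    top_k,
)
from chemxplain.attribution import export_importance_plot
from chemxplain._treeshap import parse_booster


def _small_fitted(seed=0, d=4, n=200, noise=0.2):
    spec = SyntheticSpec(
        n=n, d=d, planted_support=[0, 2], planted_weights=[1.5, -1.0],
        noise_sd=noise, seed=seed,
    )
    t = generate_synthetic(spec)
    model, _ = fit_surrogate(t, split_seed=seed)
    return model, t


class TestExactShapleyOracle:
    def test_additive_model_splits_credit(self, margin_model_factory):
        model = margin_model_factory(lambda x: x[0] + x[1], 2)
        phi = exact_shapley(model, np.array([1.0, 1.0]), np.zeros((1, 2)))
        np.testing.assert_allclose(phi, [1.0, 1.0], atol=1e-12)

    def test_symmetry_axiom(self, margin_model_factory):
        model = margin_model_factory(lambda x: x[0] * x[1], 2)
        phi = exact_shapley(model, np.array([1.0, 1.0]), np.zeros((1, 2)))
        assert phi[0] == pytest.approx(phi[1])
        assert phi.sum() == pytest.approx(1.0)

    def test_efficiency_identity_on_ensemble(self):
        model, t = _small_fitted(seed=3)
        rng = np.random.default_rng(0)
        bg = t.features[rng.choice(t.n, 8, replace=False)]
        row = t.features[17]
        phi = exact_shapley(model, row, bg)
        expected = model.predict_margin(row[None, :])[0] - model.predict_margin(bg).mean()
        assert phi.sum() == pytest.approx(expected, abs=1e-8)

    def test_dimension_cap(self, margin_model_factory):
        model = margin_model_factory(sum, 13)
        with pytest.raises(ValueError, match="d <= 12"):
            exact_shapley(model, np.zeros(13), np.zeros((1, 13)))


class TestTreeShap:
    def test_matches_exact_enumeration(self):
        """Closed-form interventional tree Shapley == subset enumeration."""
        model, t = _small_fitted(seed=1)
        bg = t.features[:8]
        rows = t.features[10:16]
        local = local_tree_shap(model, rows, background=bg)
        for i in range(len(rows)):
            oracle = exact_shapley(model, rows[i], bg)
            np.testing.assert_allclose(local.values[i], oracle, atol=1e-6)

    def test_local_accuracy_every_row(self):
        model, t = _small_fitted(seed=2)
        local = local_tree_shap(model, t.features[:50], background=t.features)
        preds = model.predict_margin(t.features[:50])
        np.testing.assert_allclose(
            local.base_values + local.values.sum(axis=1), preds, atol=1e-6
        )

    def test_constant_model_attributes_nothing(self):
        spec = SyntheticSpec(n=60, d=3, planted_support=[0], planted_weights=[0.0], seed=0)
        t = generate_synthetic(spec)  # labels identically zero
        model, _ = fit_surrogate(t, split_seed=0)
        local = local_tree_shap(model, t.features[:10], background=t.features)
        np.testing.assert_allclose(local.values, 0.0, atol=1e-8)

    def test_unused_features_get_zero(self):
        model, t = _small_fitted(seed=4, d=6)
        used = set()
        for leaf in parse_booster(model.booster_, model.feature_names_):
            used.update(leaf.feats.tolist())
        unused = [j for j in range(t.d) if j not in used]
        local = local_tree_shap(model, t.features[:30], background=t.features)
        for j in unused:
            np.testing.assert_allclose(local.values[:, j], 0.0)

    def test_classification_space_is_margin(self, fitted_classification, classification_table):
        model, _ = fitted_classification
        local = local_tree_shap(
            model, classification_table.features[:10], background=classification_table.features
        )
        assert local.metadata["space"] == "margin"
        margins = model.predict_margin(classification_table.features[:10])
        np.testing.assert_allclose(
            local.base_values + local.values.sum(axis=1), margins, atol=1e-6
        )

    def test_schema_mismatch_rejected(self):
        model, t = _small_fitted(seed=5)
        with pytest.raises(ValueError, match="schema"):
            local_tree_shap(model, t.features[:3, :2])


class TestLimeSample:
    def test_caps_at_500(self):
        spec = SyntheticSpec(n=1200, d=3, planted_support=[0], planted_weights=[1.0], seed=0)
        assert len(lime_sample(generate_synthetic(spec), seed=1)) == 500

    def test_small_datasets_taken_whole(self):
        spec = SyntheticSpec(n=80, d=3, planted_support=[0], planted_weights=[1.0], seed=0)
        idx = lime_sample(generate_synthetic(spec), seed=1)
        np.testing.assert_array_equal(idx, np.arange(80))

    def test_seed_determinism_and_distinctness(self):
        spec = SyntheticSpec(n=900, d=3, planted_support=[0], planted_weights=[1.0], seed=0)
        t = generate_synthetic(spec)
        a, b = lime_sample(t, seed=7), lime_sample(t, seed=7)
        np.testing.assert_array_equal(a, b)
        assert len(set(a.tolist())) == 500


class TestLime:
    def test_constant_model_gives_null_weights(self):
        spec = SyntheticSpec(n=60, d=4, planted_support=[0], planted_weights=[0.0], seed=0)
        t = generate_synthetic(spec)
        model, _ = fit_surrogate(t, split_seed=0)
        local = local_lime(model, t, row_indices=np.arange(10), seed=0)
        assert np.abs(local.values).max() < 1e-3

    def test_seed_determinism(self):
        model, t = _small_fitted(seed=6, n=80)
        a = local_lime(model, t, row_indices=np.arange(10), seed=3)
        b = local_lime(model, t, row_indices=np.arange(10), seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_planted_feature_dominates_across_seeds(self):
        """Single planted feature has the largest mean |weight| in >=95%
        of 20 seeded replicates."""
        hits = 0
        for seed in range(20):
            spec = SyntheticSpec(
                n=60, d=5, planted_support=[2], planted_weights=[2.0], seed=seed
            )
            t = generate_synthetic(spec)
            model, _ = fit_surrogate(t, split_seed=seed)
            local = local_lime(model, t, row_indices=np.arange(20), seed=seed)
            hits += int(np.argmax(np.abs(local.values).mean(axis=0)) == 2)
        assert hits >= 19


class TestGlobalize:
    def test_hand_computable_means(self):
        local = LocalAttribution(
            values=np.array([[1.0, 0.0], [1.0, 0.0]]),
            base_values=np.zeros(2),
            method="tree_shap",
            feature_names=["f1", "f2"],
        )
        gi = globalize(local)
        np.testing.assert_allclose(gi.scores, [1.0, 0.0])
        assert gi.directions == ["positive", "unclear"]

    def test_cancelling_signs_are_unclear(self):
        local = LocalAttribution(
            values=np.array([[1.0], [-1.0]]),
            base_values=np.zeros(2),
            method="tree_shap",
            feature_names=["f1"],
        )
        gi = globalize(local)
        assert gi.scores[0] == pytest.approx(1.0)
        assert gi.directions == ["unclear"]

    def test_matches_loop_oracle_on_random_matrix(self):
        rng = np.random.default_rng(12)
        phi = rng.normal(size=(50, 6))
        local = LocalAttribution(
            values=phi, base_values=np.zeros(50), method="tree_shap",
            feature_names=[f"f{j}" for j in range(6)],
        )
        gi = globalize(local)
        expected = np.array([np.mean([abs(phi[i, j]) for i in range(50)]) for j in range(6)])
        np.testing.assert_allclose(gi.scores, expected)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        phi = rng.normal(size=(30, 4))
        names = [f"f{j}" for j in range(4)]
        base = np.zeros(30)
        gi1 = globalize(LocalAttribution(phi, base, "tree_shap", names))
        perm = rng.permutation(30)
        gi2 = globalize(LocalAttribution(phi[perm], base, "tree_shap", names))
        np.testing.assert_allclose(gi1.scores, gi2.scores)
        np.testing.assert_array_equal(gi1.ranks, gi2.ranks)

    def test_feature_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        phi = rng.normal(size=(30, 5))
        names = [f"f{j}" for j in range(5)]
        gi1 = globalize(LocalAttribution(phi, np.zeros(30), "tree_shap", names))
        perm = [3, 1, 4, 0, 2]
        gi2 = globalize(
            LocalAttribution(phi[:, perm], np.zeros(30), "tree_shap", [names[j] for j in perm])
        )
        np.testing.assert_allclose(gi2.scores, gi1.scores[perm])

    def test_lime_z_standardization(self):
        rng = np.random.default_rng(5)
        w = rng.normal(size=(40, 6))
        local = LocalAttribution(
            w, np.zeros(40), "lime", [f"f{j}" for j in range(6)]
        )
        gi = globalize(local)
        s = np.abs(w).mean(axis=0)
        z = (s - s.mean()) / s.std()
        np.testing.assert_allclose(gi.z, z)
        np.testing.assert_allclose(gi.scores, np.maximum(z, 0))

    def test_degenerate_lime_scores_warn_to_zero(self, caplog):
        local = LocalAttribution(
            np.ones((5, 3)), np.zeros(5), "lime", ["a", "b", "c"]
        )
        gi = globalize(local)
        np.testing.assert_array_equal(gi.z, 0.0)

    def test_empty_attribution_rejected(self):
        local = LocalAttribution(
            np.ones((1, 2)), np.zeros(1), "tree_shap", ["a", "b"]
        )
        local.values = np.empty((0, 2))
        with pytest.raises(ValueError):
            globalize(local)


class TestTopK:
    def _gi(self, scores, names):
        local = LocalAttribution(
            np.array([scores]), np.zeros(1), "tree_shap", names
        )
        return globalize(local)

    def test_rank_order(self):
        gi = self._gi([3.0, 1.0, 2.0], ["f1", "f2", "f3"])
        got = top_k(gi, FeatureCatalog.passthrough(), k=2)
        assert [r["feature"] for r in got.records] == ["f1", "f3"]

    def test_lexicographic_tie_break(self):
        gi = self._gi([2.0, 2.0], ["f_b", "f_a"])
        got = top_k(gi, FeatureCatalog.passthrough(), k=1)
        assert got.records[0]["feature"] == "f_a"

    def test_k_equals_d_returns_rank_order(self):
        gi = self._gi([1.0, 3.0, 2.0], ["f1", "f2", "f3"])
        got = top_k(gi, FeatureCatalog.passthrough(), k=3)
        assert [r["feature"] for r in got.records] == ["f2", "f3", "f1"]

    def test_k_out_of_range(self):
        gi = self._gi([1.0, 2.0], ["f1", "f2"])
        with pytest.raises(ValueError):
            top_k(gi, FeatureCatalog.passthrough(), k=3)


class TestPlots:
    def test_plot_written(self, tmp_path):
        rng = np.random.default_rng(0)
        local = LocalAttribution(
            rng.normal(size=(10, 4)), np.zeros(10), "tree_shap",
            [f"f{j}" for j in range(4)],
        )
        out = tmp_path / "imp.png"
        export_importance_plot(globalize(local), out)
        assert out.stat().st_size > 0


def test_global_importance_shap_ranks_planted_support_first():
    model, t = _small_fitted(seed=9, d=6, n=400, noise=0.1)
    gi = global_importance(model, t, method="tree_shap", seed=0)
    top = top_k(gi, FeatureCatalog.passthrough(), k=2)
    assert sorted(r["feature"] for r in top.records) == ["f0", "f2"]
    assert gi.directions[0] == "positive" and gi.directions[2] == "negative"
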