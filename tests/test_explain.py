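"""Shapley attributions: additivity, exact-enumeration oracle, interactions, audit."""

from itertools import permutations

import numpy as np
import pytest
from lightgbm import LGBMClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from ieto_automl import explain as ex
from ieto_automl.explain import UnsupportedModelError


class _ConstantModel:
    """Binary classifier that always outputs the same probability."""

    def __init__(self, p):
        self.p = p

    def predict_proba(self, X):
        X = np.atleast_2d(X)
        return np.column_stack([np.full(len(X), 1 - self.p), np.full(len(X), self.p)])


@pytest.fixture(scope="module")
def toy_data():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(200, 5))
    y = (X[:, 0] + 0.5 * X[:, 1] + 0.2 * rng.normal(size=200) > 0).astype(int)
    return X, y


@pytest.fixture(scope="module")
def cube_tree():
    """Depth-2 tree on the 3-bit cube: the exact-Shapley anchor instance."""
    X = np.array([[i >> 2 & 1, i >> 1 & 1, i & 1] for i in range(8)], dtype=float)
    y = np.array([0, 0, 0, 1, 0, 1, 1, 1])
    tree = DecisionTreeClassifier(max_depth=2, random_state=0).fit(X, y)
    return tree, X


class TestAttributions:
    def test_constant_model_attributes_nothing(self, toy_data):
        X, _ = toy_data
        attr = ex.shap_attributions(_ConstantModel(0.7), X[:6], background=X[:20])
        assert np.allclose(attr.values, 0.0, atol=1e-12)
        assert attr.base_value == pytest.approx(0.7)

    def test_exact_shapley_on_enumerable_tree(self, cube_tree):
        """Enumeration path equals the coalitional oracle (all 3! permutations)."""
        tree, X = cube_tree
        attr = ex.shap_attributions(tree, X, background=X)
        f = ex.margin_function(tree)

        def v(subset, x):
            hybrid = X.copy()
            for i in subset:
                hybrid[:, i] = x[i]
            return f(hybrid).mean()

        oracle = np.zeros((8, 3))
        for si, x in enumerate(X):
            for perm in permutations(range(3)):
                held = []
                for i in perm:
                    before = v(held, x)
                    held.append(i)
                    oracle[si, i] += v(held, x) - before
        oracle /= 6
        assert np.abs(attr.values - oracle).max() < 1e-10

    def test_tree_model_additivity_contract(self, toy_data):
        X, y = toy_data
        model = LGBMClassifier(n_estimators=40, verbosity=-1, random_state=0).fit(X, y)
        attr = ex.shap_attributions(model, X[:50])
        margins = ex.margin_function(model)(X[:50])
        assert np.abs(attr.additivity_residual(margins)).max() < 1e-6

    def test_interventional_additivity_exact(self, toy_data):
        X, y = toy_data
        model = LogisticRegression(max_iter=300).fit(X, y)
        attr = ex.shap_attributions(model, X[:5], background=X[:32], seed=1)
        margins = ex.margin_function(model)(X[:5])
        assert np.abs(attr.additivity_residual(margins)).max() < 1e-10

    def test_permutation_fallback_preserves_additivity(self, toy_data):
        """Monte-Carlo permutation averaging telescopes to exact additivity."""
        X, y = toy_data
        model = LogisticRegression(max_iter=300).fit(X, y)
        attr = ex.shap_attributions(
            model, X[:3], background=X[:16], seed=1,
            max_enum_features=2, n_permutations=8,
        )
        margins = ex.margin_function(model)(X[:3])
        assert np.abs(attr.additivity_residual(margins)).max() < 1e-10

    def test_empty_data_rejected(self, toy_data):
        X, y = toy_data
        model = LogisticRegression().fit(X, y)
        with pytest.raises(ValueError, match="empty"):
            ex.shap_attributions(model, np.empty((0, 5)))


class TestGlobalImportance:
    def test_matches_direct_loop(self, rng):
        values = rng.normal(size=(30, 4))
        attr = ex.AttributionMatrix(values, 0.0, ["a", "b", "c", "d"])
        ranking = ex.global_importance(attr)
        for j, name in enumerate(["a", "b", "c", "d"]):
            direct = sum(abs(v) for v in values[:, j]) / 30
            assert ranking.importance[name] == pytest.approx(direct)

    def test_zero_column_ranks_last(self):
        values = np.ones((10, 3))
        values[:, 1] = 0.0
        ranking = ex.global_importance(ex.AttributionMatrix(values, 0.0, ["a", "b", "c"]))
        assert ranking.order[-1] == "b"
        assert ranking.importance["b"] == 0.0

    def test_ties_broken_by_name(self):
        values = np.ones((5, 3))
        ranking = ex.global_importance(ex.AttributionMatrix(values, 0.0, ["c", "a", "b"]))
        assert ranking.order == ["a", "b", "c"]


class TestInteractions:
    def test_additive_model_has_no_interactions(self, toy_data):
        X, y = toy_data
        stumps = XGBClassifier(n_estimators=30, max_depth=1, n_jobs=1,
                               verbosity=0, random_state=0).fit(X, y)
        T = ex.interaction_values(stumps, X[:20])
        off = T - np.einsum("ijj->ij", T)[:, :, None] * np.eye(5)
        off_diag = T.copy()
        for k in range(5):
            off_diag[:, k, k] = 0.0
        assert np.abs(off_diag).max() < 1e-6

    def test_symmetry_and_rowsum_consistency_native(self, toy_data):
        X, y = toy_data
        model = XGBClassifier(n_estimators=25, max_depth=3, n_jobs=1,
                              verbosity=0, random_state=0).fit(X, y)
        T = ex.interaction_values(model, X[:15])
        attr = ex.shap_attributions(model, X[:15])
        assert np.abs(T - T.transpose(0, 2, 1)).max() < 1e-8
        assert np.abs(T.sum(axis=2) - attr.values).max() < 1e-5

    def test_symmetry_and_rowsum_consistency_enumeration(self, toy_data):
        X, y = toy_data
        model = LGBMClassifier(n_estimators=25, verbosity=-1, random_state=0).fit(X, y)
        T = ex.interaction_values(model, X[:4], background=X[:24])
        attr = ex.shap_attributions(model, X[:4], background=X[:24],
                                    method="interventional")
        assert np.abs(T - T.transpose(0, 2, 1)).max() < 1e-8
        assert np.abs(T.sum(axis=2) - attr.values).max() < 1e-5

    def test_non_tree_model_unsupported(self, toy_data):
        X, y = toy_data
        with pytest.raises(UnsupportedModelError):
            ex.interaction_values(LogisticRegression().fit(X, y), X[:3])


class TestLassoReference:
    def test_planted_predictor_nonzero_with_correct_sign(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(600, 6))
        y = (1.5 * X[:, 2] + rng.normal(size=600) > 0).astype(int)
        coefs = ex.lasso_reference(X, y, seed=0, feature_names=list("abcdef"))
        assert coefs["c"] > 0.3
        assert abs(coefs["c"]) == max(abs(v) for v in coefs.values())

    def test_pure_noise_mostly_excluded(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(800, 6))
        y = rng.integers(0, 2, 800)
        coefs = ex.lasso_reference(X, y, seed=0)
        assert sum(1 for v in coefs.values() if v == 0.0) >= 4


class TestRankConcordance:
    def test_identical_topk_gives_one(self):
        r = ex.rank_concordance(list("abcde"), list("abcde"), k=5,
                                universe=list("abcdefgh"))
        assert r.kappa == 1.0

    def test_four_of_five_overlap_closed_form(self):
        # universe 16, both top-5, 4 shared: po = 14/16, pe = 146/256
        r = ex.rank_concordance(list("abcde"), list("abcdf"), k=5,
                                universe=list("abcdefghijklmnop"))
        assert r.kappa == pytest.approx(39 / 55)

    def test_complementary_sets_give_minus_one(self):
        r = ex.rank_concordance(list("abcd"), list("efgh"), k=4,
                                universe=list("abcdefgh"))
        assert r.kappa == -1.0

    def test_k_larger_than_universe_rejected(self):
        with pytest.raises(ValueError):
            ex.rank_concordance(["a"], ["a"], k=3, universe=["a", "b"])


class TestRenderReports:
    def test_figure_set_written_per_patient(self, toy_data, tmp_path):
        X, y = toy_data
        model = LGBMClassifier(n_estimators=20, verbosity=-1, random_state=0).fit(X, y)
        attr = ex.shap_attributions(model, X[:30])
        preds = model.predict_proba(X[:30])[:, 1]
        T = ex.interaction_values(model, X[:3], background=X[:16])
        paths = ex.render_reports(attr, preds, tmp_path, interactions=T,
                                  patients=[0, 1, 2])
        names = {p.name for p in paths}
        assert {"summary.png", "importance.png", "decision_paths.png",
                "interactions.png"} <= names
        assert sum(1 for n in names if n.startswith("waterfall")) == 3
        assert sum(1 for n in names if n.startswith("force")) == 3

    def test_waterfall_endpoint_equals_prediction_margin(self, toy_data):
        X, y = toy_data
        model = LGBMClassifier(n_estimators=20, verbosity=-1, random_state=0).fit(X, y)
        attr = ex.shap_attributions(model, X[:5])
        margins = ex.margin_function(model)(X[:5])
        endpoint = attr.base_value + attr.values.sum(axis=1)
        assert np.allclose(endpoint, margins, atol=1e-6)
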