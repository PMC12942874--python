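import numpy as np
import pandas as pd
import pytest

import mdagkit as mk
from mdagkit.discriminant import SparsePLSDA
from mdagkit.graphs import MBB, MDag


def dense_plsda_oracle(X, y, ncomp):
    """Independent dense PLS-DA: dominant SVD direction of the
    cross-covariance per component, with score-regression deflation."""
    X = np.asarray(X, float)
    classes, idx = np.unique(y, return_inverse=True)
    Xw = (X - X.mean(0)) / X.std(0, ddof=1)
    Y = np.eye(len(classes))[idx]
    Y = Y - Y.mean(0)
    loadings = []
    for _ in range(ncomp):
        U, s, Vt = np.linalg.svd(Xw.T @ Y, full_matrices=False)
        u = U[:, 0]
        t = Xw @ u
        tt = t @ t
        Xw = Xw - np.outer(t, (t @ Xw) / tt)
        Y = Y - np.outer(t, (t @ Y) / tt)
        loadings.append(u)
    return np.column_stack(loadings)


@pytest.fixture
def planted_data():
    rng = np.random.default_rng(3)
    n, p = 40, 101
    X = rng.normal(size=(n, p))
    y = np.array(["a"] * 20 + ["b"] * 20)
    X[:20, 0] += 3
    X[20:, 0] -= 3
    return X, y


class TestFeatureMatrix:
    def test_completeness_values(self):
        pan = MDag([MBB.from_members({"R1", "R2", "R3", "R4"}),
                    MBB.from_members({"R9"})])
        X = mk.build_mbb_features(
            {"full": {"R1", "R2", "R3", "R4"}, "one": {"R1"}, "none": {"R9"}},
            pan,
        )
        big = MBB.from_members({"R1", "R2", "R3", "R4"}).id
        assert X.loc["full", big] == 1.0
        assert X.loc["one", big] == 0.25
        assert X.loc["none", big] == 0.0

    def test_empty_sample_warns_and_zeroes(self):
        pan = MDag([MBB.from_members({"R1"})])
        with pytest.warns(UserWarning, match="empty"):
            X = mk.build_mbb_features({"s": set()}, pan)
        assert (X.loc["s"] == 0).all()

    def test_values_in_unit_interval(self, synthetic_run):
        synth = synthetic_run["synth"]
        reactions = synthetic_run["sample_reactions"]
        pan = mk.pan_reactions(list(reactions.values()))
        pan_mdag = mk.condense_to_mdag(mk.build_reaction_graph(synth.universe, pan))
        oriented = {s: mk.oriented_labels(synth.universe, r)
                    for s, r in list(reactions.items())[:10]}
        X = mk.build_mbb_features(oriented, pan_mdag)
        assert ((X.values >= 0) & (X.values <= 1)).all()


class TestSparsePLSDA:
    def test_exact_keepx_sparsity(self, planted_data):
        X, y = planted_data
        model = SparsePLSDA(n_components=2, keep_x=(5, 7)).fit(X, y)
        assert (model.x_loadings_[:, 0] != 0).sum() == 5
        assert (model.x_loadings_[:, 1] != 0).sum() == 7
        for c in range(2):
            assert np.linalg.norm(model.x_loadings_[:, c]) == pytest.approx(1.0)

    def test_dense_limit_matches_unpenalized_fit(self, planted_data):
        X, y = planted_data
        p = X.shape[1]
        model = SparsePLSDA(n_components=2, keep_x=(p, p)).fit(X, y)
        oracle = dense_plsda_oracle(X, y, 2)
        np.testing.assert_allclose(
            np.abs(model.x_loadings_), np.abs(oracle), atol=1e-8
        )

    def test_planted_informative_variable_kept_on_component_one(self, planted_data):
        X, y = planted_data
        model = SparsePLSDA(n_components=2, keep_x=(5, 5)).fit(X, y)
        assert 0 in model.kept_[0]

    def test_duplicated_rows_get_identical_scores(self, planted_data):
        X, y = planted_data
        X2 = np.vstack([X, X[:4]])
        y2 = np.concatenate([y, y[:4]])
        model = SparsePLSDA(n_components=2, keep_x=(5, 5)).fit(X2, y2)
        np.testing.assert_allclose(model.x_scores_[:4], model.x_scores_[-4:],
                                   atol=1e-10)

    def test_score_orthogonality(self, planted_data):
        X, y = planted_data
        model = SparsePLSDA(n_components=2, keep_x=(10, 10)).fit(X, y)
        t1, t2 = model.x_scores_.T
        assert abs(t1 @ t2) < 1e-6 * np.linalg.norm(t1) * np.linalg.norm(t2)

    def test_keepx_clipped_with_warning(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 4))
        y = ["a"] * 10 + ["b"] * 10
        with pytest.warns(UserWarning, match="clipped"):
            model = SparsePLSDA(n_components=1, keep_x=(9,)).fit(X, y)
        assert (model.x_loadings_[:, 0] != 0).sum() == 4

    def test_zero_variance_columns_dropped(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 5))
        X[:, 2] = 7.0
        y = ["a"] * 10 + ["b"] * 10
        with pytest.warns(UserWarning, match="zero-variance"):
            model = SparsePLSDA(n_components=1, keep_x=(4,)).fit(
                pd.DataFrame(X, columns=list("vwxyz")), y
            )
        assert list(model.dropped_features_) == ["x"]

    def test_single_sample_group_rejected(self):
        X = np.random.default_rng(2).normal(size=(5, 3))
        with pytest.raises(ValueError):
            SparsePLSDA(n_components=1, keep_x=(3,)).fit(X, ["a"] * 4 + ["b"])

    def test_label_permutation_destroys_separation(self):
        rng = np.random.default_rng(9)
        n, p = 100, 100
        X = rng.normal(size=(n, p))
        y = np.array(["a"] * 50 + ["b"] * 50)
        X[:50, :5] += 3
        X[50:, :5] -= 3

        def gap(labels):
            m = SparsePLSDA(n_components=1, keep_x=(5,)).fit(X, labels)
            cent = m.group_centroids().iloc[:, 0]
            return abs(cent.iloc[0] - cent.iloc[1])

        true_gap = gap(y)
        perm_gaps = [gap(rng.permutation(y)) for _ in range(50)]
        assert true_gap > 3 * np.mean(perm_gaps)


class TestSelection:
    @staticmethod
    def _hand_model(loadings, centroid_sign=1.0):
        model = SparsePLSDA(n_components=1, keep_x=(len(loadings),))
        model.x_loadings_ = np.asarray(loadings, float).reshape(-1, 1)
        model.classes_ = np.array(["g1", "g2"])
        model.feature_names_in_ = np.array(
            [f"v{i + 1}" for i in range(len(loadings))]
        )
        model.x_scores_ = np.array([[centroid_sign], [-centroid_sign]])
        model._y_idx = np.array([0, 1])
        model.kept_ = [np.flatnonzero(model.x_loadings_[:, 0])]
        return model

    def test_threshold_rule_and_sign_assignment(self):
        model = self._hand_model([0.9, 0.96, -1.0])
        sel = mk.select_discriminants(model, threshold=0.95)
        assert list(sel["feature"]) == ["v2", "v3"]
        assert set(sel["group"]) == {"g1", "g2"}
        assert sel.set_index("feature").loc["v3", "group"] == "g2"

    def test_single_variable_always_selected(self):
        sel = mk.select_discriminants(self._hand_model([0.0, -0.7, 0.0]))
        assert list(sel["feature"]) == ["v2"]

    def test_threshold_one_selects_only_maxima(self):
        sel = mk.select_discriminants(
            self._hand_model([0.5, -1.0, 1.0]), threshold=1.0
        )
        assert sorted(sel["feature"]) == ["v2", "v3"]


class TestPathwayRollup:
    def test_counting_rule(self, f1):
        pan = MDag([MBB.from_members({"R1", "R2"})])
        mid = MBB.from_members({"R1", "R2"}).id
        selected = pd.DataFrame(
            {"component": [1], "feature": [mid], "contribution": [1.0],
             "group": ["g1"]}
        )
        members = {mid: frozenset({"R1", "R2"})}
        out = mk.pathway_rollup(selected, members, f1)
        counts = out.set_index("pathway")["n_reactions"]
        assert counts["pwA"] == 2 and counts["pwB"] == 1

    def test_unannotated_bucket(self, f1):
        mid = MBB.from_members({"R3"}).id
        selected = pd.DataFrame(
            {"component": [1], "feature": [mid], "contribution": [1.0],
             "group": ["g1"]}
        )
        out = mk.pathway_rollup(selected, {mid: frozenset({"R3"})}, f1)
        assert list(out["pathway"]) == ["unannotated"]

    def test_shared_reaction_counted_once_per_pathway(self, f1):
        m1 = MBB.from_members({"R1"}).id
        m2 = MBB.from_members({"R1", "R2"}).id
        selected = pd.DataFrame(
            {"component": [1, 1], "feature": [m1, m2],
             "contribution": [1.0, 0.99], "group": ["g1", "g1"]}
        )
        members = {m1: frozenset({"R1"}), m2: frozenset({"R1", "R2"})}
        out = mk.pathway_rollup(selected, members, f1)
        assert out.set_index("pathway")["n_reactions"]["pwA"] == 2

    def test_orientation_collapsed(self, f1):
        mid = MBB.from_members({"R2", "R2rev"}).id
        selected = pd.DataFrame(
            {"component": [1], "feature": [mid], "contribution": [1.0],
             "group": ["g1"]}
        )
        out = mk.pathway_rollup(selected, {mid: frozenset({"R2", "R2rev"})}, f1)
        assert out.set_index("pathway")["n_reactions"]["pwA"] == 1

    def test_no_selection_gives_empty_table(self, f1):
        empty = pd.DataFrame(columns=["component", "feature", "contribution", "group"])
        assert mk.pathway_rollup(empty, {}, f1).empty
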