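"""Standardization, PCA retention, elbow rule, k-means, ordering, movement."""

import numpy as np
import pandas as pd
import pytest

from actibout.clustering import (
    ClusterModel,
    assign_periods,
    choose_k_elbow,
    elbow_point,
    fit_clusters,
    fit_pca,
    movement_matrix,
    order_clusters,
    standardize,
)


class TestStandardize:
    def test_two_point_column_sample_sd(self):
        Z, st = standardize(np.array([[1.0], [3.0]]))
        assert Z[:, 0] == pytest.approx([-0.7071067, 0.7071067], abs=1e-6)

    def test_constant_column_zeros_with_warning(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.warns(UserWarning, match="constant"):
            Z, st = standardize(X)
        assert (Z[:, 1] == 0).all()
        assert Z[:, 0].std(ddof=1) == pytest.approx(1.0)

    def test_stored_standardizer_reproduces_training_z(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 8))
        Z, st = standardize(X)
        assert np.allclose(st.transform(X), Z)

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            standardize(np.array([[1.0], [np.nan]]))


class TestPCA:
    def test_rank_one_data_needs_one_component(self):
        t = np.linspace(-1, 1, 30)
        Z = np.outer(t, np.arange(1, 9.0))
        proj, scores = fit_pca(Z, variance_target=0.99)
        assert proj.m == 1

    def test_fixed_m_four_scores(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(40, 8))
        proj, scores = fit_pca(Z, fixed_m=4)
        assert scores.shape == (40, 4)
        assert proj.loadings.shape == (8, 4)

    def test_full_rank_reconstruction_is_exact(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 8))
        Z = X - X.mean(axis=0)
        proj, scores = fit_pca(Z, fixed_m=8)
        assert np.allclose(scores @ proj.loadings.T, Z, atol=1e-10)

    def test_explained_variance_is_non_increasing(self):
        rng = np.random.default_rng(3)
        proj, _ = fit_pca(rng.normal(size=(50, 8)), fixed_m=8)
        assert (np.diff(proj.explained_variance_ratio) <= 1e-12).all()

    def test_bad_variance_target_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.eye(4), variance_target=1.5)


class TestElbow:
    def test_hand_computed_chord_distance_curve(self):
        # line from (1,100) to (6,26) has slope -14.8; vertical deviations are
        # 35.2 (k=2), 40.4 (k=3), 27.6 (k=4), 13.8 (k=5) -> elbow at k=3
        assert elbow_point([1, 2, 3, 4, 5, 6], [100, 50, 30, 28, 27, 26]) == 3

    def test_linear_decay_ties_to_smallest_interior_k(self):
        assert elbow_point([1, 2, 3, 4, 5], [100, 80, 60, 40, 20]) == 2

    def test_non_finite_wss_rejected(self):
        with pytest.raises(ValueError):
            elbow_point([1, 2, 3], [10.0, np.nan, 1.0])

    def test_three_separated_blobs_select_k3(self):
        rng = np.random.default_rng(4)
        blobs = np.concatenate([
            rng.normal(loc, 0.3, size=(40, 2))
            for loc in ([0, 0], [10, 0], [0, 10])
        ])
        assert choose_k_elbow(blobs, k_range=range(2, 8), seed=0) == 3

    def test_k_range_exceeding_rows_rejected(self):
        with pytest.raises(ValueError):
            choose_k_elbow(np.zeros((4, 2)), k_range=range(2, 11), seed=0)


class TestKMeansFit:
    def test_two_separated_clouds(self):
        rng = np.random.default_rng(5)
        X = np.concatenate([rng.normal(-10, 0.2, size=(30, 1)),
                            rng.normal(10, 0.2, size=(30, 1))])
        model = fit_clusters(np.column_stack([X, np.zeros(60)]), k=2, seed=0)
        got = np.sort(model.centroids[:, 0])
        assert got == pytest.approx([-10, 10], abs=0.5)

    def test_refit_same_seed_identical(self):
        rng = np.random.default_rng(6)
        S = rng.normal(size=(50, 3))
        a = fit_clusters(S, k=4, seed=9)
        b = fit_clusters(S, k=4, seed=9)
        assert (a.labels_ == b.labels_).all()
        assert np.allclose(a.centroids, b.centroids)

    def test_k_exceeding_distinct_rows_rejected(self):
        S = np.zeros((10, 2))
        S[:5] = 1.0
        with pytest.raises(ValueError, match="distinct"):
            fit_clusters(S, k=3, seed=0)


def _toy_model_and_features(mvpa_means, sb_means, per=5):
    """k clusters of identical members at given MVPA/SB means, 1-D scores."""
    k = len(mvpa_means)
    scores = np.concatenate([np.full((per, 1), 10.0 * i) for i in range(k)])
    model = fit_clusters(scores, k=k, seed=0)
    feats = pd.DataFrame({
        "mvpa_time_3s": np.concatenate([np.full(per, m) for m in mvpa_means]),
        "sb_time_60s": np.concatenate([np.full(per, s) for s in sb_means]),
    })
    return model, feats, scores


class TestOrdering:
    def test_by_decreasing_mvpa(self):
        model, feats, _ = _toy_model_and_features([20.0, 50.0], [300.0, 300.0])
        ordered = order_clusters(model, feats)
        means = [feats["mvpa_time_3s"][ordered.labels_ == c].mean()
                 for c in (1, 2)]
        assert means == [50.0, 20.0]

    def test_tie_breaks_by_lower_sedentary(self):
        model, feats, _ = _toy_model_and_features([30.0, 30.0], [400.0, 200.0])
        ordered = order_clusters(model, feats)
        sb = [feats["sb_time_60s"][ordered.labels_ == c].mean() for c in (1, 2)]
        assert sb == [200.0, 400.0]

    def test_idempotent(self):
        model, feats, _ = _toy_model_and_features([10.0, 40.0, 25.0],
                                                  [500.0, 250.0, 350.0])
        once = order_clusters(model, feats)
        twice = order_clusters(once, feats)
        assert (once.labels_ == twice.labels_).all()
        assert np.allclose(once.centroids, twice.centroids)

    def test_ordering_makes_mvpa_non_increasing(self):
        model, feats, _ = _toy_model_and_features([15.0, 60.0, 35.0, 25.0],
                                                  [400, 200, 300, 350])
        ordered = order_clusters(model, feats)
        means = [feats["mvpa_time_3s"][ordered.labels_ == c].mean()
                 for c in range(1, 5)]
        assert means == sorted(means, reverse=True)


class TestAssignPeriods:
    def _model(self):
        model, feats, _ = _toy_model_and_features([50.0, 20.0], [200.0, 400.0])
        return order_clusters(model, feats)

    def test_unanimous_period(self):
        model = self._model()
        scores = np.full((3, 1), 10.0)  # all days nearest the less-active centroid
        groups = pd.DataFrame({"participant": ["a"] * 3, "period": ["pre"] * 3})
        out = assign_periods(model, scores, groups)
        assert out.loc[0, "cluster"] == 2

    def test_split_days_tie_goes_to_more_active(self):
        model = self._model()
        scores = np.array([[0.0], [0.0], [10.0], [10.0]])
        groups = pd.DataFrame({"participant": ["a"] * 4, "period": ["pre"] * 4})
        out = assign_periods(model, scores, groups)
        assert out.loc[0, "cluster"] == 1

    def test_mean_vector_matches_modal_on_unanimity(self):
        model = self._model()
        scores = np.full((4, 1), 0.0)
        groups = pd.DataFrame({"participant": ["a"] * 4, "period": ["post"] * 4})
        modal = assign_periods(model, scores, groups, mode="modal-day")
        meanv = assign_periods(model, scores, groups, mode="mean-vector")
        assert modal.loc[0, "cluster"] == meanv.loc[0, "cluster"]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            assign_periods(self._model(), np.zeros((1, 1)),
                           pd.DataFrame({"participant": ["a"], "period": ["pre"]}),
                           mode="median-day")


class TestMovementMatrix:
    def test_three_participant_example(self):
        mm = movement_matrix({"a": 1, "b": 1, "c": 2}, {"a": 1, "b": 2, "c": 1})
        assert (mm.same, mm.desirable, mm.unfavorable) == (1, 1, 1)
        assert mm.n == 3

    def test_identity_is_all_diagonal(self):
        labels = {"a": 1, "b": 3, "c": 5, "d": 3}
        mm = movement_matrix(labels, labels, k=5)
        assert mm.same == 4 and mm.desirable == 0 and mm.unfavorable == 0
        assert np.trace(mm.counts) == 4

    def test_decomposition_sums_to_n(self):
        rng = np.random.default_rng(8)
        pre = {f"p{i}": int(rng.integers(1, 6)) for i in range(25)}
        post = {f"p{i}": int(rng.integers(1, 6)) for i in range(25)}
        mm = movement_matrix(pre, post, k=5)
        assert mm.desirable + mm.same + mm.unfavorable == mm.n == 25
        assert mm.counts.sum() == 25

    def test_mismatched_participants_rejected(self):
        with pytest.raises(ValueError, match="different participants"):
            movement_matrix({"a": 1}, {"b": 1})


class TestModelSerialization:
    def test_json_round_trip(self, tmp_path):
        model, feats, scores = _toy_model_and_features([50.0, 20.0], [200.0, 400.0])
        model = order_clusters(model, feats)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ClusterModel.from_json(path)
        assert back.k == model.k
        assert np.allclose(back.centroids, model.centroids)
        assert (back.labels_ == model.labels_).all()
        assert (back.predict(scores) == model.predict(scores)).all()
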