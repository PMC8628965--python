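"""Temperature-matrix assembly, transform, k-means and archetype labels."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from diffshape.io import Condition
from diffshape.synth import CLASS_ARCHETYPE
from diffshape.io import aggregate
from diffshape.thermal import (
    ReactivityStandardizer,
    TemperatureMatrix,
    ThermalArchetypeKMeans,
    build_matrix,
    elbow,
    kmeans_cluster,
    label_archetypes,
    transform,
)
from .conftest import make_replicate_set


def profile_at(temp, rows):
    rs = make_replicate_set(rows, condition=Condition(temperature_C=temp))
    return aggregate(rs)


def toy_matrix(X, temps=(37, 53, 65, 74, 85), transformed=False):
    X = np.asarray(X, float)
    return TemperatureMatrix(
        temperatures=np.array(temps[: X.shape[1]], float),
        positions=np.arange(1, X.shape[0] + 1),
        bases=np.array(["A"] * X.shape[0], dtype="U1"),
        matrix=X,
        transformed=transformed,
    )


class TestBuildMatrix:
    def test_positions_with_any_gap_are_dropped(self):
        rows = [[(0.1, 0.1)] * 5, [(0.2, 0.2)] * 5]
        p1 = profile_at(37, [(0.1, 0.1), (0.2, 0.2), ()])
        p2 = profile_at(53, [(0.3, 0.3), (0.4, 0.4), (0.5, 0.5)])
        tm = build_matrix([p1, p2])
        assert tm.positions.tolist() == [1, 2]
        assert tm.dropped_positions.tolist() == [3]
        assert tm.matrix.shape == (2, 2)

    def test_position_missing_from_one_profile_is_dropped(self):
        p1 = profile_at(37, [(0.1, 0.1), (0.2, 0.2)])
        p2 = profile_at(53, [(0.3, 0.3)])
        tm = build_matrix([p1, p2])
        assert tm.positions.tolist() == [1]
        assert tm.dropped_positions.tolist() == [2]

    def test_requires_two_temperatures(self):
        with pytest.raises(ValueError):
            build_matrix([profile_at(37, [(0.1, 0.1)])])


class TestTransform:
    def test_columns_standardized_after_full_transform(self):
        rng = np.random.default_rng(0)
        tm = toy_matrix(rng.uniform(0.05, 1.5, size=(10, 5)))
        tx = transform(tm)
        assert np.allclose(tx.matrix.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(tx.matrix.std(axis=0), 1, atol=1e-9)

    def test_constant_row_becomes_zeros(self):
        X = np.vstack([[0.5] * 5, np.linspace(0.1, 1.0, 5)])
        tx = ReactivityStandardizer().fit_transform(X)
        # after row-centering the constant row is all zero; the divide is skipped
        assert np.all(np.isfinite(tx))

    def test_values_floored_before_log(self):
        X = np.array([[0.0, 0.5, 1.0, 1.5, 2.0]])
        # one row: row-standardization of log2(max(x, 0.01)); no NaN/-inf
        tx = ReactivityStandardizer(floor=0.01).fit_transform(X)
        assert np.all(np.isfinite(tx))

    def test_invariant_to_uniform_positive_rescaling(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0.05, 2.0, size=(12, 5))
        a = ReactivityStandardizer().fit_transform(X)
        b = ReactivityStandardizer().fit_transform(3.7 * X)
        assert np.allclose(a, b, atol=1e-9)

    def test_rejects_already_transformed_matrix(self):
        tm = toy_matrix(np.random.default_rng(2).uniform(0.1, 1, (4, 5)))
        with pytest.raises(ValueError):
            transform(transform(tm))


class TestKMeans:
    def test_k1_distortion_is_total_scatter(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 5))
        tm = toy_matrix(X, transformed=True)
        asg = kmeans_cluster(tm, k=1, seed=0)
        expected = float(((X - X.mean(axis=0)) ** 2).sum())
        assert asg.distortion == pytest.approx(expected)

    def test_k_equals_rows_gives_zero_distortion(self):
        rng = np.random.default_rng(4)
        tm = toy_matrix(rng.normal(size=(6, 5)), transformed=True)
        asg = kmeans_cluster(tm, k=6, seed=0)
        assert asg.distortion == pytest.approx(0.0, abs=1e-12)

    def test_k_out_of_range_raises(self):
        tm = toy_matrix(np.zeros((3, 5)), transformed=True)
        with pytest.raises(ValueError):
            kmeans_cluster(tm, k=4, seed=0)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(5)
        tm = toy_matrix(rng.normal(size=(40, 5)), transformed=True)
        a = kmeans_cluster(tm, k=3, seed=7)
        b = kmeans_cluster(tm, k=3, seed=7)
        assert np.array_equal(a.labels, b.labels)
        assert a.distortion == b.distortion

    def test_recovers_well_separated_groups(self):
        rng = np.random.default_rng(6)
        centers = np.array([[5, 0, 0, 0, 0], [0, 5, 0, 0, 0], [0, 0, 5, 0, 0], [0, 0, 0, 5, 0]], float)
        truth = np.repeat(np.arange(4), 25)
        X = centers[truth] + 0.3 * rng.normal(size=(100, 5))
        asg = kmeans_cluster(toy_matrix(X, transformed=True), k=4, seed=0)
        assert adjusted_rand_score(truth, asg.labels) >= 0.9

    def test_distortion_non_increasing_in_k(self):
        rng = np.random.default_rng(7)
        tm = toy_matrix(rng.normal(size=(30, 5)), transformed=True)
        curve, _ = elbow(tm, k_max=8, seed=0)
        assert np.all(np.diff(curve) <= 1e-9)


class TestElbow:
    def test_exact_three_group_data_selects_three(self):
        vecs = np.array([[1, 0, 0, 0, 0], [0, 1, 0, 0, 0], [0, 0, 1, 0, 0]], float)
        X = np.repeat(vecs, 10, axis=0)
        curve, k = elbow(toy_matrix(X, transformed=True), k_max=8, seed=0)
        assert curve[2] == pytest.approx(0.0, abs=1e-12)
        assert k == 3

    def test_kmax_one_returns_one(self):
        tm = toy_matrix(np.random.default_rng(8).normal(size=(5, 5)), transformed=True)
        _, k = elbow(tm, k_max=1, seed=0)
        assert k == 1


class TestArchetypes:
    def test_planted_centroid_shapes_get_expected_labels(self):
        raw = np.vstack(
            [
                np.tile([0.9, 0.85, 0.8, 0.78, 0.75], (5, 1)),  # high at 37
                np.tile([0.1, 0.9, 0.95, 0.96, 0.97], (5, 1)),  # rise 37->53
                np.tile([0.1, 0.12, 0.5, 0.9, 0.95], (5, 1)),  # rise 65->74
                np.tile([0.06, 0.06, 0.07, 0.08, 0.8], (5, 1)),  # rise 74->85
            ]
        )
        tm = toy_matrix(raw)
        asg = kmeans_cluster(transform(tm), k=4, seed=0)
        asg = label_archetypes(asg, tm)
        assert sorted(asg.archetypes) == [
            "always_reactive",
            "secondary_65",
            "stable_85",
            "tertiary_37_53",
        ]

    def test_wrong_k_labels_unassigned(self):
        tm = toy_matrix(np.random.default_rng(9).uniform(0.1, 1, (10, 5)))
        asg = kmeans_cluster(transform(tm), k=3, seed=0)
        with pytest.warns(UserWarning):
            asg = label_archetypes(asg, tm)
        assert asg.archetypes == ["unassigned"] * 3


class TestEstimator:
    def test_full_pipeline_recovers_planted_structure(self, ann188, temperature_profiles):
        tm = build_matrix(temperature_profiles)
        est = ThermalArchetypeKMeans(n_clusters="auto", random_state=42).fit(tm)
        assert est.k_ == 4
        truth = np.array([CLASS_ARCHETYPE[c] for c in ann188.classes])[tm.positions - 1]
        assert adjusted_rand_score(truth, est.labels_) >= 0.9
        # per-sample archetype names must agree with planted truth for >90%
        agree = np.mean(est.archetype_labels_ == truth)
        assert agree >= 0.9

    def test_sklearn_param_interface(self):
        est = ThermalArchetypeKMeans(n_clusters=4, random_state=1)
        params = est.get_params()
        assert params["n_clusters"] == 4
        est.set_params(k_max=6)
        assert est.k_max == 6
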