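import numpy as np
import pandas as pd
import pytest

from accelmix import (FeatureTable, IntervalSet, compare_methods,
                      conventional_mean, distance_matrix, fit_lda,
                      group_distance, standardize)
from accelmix.errors import (ConfigError, DegenerateFeatureError,
                             InsufficientDataError)
from accelmix.features import build_feature_table, unstandardize
from accelmix.signal_io import ALL_FEATURES, GMM_FEATURES
from tests.conftest import make_trace


def table_from_matrix(X, groups, features=ALL_FEATURES):
    rows = []
    for i, (x, g) in enumerate(zip(X, groups)):
        row = {"recording_id": f"r{i}", "group": g}
        row.update({f: 0.0 for f in ALL_FEATURES})
        row.update(dict(zip(features, x)))
        rows.append(row)
    return build_feature_table(rows)


def two_cluster_table(rng, delta, n=50, features=("mu_high", "sigma_high")):
    """Two 2-D Gaussian clusters separated by ``delta`` sds per feature."""
    Xa = rng.normal(0.0, 1.0, size=(n, 2))
    Xb = rng.normal(delta, 1.0, size=(n, 2))
    # fill remaining features with shared noise so standardization works
    rows = []
    for i, (x, g) in enumerate(
            [(x, "a") for x in Xa] + [(x, "b") for x in Xb]):
        row = {"recording_id": f"r{i}", "group": g}
        row.update({f: rng.normal() for f in ALL_FEATURES})
        row.update(dict(zip(features, x)))
        rows.append(row)
    return build_feature_table(rows)


class TestConventionalMean:
    def test_constant_trace(self):
        trace = make_trace(np.tile([0.0, 0.0, 0.6], (100, 1)), rate=10.0)
        iv = IntervalSet("t", 10.0, [("in_play", 0, 100)])
        assert conventional_mean(trace, iv) == pytest.approx(0.6)

    def test_two_level_mean(self):
        xyz = np.concatenate([np.tile([0.4, 0, 0], (50, 1)),
                              np.tile([0, 0.8, 0], (50, 1))])
        iv = IntervalSet("t", 10.0, [("in_play", 0, 100)])
        assert conventional_mean(make_trace(xyz, rate=10.0), iv) == \
            pytest.approx(0.6)

    def test_restricted_to_in_play_matches_brute_force(self, rng):
        xyz = np.abs(rng.normal(size=(400, 3)))
        iv = IntervalSet("t", 10.0, [("rest", 0, 100), ("in_play", 100, 300),
                                     ("rest", 300, 400)])
        norm = np.linalg.norm(xyz, axis=1)
        expected = norm[100:300].mean()
        assert conventional_mean(make_trace(xyz, rate=10.0), iv) == \
            pytest.approx(expected)
        assert conventional_mean(make_trace(xyz, rate=10.0), iv,
                                 whole_recording=True) == \
            pytest.approx(norm.mean())

    def test_no_in_play_rejected(self):
        trace = make_trace(np.zeros((100, 3)), rate=10.0)
        iv = IntervalSet("t", 10.0, [("rest", 0, 100)])
        with pytest.raises(InsufficientDataError):
            conventional_mean(trace, iv)


class TestStandardize:
    def test_two_value_column(self):
        t = table_from_matrix([[1.0], [3.0]], ["a", "b"], features=["mu_low"])
        # avoid other constant columns
        t.data.loc[0, ALL_FEATURES[1:]] = 1.0
        z = standardize(t)
        np.testing.assert_allclose(z.data["mu_low"],
                                   [-0.7071068, 0.7071068], rtol=1e-6)

    def test_postconditions_and_idempotence(self, rng):
        t = table_from_matrix(rng.normal(size=(10, 6)), ["a"] * 5 + ["b"] * 5)
        z = standardize(t)
        for col in ALL_FEATURES:
            assert abs(z.data[col].mean()) < 1e-9
            assert abs(z.data[col].std(ddof=1) - 1.0) < 1e-9
        zz = standardize(z)
        np.testing.assert_allclose(zz.data[ALL_FEATURES], z.data[ALL_FEATURES],
                                   atol=1e-12)

    def test_invertibility(self, rng):
        t = table_from_matrix(rng.normal(size=(8, 6)), ["a"] * 4 + ["b"] * 4)
        back = unstandardize(standardize(t))
        np.testing.assert_allclose(back.data[ALL_FEATURES],
                                   t.data[ALL_FEATURES], atol=1e-12)

    def test_constant_column_named_in_error(self, rng):
        t = table_from_matrix(rng.normal(size=(6, 6)), ["a"] * 3 + ["b"] * 3)
        t.data["w_high"] = 0.5
        with pytest.raises(DegenerateFeatureError, match="w_high"):
            standardize(t)


class TestGroupDistance:
    def test_identical_means_zero(self, rng):
        X = rng.normal(size=(6, 6))
        t = standardize(table_from_matrix(np.vstack([X, X]),
                                          ["a"] * 6 + ["b"] * 6))
        assert group_distance(t, GMM_FEATURES) == pytest.approx(0.0, abs=1e-12)

    def test_three_four_five(self, rng):
        rows = []
        for i in range(40):
            g = "a" if i < 20 else "b"
            base = [0.0, 0.0] if g == "a" else [3.0, 4.0]
            x = [base[0] + 1e-3 * rng.normal(), base[1] + 1e-3 * rng.normal()]
            row = {"recording_id": f"r{i}", "group": g,
                   **{f: rng.normal() for f in ALL_FEATURES}}
            row["mu_high"], row["sigma_high"] = x
            rows.append(row)
        t = build_feature_table(rows)
        z = t
        z.standardized = True  # distances on the raw scale for this check
        assert group_distance(z, ["mu_high", "sigma_high"]) == \
            pytest.approx(5.0, rel=1e-3)

    def test_requires_standardized_and_known_features(self, rng):
        t = table_from_matrix(rng.normal(size=(4, 6)), ["a", "a", "b", "b"])
        with pytest.raises(ConfigError):
            group_distance(t, ["mu_high"])
        z = standardize(t)
        with pytest.raises(ConfigError, match="unknown"):
            group_distance(z, ["nope"])
        with pytest.raises(ConfigError, match="empty"):
            group_distance(z, [])


class TestDistanceMatrix:
    def test_contains_all_singletons_and_pairs(self, rng):
        z = standardize(table_from_matrix(rng.normal(size=(10, 6)),
                                          ["a"] * 5 + ["b"] * 5))
        dm = distance_matrix(z)
        assert set(dm["singletons"]) == set(GMM_FEATURES)
        assert len(dm["pairs"]) == 10
        assert dm["best_pair"] in dm["pairs"]

    def test_row_permutation_invariance(self, rng):
        t = table_from_matrix(rng.normal(size=(12, 6)), ["a"] * 6 + ["b"] * 6)
        z1 = standardize(t)
        shuffled = FeatureTable(
            data=t.data.sample(frac=1.0, random_state=0).reset_index(drop=True))
        z2 = standardize(shuffled)
        d1, d2 = distance_matrix(z1), distance_matrix(z2)
        for k in d1["pairs"]:
            assert d1["pairs"][k] == pytest.approx(d2["pairs"][k], rel=1e-12)

    def test_squared_distance_additive_over_features(self, rng):
        z = standardize(table_from_matrix(rng.normal(size=(10, 6)),
                                          ["a"] * 5 + ["b"] * 5))
        d_mu = group_distance(z, ["mu_high"])
        d_sig = group_distance(z, ["sigma_high"])
        d_pair = group_distance(z, ["mu_high", "sigma_high"])
        assert d_pair ** 2 == pytest.approx(d_mu ** 2 + d_sig ** 2, rel=1e-12)


class TestLDA:
    def test_well_separated_clusters_fully_classified(self):
        rng = np.random.default_rng(0)
        z = standardize(two_cluster_table(rng, delta=4.0))
        model = fit_lda(z, ["mu_high", "sigma_high"])
        assert model.accuracy == 1.0
        # brute-force check of the scores
        X = z.data[["mu_high", "sigma_high"]].to_numpy()
        scores = model.decision_scores(X)
        pred = np.where(scores > 0, model.classes[1], model.classes[0])
        assert (pred == z.data["group"].to_numpy()).all()

    def test_identical_distributions_near_chance(self):
        rng = np.random.default_rng(1)
        z = standardize(two_cluster_table(rng, delta=0.0))
        model = fit_lda(z, ["mu_high", "sigma_high"])
        assert 0.35 <= model.accuracy <= 0.65
        assert model.confusion.sum() == len(z)

    def test_label_swap_flips_weights_keeps_accuracy(self):
        rng = np.random.default_rng(2)
        t = two_cluster_table(rng, delta=2.0)
        z = standardize(t)
        m1 = fit_lda(z, ["mu_high", "sigma_high"])
        swapped = FeatureTable(data=z.data.assign(
            group=z.data["group"].map({"a": "b", "b": "a"})))
        swapped.standardized = True
        m2 = fit_lda(swapped, ["mu_high", "sigma_high"])
        assert m2.accuracy == pytest.approx(m1.accuracy)
        np.testing.assert_allclose(m2.weights, -m1.weights, rtol=1e-6)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        t = two_cluster_table(rng, delta=1.5)
        z = standardize(t)
        m1 = fit_lda(z, ["mu_high", "sigma_high"])
        rescaled = FeatureTable(data=z.data.assign(
            mu_high=3.0 * z.data["mu_high"] + 1.0,
            sigma_high=3.0 * z.data["sigma_high"] + 1.0))
        rescaled.standardized = True
        m2 = fit_lda(rescaled, ["mu_high", "sigma_high"])
        assert m2.accuracy == pytest.approx(m1.accuracy)


class TestCompareMethods:
    def test_shift_in_high_side_favors_proposed(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(60):
            g = "a" if i < 30 else "b"
            shift = 0.0 if g == "a" else 2.5
            row = {"recording_id": f"r{i}", "group": g,
                   "mu_low": rng.normal(), "sigma_low": rng.normal(),
                   "w_high": rng.normal(),
                   "mu_high": rng.normal() + shift,
                   "sigma_high": rng.normal() + shift,
                   # conventional feature dominated by shared variability
                   "mu_total": rng.normal() + 0.2 * shift}
            rows.append(row)
        z = standardize(build_feature_table(rows))
        report = compare_methods(z)
        assert report["proposed"]["accuracy"] > report["conventional"]["accuracy"]
        assert report["distance_matrix"]["best_pair"] == \
            ("mu_high", "sigma_high")

    def test_global_shift_separates_both(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0.0, 1.0, size=(30, 6)),
                       rng.normal(3.0, 1.0, size=(30, 6))])
        z = standardize(table_from_matrix(X, ["a"] * 30 + ["b"] * 30))
        report = compare_methods(z)
        assert report["proposed"]["accuracy"] > 0.9
        assert report["conventional"]["accuracy"] > 0.9
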