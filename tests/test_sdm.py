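"""Ensemble habitat models, gates, and the vulnerability map."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import BaseEstimator, ClassifierMixin

from loadscape.grids import ClimateGrid, ClimateLayerSet
from loadscape.sdm import (
    EnsembleSDM,
    auc,
    cell_areas_km2,
    default_members,
    ecological_vulnerability,
    habitat_area_change,
    make_presence_background,
    suitability_map,
    tss,
)
from loadscape.simulate import LandscapeParams, simulate_landscape, simulate_occurrences


def brute_force_auc(labels, scores):
    """Pairwise concordance enumeration (ties count half)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class RandomScorer(BaseEstimator, ClassifierMixin):
    """Dummy member whose scores carry no information about the labels."""

    def __init__(self, seed=0):
        self.seed = seed

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict_proba(self, X):
        rng = np.random.default_rng(self.seed + X.shape[0])
        p = rng.random(X.shape[0])
        return np.column_stack([1 - p, p])


class TestMetrics:
    def test_four_point_toy_auc(self):
        labels = [1, 1, 0, 0]
        scores = [0.9, 0.4, 0.6, 0.1]
        assert auc(labels, scores) == pytest.approx(0.75)
        assert brute_force_auc(labels, scores) == pytest.approx(0.75)

    def test_perfect_separation(self):
        labels = [0, 0, 1, 1]
        scores = [0.1, 0.2, 0.8, 0.9]
        assert auc(labels, scores) == 1.0
        assert tss(labels, scores) == pytest.approx(1.0)

    def test_random_scores_near_null(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 4000)
        scores = rng.random(4000)
        assert abs(auc(labels, scores) - 0.5) < 0.03
        assert tss(labels, scores) < 0.1

    @given(seed=st.integers(0, 1000))
    def test_auc_equals_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        labels = np.concatenate([np.ones(10, int), np.zeros(n - 10, int)])
        scores = np.round(rng.random(n), 2)  # rounding forces some ties
        assert auc(labels, scores) == pytest.approx(
            brute_force_auc(labels, scores)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 1], [0.2, 0.3])
        with pytest.raises(ValueError):
            tss([0, 0], [0.2, 0.3])


@pytest.fixture(scope="module")
def landscape():
    present, futures, _ = simulate_landscape(LandscapeParams(seed=40))
    return present, futures


class TestPresenceBackground:
    def test_close_pair_thinned_to_one(self, landscape):
        present, _ = landscape
        occ = pd.DataFrame({"lon": [105.0, 105.0167], "lat": [28.0, 28.0]})
        pb = make_presence_background(occ, present, n_background=10,
                                      thin_arcmin=5, seed=0)
        assert (pb["label"] == "presence").sum() == 1

    def test_exact_background_count(self, landscape):
        present, _ = landscape
        occ = pd.DataFrame({"lon": [105.0], "lat": [28.0]})
        pb = make_presence_background(occ, present, n_background=100, seed=1)
        assert (pb["label"] == "background").sum() == 100

    def test_seeded_runs_identical(self, landscape):
        present, _ = landscape
        occ = pd.DataFrame({"lon": [105.0, 108.0], "lat": [28.0, 30.0]})
        a = make_presence_background(occ, present, n_background=50, seed=3)
        b = make_presence_background(occ, present, n_background=50, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_out_of_extent_rejected(self, landscape):
        present, _ = landscape
        occ = pd.DataFrame({"lon": [99.0], "lat": [28.0]})
        with pytest.raises(ValueError, match="outside"):
            make_presence_background(occ, present, seed=0)


@pytest.fixture(scope="module")
def separable_data():
    rng = np.random.default_rng(0)
    n = 400
    X = rng.normal(size=(n, 2))
    y = (X[:, 0] > 0.0).astype(int)
    X[:, 0] += np.where(y == 1, 1.0, -1.0)  # wide margin
    return X, y


class TestEnsemble:
    def test_separable_fixture_all_members_pass_similar_weights(self, separable_data):
        X, y = separable_data
        ens = EnsembleSDM(n_replicates=4, random_state=0).fit(X, y)
        assert set(ens.accepted_) == set(default_members())
        w = np.array(list(ens.weights_.values()))
        assert w.max() / w.min() < 1.2
        assert w.sum() == pytest.approx(1.0)

    def test_random_dummy_member_excluded_by_gates(self, separable_data):
        X, y = separable_data
        members = default_members()
        members["dummy"] = RandomScorer()
        ens = EnsembleSDM(members=members, n_replicates=4, random_state=0).fit(X, y)
        assert "dummy" not in ens.accepted_

    def test_gate_monotonicity_raising_gates_never_admits(self, separable_data):
        X, y = separable_data
        members = default_members()
        members["dummy"] = RandomScorer()
        loose = EnsembleSDM(members=members, n_replicates=3, tss_gate=0.5,
                            auc_gate=0.7, random_state=1).fit(X, y)
        strict = EnsembleSDM(members=members, n_replicates=3, tss_gate=0.9,
                             auc_gate=0.95, random_state=1).fit(X, y)
        assert set(strict.accepted_) <= set(loose.accepted_)

    def test_all_members_failing_raises_with_metrics(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 2))
        y = rng.integers(0, 2, 200)  # labels carry no signal
        with pytest.raises(ValueError, match="gates"):
            EnsembleSDM(n_replicates=3, random_state=0).fit(X, y)

    def test_seeded_replicates_reproducible(self, separable_data):
        X, y = separable_data
        a = EnsembleSDM(n_replicates=3, random_state=5).fit(X, y)
        b = EnsembleSDM(n_replicates=3, random_state=5).fit(X, y)
        pd.testing.assert_frame_equal(a.member_metrics_, b.member_metrics_)

    def test_suitability_bounded(self, separable_data):
        X, y = separable_data
        ens = EnsembleSDM(n_replicates=3, random_state=0).fit(X, y)
        s = ens.predict_suitability(X)
        assert np.all((s >= 0) & (s <= 1))


class TestSuitabilityMaps:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(0, 10, 500)
        w = rng.normal(size=500)
        y = ((v > 3) & (v < 6)).astype(int)
        X = np.column_stack([v, w])
        ens = EnsembleSDM(n_replicates=3, random_state=0).fit(X, y)
        return ens

    def test_uniform_climate_uniform_suitability(self, fitted):
        ls = ClimateLayerSet("p", {
            "v": ClimateGrid(np.full((3, 4), 4.5), 100, 20, 1.0),
            "w": ClimateGrid(np.zeros((3, 4)), 100, 20, 1.0),
        })
        s = suitability_map(fitted, ls, ["v", "w"])
        assert np.ptp(s) == pytest.approx(0.0)

    def test_suitability_in_unit_interval_and_niche_shaped(self, fitted):
        vals = np.tile(np.linspace(0, 10, 12), (3, 1))
        ls = ClimateLayerSet("p", {
            "v": ClimateGrid(vals, 100, 20, 1.0),
            "w": ClimateGrid(np.zeros((3, 12)), 100, 20, 1.0),
        })
        s = suitability_map(fitted, ls, ["v", "w"])
        assert np.all((s >= 0) & (s <= 1))
        inside = s[:, (vals[0] > 3.5) & (vals[0] < 5.5)].mean()
        outside = s[:, (vals[0] < 2) | (vals[0] > 8)].mean()
        assert inside > outside + 0.3

    def test_missing_variable_rejected(self, fitted):
        ls = ClimateLayerSet("p", {"v": ClimateGrid(np.zeros((2, 2)), 100, 20, 1.0)})
        with pytest.raises(KeyError):
            suitability_map(fitted, ls, ["v", "w"])


class TestVulnerability:
    def test_identical_grids_zero(self):
        s = np.random.default_rng(0).random((4, 4))
        np.testing.assert_allclose(ecological_vulnerability(s, s), 0.0)

    def test_total_loss_is_minus_one(self):
        assert ecological_vulnerability(np.zeros((2, 2)),
                                        np.ones((2, 2)))[0, 0] == -1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((3, 3)), rng.random((3, 3))
        np.testing.assert_allclose(
            ecological_vulnerability(a, b), -ecological_vulnerability(b, a)
        )

    def test_matches_per_cell_loop(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((3, 4)), rng.random((3, 4))
        ve = ecological_vulnerability(a, b)
        for i in range(3):
            for j in range(4):
                assert ve[i, j] == a[i, j] - b[i, j]

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ecological_vulnerability(np.zeros((2, 2)), np.zeros((3, 3)))


class TestHabitatAreaChange:
    def test_future_equals_present_zero_change(self):
        s = np.random.default_rng(0).random((4, 4))
        areas = np.ones((4, 4))
        assert habitat_area_change(s, s, 0.5, areas) == 0.0

    def test_total_loss_minus_hundred(self):
        s = np.full((4, 4), 0.9)
        assert habitat_area_change(s, np.zeros((4, 4)), 0.5,
                                   np.ones((4, 4))) == -100.0

    def test_hand_counted_four_by_four(self):
        # present: 8 suitable cells; future: 6 -> change = -25%
        sp = np.zeros((4, 4))
        sp[:2, :] = 0.8
        sf = np.zeros((4, 4))
        sf[0, :] = 0.8
        sf[1, :2] = 0.8
        assert habitat_area_change(sp, sf, 0.5, np.ones((4, 4))) == pytest.approx(-25.0)

    def test_area_weighting_by_latitude(self):
        grid = ClimateGrid(np.zeros((3, 3)), 100, 0, 1.0)
        areas = cell_areas_km2(grid)
        # cells nearer the equator (row 2 here) are larger
        assert areas[2, 0] > areas[0, 0]
        one_deg_eq = (6371.0 * np.pi / 180) ** 2
        assert areas[2, 0] == pytest.approx(one_deg_eq * np.cos(np.radians(0.5)),
                                            rel=1e-6)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            habitat_area_change(np.ones((2, 2)), np.ones((2, 2)), 1.5,
                                np.ones((2, 2)))


def test_simulated_occurrence_fixture_supports_strong_members(landscape):
    """The bundled niche fixture yields members that clear the study gates."""
    present, _ = landscape
    occ = simulate_occurrences(present, n=220, seed=8)
    pb = make_presence_background(occ, present, n_background=600, seed=9)
    X = pb[[f"env_{v}" for v in present.variables]].to_numpy()
    y = (pb["label"] == "presence").to_numpy().astype(int)
    ens = EnsembleSDM(n_replicates=3, random_state=0).fit(X, y)
    assert len(ens.accepted_) >= 3
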