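"""Turnover models and genomic-offset operators."""

import numpy as np
import pytest

from loadscape.grids import ClimateGrid, ClimateLayerSet
from loadscape.offset import (
    DissimilaritySplineTurnover,
    GradientForestTurnover,
    forward_offset,
    haversine_km,
    local_offset,
    reverse_offset,
    rgb_composite,
    transform_climate,
)


class IdentityModel:
    """Stub turnover model with identity transforms, for operator tests."""

    def __init__(self, variables):
        self.variables_ = list(variables)

    def transform_variables(self, V):
        return np.asarray(V, dtype=float).copy()


def grid(vals, res=1.0):
    return ClimateGrid(np.asarray(vals, dtype=float), xll=100.0, yll=20.0,
                       cellsize=res)


def layers(name, **arrays):
    return ClimateLayerSet(name, {k: grid(v) for k, v in arrays.items()})


def test_haversine_one_degree_latitude():
    # one degree of latitude on a 6371-km sphere: ~111.19 km
    assert haversine_km(100, 30, 100, 31) == pytest.approx(111.19, abs=0.1)


class TestGradientForest:
    @pytest.fixture(scope="class")
    def cline_fit(self):
        rng = np.random.default_rng(0)
        env = np.linspace(0, 10, 12)[:, None]
        X = np.hstack([env, rng.normal(0, 1, (12, 1))])
        F = 1 / (1 + np.exp(-(env - 5))) + rng.normal(0, 0.05, (12, 15))
        return GradientForestTurnover(random_state=0).fit(
            X, F, variables=["causal", "shuffled"]
        )

    def test_transforms_monotone_nondecreasing(self, cline_fit):
        v = np.linspace(-3, 13, 200)
        tr = cline_fit.transform_variables(np.column_stack([v, v]))
        assert np.all(np.diff(tr[:, 0]) >= 0)
        assert np.all(np.diff(tr[:, 1]) >= 0)

    def test_unassociated_variable_importance_below_ten_percent(self, cline_fit):
        imp = cline_fit.variable_importance_
        assert imp["shuffled"] < 0.1 * imp["causal"]

    def test_step_cline_split_near_midpoint(self):
        env = np.linspace(0, 10, 21)[:, None]
        f = (env[:, 0] > 5).astype(float)
        model = GradientForestTurnover(random_state=1).fit(
            env, f[:, None], variables=["v"]
        )
        thr, cum = model.cumulative_importance_["v"]
        jump_at = thr[np.argmax(np.diff(np.concatenate([[0.0], cum])))]
        assert abs(jump_at - 5.0) <= 0.5  # one grid bin

    def test_clamps_outside_training_range(self, cline_fit):
        lo = cline_fit.transform_variables(np.array([[-100.0, 0.0]]))
        hi = cline_fit.transform_variables(np.array([[+100.0, 0.0]]))
        assert lo[0, 0] == pytest.approx(0.0)
        assert hi[0, 0] == pytest.approx(cline_fit.variable_importance_["causal"])

    def test_constant_variable_warns_zero_transform(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 1, 10)
        X = np.column_stack([x, np.ones(10)])
        F = x[:, None] + rng.normal(0, 0.05, (10, 5))
        with pytest.warns(UserWarning, match="constant"):
            model = GradientForestTurnover(random_state=0).fit(
                X, F, variables=["a", "const"]
            )
        assert model.variable_importance_["const"] == 0.0

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            GradientForestTurnover().fit(np.zeros((3, 1)), np.zeros((3, 2)))


class TestDissimilaritySpline:
    def test_rescaling_maps_extremes_to_unit_interval(self):
        rng = np.random.default_rng(0)
        env = np.column_stack([np.linspace(0, 10, 6), rng.normal(0, 1, 6)])
        d = np.abs(env[:, 0][:, None] - env[:, 0][None, :])
        fst = d / d.max() * 0.6 + 0.1
        np.fill_diagonal(fst, 0.0)
        model = DissimilaritySplineTurnover().fit(fst, env)
        assert model.fst_range_[0] == pytest.approx(fst[np.triu_indices(6, 1)].min())
        assert model.fst_range_[1] == pytest.approx(fst[np.triu_indices(6, 1)].max())

    def test_distance_proportional_fst_credits_causal_variable(self):
        rng = np.random.default_rng(1)
        env = np.column_stack([np.linspace(0, 10, 8), rng.normal(0, 1, 8)])
        d = np.abs(env[:, 0][:, None] - env[:, 0][None, :])
        fst = d / d.max() * 0.8
        np.fill_diagonal(fst, 0.0)
        model = DissimilaritySplineTurnover().fit(fst, env, variables=["v", "noise"])
        total = sum(model.variable_importance_.values())
        assert model.variable_importance_["v"] / total > 0.9

    def test_all_zero_fst_gives_zero_transforms_and_offsets(self):
        env = np.column_stack([np.linspace(0, 10, 5)])
        model = DissimilaritySplineTurnover().fit(np.zeros((5, 5)), env,
                                                  variables=["v"])
        tr = model.transform_variables(np.linspace(0, 10, 20)[:, None])
        np.testing.assert_allclose(tr, 0.0)

    def test_transforms_monotone(self):
        rng = np.random.default_rng(2)
        env = rng.uniform(0, 10, (7, 2))
        fst = np.abs(env[:, 0][:, None] - env[:, 0][None, :]) / 20
        np.fill_diagonal(fst, 0.0)
        model = DissimilaritySplineTurnover().fit(fst, env)
        v = np.linspace(0, 10, 100)
        tr = model.transform_variables(np.column_stack([v, v]))
        assert np.all(np.diff(tr[:, 0]) >= -1e-9)
        assert np.all(np.diff(tr[:, 1]) >= -1e-9)

    @pytest.mark.parametrize("bad", ["asym", "diag", "small"])
    def test_invalid_fst_matrix_rejected(self, bad):
        env = np.zeros((5, 1)) + np.arange(5)[:, None]
        fst = np.zeros((5, 5))
        if bad == "asym":
            fst[0, 1] = 0.5
        elif bad == "diag":
            np.fill_diagonal(fst, 0.1)
        else:
            fst = np.zeros((3, 3))
            env = env[:3]
        with pytest.raises(ValueError):
            DissimilaritySplineTurnover().fit(fst, env)


class TestTransformClimate:
    def test_identity_model_returns_input(self):
        vals = np.arange(12.0).reshape(3, 4)
        ls = layers("present", v=vals)
        out = transform_climate(IdentityModel(["v"]), ls)
        np.testing.assert_allclose(out[..., 0], vals)

    def test_missing_layer_rejected(self):
        ls = layers("present", v=np.ones((2, 2)))
        with pytest.raises(KeyError, match="missing"):
            transform_climate(IdentityModel(["other"]), ls)

    def test_nodata_propagates(self):
        vals = np.ones((2, 2))
        vals[0, 0] = -9999.0
        ls = layers("present", v=vals)
        out = transform_climate(IdentityModel(["v"]), ls)
        assert np.isnan(out[0, 0, 0]) and out[1, 1, 0] == 1.0


class TestOffsets:
    @pytest.fixture()
    def geometry(self):
        g = grid(np.zeros((5, 5)))
        lon, lat = g.cell_centers()
        return lon, lat

    def brute_force(self, tp, tf, lon, lat, max_km):
        nrows, ncols, _ = tp.shape
        loc = np.zeros((nrows, ncols))
        fwd = np.zeros((nrows, ncols))
        rev = np.zeros((nrows, ncols))
        for i in range(nrows):
            for j in range(ncols):
                loc[i, j] = np.sqrt(((tf[i, j] - tp[i, j]) ** 2).sum())
                best = np.inf
                for a in range(nrows):
                    for b in range(ncols):
                        d_geo = haversine_km(lon[i, j], lat[i, j],
                                             lon[a, b], lat[a, b])
                        if d_geo <= max_km or (a == i and b == j):
                            best = min(best, np.sqrt(
                                ((tf[a, b] - tp[i, j]) ** 2).sum()))
                fwd[i, j] = best
                rev[i, j] = min(
                    np.sqrt(((tp[a, b] - tf[i, j]) ** 2).sum())
                    for a in range(nrows) for b in range(ncols)
                )
        return loc, fwd, rev

    def test_future_equals_present_all_offsets_zero(self, geometry):
        lon, lat = geometry
        rng = np.random.default_rng(0)
        t = rng.random((5, 5, 2))
        assert local_offset(t, t).max() == 0.0
        assert forward_offset(t, t, lon, lat, np.inf).max() == 0.0
        assert reverse_offset(t, t).max() == 0.0

    def test_uniform_shift_local_offset_closed_form(self):
        t = np.zeros((4, 4, 2))
        tf = t.copy()
        tf[..., 0] += 3.0
        np.testing.assert_allclose(local_offset(t, tf), 3.0)

    def test_all_three_offsets_match_brute_force(self, geometry):
        lon, lat = geometry
        rng = np.random.default_rng(1)
        tp = rng.random((5, 5, 3))
        tf = rng.random((5, 5, 3))
        for cap in (100.0, 250.0, np.inf):
            loc_o, fwd_o, rev_o = self.brute_force(tp, tf, lon, lat, cap)
            np.testing.assert_allclose(local_offset(tp, tf), loc_o)
            np.testing.assert_allclose(forward_offset(tp, tf, lon, lat, cap), fwd_o)
            np.testing.assert_allclose(reverse_offset(tp, tf), rev_o)

    def test_forward_nonincreasing_in_dispersal_cap(self, geometry):
        lon, lat = geometry
        rng = np.random.default_rng(2)
        tp = rng.random((5, 5, 2))
        tf = rng.random((5, 5, 2))
        caps = [100.0, 250.0, 500.0, 1000.0, np.inf]
        maps = [forward_offset(tp, tf, lon, lat, c) for c in caps]
        for small, big in zip(maps, maps[1:]):
            assert np.all(small >= big - 1e-12)

    def test_forward_bounded_by_local(self, geometry):
        lon, lat = geometry
        rng = np.random.default_rng(3)
        tp = rng.random((5, 5, 2))
        tf = rng.random((5, 5, 2))
        assert np.all(forward_offset(tp, tf, lon, lat, np.inf)
                      <= local_offset(tp, tf) + 1e-12)

    def test_tiny_cap_equals_local(self, geometry):
        lon, lat = geometry
        rng = np.random.default_rng(4)
        tp = rng.random((5, 5, 2))
        tf = rng.random((5, 5, 2))
        np.testing.assert_allclose(
            forward_offset(tp, tf, lon, lat, 1e-6), local_offset(tp, tf)
        )

    def test_reverse_zero_when_future_matches_some_present_cell(self, geometry):
        tp = np.zeros((5, 5, 1))
        tp[2, 3, 0] = 7.0
        tf = np.full((5, 5, 1), 7.0)  # every future cell matches present (2,3)
        np.testing.assert_allclose(reverse_offset(tp, tf), 0.0)

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            local_offset(np.zeros((2, 2, 1)), np.zeros((3, 2, 1)))


class TestRgbComposite:
    def test_all_zero_maps_black_with_warning(self):
        z = np.zeros((3, 3))
        with pytest.warns(UserWarning, match="constant"):
            img = rgb_composite(z, z, z)
        np.testing.assert_allclose(img, 0.0)

    def test_band_order_local_forward_reverse(self):
        base = np.zeros((2, 2))
        hot = base.copy()
        hot[0, 0] = 1.0
        img = rgb_composite(hot, base + np.eye(2), base)
        assert img[0, 0, 0] == 1.0  # local -> red
        assert img[0, 0, 1] == 1.0  # forward -> green (eye has 1 at 0,0)
        with pytest.warns(UserWarning):
            img2 = rgb_composite(base, base, hot)
        assert img2[0, 0, 2] == 1.0  # reverse -> blue

    def test_cell_maximal_in_all_three_is_white(self):
        rng = np.random.default_rng(0)
        a = rng.random((4, 4))
        a[1, 2] = 2.0  # strict max
        img = rgb_composite(a, a, a)
        np.testing.assert_allclose(img[1, 2], [1.0, 1.0, 1.0])

    def test_nodata_propagates(self):
        a = np.array([[np.nan, 1.0], [0.0, 0.5]])
        img = rgb_composite(a, a, a)
        assert np.isnan(img[0, 0]).all()
        assert np.isfinite(img[1, 1]).all()
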