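"""World, route and pitch-distribution generators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antcompass import (PitchDistribution, Route, World, WorldParams,
                        generate_route, generate_world, sample_pitch_trace)
from antcompass.world import spawn_seeds


class TestWorldParams:
    @pytest.mark.parametrize("kwargs", [
        dict(n_tussocks=-1),
        dict(blades_per_tussock=0),
        dict(radius_range=(0.3, 0.1)),
        dict(height_range=(-0.1, 0.3)),
        dict(blade_intensity_range=(0.5, 0.5)),
        dict(ground_intensity=0.2),          # inside the blade range
        dict(sky_intensity=0.5),
        dict(ground_intensity=1.0),          # equal to sky
        dict(extent=0.0),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            WorldParams(**kwargs)


class TestGenerateWorld:
    def test_empty_world(self):
        w = generate_world(WorldParams(n_tussocks=0))
        assert w.n_blades == 0
        assert w.ground_intensity != w.sky_intensity

    def test_blade_count_and_bounds(self):
        w = generate_world(WorldParams(n_tussocks=50, blades_per_tussock=30,
                                       seed=7))
        assert w.n_blades == 1500
        assert w.triangles.shape == (1500, 3, 3)
        xy = w.triangles[:, :, :2]
        assert xy.min() >= 0.0 and xy.max() <= 10.0
        assert w.triangles[:, :, 2].min() >= 0.0
        # blade intensities stay inside their range, away from ground/sky
        assert w.intensities.min() >= 0.0 and w.intensities.max() <= 0.55

    def test_determinism(self):
        p = WorldParams(n_tussocks=5, blades_per_tussock=8, seed=11)
        w1, w2 = generate_world(p), generate_world(p)
        np.testing.assert_array_equal(w1.triangles, w2.triangles)
        np.testing.assert_array_equal(w1.intensities, w2.intensities)

    def test_different_seeds_differ(self):
        p1 = WorldParams(n_tussocks=5, blades_per_tussock=8, seed=1)
        p2 = WorldParams(n_tussocks=5, blades_per_tussock=8, seed=2)
        assert not np.array_equal(generate_world(p1).triangles,
                                  generate_world(p2).triangles)

    @settings(max_examples=15, deadline=None)
    @given(n=st.integers(1, 6), b=st.integers(1, 10), seed=st.integers(0, 999))
    def test_invariants_hold_for_arbitrary_params(self, n, b, seed):
        w = generate_world(WorldParams(n_tussocks=n, blades_per_tussock=b,
                                       seed=seed))
        assert w.n_blades == n * b
        assert w.triangles[:, :, :2].min() >= 0.0
        assert w.triangles[:, :, :2].max() <= w.extent
        assert w.triangles[:, :, 2].min() >= 0.0

    def test_json_roundtrip(self, tmp_path):
        w = generate_world(WorldParams(n_tussocks=3, blades_per_tussock=4,
                                       seed=5))
        path = tmp_path / "world.json"
        w.to_json(path)
        w2 = World.from_json(path)
        np.testing.assert_array_equal(w.triangles, w2.triangles)
        np.testing.assert_array_equal(w.intensities, w2.intensities)
        assert w2.ground_intensity == w.ground_intensity

    def test_obj_export(self, tmp_path):
        w = generate_world(WorldParams(n_tussocks=2, blades_per_tussock=3,
                                       seed=5))
        w.to_obj(tmp_path / "world.obj")
        text = (tmp_path / "world.obj").read_text()
        assert text.count("\nf ") + text.startswith("f ") == 6


class TestGenerateRoute:
    def test_storage_positions_812(self, env_std):
        # 8.12 m at 1 cm spacing: memories at 1..812 cm; the 0 cm start is
        # the first test origin, not a memory
        assert len(env_std.route.storage_indices(0.01)) == 812

    def test_short_route_storage_count(self, small_world):
        r = generate_route(small_world, 0.05, 0.01, seed=1)
        assert len(r.storage_indices(0.01)) == 5

    def test_length_spacing_and_curvature(self, small_world):
        r = generate_route(small_world, 2.0, 0.01, seed=9, max_turn_deg=2.0)
        assert abs(r.length_m - 2.0) < 1e-3
        steps = np.sqrt((np.diff(r.points, axis=0) ** 2).sum(axis=1))
        np.testing.assert_allclose(steps, 0.01, rtol=1e-9)
        turns = np.abs((np.diff(r.headings_deg) + 180) % 360 - 180)
        assert turns.max() <= 2.0 + 1e-9

    def test_stays_inside_margin(self, small_world):
        r = generate_route(small_world, 4.0, 0.01, seed=2, margin_m=1.5)
        assert r.points.min() >= 1.5 - 1e-9
        assert r.points.max() <= 8.5 + 1e-9

    def test_determinism(self, small_world):
        r1 = generate_route(small_world, 1.0, 0.01, seed=4)
        r2 = generate_route(small_world, 1.0, 0.01, seed=4)
        np.testing.assert_array_equal(r1.points, r2.points)

    def test_bad_arguments(self, small_world):
        with pytest.raises(ValueError):
            generate_route(small_world, -1.0, 0.01)
        with pytest.raises(ValueError):
            generate_route(small_world, 1.005, 0.01)   # not a spacing multiple
        tiny = World(np.zeros((0, 3, 3)), np.zeros(0), np.zeros(0, int),
                     0.65, 1.0, extent=3.0)
        with pytest.raises(ValueError):
            generate_route(tiny, 1.0, 0.01, margin_m=1.5)

    def test_csv_export(self, small_world, tmp_path):
        import pandas as pd
        r = generate_route(small_world, 0.5, 0.01, seed=1)
        r.to_csv(tmp_path / "route.csv")
        df = pd.read_csv(tmp_path / "route.csv")
        assert list(df.columns) == ["index", "s_m", "x_m", "y_m", "heading_deg"]
        assert len(df) == r.n_points


class TestPitchDistributions:
    def test_zero_kind(self):
        trace = sample_pitch_trace(PitchDistribution.from_kind("zero"), 812,
                                   seed=1)
        assert len(trace) == 812
        assert np.all(trace.angles_deg == 0.0)

    @pytest.mark.parametrize("kind,lo,hi", [
        ("small", -20.6, 12.99),
        ("large", -40.4, 21.69),
    ])
    def test_observed_ranges_and_zero_mean(self, kind, lo, hi):
        d = PitchDistribution.from_kind(kind)
        assert abs(d.pool.mean()) < 1e-9
        assert d.pool.min() == pytest.approx(lo)
        assert d.pool.max() == pytest.approx(hi)
        trace = sample_pitch_trace(d, 10_000, seed=2)
        assert trace.angles_deg.min() >= lo and trace.angles_deg.max() <= hi

    def test_large_sample_attains_pool_extremes(self):
        d = PitchDistribution.from_kind("small")
        trace = sample_pitch_trace(d, 100_000, seed=5)
        assert trace.angles_deg.min() == d.pool.min()
        assert trace.angles_deg.max() == d.pool.max()
        se = d.pool.std() / np.sqrt(100_000)
        assert abs(trace.angles_deg.mean()) < 3 * se

    def test_empirical_kind(self):
        d = PitchDistribution.from_kind("empirical", angles=[-5.0, 1.0, 10.0])
        assert abs(d.pool.mean()) < 1e-9
        assert d.kind == "empirical"
        with pytest.raises(ValueError):
            PitchDistribution.from_kind("empirical")

    def test_trace_determinism(self):
        d = PitchDistribution.from_kind("large")
        t1 = sample_pitch_trace(d, 100, seed=9)
        t2 = sample_pitch_trace(d, 100, seed=9)
        np.testing.assert_array_equal(t1.angles_deg, t2.angles_deg)
        with pytest.raises(ValueError):
            sample_pitch_trace(d, 0, seed=1)


def test_spawn_seeds_deterministic_and_bounded():
    s1 = spawn_seeds(123, 6)
    s2 = spawn_seeds(123, 6)
    np.testing.assert_array_equal(s1, s2)
    assert (s1 < 2**31).all()
    assert len(set(s1.tolist())) == 6
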