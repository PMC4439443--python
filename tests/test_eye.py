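"""Retina geometry and the ray-casting renderer."""

import numpy as np
import pytest
from oracle_utils import brute_force_pixel

from antcompass import (PanoramicImage, Pose, RetinaSpec, WorldParams,
                        generate_world, pixel_directions, render_view)
from antcompass.eye import render_scan, wrap_deg


class TestRetinaSpec:
    def test_standard_grid(self):
        spec = RetinaSpec()
        assert spec.n_cols == 296 // 4 == 74
        assert spec.n_rows == 76 // 4 == 19
        assert spec.n_pixels == 1406
        # row centres span +/-36 deg inside the +/-38 deg field
        assert spec.elevations_deg[0] == 36.0
        assert spec.elevations_deg[-1] == -36.0
        assert spec.elevations_deg[9] == 0.0
        # symmetric rear blindspot: column centres at +/-146 .. +/-2
        assert spec.azimuths_deg[0] == 146.0
        assert spec.azimuths_deg[-1] == -146.0

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            RetinaSpec(hfov_deg=295.0)       # not a multiple of 4
        with pytest.raises(ValueError):
            RetinaSpec(vfov_deg=200.0)
        with pytest.raises(ValueError):
            RetinaSpec(supersampling=0)

    def test_pitch_limit(self):
        with pytest.raises(ValueError):
            Pose(5, 5, pitch_deg=95.0)

    def test_yaw_wrapped(self):
        assert Pose(5, 5, yaw_deg=190.0).yaw_deg == -170.0
        assert Pose(5, 5, yaw_deg=-180.0).yaw_deg == 180.0


class TestPixelDirections:
    def test_grid_size_and_unit_norm(self):
        d = pixel_directions(RetinaSpec(), Pose(5, 5))
        assert d.shape == (19, 74, 3)
        np.testing.assert_allclose(np.linalg.norm(d, axis=-1), 1.0, atol=1e-12)

    def test_forward_within_half_pixel(self):
        # 74 columns with a symmetric blindspot leave no exact 0-azimuth
        # column; the two central columns straddle forward within 2 deg
        d = pixel_directions(RetinaSpec(), Pose(5, 5))
        angles = np.degrees(np.arccos(np.clip(d @ [1.0, 0.0, 0.0], -1, 1)))
        assert angles.min() <= 2.0 + 1e-9

    def test_top_row_elevation(self):
        d = pixel_directions(RetinaSpec(), Pose(5, 5))
        elev = np.degrees(np.arcsin(d[..., 2]))
        np.testing.assert_allclose(elev[0], 36.0, atol=1e-9)
        np.testing.assert_allclose(elev[-1], -36.0, atol=1e-9)

    def test_pitch_rotates_forward_up(self):
        # central-row pixels gain elevation equal to the pitch
        d0 = pixel_directions(RetinaSpec(), Pose(5, 5, pitch_deg=0.0))
        d20 = pixel_directions(RetinaSpec(), Pose(5, 5, pitch_deg=20.0))
        c = 36  # near-forward column
        e0 = np.degrees(np.arcsin(d0[9, c, 2]))
        e20 = np.degrees(np.arcsin(d20[9, c, 2]))
        assert e20 > e0
        # exactly +20 deg for the forward-most direction component
        np.testing.assert_allclose(
            np.degrees(np.arcsin(d20[9, :, 2].max())), 20.0, atol=2.1)

    def test_yaw_rotates_azimuth(self):
        d = pixel_directions(RetinaSpec(), Pose(5, 5, yaw_deg=90.0))
        # forward pixels now point along +y
        assert d[9, 36, 1] > 0.9


class TestRenderView:
    def test_empty_world_horizon_split(self):
        w = generate_world(WorldParams(n_tussocks=0))
        img = render_view(w, Pose(5, 5), RetinaSpec(supersampling=1))
        assert np.all(img.values[:10] == w.sky_intensity)     # elev >= 0
        assert np.all(img.values[10:] == w.ground_intensity)  # elev < 0

    def test_determinism(self, small_world):
        p = Pose(5.2, 4.8, yaw_deg=33.0, pitch_deg=-7.0)
        a = render_view(small_world, p)
        b = render_view(small_world, p)
        np.testing.assert_array_equal(a.values, b.values)

    def test_pose_outside_extent_rejected(self, small_world):
        with pytest.raises(ValueError):
            render_view(small_world, Pose(-1.0, 5.0))

    def test_single_triangle_ahead_fills_central_pixels(self):
        from antcompass import World
        # a big triangle dead ahead (1 m away, 1 m wide) subtending >> 4 deg
        tri = np.array([[[6.0, 4.5, 0.0], [6.0, 5.5, 0.0], [6.0, 5.0, 1.5]]])
        w = World(tri, np.array([0.2]), np.array([0]),
                  ground_intensity=0.65, sky_intensity=1.0)
        img = render_view(w, Pose(5.0, 5.0), RetinaSpec(supersampling=1))
        # the two central columns look at azimuth +/-2 deg
        assert img.values[9, 36] == 0.2
        assert img.values[9, 37] == 0.2

    def test_matches_brute_force_oracle(self, small_world):
        rng = np.random.default_rng(0)
        spec = RetinaSpec(supersampling=1)
        pose = Pose(5.4, 5.1, yaw_deg=17.0, pitch_deg=5.0)
        img = render_view(small_world, pose, spec)
        rows = rng.integers(0, spec.n_rows, 120)
        cols = rng.integers(0, spec.n_cols, 120)
        for r, c in zip(rows, cols):
            assert img.values[r, c] == brute_force_pixel(
                small_world, pose, spec, int(r), int(c))

    def test_supersampled_matches_brute_force_oracle(self, small_world):
        rng = np.random.default_rng(1)
        spec = RetinaSpec(supersampling=2)
        pose = Pose(4.9, 5.3, yaw_deg=-40.0, pitch_deg=-8.0)
        img = render_view(small_world, pose, spec)
        for r, c in zip(rng.integers(0, 19, 25), rng.integers(0, 74, 25)):
            assert img.values[r, c] == pytest.approx(
                brute_force_pixel(small_world, pose, spec, int(r), int(c)),
                abs=1e-12)

    def test_yaw_shift_equivalence_at_pitch_zero(self, small_world):
        # yawing by a whole pixel at pitch 0 shifts columns exactly
        a = render_view(small_world, Pose(5, 5, yaw_deg=0.0)).values
        b = render_view(small_world, Pose(5, 5, yaw_deg=8.0)).values
        np.testing.assert_array_equal(b[:, 2:], a[:, :-2])

    def test_full_sphere_window_equivalence(self, small_world):
        # a 360 x 180 deg sphere render windows down to the retina view at
        # pitch 0 for any whole-pixel yaw
        retina = RetinaSpec(supersampling=1)
        sphere_spec = RetinaSpec(hfov_deg=360.0, vfov_deg=180.0,
                                 supersampling=1)
        sphere = render_view(small_world, Pose(5, 5), sphere_spec).values
        s_az = sphere_spec.azimuths_deg
        s_el = sphere_spec.elevations_deg
        for yaw in (0.0, 40.0, -120.0):
            img = render_view(small_world, Pose(5, 5, yaw_deg=yaw),
                              retina).values
            for r, el in enumerate(retina.elevations_deg):
                sr = int(np.argmin(np.abs(s_el - el)))
                for c, az in enumerate(retina.azimuths_deg):
                    world_az = wrap_deg(az + yaw)
                    sc = int(np.argmin(np.abs(s_az - world_az)))
                    assert img[r, c] == sphere[sr, sc]

    def test_horizon_shifts_with_pitch(self, small_world):
        # pitching up raises the fraction of sky in view, monotonically
        fractions = []
        for pitch in (-20.0, -10.0, 0.0, 10.0, 20.0):
            img = render_view(small_world, Pose(5, 5, pitch_deg=pitch),
                              RetinaSpec(supersampling=1))
            fractions.append((img.values == small_world.sky_intensity).mean())
        assert np.all(np.diff(fractions) > 0)

    def test_render_scan_matches_render_view(self, small_world):
        yaws = np.array([0.0, 45.0, 170.0])
        scan = render_scan(small_world, 5.0, 5.0, -6.0, yaws)
        for k, yaw in enumerate(yaws):
            img = render_view(small_world,
                              Pose(5.0, 5.0, yaw_deg=yaw, pitch_deg=-6.0))
            np.testing.assert_array_equal(scan[k], img.flat())


class TestPanoramicImage:
    def test_shape_checked(self):
        with pytest.raises(ValueError):
            PanoramicImage(np.zeros((5, 5)), Pose(5, 5))

    def test_export(self, small_world, tmp_path):
        img = render_view(small_world, Pose(5, 5))
        img.save_npy(tmp_path / "view.npy")
        assert np.load(tmp_path / "view.npy").shape == (19, 74)
        img.to_png(tmp_path / "view.png")
        assert (tmp_path / "view.png").stat().st_size > 0
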