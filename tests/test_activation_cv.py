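"""Activation maps and conduction-velocity fields."""

import numpy as np
import pytest

import rotorkit as rk
from rotorkit import analytic
from rotorkit.activation import ActivationMap
from rotorkit.errors import InputError


def plane_map(speed_cm_s, direction_deg, shape=(40, 40), dx=0.1):
    """Analytic planar activation map T = projection / speed."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    th = np.deg2rad(direction_deg)
    proj = (xx * np.cos(th) + yy * np.sin(th)) * dx
    times = (proj - proj.min()) / (speed_cm_s / 100.0)
    return ActivationMap(times=times, valid=np.ones(shape, dtype=bool), dx=dx)


class TestActivationMap:
    def test_planar_movie_activation_matches_construction(self):
        mov = analytic.planar_wave_movie(speed_cm_s=5.0, direction_deg=0.0)
        amap = rk.activation_map(mov, (0.0, 300.0))
        r = 30
        cols = np.arange(5, 55)
        expected = (cols - 5) * mov.dx / 0.05          # ms
        got = amap.times[r, cols] - amap.times[r, 5]
        assert np.nanmax(np.abs(got - expected)) <= mov.frame_interval

    def test_target_wave_isochrones_are_radial(self):
        mov = analytic.target_wave_movie(speed_cm_s=5.0)
        amap = rk.activation_map(mov, (0.0, 350.0))
        yy, xx = np.mgrid[0:80, 0:80]
        r_mm = np.hypot(yy - 39.5, xx - 39.5) * mov.dx
        sel = amap.valid & (r_mm > 0.5) & (r_mm < 3.5)
        expected = r_mm[sel] / 0.05
        got = amap.times[sel]
        got -= got.min() - expected.min()
        assert np.nanstd(got - expected) < mov.frame_interval

    def test_pixels_without_upstroke_invalidated(self):
        mov = analytic.planar_wave_movie(shape=(30, 30))
        data = mov.data.copy()
        data[0:3, 0:3, :] = 0.01                        # silent corner
        broken = mov.copy_with(data)
        amap = rk.activation_map(broken, (0.0, 300.0))
        assert not amap.valid[1, 1]
        assert np.isnan(amap.times[1, 1])


class TestCVField:
    @pytest.mark.parametrize("speed", [1.0, 3.0, 5.4, 10.0])
    @pytest.mark.parametrize("direction", [0.0, 37.0, 90.0, 208.0, 315.0])
    def test_plane_fit_recovers_speed_within_2pct(self, speed, direction):
        amap = plane_map(speed, direction)
        cvf = rk.cv_field(amap)
        s = rk.cv_summary(cvf, speed_cap=None)
        assert s.mean == pytest.approx(speed, rel=0.02)
        assert s.sd < 0.02 * speed + 1e-9

    def test_direction_recovered(self):
        amap = plane_map(5.0, 30.0)
        cvf = rk.cv_field(amap)
        ang = np.rad2deg(np.arctan2(np.nanmedian(cvf.vy), np.nanmedian(cvf.vx)))
        assert ang == pytest.approx(30.0, abs=1.0)

    def test_circular_wave_speed_and_radial_direction(self):
        """T = r / v: speed constant and velocity radial away from the
        source, within 5% beyond a few window widths."""
        shape, dx = (80, 80), 0.1
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        r_mm = np.hypot(yy - 39.5, xx - 39.5) * dx
        amap = ActivationMap(times=r_mm / 0.05, valid=np.ones(shape, bool), dx=dx)
        cvf = rk.cv_field(amap)
        sel = cvf.valid & (r_mm > 2.5)
        speeds = cvf.speed[sel]
        assert np.nanmax(np.abs(speeds - 5.0)) / 5.0 < 0.05
        # radial direction check at a probe point east of the center
        vx, vy = cvf.vx[40, 70], cvf.vy[40, 70]
        assert vx > 0 and abs(vy) < 0.1 * vx

    def test_agrees_with_independent_gradient_stencil(self):
        """Five-point central-difference gradient is an independent estimator
        of the same velocity on noiseless planes."""
        amap = plane_map(4.0, 25.0)
        cvf = rk.cv_field(amap)
        T, dx = amap.times, amap.dx
        gy, gx = np.gradient(T, dx)             # ms/mm
        g2 = gx ** 2 + gy ** 2
        speed_stencil = 100.0 / np.sqrt(g2)     # cm/s
        sel = cvf.valid
        ratio = cvf.speed[sel] / speed_stencil[sel]
        assert np.nanmax(np.abs(ratio - 1.0)) < 0.01

    def test_rotating_input_rotates_vectors(self):
        amap = plane_map(5.0, 0.0, shape=(40, 40))
        cvf = rk.cv_field(amap)
        rot = ActivationMap(times=np.rot90(amap.times).copy(),
                            valid=np.ones((40, 40), bool), dx=amap.dx)
        cvf_r = rk.cv_field(rot)
        # rotating the map by 90 deg turns +x propagation into -y propagation
        assert np.nanmedian(cvf.vx) == pytest.approx(5.0, rel=0.02)
        assert np.nanmedian(cvf_r.vy) == pytest.approx(-5.0, rel=0.02)
        np.testing.assert_allclose(np.nanmedian(cvf_r.speed),
                                   np.nanmedian(cvf.speed), rtol=1e-6)

    def test_noisy_window_rejected_by_residual_tolerance(self):
        amap = plane_map(5.0, 0.0)
        amap.times[20, 20] += 40.0              # gross outlier
        cvf = rk.cv_field(amap, residual_tol=3.0)
        assert not np.isfinite(cvf.speed[20, 20])


class TestCVSummary:
    def make_uniform(self, speed, shape=(20, 20)):
        vx = np.full(shape, float(speed))
        vy = np.zeros(shape)
        return rk.CVField(vx=vx, vy=vy, speed=np.hypot(vx, vy), dx=0.1,
                          fit_window=5, residual_tol=3.0)

    def test_uniform_field(self):
        s = rk.cv_summary(self.make_uniform(5.0))
        assert s.mean == 5.0
        assert s.sd == 0.0

    def test_two_region_mean(self):
        cv = self.make_uniform(2.0)
        cv.vx[:, 10:] = 4.0
        cv.speed = np.hypot(cv.vx, cv.vy)
        s = rk.cv_summary(cv)
        assert s.mean == pytest.approx(3.0)

    def test_histogram_uses_fixed_bins(self):
        s = rk.cv_summary(self.make_uniform(5.25))
        assert np.allclose(np.diff(s.hist_edges), 0.5)
        assert s.hist_counts.sum() == s.n

    def test_empty_region_rejected(self):
        cv = self.make_uniform(5.0)
        with pytest.raises(InputError):
            rk.cv_summary(cv, region=np.zeros((20, 20), dtype=bool))

    def test_fast_inward_block_left_shifts_cv_histogram(self):
        """Planar waves with half fast-inward conductance conduct slower:
        the speed histogram shifts toward lower bins."""
        def planar_cv_summary(drug):
            cfg = rk.TissueConfig(grid_shape=(30, 100), duration=500.0,
                                  sheet_diameter_mm=None)
            proto = rk.StimulusProtocol(kind="cross_field_S1S2",
                                        s2_delay=9999.0)
            res = rk.simulate(cfg, proto, drug=drug)
            amap = rk.activation_map(res.movie, (0.0, 450.0),
                                     min_amplitude=0.4)
            cvf = rk.cv_field(amap)
            region = np.zeros((30, 100), dtype=bool)
            region[10:20, 20:90] = True
            return rk.cv_summary(cvf, region=region)

        s_base = planar_cv_summary(None)
        s_block = planar_cv_summary(rk.DrugModel(g_fi_scale=0.5))
        assert s_block.mean < s_base.mean
        med = lambda s: s.hist_edges[:-1][np.argmax(s.hist_counts)]
        assert med(s_block) < med(s_base)
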