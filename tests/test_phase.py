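"""Phase mapping, singularity detection/tracking, curvature, rotor metrics."""

import numpy as np
import pytest

import rotorkit as rk
from rotorkit import analytic
from rotorkit.activation import ActivationMap
from rotorkit.phase import PhaseMap, _wrap, fit_circle

TWO_PI = 2 * np.pi


def phase_movie(ph_of_t, shape, dx=0.1, fi=5.0):
    """Movie whose pixel traces are cos(phase(t))."""
    data = np.cos(ph_of_t)
    return rk.OpticalMovie(data=data, dx=dx, frame_interval=fi,
                           mask=np.ones(shape, dtype=bool))


def still_phase(ph, n_frames=2, dx=0.1):
    return PhaseMap(phase=np.repeat(ph[:, :, None], n_frames, axis=2),
                    dx=dx, frame_interval=5.0,
                    mask=np.ones(ph.shape, dtype=bool))


def brute_force_winding(ph):
    """Independent plaquette winding: explicit loop over corners."""
    rows, cols = ph.shape
    w = np.zeros((rows - 1, cols - 1))
    for r in range(rows - 1):
        for c in range(cols - 1):
            loop = [ph[r, c], ph[r, c + 1], ph[r + 1, c + 1], ph[r + 1, c],
                    ph[r, c]]
            w[r, c] = sum(_wrap(b - a) for a, b in zip(loop[:-1], loop[1:]))
    return w


class TestPhaseMap:
    def test_sinusoid_unwrapped_slope(self):
        period = 300.0
        fi = 5.0
        t = np.arange(200) * fi
        ph = TWO_PI * t / period
        mov = phase_movie(np.broadcast_to(ph, (6, 6, 200)), (6, 6), fi=fi)
        pm = rk.phase_map(mov)
        slope = np.polyfit(t, np.unwrap(pm.phase[3, 3]), 1)[0]
        assert slope == pytest.approx(TWO_PI / period, rel=0.01)

    def test_spiral_phase_field_recovered_modulo_offset(self):
        rows = cols = 50
        yy, xx = np.mgrid[0:rows, 0:cols]
        theta = np.arctan2(yy - 24.5, xx - 24.5)
        r = np.hypot(yy - 24.5, xx - 24.5)
        t = np.arange(240) * 5.0
        chi = (TWO_PI * t[None, None, :] / 300.0
               - theta[:, :, None] - 0.15 * r[:, :, None])
        mov = phase_movie(chi, (rows, cols))
        pm = rk.phase_map(mov)
        ring = (r > 8) & (r < 20)
        diff = _wrap(pm.phase[:, :, 120] - _wrap(chi[:, :, 120]))[ring]
        # agreement modulo a constant offset
        off = np.angle(np.exp(1j * diff).mean())
        assert np.sqrt(np.mean(_wrap(diff - off) ** 2)) < 0.2

    def test_delay_embedding_agrees_with_analytic_signal(self):
        period = 300.0
        t = np.arange(300) * 5.0
        ph = TWO_PI * t / period
        mov = phase_movie(np.broadcast_to(ph, (5, 5, 300)), (5, 5))
        a = rk.phase_map(mov, method="hilbert")
        b = rk.phase_map(mov, method="delay_embedding")
        d = _wrap(a.phase[2, 2, 20:-20] - b.phase[2, 2, 20:-20])
        off = np.angle(np.exp(1j * d).mean())
        assert np.sqrt(np.mean(_wrap(d - off) ** 2)) < 0.2

    def test_silent_pixels_undefined(self):
        t = np.arange(100) * 5.0
        ph = TWO_PI * t / 300.0
        data = np.cos(np.broadcast_to(ph, (5, 5, 100))).copy()
        data[0, 0, :] = 0.001 * np.cos(ph)
        mov = rk.OpticalMovie(data=data, dx=0.1, frame_interval=5.0,
                              mask=np.ones((5, 5), dtype=bool))
        pm = rk.phase_map(mov)
        assert np.isnan(pm.phase[0, 0]).all()
        assert np.isfinite(pm.phase[2, 2]).all()


class TestSingularities:
    def test_canonical_vortex_found_at_center_with_positive_charge(self):
        ph = analytic.vortex_phase(shape=(40, 40), charge=1)
        pts = rk.find_singularities(still_phase(ph))[0]
        assert len(pts) == 1
        assert pts[0].charge == 1
        assert pts[0].row == pytest.approx(19.5, abs=0.5)
        assert pts[0].col == pytest.approx(19.5, abs=0.5)

    def test_planar_phase_ramp_has_no_singularity(self):
        yy, xx = np.mgrid[0:30, 0:30]
        ph = _wrap(0.3 * xx + 0.1 * yy)
        assert rk.find_singularities(still_phase(ph))[0] == []

    def test_vortex_antivortex_pair_charges_cancel(self):
        yy, xx = np.mgrid[0:60, 0:60]
        ph = (np.arctan2(yy - 29.5, xx - 14.5)
              - np.arctan2(yy - 29.5, xx - 44.5))
        ph = _wrap(ph)
        pts = rk.find_singularities(still_phase(ph))[0]
        assert len(pts) == 2
        assert sum(p.charge for p in pts) == 0
        # cross-check every detection against the brute-force winding oracle
        w = brute_force_winding(ph)
        for p in pts:
            assert abs(w[int(p.row), int(p.col)]) >= 1.8 * np.pi

    @pytest.mark.parametrize("charges", [(1, 1), (1, -1, 1), (-1, -1)])
    def test_total_charge_conserved_on_multivortex_fields(self, charges):
        yy, xx = np.mgrid[0:80, 0:80]
        cores = [(20.0 + 18 * k, 25.0 + 11 * k) for k in range(len(charges))]
        ph = np.zeros((80, 80))
        for q, (r0, c0) in zip(charges, cores):
            ph = ph + q * np.arctan2(yy - r0, xx - c0)
        ph = _wrap(ph)
        pts = rk.find_singularities(still_phase(ph))[0]
        # total topological charge across the sheet = boundary winding
        boundary = np.concatenate([ph[0, :], ph[1:, -1], ph[-1, -2::-1],
                                   ph[-2:0:-1, 0]])
        boundary_winding = np.sum(_wrap(np.diff(boundary))) / TWO_PI
        assert sum(p.charge for p in pts) == round(boundary_winding)
        assert sum(p.charge for p in pts) == sum(charges)


class TestTracking:
    def test_stationary_spiral_core_trajectory_tight_and_cl_exact(self):
        mov = analytic.spiral_wave_movie(period=300.0, n_frames=240)
        pm = rk.phase_map(mov)
        rotors = rk.track_rotors(rk.find_singularities(pm), pm)
        assert len(rotors) == 1
        r = rotors[0]
        assert r.trajectory["row"].std() < 1.0
        assert r.trajectory["col"].std() < 1.0
        assert r.cycle_length == pytest.approx(300.0, rel=0.02)
        assert r.n_rotations == pytest.approx(240 * 5.0 / 300.0, rel=0.05)

    def test_cycle_length_matches_autocorrelation_oracle(self, rotor_state):
        """Rotor CL from ring-phase rotation vs the autocorrelation peak of a
        peripheral voltage trace — two independent estimators."""
        mov = rotor_state.movie
        sel = mov.times >= 800.0
        window = mov.copy_with(mov.data[:, :, sel])
        pm = rk.phase_map(window)
        rotors = rk.track_rotors(rk.find_singularities(pm), pm)
        cl = max(rotors, key=lambda r: r.n_rotations).cycle_length

        x = window.data[30, 70, :]
        x = x - x.mean()
        ac = np.correlate(x, x, "full")[len(x) - 1:]
        # first local maximum after the zero-lag peak
        k = np.nonzero((ac[1:-1] > ac[:-2]) & (ac[1:-1] >= ac[2:]))[0] + 1
        lag = k[np.argmax(ac[k])] * window.frame_interval
        assert cl == pytest.approx(lag, rel=0.05)


class TestCurvature:
    def test_circle_fit_exact(self):
        th = np.linspace(0, 1.2, 40)
        pts = np.column_stack([30 + 125 * np.sin(th), 10 + 125 * np.cos(th)])
        r0, c0, R = fit_circle(pts)
        assert R == pytest.approx(125.0, rel=1e-6)
        assert (r0, c0) == (pytest.approx(30.0, abs=1e-6),
                            pytest.approx(10.0, abs=1e-6))

    @staticmethod
    def _annulus_map(radius_mm, dx=0.25, band_mm=1.0):
        n = int(2.4 * radius_mm / dx)
        yy, xx = np.mgrid[0:n, 0:n]
        c0 = (n - 1) / 2.0
        r_mm = np.hypot(yy - c0, xx - c0) * dx
        times = (r_mm - radius_mm) / 0.05
        valid = np.abs(r_mm - radius_mm) < band_mm
        return ActivationMap(times=times, valid=valid, dx=dx), c0

    @pytest.mark.parametrize("radius_mm", [5.0, 12.5, 25.0, 50.0])
    def test_circular_isochrones_give_kappa_equal_inverse_radius(self, radius_mm):
        """Circular isochrones of radius R: kappa = 1/R within 2%.
        R = 12.5 mm reproduces the printed rotor curvature magnitude 0.08/mm."""
        amap, c0 = self._annulus_map(radius_mm)
        kappa = rk.wavefront_curvature(amap, (c0, c0),
                                       radius_mm=1.3 * radius_mm)
        assert kappa == pytest.approx(1.0 / radius_mm, rel=0.02)
        if radius_mm == 12.5:
            assert kappa == pytest.approx(0.08, rel=0.02)

    def test_straight_isochrones_report_near_zero_kappa(self):
        yy, xx = np.mgrid[0:60, 0:60]
        amap = ActivationMap(times=xx * 0.1 / 0.05,
                             valid=np.ones((60, 60), bool), dx=0.1)
        kappa = rk.wavefront_curvature(amap, (29.5, 29.5), radius_mm=5.0)
        assert kappa < 0.011

    def test_archimedean_spiral_arc_curvature(self):
        """kappa of r = b*theta at the sampled arc equals the closed form
        (r^2 + 2 b^2) / (r^2 + b^2)^(3/2) within 5%."""
        b = 2.0                              # mm per radian
        th = np.linspace(4.0, 5.0, 200)      # short arc, r ~ 8-10 mm
        r = b * th
        pts_mm = np.column_stack([r * np.sin(th), r * np.cos(th)])
        _, _, R_fit = fit_circle(pts_mm)
        r_mid = b * th.mean()
        kappa_true = (r_mid ** 2 + 2 * b ** 2) / (r_mid ** 2 + b ** 2) ** 1.5
        assert 1.0 / R_fit == pytest.approx(kappa_true, rel=0.05)


class TestRotorMetrics:
    def test_identity_with_zero_apd(self):
        assert rk.rotor_wavelength(1.0, 1000.0) == pytest.approx(1.0)
        assert rk.spatial_excitability_gap(1.0, 1000.0, 0.0) == pytest.approx(1.0)

    def test_temporal_gap_plus_apd_equals_cl(self):
        cl, apd = 304.0, 142.0
        assert rk.temporal_excitability_gap(cl, apd) + apd == cl

    def test_full_metrics_on_analytic_spiral(self):
        mov = analytic.spiral_wave_movie(period=300.0, wavelength_mm=9.0,
                                         n_frames=240)
        pm = rk.phase_map(mov)
        rotors = rk.track_rotors(rk.find_singularities(pm), pm)
        rotor = rotors[0]
        amap = rk.activation_map(mov, (600.0, 900.0))
        cvf = rk.cv_field(amap)
        apd, _ = rk.optical_apd_map(mov, (600.0, 900.0))
        met = rk.rotor_metrics(rotor, cvf, apd, amap)
        assert met.cl == pytest.approx(300.0, rel=0.02)
        assert met.cv_periphery == pytest.approx(3.0, rel=0.1)   # 9 mm / 300 ms
        assert met.wavelength == pytest.approx(0.9, rel=0.1)
        assert met.temporal_gap + met.apd90_optical == pytest.approx(met.cl,
                                                                     rel=0.02)
        assert not met.head_to_tail

    def test_head_to_tail_flag_zeroes_gaps(self):
        mov = analytic.spiral_wave_movie(period=300.0, n_frames=120)
        pm = rk.phase_map(mov)
        rotor = rk.track_rotors(rk.find_singularities(pm), pm)[0]
        cvf = rk.cv_field(rk.activation_map(mov, (300.0, 600.0)))
        apd_map = np.full(mov.shape, 400.0)     # APD exceeding the CL
        met = rk.rotor_metrics(rotor, cvf, apd_map,
                               rk.activation_map(mov, (300.0, 600.0)))
        assert met.head_to_tail
        assert met.spatial_gap == 0.0
        assert met.temporal_gap == 0.0
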