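"""AP feature extraction, phenotype classification, restitution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rotorkit as rk
from rotorkit.errors import FitError
from rotorkit.traces import ap_train, ap_waveform, restitution_pairs


class TestAPFeatures:
    def test_square_pulse(self):
        dt = 0.5
        t = np.arange(0, 400.0, dt)
        v = np.where((t >= 100.0) & (t < 300.0), 20.0, -80.0)
        f = rk.ap_features(v, dt)
        assert f.dmp == pytest.approx(-80.0)
        assert f.apa == pytest.approx(100.0)
        # square pulse: all repolarization levels cross together at 200 ms
        assert f.apd30 == pytest.approx(200.0, abs=2 * dt)
        assert f.apd90 == pytest.approx(200.0, abs=2 * dt)

    def test_exponential_repolarization_closed_form(self):
        """V = -80 + 100 exp(-t/tau), tau = 100 ms: the x% crossing lies at
        -tau*log(1 - x/100) -> APD30 = 35.67 ms, APD90 = 230.26 ms."""
        dt = 0.2
        t = np.arange(-50.0, 400.0, dt)
        v = np.where(t < 0, -80.0, -80.0 + 100.0 * np.exp(-np.maximum(t, 0) / 100.0))
        f = rk.ap_features(v, dt)
        tau = 100.0
        assert f.apd30 == pytest.approx(-tau * np.log(0.7), abs=3 * dt)
        assert f.apd50 == pytest.approx(-tau * np.log(0.5), abs=3 * dt)
        assert f.apd90 == pytest.approx(-tau * np.log(0.1), abs=3 * dt)

    def test_atrial_profile_apds_recovered(self):
        # triangular atrial-like AP built with APD30/APD90 = 37/247 ms
        dt = 0.5
        t = np.arange(-60.0, 700.0, dt)
        v = ap_waveform(t, apd30=37.0, apd90=247.0, rise_ms=0.5)
        f = rk.ap_features(v, dt)
        assert f.apd30 == pytest.approx(37.0, abs=1.0)
        assert f.apd90 == pytest.approx(247.0, abs=1.0)
        assert f.dmp == pytest.approx(-56.0, abs=0.5)
        assert f.apa == pytest.approx(80.0, abs=1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(apd30=st.floats(15.0, 320.0), spread=st.floats(1.3, 8.0))
    def test_apd_ordering_invariant(self, apd30, spread):
        dt = 0.5
        apd90 = apd30 * spread
        t = np.arange(-60.0, apd90 * 2.5, dt)
        f = rk.ap_features(ap_waveform(t, apd30, apd90), dt)
        assert f.apd30 <= f.apd50 <= f.apd90

    def test_offset_invariance(self):
        dt = 0.5
        t = np.arange(-60.0, 700.0, dt)
        v = ap_waveform(t)
        f0 = rk.ap_features(v, dt)
        f1 = rk.ap_features(v + 17.0, dt)
        assert f1.dmp == pytest.approx(f0.dmp + 17.0)
        assert f1.apa == pytest.approx(f0.apa)
        assert f1.apd90 == pytest.approx(f0.apd90, abs=1e-9)
        assert f1.dvdt_max == pytest.approx(f0.dvdt_max)

    def test_downsampling_robustness(self):
        dt = 0.5
        t = np.arange(-60.0, 700.0, dt)
        v = ap_waveform(t)
        f_full = rk.ap_features(v, dt)
        f_half = rk.ap_features(v[::2], 2 * dt)
        assert abs(f_half.apd90 - f_full.apd90) < 2 * dt

    def test_incomplete_repolarization_flagged(self):
        dt = 1.0
        t = np.arange(-50.0, 120.0, dt)       # window ends mid-plateau
        v = ap_waveform(t, apd30=150.0, apd90=400.0)
        f = rk.ap_features(v, dt)
        assert f.incomplete_repolarization
        assert np.isnan(f.apd90)


class TestClassification:
    def make(self, ratio, apa=80.0, dvdt=63.0):
        return rk.APFeatures(dmp=-56, apa=apa, dvdt_max=dvdt,
                             apd30=ratio * 247, apd50=np.nan, apd90=247,
                             cl=800, t_act=0.0)

    def test_triangular_ap_is_atrial_like(self):
        assert rk.classify_ap(self.make(0.17)) == "atrial-like"

    def test_plateau_ap_is_ventricular_like(self):
        assert rk.classify_ap(self.make(0.57, apa=102.0, dvdt=62.0)) == \
            "ventricular-like"

    def test_small_slow_upstroke_overrides_to_nodal(self):
        assert rk.classify_ap(self.make(0.17, apa=50.0, dvdt=5.0)) == "nodal-like"
        assert rk.classify_ap(self.make(0.57, apa=50.0, dvdt=5.0)) == "nodal-like"

    def test_undefined_apds_unclassified(self):
        f = self.make(0.2)
        f.apd90 = np.nan
        assert rk.classify_ap(f) == "unclassified"


class TestRestitution:
    def test_exact_line(self):
        cl = np.array([300.0, 500.0, 700.0, 900.0])
        fit = rk.restitution_fit(np.column_stack([cl, cl]))
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(7)
        cl = rng.uniform(300, 1200, 15)
        apd = 0.3 * cl - 100 + rng.normal(0, 20, 15)
        fit = rk.restitution_fit(np.column_stack([cl, apd]))
        # closed-form normal equations, computed independently
        X = np.column_stack([cl, np.ones_like(cl)])
        beta = np.linalg.solve(X.T @ X, X.T @ apd)
        assert fit.slope == pytest.approx(beta[0], abs=1e-9)
        assert fit.intercept == pytest.approx(beta[1], abs=1e-9)

    def test_matches_grid_search_minimizer(self):
        rng = np.random.default_rng(11)
        cl = rng.uniform(400, 1000, 8)
        apd = 0.25 * cl - 60 + rng.normal(0, 10, 8)
        fit = rk.restitution_fit(np.column_stack([cl, apd]))
        slopes = np.linspace(fit.slope - 0.02, fit.slope + 0.02, 401)
        sse = [np.sum((apd - (s * cl + np.mean(apd - s * cl))) ** 2)
               for s in slopes]
        assert slopes[int(np.argmin(sse))] == pytest.approx(fit.slope, abs=1e-4)

    def test_degenerate_cls_rejected(self):
        with pytest.raises(FitError):
            rk.restitution_fit([(500.0, 150.0), (500.0, 160.0), (500.0, 170.0)])

    def test_generator_matches_requested_population_r2_on_average(self):
        r2 = [rk.restitution_fit(np.column_stack(
            restitution_pairs(n=50, seed=s))).r_squared for s in range(200)]
        assert np.mean(r2) == pytest.approx(0.69, abs=0.03)

    def test_recovery_is_unbiased(self):
        slopes = [rk.restitution_fit(np.column_stack(
            restitution_pairs(seed=s))).slope for s in range(300)]
        assert np.mean(slopes) == pytest.approx(0.30, abs=0.01)


class TestPredictedChange:
    def test_zero_slope_zero_change(self):
        assert rk.predicted_apd_change(0.0, 500.0, 900.0) == 0.0

    def test_linear_arithmetic(self):
        assert rk.predicted_apd_change(0.5, 600.0, 700.0) == pytest.approx(50.0)

    def test_drug_induced_cl_slowing_prediction(self):
        # slope 0.30, spontaneous CL 800 -> 1027 ms under Na-channel block
        pred = rk.predicted_apd_change(0.30, 800.0, 1027.0)
        assert pred == pytest.approx(68.1, abs=0.01)
        assert 68.0 <= pred <= 69.0


def test_features_per_beat_on_train():
    t, v = ap_train(cycle_length=800.0, n_beats=6, dt=1.0)
    norm = (v - v.min()) / np.ptp(v)
    seg = rk.segment_beats(norm, 1.0)
    feats = rk.features_per_beat(v, 1.0, seg)
    assert len(feats) == 6
    for f in feats:
        assert f.apd30 <= f.apd50 <= f.apd90
        assert rk.classify_ap(f) == "atrial-like"
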