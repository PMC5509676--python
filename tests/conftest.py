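"""Shared fixtures.

The expensive reaction-diffusion runs (rotor induction and the drug
wash-in continuations) are session-scoped and shared by the phase,
pipeline and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import rotorkit as rk


def analyze_rotor_movie(movie: rk.OpticalMovie, n_kappa_windows: int = 4):
    """Condition a raw optical rotor movie and extract rotor + field metrics.

    Curvature is averaged over several consecutive rotor cycles: a single
    isochrone set samples one arc geometry and is noticeably noisier than
    the cycle-averaged value.
    """
    mov = rk.condition(movie)
    pm = rk.phase_map(mov)
    ps = rk.find_singularities(pm)
    rotors = rk.track_rotors(ps, pm)
    if not rotors:
        return mov, None, None
    rotor = max(rotors, key=lambda r: r.n_rotations)
    cl = rotor.cycle_length
    t_end = mov.times[-1]
    window = (t_end - 2.0 * cl, t_end - cl)
    amap = rk.activation_map(mov, window)
    cvf = rk.cv_field(amap)
    apd, _ = rk.optical_apd_map(mov, window)
    metrics = rk.rotor_metrics(rotor, cvf, apd, amap)
    kappas = [metrics.kappa]
    for k in range(1, n_kappa_windows):
        w = (t_end - (k + 2) * cl, t_end - (k + 1) * cl)
        if w[0] < 200.0:
            break
        kappas.append(rk.wavefront_curvature(rk.activation_map(mov, w),
                                             rotor.core))
    metrics.kappa = float(np.nanmean(kappas))
    return mov, rotor, metrics


@pytest.fixture(scope="session")
def rotor_state():
    """Established baseline rotor on the 1-cm sheet (cross-field S1-S2)."""
    cfg = rk.TissueConfig(duration=2500.0)
    proto = rk.StimulusProtocol(kind="cross_field_S1S2", s2_delay=280.0)
    return rk.simulate(cfg, proto)


def _continue_and_analyze(state, drug):
    cfg = rk.TissueConfig(duration=2000.0)
    res = rk.simulate(cfg, None, drug=drug, initial_state=state)
    raw = rk.voltage_to_optical(res.movie, rk.OpticalTransform(), seed=1)
    return analyze_rotor_movie(raw)


@pytest.fixture(scope="session")
def rotor_bundle(rotor_state):
    """Baseline / fast-inward-blocked / repolarization-blocked rotor analyses,
    each continued from the same established rotor (drug wash-in design)."""
    out = {}
    for name, drug in [("baseline", None),
                       ("flecainide", rk.flecainide_like()),
                       ("dofetilide", rk.dofetilide_like())]:
        mov, rotor, metrics = _continue_and_analyze(rotor_state.state, drug)
        out[name] = {"movie": mov, "rotor": rotor, "metrics": metrics}
    return out
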