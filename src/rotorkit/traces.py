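"""Parametric single-cell trace generators.

These produce action-potential waveforms with exactly known features (DMP,
APA, APD30/50/90, cycle length) for testing the extractors, plus
restitution data sets with a known slope and correlation.  The
repolarization phase is a stretched exponential, whose two shape
parameters are solved from the requested APD30 and APD90 — a compact way
to span atrial-like (triangular, APD30/APD90 ~ 0.15) through
ventricular-like (plateau, ratio ~ 0.6) morphologies.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError

__all__ = ["ap_waveform", "ap_train", "restitution_pairs"]


def _shape_params(apd30: float, apd90: float):
    """Solve (tau, p) of f(t) = exp(-(t/tau)^p) from two repolarization levels:
    f(APD30) = 0.7, f(APD90) = 0.1."""
    if not (0 < apd30 < apd90):
        raise ConfigurationError("need 0 < apd30 < apd90")
    l30, l90 = -np.log(0.7), -np.log(0.1)
    p = np.log(l90 / l30) / np.log(apd90 / apd30)
    tau = apd90 / l90 ** (1.0 / p)
    return tau, p


def ap_waveform(t_ms: np.ndarray, apd30: float = 37.0, apd90: float = 247.0,
                dmp: float = -56.0, apa: float = 80.0,
                rise_ms: float = 1.0) -> np.ndarray:
    """One action potential starting at t = 0 (mV).

    The upstroke is a fast logistic of 10-90% width ``rise_ms``; APDs are
    measured from t = 0, so the requested APD30/APD90 hold exactly at the
    repolarization crossings for rise_ms << apd30.
    """
    t = np.asarray(t_ms, dtype=float)
    tau, p = _shape_params(apd30, apd90)
    rise_ms = max(rise_ms, 1e-3)
    # upstroke over [-rise_ms, 0): reaches the full amplitude at t = 0 so the
    # requested repolarization crossings are exact
    arg = np.clip(-8.8 * (t + rise_ms / 2.0) / rise_ms, -700, 700)
    upstroke = 1.0 / (1.0 + np.exp(arg))
    repol = np.exp(-(np.maximum(t, 0.0) / tau) ** p)
    v = dmp + apa * np.where(t < 0, upstroke, repol)
    return np.where(t < -rise_ms, dmp, v)


def ap_train(cycle_length: float = 800.0, n_beats: int = 10, dt: float = 1.0,
             apd30: float = 37.0, apd90: float = 247.0, dmp: float = -56.0,
             apa: float = 80.0, rise_ms: float = 1.0, noise_sd: float = 0.0,
             seed: int = 0, lead_in_ms: float = 100.0):
    """Periodic train of identical APs; returns (times_ms, v_mv).

    ``apd30``/``apd90`` may be scalars or per-beat sequences (for building
    alternating trains).
    """
    apd30 = np.broadcast_to(np.asarray(apd30, dtype=float), (n_beats,))
    apd90 = np.broadcast_to(np.asarray(apd90, dtype=float), (n_beats,))
    dur = lead_in_ms + cycle_length * n_beats
    t = np.arange(0.0, dur, dt)
    v = np.full_like(t, dmp)
    for k in range(n_beats):
        t0 = lead_in_ms + k * cycle_length
        seg = ap_waveform(t - t0, apd30[k], apd90[k], dmp, apa, rise_ms)
        v = np.maximum(v, seg)  # beats never overlap for apd90 < CL
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sd, v.shape)
    return t, v


def restitution_pairs(slope: float = 0.30, intercept: float = -103.0,
                      r_squared: float = 0.69, n: int = 10,
                      cl_range: tuple[float, float] = (700.0, 1250.0),
                      seed: int = 0):
    """(CL, APD50) pairs from a linear restitution relation plus noise.

    The residual standard deviation is set from the requested population
    r-squared: sd_e = |slope| * sd_CL * sqrt(1/r^2 - 1), so the generated
    sets scatter like the measured regression they emulate.  Cycle lengths
    are evenly spread over ``cl_range``.
    """
    if not (0 < r_squared <= 1):
        raise ConfigurationError("r_squared must be in (0, 1]")
    rng = np.random.default_rng(seed)
    cl = np.linspace(*cl_range, n)
    sd_e = abs(slope) * cl.std() * np.sqrt(1.0 / r_squared - 1.0)
    apd50 = slope * cl + intercept + rng.normal(0.0, sd_e, n)
    return cl, apd50
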