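"""Constructed wave fields with closed-form ground truth.

Synthetic stand-ins for optically mapped activity — planar waves, target
waves, and rigidly rotating spiral waves — where speed, period, core
position and APD are exact by construction.  They exercise every analysis
stage independently of the reaction-diffusion simulator and provide the
deterministic fixtures shipped by the pipeline.
"""

from __future__ import annotations

import numpy as np

from .movie import OpticalMovie
from .traces import _shape_params

__all__ = ["pulse_shape", "planar_wave_movie", "target_wave_movie",
           "spiral_wave_movie", "vortex_phase"]


def pulse_shape(phase_ms: np.ndarray, apd90: float, rise_ms: float = 4.0,
                ratio30: float = 0.17) -> np.ndarray:
    """Normalized AP-like pulse v(t), t in ms since local activation.

    Stretched-exponential repolarization hits 30%/90% repolarization at
    ``ratio30 * apd90`` and ``apd90``; v = 0 before activation.
    """
    t = np.asarray(phase_ms, dtype=float)
    tau, p = _shape_params(ratio30 * apd90, apd90)
    up = 1.0 / (1.0 + np.exp(-4.4 * (t - rise_ms / 2.0) / rise_ms))
    v = up * np.exp(-(np.maximum(t, 0.0) / tau) ** p)
    return np.where(t < 0, 0.0, v)


def _movie_from_activation(t_act: np.ndarray, dx: float, frame_interval: float,
                           n_frames: int, cl: float, apd90: float,
                           mask: np.ndarray | None = None) -> OpticalMovie:
    """Movie whose pixel (r, c) fires at t_act[r, c] and every ``cl`` after."""
    times = np.arange(n_frames) * frame_interval
    local = times[None, None, :] - t_act[:, :, None]
    if cl > 0:
        local = np.mod(local, cl)
        # keep pre-first-activation pixels quiescent
        local = np.where(times[None, None, :] < t_act[:, :, None], -1.0, local)
    data = pulse_shape(local, apd90)
    if mask is not None:
        data = np.where(mask[:, :, None], data, np.nan)
    return OpticalMovie(data=data, dx=dx, frame_interval=frame_interval,
                        mask=mask, polarity="positive",
                        meta={"analytic": True})


def planar_wave_movie(shape=(60, 60), dx: float = 0.1,
                      frame_interval: float = 5.0, speed_cm_s: float = 5.0,
                      direction_deg: float = 0.0, cl: float = 500.0,
                      apd90: float = 150.0, n_frames: int = 140,
                      mask: np.ndarray | None = None) -> OpticalMovie:
    """Plane wave crossing the sheet at an exact speed and direction.

    ``direction_deg`` = 0 propagates along +columns; 90 along +rows.
    Ground truth activation time: T = (projection along direction) / speed.
    """
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    th = np.deg2rad(direction_deg)
    proj = (xx * np.cos(th) + yy * np.sin(th)) * dx          # mm
    proj -= proj.min()
    v = speed_cm_s / 100.0                                   # cm/s -> mm/ms
    t_act = proj / v + 3 * frame_interval
    return _movie_from_activation(t_act, dx, frame_interval, n_frames, cl,
                                  apd90, mask)


def target_wave_movie(shape=(80, 80), dx: float = 0.1,
                      frame_interval: float = 5.0, speed_cm_s: float = 5.0,
                      center: tuple[float, float] | None = None,
                      cl: float = 600.0, apd90: float = 150.0,
                      n_frames: int = 160,
                      mask: np.ndarray | None = None) -> OpticalMovie:
    """Concentric wave from a focal source: T = r / speed (circular isochrones)."""
    rows, cols = shape
    if center is None:
        center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    yy, xx = np.mgrid[0:rows, 0:cols]
    r = np.hypot(yy - center[0], xx - center[1]) * dx
    v = speed_cm_s / 100.0
    t_act = r / v + 3 * frame_interval
    return _movie_from_activation(t_act, dx, frame_interval, n_frames, cl,
                                  apd90, mask)


def spiral_wave_movie(shape=(100, 100), dx: float = 0.1,
                      frame_interval: float = 5.0, period: float = 300.0,
                      wavelength_mm: float = 9.0,
                      core: tuple[float, float] | None = None,
                      chirality: int = 1, apd_fraction: float = 0.55,
                      n_frames: int = 300,
                      mask: np.ndarray | None = None) -> OpticalMovie:
    """Rigidly rotating Archimedean spiral wave.

    Phase field chi = 2*pi*t/T - chirality*theta - 2*pi*r/lambda; the local
    "voltage" is an AP-shaped pulse of duty cycle ``apd_fraction`` of the
    period.  Ground truth: core at ``core``, cycle length = ``period``,
    front speed = wavelength / period, APD90 ~ apd_fraction * period.
    """
    rows, cols = shape
    if core is None:
        core = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    yy, xx = np.mgrid[0:rows, 0:cols]
    theta = np.arctan2(yy - core[0], xx - core[1])
    r = np.hypot(yy - core[0], xx - core[1]) * dx
    times = np.arange(n_frames) * frame_interval
    chi = (2 * np.pi * times[None, None, :] / period
           - chirality * theta[:, :, None]
           - 2 * np.pi * r[:, :, None] / wavelength_mm)
    local = np.mod(chi, 2 * np.pi) / (2 * np.pi) * period    # ms since front
    data = pulse_shape(local, apd_fraction * period)
    if mask is not None:
        data = np.where(mask[:, :, None], data, np.nan)
    return OpticalMovie(data=data, dx=dx, frame_interval=frame_interval,
                        mask=mask, polarity="positive",
                        meta={"analytic": True, "period": period,
                              "core": list(core),
                              "wavelength_mm": wavelength_mm})


def vortex_phase(shape=(60, 60), core: tuple[float, float] | None = None,
                 charge: int = 1, k_radial: float = 0.0,
                 offset: float = 0.0) -> np.ndarray:
    """Single-frame canonical vortex phase field.

    phi = charge * theta + k_radial * r + offset, wrapped to (-pi, pi].
    ``charge`` may be any nonzero integer; superpose several fields (add
    their unwrapped forms) to build multi-vortex tests.
    """
    rows, cols = shape
    if core is None:
        core = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    yy, xx = np.mgrid[0:rows, 0:cols]
    theta = np.arctan2(yy - core[0], xx - core[1])
    r = np.hypot(yy - core[0], xx - core[1])
    phi = charge * theta + k_radial * r + offset
    return (phi + np.pi) % (2 * np.pi) - np.pi
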