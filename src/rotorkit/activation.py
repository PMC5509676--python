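"""Activation-time maps and conduction-velocity vector fields.

Activation is the time of maximal temporal derivative per pixel within a
beat window (with a 50%-upstroke fallback at low derivative SNR).  Local
conduction velocity comes from a first-order plane fit of the activation
surface T(x, y) over a sliding window: if T = a + b x + c y then the front
moves with velocity (b, c) / (b^2 + c^2) — the classical local-gradient
estimator for optical maps.  Physical units throughout: mm, ms, cm/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .movie import OpticalMovie

__all__ = ["ActivationMap", "activation_map", "CVField", "cv_field",
           "CVSummary", "cv_summary"]


@dataclass
class ActivationMap:
    times: np.ndarray               # ms; NaN where invalid
    valid: np.ndarray               # bool
    dx: float                       # mm / pixel
    beat_index: int = 0
    low_quality: bool = False       # > 30% of masked pixels invalid

    def normalized(self) -> "ActivationMap":
        t = self.times.copy()
        if self.valid.any():
            t -= np.nanmin(t[self.valid])
        return ActivationMap(t, self.valid.copy(), self.dx, self.beat_index,
                             self.low_quality)


def activation_map(movie: OpticalMovie,
                   beat_window: tuple[float, float] | None = None,
                   snr_min: float = 3.0, min_amplitude: float = 0.25,
                   beat_index: int = 0) -> ActivationMap:
    """Per-pixel activation times for the beat inside ``beat_window``.

    Uses the maximal temporal derivative (sub-frame parabolic refinement);
    when the derivative SNR (peak over robust noise) is below ``snr_min``,
    falls back to the 50% upstroke crossing.  Pixels without an upstroke
    (amplitude below ``min_amplitude`` of a conditioned movie) are
    invalidated; the map is flagged low-quality when > 30% of masked pixels
    fail.  Times are shifted so the earliest activation is 0.
    """
    t = movie.times
    if beat_window is None:
        beat_window = (0.0, t[-1] + movie.frame_interval)
    sel = (t >= beat_window[0]) & (t < beat_window[1])
    if sel.sum() < 4:
        raise InputError("beat window shorter than 4 frames")
    tw = t[sel]
    dtf = movie.frame_interval

    times = np.full(movie.shape, np.nan)
    valid = np.zeros(movie.shape, dtype=bool)
    for r, c in zip(*np.nonzero(movie.mask)):
        x = movie.data[r, c, sel]
        if not np.isfinite(x).all():
            continue
        amp = x.max() - x.min()
        if amp < min_amplitude:
            continue
        d = np.gradient(x, dtf)
        i = int(np.argmax(d))
        mad = np.median(np.abs(d - np.median(d))) * 1.4826
        snr = d[i] / mad if mad > 0 else np.inf
        if snr >= snr_min:
            # parabolic sub-frame refinement of the derivative peak
            if 0 < i < len(d) - 1:
                denom = d[i - 1] - 2 * d[i] + d[i + 1]
                shift = 0.5 * (d[i - 1] - d[i + 1]) / denom if denom != 0 else 0.0
                shift = np.clip(shift, -0.5, 0.5)
            else:
                shift = 0.0
            times[r, c] = tw[i] + shift * dtf
            valid[r, c] = True
        else:
            level = x.min() + 0.5 * amp
            up = np.nonzero((x[:-1] < level) & (x[1:] >= level))[0]
            if len(up):
                j = up[0]
                frac = (level - x[j]) / (x[j + 1] - x[j])
                times[r, c] = tw[j] + frac * dtf
                valid[r, c] = True

    n_mask = int(movie.mask.sum())
    low_q = n_mask > 0 and (n_mask - int(valid.sum())) / n_mask > 0.30
    amap = ActivationMap(times=times, valid=valid, dx=movie.dx,
                         beat_index=beat_index, low_quality=low_q)
    return amap.normalized()


@dataclass
class CVField:
    vx: np.ndarray                  # cm/s, along +columns
    vy: np.ndarray                  # cm/s, along +rows
    speed: np.ndarray               # cm/s; NaN where the fit was rejected
    dx: float
    fit_window: int
    residual_tol: float

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.speed)


def cv_field(act: ActivationMap, dx: float | None = None,
             fit_window: int = 5, residual_tol: float = 3.0,
             min_valid_frac: float = 0.6) -> CVField:
    """Local plane-fit conduction velocity over a sliding window.

    Windows with fewer than ``min_valid_frac`` valid pixels, a singular
    design (collinear valid pixels), or residual RMS above ``residual_tol``
    ms are rejected (NaN speed).
    """
    if dx is None:
        dx = act.dx
    half = fit_window // 2
    rows, cols = act.times.shape
    vx = np.full((rows, cols), np.nan)
    vy = np.full((rows, cols), np.nan)
    T = act.times
    need = max(3, int(np.ceil(min_valid_frac * fit_window ** 2)))

    # design matrix of a full window, reused for the common complete case
    off = np.arange(-half, half + 1) * dx
    XX, YY = np.meshgrid(off, off)
    A_full = np.column_stack([np.ones(XX.size), XX.ravel(), YY.ravel()])
    pinv_full = np.linalg.pinv(A_full)

    for r in range(half, rows - half):
        for c in range(half, cols - half):
            if not act.valid[r, c]:
                continue
            win = T[r - half:r + half + 1, c - half:c + half + 1]
            ok = np.isfinite(win)
            n_ok = int(ok.sum())
            if n_ok < need:
                continue
            y = win[ok]
            if n_ok == fit_window ** 2:
                coef = pinv_full @ win.ravel()
                resid = win.ravel() - A_full @ coef
            else:
                A = A_full[ok.ravel()]
                coef, *_ = np.linalg.lstsq(A, y, rcond=None)
                # collinearity check
                if np.linalg.matrix_rank(A) < 3:
                    continue
                resid = y - A @ coef
            if np.sqrt(np.mean(resid ** 2)) > residual_tol:
                continue
            b, cgrad = coef[1], coef[2]     # ms/mm along x (cols), y (rows)
            g2 = b * b + cgrad * cgrad
            if g2 <= 0:
                continue
            vx[r, c] = b / g2 * 100.0       # mm/ms -> cm/s
            vy[r, c] = cgrad / g2 * 100.0
    speed = np.hypot(vx, vy)
    return CVField(vx=vx, vy=vy, speed=speed, dx=dx, fit_window=fit_window,
                   residual_tol=residual_tol)


@dataclass
class CVSummary:
    mean: float
    sd: float
    n: int
    hist_counts: np.ndarray
    hist_edges: np.ndarray          # cm/s, fixed bin width


def cv_summary(cv: CVField, region: np.ndarray | None = None,
               bin_width: float = 0.5, speed_cap: float | None = 30.0) -> CVSummary:
    """Mean, SD, and fixed-bin histogram of speeds in a region.

    ``speed_cap`` discards non-physiological outliers from near-singular
    fits (e.g. at a rotor core isochrone crowding); None keeps everything.
    """
    sel = cv.valid
    if region is not None:
        sel = sel & region
    speeds = cv.speed[sel]
    if speed_cap is not None:
        speeds = speeds[speeds <= speed_cap]
    if speeds.size < 10:
        raise InputError("fewer than 10 valid velocity vectors in region")
    hi = np.ceil(speeds.max() / bin_width) * bin_width
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, edges = np.histogram(speeds, bins=edges)
    return CVSummary(mean=float(speeds.mean()), sd=float(speeds.std()),
                     n=int(speeds.size), hist_counts=counts, hist_edges=edges)
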