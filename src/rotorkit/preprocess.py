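"""Conditioning of raw optical movies and traces.

The raw camera signal has arbitrary offset and gain per pixel, dye polarity
(darkening on depolarization), slow photobleaching drift, and shot noise.
``condition`` turns it into a positive-polarity, per-pixel [0, 1] movie
ready for activation/phase analysis; ``segment_beats`` and
``alternans_magnitude`` operate on single (global or per-pixel) traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.stats import skew

from .errors import InputError
from .movie import OpticalMovie

__all__ = ["ConditionOptions", "condition", "BeatSegmentation",
           "segment_beats", "alternans_magnitude", "AlternansResult"]


@dataclass(frozen=True)
class ConditionOptions:
    """Knobs of the conditioning chain; all stages can be switched off.

    ``invert`` may be True/False or ``"auto"``, which flips the movie when
    the pooled temporal-derivative distribution is negatively skewed (fast
    downstrokes = inverted dye polarity).  The temporal filter is zero-phase
    (forward-backward Butterworth) to preserve upstroke timing.
    """

    invert: bool | str = "auto"
    detrend: bool = True
    spatial_sigma_px: float = 1.0
    temporal_cutoff_hz: float = 40.0
    flat_range_eps: float = 1e-9


def _auto_invert(data: np.ndarray, mask: np.ndarray) -> bool:
    d = np.diff(data[mask], axis=1)
    d = d[np.isfinite(d)]
    if d.size == 0:
        return False
    return skew(d) < 0


def condition(movie: OpticalMovie,
              opts: ConditionOptions = ConditionOptions()) -> OpticalMovie:
    """Polarity-correct, detrend, filter, and per-pixel normalize a movie.

    Order: polarity -> linear detrend -> spatial Gaussian -> zero-phase
    temporal low-pass -> per-pixel min-max normalization.  Pixels with no
    dynamic range are removed from the mask and set to NaN (excluded, never
    interpolated); their count is logged in ``meta["n_invalid_pixels"]``.
    """
    data = movie.data.astype(float).copy()
    mask = movie.mask.copy()

    if opts.invert == "auto":
        flip = (movie.polarity == "negative") or _auto_invert(data, mask)
    else:
        flip = bool(opts.invert)
    if flip:
        data = -data

    # flat pixels cannot carry an activation time
    rng_ok = np.zeros(mask.shape, dtype=bool)
    sub = data[mask]
    rng_ok[mask] = (np.nanmax(sub, axis=1) - np.nanmin(sub, axis=1)
                    ) > opts.flat_range_eps
    n_invalid = int((mask & ~rng_ok).sum())
    mask &= rng_ok

    traces = data[mask]                       # (n_pixels, frames)
    if traces.size == 0:
        raise InputError("no valid pixels after flat-pixel exclusion")

    if opts.detrend:
        traces = sps.detrend(traces, axis=1, type="linear")

    data = np.full_like(data, np.nan)
    data[mask] = traces

    if opts.spatial_sigma_px > 0:
        from .optics import _masked_blur
        data = np.stack([_masked_blur(data[:, :, k], mask, opts.spatial_sigma_px)
                         for k in range(data.shape[2])], axis=2)

    if opts.temporal_cutoff_hz > 0:
        fs = 1000.0 / movie.frame_interval
        if opts.temporal_cutoff_hz < 0.95 * fs / 2.0:
            b, a = sps.butter(3, opts.temporal_cutoff_hz / (fs / 2.0))
            padlen = min(3 * max(len(a), len(b)), data.shape[2] - 1)
            data[mask] = sps.filtfilt(b, a, data[mask], axis=1, padlen=padlen)

    tr = data[mask]
    lo = tr.min(axis=1, keepdims=True)
    hi = tr.max(axis=1, keepdims=True)
    span = hi - lo
    ok = span[:, 0] > opts.flat_range_eps
    tr[ok] = (tr[ok] - lo[ok]) / span[ok]
    data[mask] = tr

    meta = dict(movie.meta)
    meta.update({"conditioned": True, "inverted": bool(flip),
                 "n_invalid_pixels": n_invalid})
    return movie.copy_with(np.where(mask[:, :, None], data, np.nan),
                           mask=mask, polarity="positive", meta=meta)


@dataclass
class BeatSegmentation:
    """Beat windows [t_start, t_end) in ms plus the upstroke times used."""

    windows: list[tuple[float, float]]
    upstroke_times: np.ndarray
    threshold: float
    cl_series: np.ndarray            # ms; empty when < 2 beats
    cl_defined: bool


def segment_beats(trace: np.ndarray, dt: float, threshold_frac: float = 0.5,
                  lockout_ms: float = 80.0, pre_ms: float = 50.0) -> BeatSegmentation:
    """Delimit beats by upward threshold crossings with a refractory lockout.

    The trace should be normalized (threshold is an absolute level on it).
    Each window starts ``pre_ms`` before its upstroke (clipped at 0) so the
    diastolic baseline is available to downstream feature extraction, and
    ends ``pre_ms`` before the next upstroke.
    """
    x = np.asarray(trace, dtype=float)
    t = np.arange(len(x)) * dt
    up = np.nonzero((x[:-1] < threshold_frac) & (x[1:] >= threshold_frac))[0]
    times = []
    for i in up:
        frac = (threshold_frac - x[i]) / (x[i + 1] - x[i])
        tc = t[i] + frac * dt
        if times and tc - times[-1] < lockout_ms:
            continue
        times.append(tc)
    times = np.asarray(times)
    windows = []
    for k, tc in enumerate(times):
        t0 = max(0.0, tc - pre_ms)
        t1 = times[k + 1] - pre_ms if k + 1 < len(times) else t[-1] + dt
        windows.append((t0, t1))
    cl = np.diff(times)
    return BeatSegmentation(windows=windows, upstroke_times=times,
                            threshold=threshold_frac, cl_series=cl,
                            cl_defined=len(times) >= 2)


@dataclass(frozen=True)
class AlternansResult:
    magnitude: float      # ms; mean |APD_n - APD_{n+1}|; NaN when undefined
    is_alternans: bool
    n: int


def alternans_magnitude(apd_series, threshold_ms: float = 5.0) -> AlternansResult:
    """Beat-to-beat APD alternation magnitude and detection flag.

    Flags alternans when the mean absolute successive difference exceeds
    ``threshold_ms`` *and* the successive differences alternate in sign
    consistently (long-short-long-short), which separates true alternans
    from random beat-to-beat jitter.  Series shorter than 4 beats are
    undefined (NaN magnitude, flag False).
    """
    apd = np.asarray(apd_series, dtype=float)
    if len(apd) < 4 or not np.isfinite(apd).all():
        return AlternansResult(np.nan, False, len(apd))
    d = np.diff(apd)
    mag = float(np.mean(np.abs(d)))
    signs = np.sign(d)
    alternating = bool(np.all(signs[:-1] * signs[1:] < 0))
    return AlternansResult(mag, alternating and mag > threshold_ms, len(apd))
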