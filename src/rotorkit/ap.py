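"""Action-potential feature extraction, phenotype classification, and
APD-restitution fitting.

Conventions (documented in every output):

* activation time = time of maximal dV/dt within the beat window
  (patch-clamp convention); per-pixel optical maps use the 50% upstroke
  instead for noise robustness (see :func:`optical_apd_map`);
* DMP = minimum over the 50 ms preceding the upstroke;
* APA = peak - DMP, per beat (so alternating trains are handled correctly);
* APDx = time from activation to the first downward crossing of
  ``peak - x% * APA``, crossings located by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .errors import FitError, InputError
from .movie import OpticalMovie
from .preprocess import BeatSegmentation

__all__ = [
    "APFeatures", "ap_features", "features_per_beat", "classify_ap",
    "RestitutionFit", "restitution_fit", "predicted_apd_change",
    "optical_apd_map",
]


@dataclass
class APFeatures:
    """Per-beat scalar features.  Units: mV, ms, V/s; NaN = undefined."""

    dmp: float
    apa: float
    dvdt_max: float          # V/s for a trace in mV sampled in ms
    apd30: float
    apd50: float
    apd90: float
    cl: float
    t_act: float             # ms, absolute time of max dV/dt
    beat_index: int = 0
    incomplete_repolarization: bool = False

    def apd_ratio(self) -> float:
        return self.apd30 / self.apd90

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("beat_index", "dmp", "apa", "dvdt_max", "apd30", "apd50",
                 "apd90", "cl", "t_act", "incomplete_repolarization")}


def _crossing_after(t, x, i0, level):
    """First downward crossing of ``level`` at/after index i0 (linear interp)."""
    seg = x[i0:]
    below = np.nonzero((seg[:-1] >= level) & (seg[1:] < level))[0]
    if len(below) == 0:
        return np.nan
    i = i0 + below[0]
    frac = (x[i] - level) / (x[i] - x[i + 1])
    return t[i] + frac * (t[i + 1] - t[i])


def ap_features(trace: np.ndarray, dt: float,
                beat_window: tuple[float, float] | None = None,
                cl: float = np.nan, beat_index: int = 0,
                baseline_ms: float = 50.0) -> APFeatures:
    """Extract features of the single beat inside ``beat_window`` (ms).

    ``dt`` should be <= 2 ms for a faithful dV/dt_max.  Missing
    repolarization crossings before the window end leave the corresponding
    APD NaN and set ``incomplete_repolarization``.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1 or len(x) < 5:
        raise InputError("trace must be a 1-D array with >= 5 samples")
    t = np.arange(len(x)) * dt
    if beat_window is None:
        beat_window = (0.0, t[-1] + dt)
    w0, w1 = beat_window
    sel = (t >= w0) & (t < w1)
    if sel.sum() < 5:
        raise InputError("beat window too short")
    tw, xw = t[sel], x[sel]

    dvdt = np.gradient(xw, dt)       # mV/ms == V/s
    i_act = int(np.argmax(dvdt))
    t_act = tw[i_act]
    dvdt_max = float(dvdt[i_act])

    pre = xw[(tw >= t_act - baseline_ms) & (tw <= t_act)]
    dmp = float(pre.min()) if len(pre) else float(xw[:i_act + 1].min())

    i_peak = i_act + int(np.argmax(xw[i_act:]))
    peak = float(xw[i_peak])
    apa = peak - dmp
    if apa <= 0:
        raise InputError("non-positive action-potential amplitude")

    apds = {}
    incomplete = False
    for lvl in (30, 50, 90):
        level = peak - lvl / 100.0 * apa
        tc = _crossing_after(tw, xw, i_peak, level)
        if np.isnan(tc):
            incomplete = True
            apds[lvl] = np.nan
        else:
            apds[lvl] = tc - t_act
    return APFeatures(dmp=dmp, apa=apa, dvdt_max=dvdt_max,
                      apd30=apds[30], apd50=apds[50], apd90=apds[90],
                      cl=cl, t_act=t_act, beat_index=beat_index,
                      incomplete_repolarization=incomplete)


def features_per_beat(trace: np.ndarray, dt: float,
                      seg: BeatSegmentation) -> list[APFeatures]:
    """Apply :func:`ap_features` to every window of a beat segmentation."""
    out = []
    for k, (w0, w1) in enumerate(seg.windows):
        cl = seg.cl_series[k] if k < len(seg.cl_series) else np.nan
        try:
            out.append(ap_features(trace, dt, (w0, w1), cl=cl, beat_index=k))
        except InputError:
            continue
    return out


def features_frame(feats: list[APFeatures]) -> pd.DataFrame:
    return pd.DataFrame([f.as_dict() for f in feats])


def classify_ap(features: APFeatures, ratio_threshold: float = 0.35,
                nodal_apa_mv: float = 70.0, nodal_dvdt: float = 10.0) -> str:
    """Phenotype from the APD30/APD90 ratio with a nodal override.

    Triangular repolarization (ratio < ``ratio_threshold``) reads
    atrial-like; a pronounced plateau reads ventricular-like.  Small, slow
    upstrokes (APA < 70 mV and dV/dt_max < 10 V/s) override either as
    nodal-like.  The ratio threshold sits midway between the two measured
    cohort means (0.17 atrial, 0.57 ventricular).
    """
    if np.isnan(features.apd30) or np.isnan(features.apd90):
        return "unclassified"
    if features.apa < nodal_apa_mv and features.dvdt_max < nodal_dvdt:
        return "nodal-like"
    return "atrial-like" if features.apd_ratio() < ratio_threshold else "ventricular-like"


@dataclass(frozen=True)
class RestitutionFit:
    slope: float            # ms APD per ms CL
    intercept: float        # ms
    r_squared: float
    n: int
    stderr: float

    def predict(self, cl: float) -> float:
        return self.slope * cl + self.intercept


def restitution_fit(pairs) -> RestitutionFit:
    """Ordinary least squares of APD50 on cycle length.

    ``pairs`` is an iterable of (CL ms, APD50 ms) or a tuple of two arrays.
    Requires >= 3 distinct cycle lengths.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim == 2 and arr.shape[0] == 2 and arr.shape[1] != 2:
        cl, apd = arr
    else:
        cl, apd = arr[:, 0], arr[:, 1]
    if len(cl) < 3 or len(np.unique(cl)) < 3:
        raise FitError("need >= 3 distinct cycle lengths")
    if np.ptp(cl) == 0:
        raise FitError("degenerate cycle lengths (zero variance)")
    res = linregress(cl, apd)
    return RestitutionFit(slope=float(res.slope), intercept=float(res.intercept),
                          r_squared=float(res.rvalue ** 2), n=len(cl),
                          stderr=float(res.stderr))


def predicted_apd_change(fit: RestitutionFit | float, cl_before: float,
                         cl_after: float) -> float:
    """Restitution-predicted APD50 change (ms) for a cycle-length change."""
    slope = fit.slope if isinstance(fit, RestitutionFit) else float(fit)
    return slope * (cl_after - cl_before)


def optical_apd_map(movie: OpticalMovie, beat_window: tuple[float, float],
                    level: float = 0.9, activation_frac: float = 0.5,
                    min_amplitude: float = 0.3):
    """Per-pixel optical APD at ``level`` repolarization within one beat.

    Optical traces are noisy, so activation is referenced to the 50%
    upstroke crossing (not max dV/dt) and repolarization levels to the
    per-beat amplitude.  Returns (apd_map ms, valid mask).
    """
    t = movie.times
    sel = (t >= beat_window[0]) & (t < beat_window[1])
    if sel.sum() < 4:
        raise InputError("beat window too short for the frame rate")
    tw = t[sel]
    apd = np.full(movie.shape, np.nan)
    valid = np.zeros(movie.shape, dtype=bool)
    rows, cols = np.nonzero(movie.mask)
    for r, c in zip(rows, cols):
        x = movie.data[r, c, sel]
        lo, hi = np.nanmin(x), np.nanmax(x)
        if not np.isfinite(lo) or hi - lo < min_amplitude:
            continue
        up_level = lo + activation_frac * (hi - lo)
        up = np.nonzero((x[:-1] < up_level) & (x[1:] >= up_level))[0]
        if len(up) == 0:
            continue
        i = up[0]
        frac = (up_level - x[i]) / (x[i + 1] - x[i])
        t_act = tw[i] + frac * (tw[i + 1] - tw[i])
        i_peak = i + int(np.argmax(x[i:]))
        rep_level = x[i_peak] - level * (x[i_peak] - lo)
        tc = _crossing_after(tw, x, i_peak, rep_level)
        if np.isnan(tc):
            continue
        apd[r, c] = tc - t_act
        valid[r, c] = True
    return apd, valid
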