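"""Phase mapping, phase-singularity detection and tracking, wavefront
curvature, and the rotor metrics that summarize a re-entrant episode.

A rotor (functionally re-entrant spiral wave) organizes around a phase
singularity (PS): the point where all phases of the activation cycle
converge and the topological charge — the winding of the phase around any
small loop — is +/-1.  Detection sums wrapped phase differences around
every 2x2 plaquette of the phase map; tracking links detections across
frames; the rotor's cycle length is read from the phase-rotation period on
a ring around the mean core.

Derived metrics follow the standard reentry bookkeeping:

* wavelength            lambda = CV * CL          (cm)
* temporal excitability gap    = CL - APD90       (ms)
* spatial excitability gap     = CV * (CL - APD90) (cm)

with CV taken from the rotor periphery, because conduction near the core
is electrotonically depressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert
from skimage import measure

from .activation import ActivationMap, CVField
from .errors import FitError, InputError
from .movie import OpticalMovie

__all__ = [
    "PhaseMap", "phase_map", "PSPoint", "find_singularities",
    "PhaseSingularity", "track_rotors", "fit_circle", "wavefront_curvature",
    "RotorMetrics", "rotor_metrics", "spatial_excitability_gap",
    "temporal_excitability_gap", "rotor_wavelength",
]

TWO_PI = 2.0 * np.pi


@dataclass
class PhaseMap:
    phase: np.ndarray               # rows x cols x frames, (-pi, pi]; NaN invalid
    dx: float
    frame_interval: float
    mask: np.ndarray
    method: str = "hilbert"

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.phase.shape[2]) * self.frame_interval


def _dominant_period(x: np.ndarray, dt: float) -> float:
    """Dominant period (ms) of a mean trace via the FFT peak."""
    x = x - x.mean()
    n = len(x)
    spec = np.abs(np.fft.rfft(x * np.hanning(n)))
    freqs = np.fft.rfftfreq(n, dt)
    k = int(np.argmax(spec[1:]) + 1)
    return 1.0 / freqs[k]


def phase_map(movie: OpticalMovie, method: str = "hilbert",
              silent_frac: float = 0.1) -> PhaseMap:
    """Instantaneous phase of every pixel's mean-subtracted trace.

    ``hilbert`` uses the analytic signal; ``delay_embedding`` uses
    atan2(-x(t + tau), x(t)) with tau = a quarter of the dominant period
    (sign chosen so both methods rotate the same way on a sinusoid).
    Near-silent pixels (peak-to-peak below ``silent_frac`` of the movie's
    global range) get NaN phase.
    """
    if method not in ("hilbert", "delay_embedding"):
        raise InputError(f"unknown phase method {method!r}")
    data = movie.data
    mask = movie.mask
    traces = data[mask].astype(float)
    if not np.isfinite(traces).all():
        raise InputError("phase mapping requires finite traces on the mask")
    ptp = traces.max(axis=1) - traces.min(axis=1)
    global_rng = float(traces.max() - traces.min())
    live = ptp > silent_frac * global_rng
    centered = traces - traces.mean(axis=1, keepdims=True)

    if method == "hilbert":
        ph = np.angle(hilbert(centered, axis=1))
    else:
        period = _dominant_period(centered.mean(axis=0), movie.frame_interval)
        tau = max(1, int(round(period / 4.0 / movie.frame_interval)))
        shifted = np.concatenate(
            [centered[:, tau:], centered[:, -1:].repeat(tau, axis=1)], axis=1)
        ph = np.arctan2(-shifted, centered)

    ph[~live] = np.nan
    out = np.full(data.shape, np.nan)
    out[mask] = ph
    return PhaseMap(phase=out, dx=movie.dx, frame_interval=movie.frame_interval,
                    mask=mask & True, method=method)


@dataclass(frozen=True)
class PSPoint:
    t_ms: float
    row: float                      # subpixel
    col: float
    charge: int


def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % TWO_PI - np.pi


def _refine_bilinear(ph: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """Subpixel PS position inside plaquette (r, c): zero of the bilinear
    interpolants of cos(phase) and sin(phase) over the 2x2 corners."""
    z = np.exp(1j * ph[r:r + 2, c:c + 2])

    def zero_lines(f):
        # f(x, y) = a0 + a1 x + a2 y + a3 x y on the unit square
        a0 = f[0, 0]
        a1 = f[0, 1] - f[0, 0]
        a2 = f[1, 0] - f[0, 0]
        a3 = f[1, 1] - f[1, 0] - f[0, 1] + f[0, 0]
        return a0, a1, a2, a3

    A = zero_lines(z.real)
    B = zero_lines(z.imag)
    # solve A = B = 0; eliminating y = -(a0 + a1 x)/(a2 + a3 x) leaves the
    # quadratic (b0 + b1 x)(a2 + a3 x) - (b2 + b3 x)(a0 + a1 x) = 0
    c0 = B[0] * A[2] - B[2] * A[0]
    c1 = B[0] * A[3] + B[1] * A[2] - B[2] * A[1] - B[3] * A[0]
    c2 = B[1] * A[3] - B[3] * A[1]
    xs = []
    if abs(c2) > 1e-12:
        disc = c1 * c1 - 4 * c2 * c0
        if disc >= 0:
            sq = np.sqrt(disc)
            xs = [(-c1 + sq) / (2 * c2), (-c1 - sq) / (2 * c2)]
    elif abs(c1) > 1e-12:
        xs = [-c0 / c1]
    for x in xs:
        den = A[2] + A[3] * x
        if abs(den) < 1e-12:
            continue
        y = -(A[0] + A[1] * x) / den
        if -0.05 <= x <= 1.05 and -0.05 <= y <= 1.05:
            return r + float(np.clip(y, 0, 1)), c + float(np.clip(x, 0, 1))
    return r + 0.5, c + 0.5


def find_singularities(pm: PhaseMap, frames=None,
                       min_winding: float = 1.8 * np.pi) -> list[list[PSPoint]]:
    """Phase singularities per frame by plaquette winding.

    The topological charge of each 2x2 plaquette is the closed-loop sum of
    wrapped phase differences; |sum| = 2*pi marks a singularity (threshold
    ``min_winding`` tolerates discretization).  Returns one list of
    :class:`PSPoint` per requested frame (all frames by default); empty
    lists are valid results.
    """
    ph = pm.phase
    n_frames = ph.shape[2]
    frames = range(n_frames) if frames is None else frames
    out = []
    for k in frames:
        f = ph[:, :, k]
        d_right = _wrap(f[:-1, 1:] - f[:-1, :-1])      # top edge, left->right
        d_down = _wrap(f[1:, 1:] - f[:-1, 1:])         # right edge, down
        d_left = _wrap(f[1:, :-1] - f[1:, 1:])         # bottom edge, right->left
        d_up = _wrap(f[:-1, :-1] - f[1:, :-1])         # left edge, up
        winding = d_right + d_down + d_left + d_up
        winding[~np.isfinite(winding)] = 0.0
        rr, cc = np.nonzero(np.abs(winding) >= min_winding)
        pts = []
        for r, c in zip(rr, cc):
            row, col = _refine_bilinear(f, r, c)
            pts.append(PSPoint(t_ms=k * pm.frame_interval, row=row, col=col,
                               charge=int(np.sign(winding[r, c]))))
        out.append(pts)
    return out


@dataclass
class PhaseSingularity:
    """A tracked spiral core: trajectory, charge, and rotation statistics."""

    trajectory: pd.DataFrame        # t_ms, row, col
    charge: int
    lifespan_ms: float
    n_rotations: float
    cycle_length: float             # ms; NaN if unresolvable

    @property
    def core(self) -> tuple[float, float]:
        return (float(self.trajectory["row"].mean()),
                float(self.trajectory["col"].mean()))


def _ring_cycle_stats(pm: PhaseMap, core: tuple[float, float],
                      r_in_mm: float = 2.0, r_out_mm: float = 3.0):
    """Rotation period and count from unwrapped phase on a ring around the core."""
    rows, cols = pm.mask.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    dist = np.hypot(yy - core[0], xx - core[1]) * pm.dx
    ring = pm.mask & (dist >= r_in_mm) & (dist <= r_out_mm)
    ring &= np.isfinite(pm.phase).all(axis=2)
    if ring.sum() < 5:
        return np.nan, 0.0
    ph = np.unwrap(pm.phase[ring], axis=1)
    t = pm.times
    slopes = np.polyfit(t, ph.T, 1)[0]          # rad/ms per pixel
    slope = np.median(slopes)
    if abs(slope) < 1e-9:
        return np.nan, 0.0
    cl = TWO_PI / abs(slope)
    n_rot = abs(np.median(ph[:, -1] - ph[:, 0])) / TWO_PI
    return float(cl), float(n_rot)


def track_rotors(ps_frames: list[list[PSPoint]], pm: PhaseMap,
                 gate_mm_per_frame: float = 1.0, max_gap: int = 3,
                 min_frames: int | None = None) -> list[PhaseSingularity]:
    """Link per-frame PS detections into trajectories and score each rotor.

    Greedy nearest-neighbour linking with a distance gate of
    ``gate_mm_per_frame``; a track is split when its PS disappears for more
    than ``max_gap`` frames.  Each surviving track gets a cycle length and
    rotation count from the ring statistics around its mean core.
    """
    gate_px = gate_mm_per_frame / pm.dx
    open_tracks: list[dict] = []
    done: list[dict] = []
    for k, pts in enumerate(ps_frames):
        unmatched = list(pts)
        for tr in open_tracks:
            if not unmatched:
                break
            last = tr["pts"][-1]
            gap = k - tr["last_frame"]
            if gap > max_gap + 1:
                continue
            cands = [p for p in unmatched if p.charge == tr["charge"]]
            if not cands:
                continue
            d = [np.hypot(p.row - last.row, p.col - last.col) for p in cands]
            j = int(np.argmin(d))
            if d[j] <= gate_px * gap:
                tr["pts"].append(cands[j])
                tr["last_frame"] = k
                unmatched.remove(cands[j])
        for p in unmatched:
            open_tracks.append({"pts": [p], "charge": p.charge, "last_frame": k})
        still = []
        for tr in open_tracks:
            if k - tr["last_frame"] > max_gap:
                done.append(tr)
            else:
                still.append(tr)
        open_tracks = still
    done.extend(open_tracks)

    n_frames = pm.phase.shape[2]
    if min_frames is None:
        min_frames = max(3, n_frames // 2)
    rotors = []
    for tr in done:
        if len(tr["pts"]) < min_frames:
            continue
        df = pd.DataFrame([(p.t_ms, p.row, p.col) for p in tr["pts"]],
                          columns=["t_ms", "row", "col"])
        core = (df["row"].mean(), df["col"].mean())
        cl, n_rot = _ring_cycle_stats(pm, core)
        rotors.append(PhaseSingularity(
            trajectory=df, charge=tr["charge"],
            lifespan_ms=float(df["t_ms"].iloc[-1] - df["t_ms"].iloc[0]),
            n_rotations=n_rot, cycle_length=cl))
    return rotors


def fit_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) least-squares circle fit; returns (row0, col0, R).

    ``points`` is (n, 2) in any consistent length unit; the fit minimizes
    the algebraic distance, adequate for curvature estimation on short
    isochrone arcs.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise FitError("need >= 3 points for a circle fit")
    y, x = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * y, 2 * x, np.ones(len(y))])
    b = y ** 2 + x ** 2
    sol, res, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        # collinear points: a straight front, i.e. an infinite-radius circle
        return float(y.mean()), float(x.mean()), np.inf
    y0, x0, c = sol
    r = np.sqrt(max(c + y0 ** 2 + x0 ** 2, 0.0))
    return float(y0), float(x0), float(r)


def _mask_temporal_seam(t: np.ndarray, jump_frac: float = 0.5) -> np.ndarray:
    """NaN-out pixels sitting on a temporal discontinuity of the map.

    A pixel is seam-adjacent when it differs from a 4-neighbour by more
    than ``jump_frac`` of the map's time range.
    """
    rng = np.nanmax(t) - np.nanmin(t)
    if not np.isfinite(rng) or rng == 0:
        return t
    thr = jump_frac * rng
    out = t.copy()
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        nb = np.roll(t, shift, axis=axis)
        if axis == 0:
            nb[0 if shift == 1 else -1, :] = np.nan
        else:
            nb[:, 0 if shift == 1 else -1] = np.nan
        with np.errstate(invalid="ignore"):
            out[np.abs(t - nb) > thr] = np.nan
    return out


def wavefront_curvature(act: ActivationMap, core: tuple[float, float],
                        radius_mm: float = 5.0, n_levels: int = 5,
                        min_points: int = 10,
                        max_radius_mm: float = 100.0) -> float:
    """Core-proximal wavefront curvature kappa (1/mm) from isochrone arcs.

    For ``n_levels`` isochrone levels spanning the central part of the
    activation range, extract the contour segment within ``radius_mm`` of
    the core, fit a circle, and average kappa = 1/R over levels.  Nearly
    straight fronts (R above ``max_radius_mm``) count as kappa ~ 0; NaN if
    no level yields enough contour points.

    On maps of periodic (re-entrant) activity the window edge leaves a
    temporal seam — adjacent pixels activating at the start vs the end of
    the window.  Pixels across such jumps are masked before contour
    extraction so the seam cannot masquerade as a wavefront.
    """
    t = act.times.copy()
    t[~act.valid] = np.nan
    t = _mask_temporal_seam(t)
    lo, hi = np.nanpercentile(t, [25, 75])
    if not np.isfinite(lo) or hi <= lo:
        return np.nan
    kappas = []
    for level in np.linspace(lo, hi, n_levels):
        # the wavefront is the longest contour segment near the core;
        # short fragments are mask-edge debris
        segs = []
        for contour in measure.find_contours(t, level):
            d = np.hypot(contour[:, 0] - core[0], contour[:, 1] - core[1]) * act.dx
            seg = contour[d <= radius_mm]
            if len(seg) >= min_points:
                segs.append(seg)
        if not segs:
            continue
        seg = max(segs, key=len)
        try:
            _, _, r_px = fit_circle(seg)
        except FitError:
            continue
        r_mm = r_px * act.dx
        kappas.append(1.0 / r_mm if r_mm < max_radius_mm
                      else 1.0 / max_radius_mm)
    return float(np.mean(kappas)) if kappas else np.nan


def rotor_wavelength(cv_cm_s: float, cl_ms: float) -> float:
    """lambda = CV * CL, in cm."""
    return cv_cm_s * cl_ms / 1000.0


def temporal_excitability_gap(cl_ms: float, apd90_ms: float) -> float:
    """CL - APD90, in ms."""
    return cl_ms - apd90_ms


def spatial_excitability_gap(cv_cm_s: float, cl_ms: float,
                             apd90_ms: float) -> float:
    """CV * (CL - APD90), in cm."""
    return cv_cm_s * temporal_excitability_gap(cl_ms, apd90_ms) / 1000.0


@dataclass
class RotorMetrics:
    """Summary of one tracked rotor.  All CVs in cm/s, times in ms,
    lengths in cm, curvature in 1/mm."""

    cl: float
    cv_core: float
    cv_periphery: float
    kappa: float
    wavelength: float
    spatial_gap: float
    temporal_gap: float
    apd90_optical: float
    head_to_tail: bool = False      # CL <= APD90: no excitable gap

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def rotor_metrics(rotor: PhaseSingularity, cv: CVField,
                  apd90_map: np.ndarray, act: ActivationMap | None = None,
                  core_radius_mm: float = 1.5,
                  periphery_radius_mm: float = 3.5,
                  kappa_radius_mm: float = 5.0) -> RotorMetrics:
    """Assemble the rotor metric set from tracked core + field maps.

    CV is averaged over two annuli around the mean core (< ``core_radius_mm``
    and >= ``periphery_radius_mm``); wavelength and both excitability gaps
    use the peripheral CV.  When CL <= APD90 the gaps are reported as 0 with
    the head-to-tail flag set.
    """
    core = rotor.core
    rows, cols = cv.speed.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    dist = np.hypot(yy - core[0], xx - core[1]) * cv.dx

    def annulus_mean(sel):
        vals = cv.speed[sel & cv.valid]
        vals = vals[vals <= 30.0]
        return float(vals.mean()) if vals.size else np.nan

    cv_core = annulus_mean(dist < core_radius_mm)
    cv_per = annulus_mean(dist >= periphery_radius_mm)
    apd_vals = apd90_map[np.isfinite(apd90_map) & (dist >= periphery_radius_mm)]
    apd90 = float(apd_vals.mean()) if apd_vals.size else np.nan

    kappa = (wavefront_curvature(act, core, kappa_radius_mm)
             if act is not None else np.nan)

    cl = rotor.cycle_length
    head_to_tail = bool(np.isfinite(cl) and np.isfinite(apd90) and cl <= apd90)
    if head_to_tail:
        t_gap, s_gap = 0.0, 0.0
    else:
        t_gap = temporal_excitability_gap(cl, apd90)
        s_gap = spatial_excitability_gap(cv_per, cl, apd90)
    return RotorMetrics(cl=cl, cv_core=cv_core, cv_periphery=cv_per,
                        kappa=kappa, wavelength=rotor_wavelength(cv_per, cl),
                        spatial_gap=s_gap, temporal_gap=t_gap,
                        apd90_optical=apd90, head_to_tail=head_to_tail)
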