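"""Run orchestration: simulate -> image -> condition -> analyze -> report.

A :class:`RunConfig` fully describes one experiment (simulation spec or
input movie, stage options, seed, output directory); :func:`run` executes
the stages, writes every intermediate product, and returns an
:class:`ExperimentReport`.  Reruns with the same config and seed are
bit-identical.  :func:`make_fixtures` writes the deterministic fixture set
(analytic waves with declared ground truth plus trace CSVs) with a
checksummed manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analytic, traces
from .activation import activation_map, cv_field, cv_summary
from .ap import features_frame, features_per_beat, optical_apd_map
from .drugs import DrugModel, dofetilide_like, flecainide_like
from .errors import InputError
from .movie import load_movie, save_movie, _jsonable
from .optics import OpticalTransform, voltage_to_optical
from .phase import find_singularities, phase_map, rotor_metrics, track_rotors
from .preprocess import ConditionOptions, condition, segment_beats
from .tissue import StimulusProtocol, TissueConfig, simulate

log = logging.getLogger("rotorkit")

__all__ = ["RunConfig", "ExperimentReport", "run", "make_fixtures"]

_DRUGS = {"none": None, "flecainide": flecainide_like, "dofetilide": dofetilide_like}


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    out_dir: str = "rotorkit_run"
    input_movie: str | None = None        # path; None = simulate
    protocol: str = "focal_pacemaker"     # simulation protocol kind
    cycle_length: float = 60000.0 / 78.0
    duration: float = 2000.0
    s2_delay: float = 280.0
    drug: str = "none"
    g_fi_scale: float | None = None
    g_rep_scale: float | None = None
    grid_shape: tuple[int, int] = (100, 100)
    seed: int = 0
    camera: bool = True                   # apply the dye/camera model
    noise_sd: float = 0.02
    frame_interval: float = 5.0
    beat_window: tuple[float, float] | None = None
    stages: tuple[str, ...] = ("condition", "beats", "activation", "rotor")
    render_png: bool = True

    def to_json(self) -> str:
        return json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["grid_shape"] = tuple(d.get("grid_shape", (100, 100)))
        d["stages"] = tuple(d.get("stages", ()))
        if d.get("beat_window") is not None:
            d["beat_window"] = tuple(d["beat_window"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    def build_drug(self) -> DrugModel | None:
        maker = _DRUGS.get(self.drug)
        if self.drug not in _DRUGS:
            raise InputError(f"unknown drug {self.drug!r}")
        if maker is None:
            return None
        kw = {}
        if self.drug == "flecainide" and self.g_fi_scale is not None:
            kw["g_fi_scale"] = self.g_fi_scale
        if self.drug == "dofetilide" and self.g_rep_scale is not None:
            kw["g_rep_scale"] = self.g_rep_scale
        return maker(**kw)


@dataclass
class ExperimentReport:
    config_hash: str
    seed: int
    outputs: dict = field(default_factory=dict)       # stage -> file(s)
    summary: dict = field(default_factory=dict)       # numbers

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(_jsonable(dataclasses.asdict(self)),
                                   indent=1, sort_keys=True))


def _stage(report, name, t0):
    log.info("stage=%s elapsed=%.2fs", name, time.time() - t0)


def run(config: RunConfig) -> ExperimentReport:
    """Execute the configured stages; every reported number traces to a file."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = ExperimentReport(config_hash=config.config_hash, seed=config.seed)
    (out / "config.json").write_text(config.to_json())
    t0 = time.time()

    # --- acquire -----------------------------------------------------------
    if config.input_movie is not None:
        movie = load_movie(config.input_movie)
        report.outputs["input"] = str(config.input_movie)
    else:
        tc = TissueConfig(grid_shape=config.grid_shape,
                          duration=config.duration, seed=config.seed)
        proto = StimulusProtocol(kind=config.protocol,
                                 cycle_length=config.cycle_length,
                                 s2_delay=config.s2_delay)
        sim = simulate(tc, proto, drug=config.build_drug())
        sim.events.to_csv(out / "events.csv", index=False)
        movie = sim.movie
        if config.camera:
            movie = voltage_to_optical(
                movie, OpticalTransform(noise_sd=config.noise_sd,
                                        frame_interval=config.frame_interval),
                seed=config.seed)
        save_movie(movie, out / "movie.npy")
        report.outputs["movie"] = "movie.npy"
        report.outputs["events"] = "events.csv"
    _stage(report, "acquire", t0)

    # --- condition ---------------------------------------------------------
    if "condition" in config.stages:
        movie = condition(movie, ConditionOptions())
        save_movie(movie, out / "conditioned.npy")
        report.outputs["conditioned"] = "conditioned.npy"
        report.summary["n_invalid_pixels"] = movie.meta["n_invalid_pixels"]
        _stage(report, "condition", t0)

    # --- global trace and beats -------------------------------------------
    sheet_trace = np.nanmean(movie.data[movie.mask], axis=0)
    seg = segment_beats(sheet_trace, movie.frame_interval)
    if "beats" in config.stages:
        feats = features_per_beat(sheet_trace, movie.frame_interval, seg)
        df = features_frame(feats) if feats else pd.DataFrame()
        df.to_csv(out / "beats.csv", index=False)
        report.outputs["beats"] = "beats.csv"
        report.summary["n_beats"] = len(seg.upstroke_times)
        if seg.cl_defined:
            report.summary["mean_cl_ms"] = float(seg.cl_series.mean())
        _stage(report, "beats", t0)

    window = config.beat_window
    if window is None:
        if seg.cl_defined and len(seg.windows) > 1:
            window = seg.windows[-2]
        else:
            window = (0.0, movie.times[-1])

    # --- activation & CV ---------------------------------------------------
    amap = cvf = None
    if "activation" in config.stages or "rotor" in config.stages:
        amap = activation_map(movie, window)
        np.save(out / "activation.npy", amap.times)
        cvf = cv_field(amap)
        np.save(out / "cv_speed.npy", cvf.speed)
        try:
            summ = cv_summary(cvf)
            report.summary["cv_mean_cm_s"] = summ.mean
            report.summary["cv_sd_cm_s"] = summ.sd
            report.summary["cv_n"] = summ.n
        except InputError:
            report.summary["cv_mean_cm_s"] = float("nan")
        report.outputs["activation"] = "activation.npy"
        report.outputs["cv_speed"] = "cv_speed.npy"
        if config.render_png:
            _render_maps(out, movie, amap, cvf)
            report.outputs["maps_png"] = "maps.png"
        _stage(report, "activation", t0)

    # --- phase / rotor -----------------------------------------------------
    if "rotor" in config.stages:
        pm = phase_map(movie)
        ps_frames = find_singularities(pm)
        rotors = track_rotors(ps_frames, pm)
        rows = []
        for k, pts in enumerate(ps_frames):
            for p in pts:
                rows.append((p.t_ms, p.row, p.col, p.charge))
        pd.DataFrame(rows, columns=["t_ms", "row", "col", "charge"]).to_csv(
            out / "singularities.csv", index=False)
        report.outputs["singularities"] = "singularities.csv"
        report.summary["n_rotors"] = len(rotors)
        if rotors:
            rotor = max(rotors, key=lambda r: r.n_rotations)
            # re-map over one full rotor cycle: the beat window segmented
            # from the sheet-mean trace is meaningless during reentry
            if np.isfinite(rotor.cycle_length):
                t_end = movie.times[-1]
                window = (t_end - 2.0 * rotor.cycle_length,
                          t_end - rotor.cycle_length)
                amap = activation_map(movie, window)
                cvf = cv_field(amap)
            apd_map, _ = optical_apd_map(movie, window)
            met = rotor_metrics(rotor, cvf, apd_map, amap)
            report.summary["rotor"] = met.as_dict()
            (out / "rotor_metrics.json").write_text(
                json.dumps(_jsonable(met.as_dict()), indent=1))
            report.outputs["rotor_metrics"] = "rotor_metrics.json"
        _stage(report, "rotor", t0)

    report.save(out / "report.json")
    return report


def _render_maps(out: Path, movie, amap, cvf) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    axes[0].imshow(movie.data[:, :, movie.n_frames // 2], cmap="viridis")
    axes[0].set_title("frame")
    im1 = axes[1].imshow(amap.times, cmap="turbo")
    axes[1].set_title("activation (ms)")
    fig.colorbar(im1, ax=axes[1], shrink=0.7)
    im2 = axes[2].imshow(cvf.speed, cmap="magma", vmax=15)
    axes[2].set_title("CV (cm/s)")
    fig.colorbar(im2, ax=axes[2], shrink=0.7)
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(out / "maps.png", dpi=110)
    plt.close(fig)


# ---------------------------------------------------------------------------
# fixtures

def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict:
    """Write the deterministic fixture set and its manifest.

    All wave fixtures are analytic constructions with exact ground truth
    (synthetic stand-ins for mapped recordings); trace fixtures come from
    the parametric AP generator.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest = {"seed": seed, "fixtures": {}}

    def add(name, path, truth):
        manifest["fixtures"][name] = {
            "file": path.name, "sha256": _sha(path), "ground_truth": truth}
        side = path.with_suffix(path.suffix + ".json")
        if side.exists():
            manifest["fixtures"][name]["sidecar_sha256"] = _sha(side)

    mov = analytic.planar_wave_movie(speed_cm_s=5.0, direction_deg=0.0)
    p = save_movie(mov, out / "planar_wave_small.npy")
    add("planar_wave_small", p, {"speed_cm_s": 5.0, "direction_deg": 0.0})

    mov = analytic.target_wave_movie(speed_cm_s=5.0)
    p = save_movie(mov, out / "target_wave.npy")
    add("target_wave", p, {"speed_cm_s": 5.0, "pattern": "target"})

    ph = analytic.vortex_phase(shape=(60, 60), charge=1)
    p = out / "vortex_phase.npy"
    np.save(p, ph)
    add("vortex_phase", p, {"charge": 1, "core": [29.5, 29.5]})

    base = dict(period=300.0, wavelength_mm=9.0, n_frames=240)
    mov = analytic.spiral_wave_movie(**base)
    p = save_movie(mov, out / "rotor_baseline.npy")
    add("rotor_baseline", p, {"cl_ms": 300.0,
                              "cv_cm_s": 9.0 / 300.0 * 100.0,
                              "core": [49.5, 49.5]})

    mov = analytic.spiral_wave_movie(period=450.0, wavelength_mm=10.0,
                                     apd_fraction=0.38, n_frames=240)
    p = save_movie(mov, out / "rotor_flecainide.npy")
    add("rotor_flecainide", p, {"cl_ms": 450.0,
                                "cv_cm_s": 10.0 / 450.0 * 100.0,
                                "note": "slower, larger rotor; APD similar"})

    mov = analytic.spiral_wave_movie(period=420.0, wavelength_mm=9.0,
                                     apd_fraction=0.62, n_frames=240)
    p = save_movie(mov, out / "rotor_dofetilide.npy")
    add("rotor_dofetilide", p, {"cl_ms": 420.0,
                                "cv_cm_s": 9.0 / 420.0 * 100.0,
                                "note": "longer APD"})

    for name, (apd30, apd90) in {"ap_trace_atrial": (37.0, 247.0),
                                 "ap_trace_ventricular": (327.0, 520.0)}.items():
        t, v = traces.ap_train(cycle_length=800.0, n_beats=6, dt=1.0,
                               apd30=apd30, apd90=apd90)
        p = out / f"{name}.csv"
        pd.DataFrame({"time_ms": t, "value": v}).to_csv(p, index=False)
        add(name, p, {"apd30_ms": apd30, "apd90_ms": apd90, "cl_ms": 800.0})

    t, v = traces.ap_train(cycle_length=150.0, n_beats=12, dt=1.0,
                           apd30=20.0, apd90=110.0)
    p = out / "ap_train_cl150.csv"
    pd.DataFrame({"time_ms": t, "value": v}).to_csv(p, index=False)
    add("ap_train_cl150", p, {"cl_ms": 150.0})

    cl, apd = traces.restitution_pairs(slope=0.30, r_squared=0.69, n=100,
                                       seed=int(rng.integers(2 ** 31)))
    p = out / "restitution_series.csv"
    pd.DataFrame({"cl_ms": cl, "apd50_ms": apd}).to_csv(p, index=False)
    add("restitution_series", p, {"slope": 0.30, "r_squared": 0.69})

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest
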