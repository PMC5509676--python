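"""The movie container shared by every stage of the pipeline.

An :class:`OpticalMovie` is a calibrated 2-D + time array: fluorescence (or
model voltage) sampled on a ``rows x cols`` grid every ``frame_interval``
milliseconds, with ``dx`` millimetres per pixel and a boolean ``mask``
marking tissue pixels.  Movies round-trip to disk as either a ``.npy`` array
or a multi-page TIFF, always with a JSON sidecar carrying the calibration
metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import InputError

__all__ = ["OpticalMovie", "save_movie", "load_movie"]


@dataclass
class OpticalMovie:
    """Voltage/fluorescence movie with spatial and temporal calibration.

    Parameters
    ----------
    data
        Array of shape ``(rows, cols, frames)``.  Fluorescence in arbitrary
        units or normalized [0, 1]; model units for simulator output.
        Pixels outside ``mask`` may be NaN.
    dx
        Pixel pitch in mm.
    frame_interval
        Frame spacing in ms.
    mask
        Boolean tissue mask, shape ``(rows, cols)``.  Defaults to all pixels
        whose trace is entirely finite.
    polarity
        ``"positive"`` if depolarization increases the signal, ``"negative"``
        for dyes that darken on depolarization.
    meta
        Free-form provenance (seed, config hash, processing log).
    """

    data: np.ndarray
    dx: float
    frame_interval: float
    mask: np.ndarray | None = None
    polarity: str = "positive"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InputError("movie data must be rows x cols x frames")
        if self.n_frames < 2:
            raise InputError("movie needs at least 2 frames")
        if self.dx <= 0 or self.frame_interval <= 0:
            raise InputError("dx and frame_interval must be positive")
        if self.mask is None:
            self.mask = np.isfinite(self.data).all(axis=2)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:2]:
            raise InputError("mask shape does not match movie frames")
        if self.polarity not in ("positive", "negative"):
            raise InputError(f"unknown polarity {self.polarity!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ms, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval

    def trace(self, row: int, col: int) -> np.ndarray:
        return self.data[row, col, :]

    def copy_with(self, data: np.ndarray, **updates) -> "OpticalMovie":
        kw = dict(dx=self.dx, frame_interval=self.frame_interval,
                  mask=self.mask.copy(), polarity=self.polarity,
                  meta=dict(self.meta))
        kw.update(updates)
        return OpticalMovie(data=data, **kw)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_movie(movie: OpticalMovie, path: str | Path) -> Path:
    """Write a movie as ``.npy`` or multi-page ``.tif`` plus JSON sidecar.

    TIFF pages are frame-major (one page per time point); the in-memory
    layout stays space-major.
    """
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, movie.data)
    elif path.suffix in (".tif", ".tiff"):
        frames = np.moveaxis(movie.data, 2, 0)
        tifffile.imwrite(path, np.nan_to_num(frames).astype(np.float32))
    else:
        raise InputError(f"unsupported movie format {path.suffix!r}")
    meta = {
        "dx_mm": movie.dx,
        "frame_interval_ms": movie.frame_interval,
        "polarity": movie.polarity,
        "mask_rle": _encode_mask(movie.mask),
        "meta": _jsonable(movie.meta),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def load_movie(path: str | Path) -> OpticalMovie:
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise InputError(f"missing sidecar {side}")
    meta = json.loads(side.read_text())
    if path.suffix == ".npy":
        data = np.load(path)
    elif path.suffix in (".tif", ".tiff"):
        data = np.moveaxis(tifffile.imread(path), 0, 2).astype(float)
    else:
        raise InputError(f"unsupported movie format {path.suffix!r}")
    mask = _decode_mask(meta["mask_rle"], data.shape[:2])
    return OpticalMovie(data=data, dx=meta["dx_mm"],
                        frame_interval=meta["frame_interval_ms"],
                        mask=mask, polarity=meta.get("polarity", "positive"),
                        meta=meta.get("meta", {}))


def _encode_mask(mask: np.ndarray) -> list[int]:
    """Flat run-length encoding (JSON-friendly, exact)."""
    flat = mask.ravel().astype(np.int8)
    edges = np.flatnonzero(np.diff(flat)) + 1
    runs = np.diff(np.concatenate(([0], edges, [flat.size])))
    return [int(flat[0])] + [int(r) for r in runs]


def _decode_mask(rle: list[int], shape: tuple[int, int]) -> np.ndarray:
    first, runs = rle[0], rle[1:]
    out = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, val = 0, bool(first)
    for r in runs:
        out[pos:pos + r] = val
        pos += r
        val = not val
    return out.reshape(shape)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
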