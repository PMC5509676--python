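"""Dye + camera forward model: voltage movies to noisy fluorescence movies.

Emulates the imaging chain of a voltage-sensitive-dye experiment: optical
point-spread blur, camera frame integration (temporal downsampling),
min-max scaling, dye polarity (this dye class darkens on depolarization),
and additive sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

from .errors import ConfigurationError, InputError
from .movie import OpticalMovie

__all__ = ["OpticalTransform", "voltage_to_optical"]


@dataclass(frozen=True)
class OpticalTransform:
    psf_sigma: float = 0.1        # mm; optical blur
    noise_sd: float = 0.02        # fraction of the [0, 1] signal range
    frame_interval: float = 5.0   # ms; camera frame spacing
    invert_polarity: bool = True  # fluorescence falls on depolarization
    output_shape: tuple[int, int] | None = None

    def __post_init__(self):
        if self.psf_sigma < 0 or self.noise_sd < 0:
            raise ConfigurationError("psf_sigma and noise_sd must be >= 0")
        if self.frame_interval <= 0:
            raise ConfigurationError("frame_interval must be positive")


def _masked_blur(frame: np.ndarray, mask: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian blur that ignores out-of-mask pixels (normalized convolution)."""
    if sigma == 0:
        return frame
    filled = np.where(mask, frame, 0.0)
    num = gaussian_filter(filled, sigma)
    den = gaussian_filter(mask.astype(float), sigma)
    out = np.full_like(frame, np.nan)
    ok = den > 1e-9
    out[ok] = num[ok] / den[ok]
    return np.where(mask, out, np.nan)


def voltage_to_optical(movie: OpticalMovie, xform: OpticalTransform,
                       seed: int = 0) -> OpticalMovie:
    """Render a model-unit voltage movie as a camera-like fluorescence movie.

    Per frame: masked Gaussian blur (``psf_sigma`` converted to pixels);
    then block-averaging down to the camera ``frame_interval``; global
    min-max scaling of masked pixels to [0, 1]; optional polarity inversion;
    additive Gaussian noise with standard deviation ``noise_sd``.  ``dx``
    and ``frame_interval`` metadata are propagated.
    """
    if movie.n_frames < 2:
        raise InputError("empty movie")
    if xform.frame_interval < movie.frame_interval - 1e-9:
        raise InputError("camera frame_interval shorter than source sampling")

    data = movie.data.astype(float)
    mask = movie.mask
    sigma_px = xform.psf_sigma / movie.dx
    if sigma_px > 0:
        data = np.stack(
            [_masked_blur(data[:, :, k], mask, sigma_px)
             for k in range(data.shape[2])], axis=2)

    # camera integration: average groups of source frames
    factor = max(1, int(round(xform.frame_interval / movie.frame_interval)))
    if factor > 1:
        n = (data.shape[2] // factor) * factor
        data = data[:, :, :n].reshape(data.shape[0], data.shape[1], -1, factor)
        data = data.mean(axis=3)
    frame_interval = movie.frame_interval * factor

    if xform.output_shape is not None and xform.output_shape != movie.shape:
        scale = (xform.output_shape[0] / movie.shape[0]
                 + xform.output_shape[1] / movie.shape[1]) / 2.0
        data = resize(np.nan_to_num(data), xform.output_shape + (data.shape[2],),
                      order=1, anti_aliasing=False)
        mask = resize(mask.astype(float), xform.output_shape, order=0) > 0.5
        dx = movie.dx / scale
    else:
        dx = movie.dx

    vals = data[mask]
    lo, hi = np.nanmin(vals), np.nanmax(vals)
    if hi <= lo:
        raise InputError("movie has no dynamic range")
    data = (data - lo) / (hi - lo)

    polarity = "positive"
    if xform.invert_polarity:
        data = 1.0 - data
        polarity = "negative"

    if xform.noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, xform.noise_sd, size=data.shape)
    data = np.where(mask[:, :, None], data, np.nan)

    meta = dict(movie.meta)
    meta.update({"optics_seed": seed, "psf_sigma_mm": xform.psf_sigma,
                 "noise_sd": xform.noise_sd})
    return OpticalMovie(data=data, dx=dx, frame_interval=frame_interval,
                        mask=mask, polarity=polarity, meta=meta)
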