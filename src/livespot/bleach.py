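"""Exponential photobleaching estimation and correction.

Photobleaching is modeled as a single exponential on the per-frame mean
intensity of a region of interest, I(t) = A * exp(-kb * t) + offset.
Fitting the region mean rather than individual pixels matches whole-field
bleaching physics and is robust to per-pixel shot noise. The additive
offset absorbs the camera background, which does not bleach; correction
therefore rescales only the signal above the offset.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import curve_fit

from .core_io import MovieStack

__all__ = ["BleachModel", "fit_bleach", "correct_bleach"]

MIN_FRAMES = 10


@dataclasses.dataclass
class BleachModel:
    """Fitted decay I(t) = amplitude * exp(-kb * t) + offset."""

    amplitude: float
    kb: float            # 1/s, >= 0
    offset: float
    fit_r2: float
    constant_input: bool = False  # set when the input had zero variance
    clipped_pixels: int = 0       # populated by correct_bleach

    def evaluate(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.amplitude * np.exp(-self.kb * np.asarray(t, dtype=float)) + self.offset


def _frame_means(movie: MovieStack, channel: int, mask: np.ndarray | None) -> np.ndarray:
    """Per-frame mean inside the mask (2D static or (T, Y, X) time-varying).

    Frames are reduced one at a time to avoid materializing a float copy
    of the whole channel.
    """
    mask = None if mask is None else np.asarray(mask)
    if mask is not None and mask.ndim not in (2, 3):
        raise ValueError("mask must be 2D or 3D")
    if mask is not None and mask.ndim == 3 and mask.shape[0] != movie.n_frames:
        raise ValueError("time-varying mask must have one plane per frame")
    static_sel = None
    if mask is not None and mask.ndim == 2:
        static_sel = mask > 0
        if not static_sel.any():
            raise ValueError("mask selects no pixels")
    means = np.empty(movie.n_frames)
    for t in range(movie.n_frames):
        plane = movie.data[t, channel]
        if mask is None:
            means[t] = plane.mean(dtype=np.float64)
        else:
            sel = static_sel if static_sel is not None else mask[t] > 0
            if not sel.any():
                raise ValueError(f"mask selects no pixels at frame {t}")
            means[t] = plane[sel].mean(dtype=np.float64)
    return means


def _log_linear_init(times: np.ndarray, means: np.ndarray, offset0: float) -> tuple[float, float]:
    """Closed-form initialization: linear regression of log(mean - offset0) on t."""
    signal = means - offset0
    valid = signal > 0
    if valid.sum() < 2:
        return max(float(means[0] - offset0), 1e-9), 0.0
    coeffs = np.polyfit(times[valid], np.log(signal[valid]), 1)
    kb0 = max(-coeffs[0], 0.0)
    amp0 = float(np.exp(coeffs[1]))
    return amp0, kb0


def fit_bleach(movie: MovieStack, channel: int = 0,
               mask: np.ndarray | None = None) -> BleachModel:
    """Fit the bleaching model to the per-frame mean intensity.

    The fit is nonlinear least squares, initialized from a log-linear
    regression on offset-subtracted means; the offset initializes at the
    1st percentile of the frame-mean series. A movie with zero temporal
    variance returns ``kb = 0`` with ``constant_input`` set rather than
    raising.
    """
    if movie.n_frames < MIN_FRAMES:
        raise ValueError(f"bleach fitting needs >= {MIN_FRAMES} frames, got {movie.n_frames}")
    times = movie.times_s()
    means = _frame_means(movie, channel, mask)
    if np.ptp(means) == 0:
        return BleachModel(amplitude=0.0, kb=0.0, offset=float(means[0]),
                           fit_r2=1.0, constant_input=True)
    offset0 = float(np.percentile(means, 1))
    amp0, kb0 = _log_linear_init(times, means, offset0)

    def model(t, amp, kb, off):
        return amp * np.exp(-kb * t) + off

    try:
        popt, _ = curve_fit(
            model, times, means,
            p0=[amp0, max(kb0, 1e-6), offset0],
            bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        amp, kb, off = (float(v) for v in popt)
    except RuntimeError:
        amp, kb, off = amp0, kb0, offset0
    resid = means - model(times, amp, kb, off)
    ss_tot = float(np.sum((means - means.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return BleachModel(amplitude=amp, kb=max(kb, 0.0), offset=off, fit_r2=r2)


def correct_bleach(movie: MovieStack, model: BleachModel, channel: int = 0) -> MovieStack:
    """Undo exponential bleaching on one channel.

    Each frame's signal above the model offset is multiplied by
    ``exp(+kb * t)``; the offset (camera background) is left untouched.
    Values are clipped to the 16-bit range and the clipped-pixel count is
    recorded on the model.
    """
    if model.kb < 0:
        raise ValueError("bleach model must have kb >= 0")
    out = movie.data.astype(np.float64).copy()
    gains = np.exp(model.kb * movie.times_s())
    planes = (out[:, channel] - model.offset) * gains[:, None, None] + model.offset
    clipped = int(np.count_nonzero(planes > 65535))
    model.clipped_pixels = clipped
    out[:, channel] = np.clip(planes, 0, 65535)
    return MovieStack(
        data=np.rint(out).astype(np.uint16) if model.kb > 0 else movie.data.copy(),
        pixel_size_um=movie.pixel_size_um,
        frame_interval_s=movie.frame_interval_s,
        channel_names=list(movie.channel_names),
    )
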