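"""Synthetic two-channel translation movies with exported ground truth.
The simulator emulates live-cell single-mRNA translation imaging: each
field of view carries membrane-tethered mRNA spots (channel 0, constant
unit brightness) and their nascent-protein signal (channel 1), whose
intensity tracks the instantaneous ribosome load on the transcript.
Translation kinetics follow a simple totally-asymmetric-free model:
ribosome initiations on each mRNA are a Poisson process with rate ``ki``;
every ribosome advances deterministically at ``ke`` codons/s and leaves at
the stop codon ``L_total``. A ribosome contributes the fraction of epitope
probes it has already translated, so the normalized spot intensity is
    I(t) = sum_ribosomes  #(probe_positions <= position) / n_probes
in units of one mature protein. Ribosomes are points (no exclusion): at
the default occupancy (~15 ribosomes on 1900 codons) steric effects are
negligible and the model stays analytically tractable.
Rendering places each spot as a 2D Gaussian PSF, applies exponential
photobleaching to the signal (not to the camera background), then Poisson
shot noise and Gaussian read noise, and quantizes to 16-bit.
"""
from __future__ import annotations
import dataclasses
import numpy as np
import pandas as pd
from .core_io import MovieStack
__all__ = [
    "SimulationParams",
    "GroundTruth",
    "benchmark_params",
    "simulate_translation_traces",
    "simulate_positions",
    "render_movie",
    "simulate_movie",
    "benchmark_fixture",
]
#: Default epitope layout: 10 tags uniformly spaced over the first 10% of
#: the open reading frame (an N-terminal spaghetti-monster-style tag).
_DEFAULT_PROBES = tuple(range(10, 200, 20))  # mean position = 100 codons
@dataclasses.dataclass
class SimulationParams:
    """Study conditions for one synthetic movie.
    Defaults reproduce the validation benchmark: 360 frames at 5-s
    intervals, 512x512 pixels, 80 spots, initiation rate 0.04 1/s,
    elongation rate 5 codons/s, photobleaching decay 0.001 1/s, and an
    effective probe-to-termination length of 1900 codons (``L_total`` =
    2000 with the mean epitope at codon 100).
    """
    ki: float = 0.04                      # initiation rate, events/s
    ke: float = 5.0                       # elongation rate, codons/s
    L_total: int = 2000                   # construct length, codons
    probe_positions: tuple[int, ...] = _DEFAULT_PROBES
    n_spots: int = 80
    n_frames: int = 360
    frame_interval_s: float = 5.0
    fov_yx: tuple[int, int] = (512, 512)
    psf_sigma_px: float = 1.3
    spot_amplitude: float = 150.0         # peak counts of a unit-intensity spot
    background_level: float = 100.0       # camera background, counts
    read_noise_sd: float = 2.0            # Gaussian read noise, counts
    bleach_rate: tuple[float, float] = (0.001, 0.001)  # kb per channel, 1/s
    diffusion_coeff_px2s: float = 0.02    # tethered-spot jiggle, px^2/s
    min_separation_px: float = 12.0
    seed: int = 0
    def __post_init__(self) -> None:
        if self.ki < 0:
            raise ValueError("ki must be >= 0")
        if not self.ke > 0:
            raise ValueError("ke must be > 0")
        if not self.L_total > 0:
            raise ValueError("L_total must be > 0")
        probes = tuple(sorted(self.probe_positions))
        if probes != tuple(self.probe_positions):
            raise ValueError("probe_positions must be sorted ascending")
        if probes and not (1 <= probes[0] and probes[-1] <= self.L_total):
            raise ValueError("probe_positions must lie in [1, L_total]")
        if not probes:
            raise ValueError("at least one probe position is required")
        if self.effective_length <= 0:
            raise ValueError("effective length L_total - mean(probe_positions) must be > 0")
        if not self.psf_sigma_px > 0:
            raise ValueError("psf_sigma_px must be > 0")
        if self.diffusion_coeff_px2s < 0:
            raise ValueError("diffusion_coeff_px2s must be >= 0")
        if any(kb < 0 for kb in self.bleach_rate):
            raise ValueError("bleach rates must be >= 0")
    @property
    def effective_length(self) -> float:
        """Mean probe-to-termination distance, codons (sets the ACF de-correlation time)."""
        return self.L_total - float(np.mean(self.probe_positions))
    @property
    def snr_t0(self) -> float:
        """Peak-over-background-noise ratio of a unit spot at t=0."""
        noise_sd = np.sqrt(self.background_level + self.read_noise_sd**2)
        return self.spot_amplitude / noise_sd
@dataclasses.dataclass
class GroundTruth:
    """Per (frame, spot) truth records plus the parameters that made them."""
    table: pd.DataFrame  # frame, spot_id, y_px, x_px, intensity_norm, mrna_present
    params: SimulationParams
    def positions_at(self, frame: int) -> np.ndarray:
        sub = self.table[self.table["frame"] == frame].sort_values("spot_id")
        return sub[["y_px", "x_px"]].to_numpy()
def benchmark_params(seed: int = 0, **overrides) -> SimulationParams:
    """The packaged benchmark configuration, optionally overridden."""
    return SimulationParams(seed=seed, **overrides)
def simulate_translation_traces(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Simulate normalized nascent-protein intensity traces.
    Returns an ``(n_spots, n_frames)`` array in units of one mature
    protein. A burn-in of one full transit time before frame 0 puts every
    trace in steady state from the first sample.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    probes = np.asarray(params.probe_positions, dtype=float)
    n_probes = probes.size
    transit_s = params.L_total / params.ke
    t_frames = np.arange(params.n_frames) * params.frame_interval_s
    horizon = t_frames[-1] + transit_s if params.n_frames else transit_s
    traces = np.zeros((params.n_spots, params.n_frames))
    if params.ki == 0:
        return traces
    window = transit_s + horizon  # arrivals in [-transit, horizon)
    for s in range(params.n_spots):
        n_arrivals = rng.poisson(params.ki * window)
        arrivals = rng.uniform(-transit_s, horizon, size=n_arrivals)
        if n_arrivals == 0:
            continue
        # codon position of each ribosome at each frame time
        pos = params.ke * (t_frames[None, :] - arrivals[:, None])
        active = (pos >= 0.0) & (pos < params.L_total)
        # probes already translated per ribosome (ascending probe list)
        counts = np.searchsorted(probes, pos, side="right").astype(float)
        traces[s] = np.sum(np.where(active, counts, 0.0), axis=0) / n_probes
    return traces
def simulate_positions(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Brownian spot positions, shape ``(n_spots, n_frames, 2)`` as (y, x).
    Per-axis increments have variance ``2 * D * dt``; trajectories reflect
    at the field boundary. ``D = 0`` yields static tethered spots. Initial
    positions are drawn with a minimum pairwise separation so rendered
    spots do not overlap at t=0.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    ny, nx = params.fov_yx
    margin = max(4.0 * params.psf_sigma_px, 4.0)
    sep = params.min_separation_px
    usable = (ny - 2 * margin) * (nx - 2 * margin)
    if usable < params.n_spots * (sep**2):
        raise ValueError(
            f"field {params.fov_yx} too small for {params.n_spots} spots at "
            f"minimum separation {sep} px"
        )
    starts = np.empty((params.n_spots, 2))
    placed = 0
    attempts = 0
    while placed < params.n_spots:
        cand = np.array([rng.uniform(margin, ny - margin), rng.uniform(margin, nx - margin)])
        if placed == 0 or np.min(np.linalg.norm(starts[:placed] - cand, axis=1)) >= sep:
            starts[placed] = cand
            placed += 1
        attempts += 1
        if attempts > 10000 * params.n_spots:
            raise ValueError("could not place spots at the requested minimum separation")
    step_sd = np.sqrt(2.0 * params.diffusion_coeff_px2s * params.frame_interval_s)
    pos = np.empty((params.n_spots, params.n_frames, 2))
    pos[:, 0] = starts
    if step_sd > 0 and params.n_frames > 1:
        steps = rng.normal(0.0, step_sd, size=(params.n_spots, params.n_frames - 1, 2))
        walk = starts[:, None, :] + np.cumsum(steps, axis=1)
        pos[:, 1:] = walk
        # reflect at [0, ny-1] x [0, nx-1]
        for axis, hi in enumerate((ny - 1.0, nx - 1.0)):
            p = pos[..., axis]
            p = np.abs(p)  # reflect at 0
            period = 2.0 * hi
            p = np.mod(p, period)
            p = np.where(p > hi, period - p, p)
            pos[..., axis] = p
    else:
        pos[:] = starts[:, None, :]
    return pos
def _render_spots(frame: np.ndarray, positions: np.ndarray, amplitudes: np.ndarray,
                  sigma: float) -> None:
    """Add 2D Gaussians (peak = amplitude) into ``frame`` in place."""
    ny, nx = frame.shape
    half = int(np.ceil(4 * sigma))
    for (y, x), amp in zip(positions, amplitudes):
        if amp <= 0:
            continue
        iy, ix = int(round(y)), int(round(x))
        y0, y1 = max(iy - half, 0), min(iy + half + 1, ny)
        x0, x1 = max(ix - half, 0), min(ix + half + 1, nx)
        if y0 >= y1 or x0 >= x1:
            continue
        yy = np.arange(y0, y1)[:, None] - y
        xx = np.arange(x0, x1)[None, :] - x
        frame[y0:y1, x0:x1] += amp * np.exp(-(yy**2 + xx**2) / (2.0 * sigma**2))
def render_movie(
    traces: np.ndarray,
    positions: np.ndarray,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> tuple[MovieStack, GroundTruth]:
    """Render traces and positions into a noisy two-channel movie.
    Channel 0 (mRNA) carries every spot at unit intensity; channel 1
    (nascent protein) scales by the normalized trace value. Both signals
    decay as ``exp(-kb * t)`` before background, shot noise and read noise
    are applied. Deterministic for a given generator state.
    """
    rng = np.random.default_rng(params.seed + 1) if rng is None else rng
    n_spots, n_frames = traces.shape
    if positions.shape[:2] != (n_spots, n_frames):
        raise ValueError("traces and positions disagree in spot or frame count")
    ny, nx = params.fov_yx
    data = np.empty((n_frames, 2, ny, nx), dtype=np.uint16)
    times = np.arange(n_frames) * params.frame_interval_s
    unit = np.ones(n_spots)
    for t in range(n_frames):
        for c, channel_traces in enumerate((unit, traces[:, t])):
            clean = np.zeros((ny, nx))
            bleach = np.exp(-params.bleach_rate[c] * times[t])
            amps = params.spot_amplitude * channel_traces * bleach
            _render_spots(clean, positions[:, t], amps, params.psf_sigma_px)
            clean += params.background_level
            noisy = rng.poisson(clean).astype(np.float64)
            if params.read_noise_sd > 0:
                noisy += rng.normal(0.0, params.read_noise_sd, size=clean.shape)
            data[t, c] = np.clip(np.rint(noisy), 0, 65535).astype(np.uint16)
    movie = MovieStack(
        data=data,
        frame_interval_s=params.frame_interval_s,
        channel_names=["mRNA", "nascent"],
    )
    records = pd.DataFrame({
        "frame": np.repeat(np.arange(n_frames), n_spots),
        "spot_id": np.tile(np.arange(n_spots), n_frames),
        "y_px": positions[:, :, 0].T.ravel(),
        "x_px": positions[:, :, 1].T.ravel(),
        "intensity_norm": traces.T.ravel(),
        "mrna_present": True,
    })
    return movie, GroundTruth(table=records, params=params)
def render_noiseless_frame(positions: np.ndarray, amplitudes: np.ndarray,
                           shape: tuple[int, int], sigma: float,
                           background: float = 0.0) -> np.ndarray:
    """Clean (noise-free) render of one frame; used for oracles and calibration."""
    frame = np.full(shape, float(background))
    _render_spots(frame, positions, np.asarray(amplitudes, dtype=float), sigma)
    return frame
def simulate_movie(params: SimulationParams) -> tuple[MovieStack, GroundTruth]:
    """Full simulation: kinetics, motion and rendering from one seed.
    All randomness derives deterministically from ``params.seed``.
    """
    root = np.random.SeedSequence(params.seed)
    rng_traces, rng_pos, rng_render = (np.random.default_rng(s) for s in root.spawn(3))
    traces = simulate_translation_traces(params, rng_traces)
    positions = simulate_positions(params, rng_pos)
    return render_movie(traces, positions, params, rng_render)
def benchmark_fixture(seed: int = 0, **overrides) -> tuple[MovieStack, GroundTruth]:
    """The packaged benchmark movie (see :class:`SimulationParams` defaults)."""
    return simulate_movie(benchmark_params(seed=seed, **overrides))
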