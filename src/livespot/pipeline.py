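"""Configuration-driven orchestration of all analysis stages.

Stages run in the fixed order simulate -> bleach -> segment -> detect ->
track -> intensity -> colocalize -> correlate. Every stage records its
parameters in the run metadata, and identical config + seed reproduces
byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bleach import correct_bleach, fit_bleach
from .colocalize import colocalize_tracks, pairs_to_table
from .config import PipelineConfig
from .core_io import (MovieStack, RunMetadata, export_metadata, export_table,
                      load_movie, save_movie)
from .detection import DetectionParams, auto_threshold, detect_movie
from .kinetics import (autocorrelate, crosscorrelate, decorrelation_time,
                       estimate_rates)
from .quantify import extract_traces, traces_to_table
from .segmentation import (assign_spots_to_cells, export_mask, import_mask,
                           polygon_to_mask, watershed_segment)
from .simulator import SimulationParams, simulate_movie
from .tracking import link_spots, tracks_to_table

logger = logging.getLogger("livespot")

__all__ = ["run_pipeline"]


def _simulation_params(config: PipelineConfig) -> SimulationParams:
    sim = config.simulate
    return SimulationParams(
        ki=sim.ki, ke=sim.ke, L_total=sim.l_total, n_spots=sim.n_spots,
        n_frames=sim.n_frames, frame_interval_s=sim.frame_interval_s,
        fov_yx=tuple(sim.fov), psf_sigma_px=sim.psf_sigma_px,
        spot_amplitude=sim.spot_amplitude, background_level=sim.background_level,
        read_noise_sd=sim.read_noise_sd, bleach_rate=tuple(sim.bleach_rate),
        diffusion_coeff_px2s=sim.diffusion_px2s, seed=config.seed,
    )


def _detect_channel(movie: MovieStack, config: PipelineConfig, channel: int,
                    meta: RunMetadata) -> pd.DataFrame:
    det = config.detect
    threshold = det.threshold
    if threshold is None:
        sample_idx = np.unique(np.linspace(0, movie.n_frames - 1, min(8, movie.n_frames)).astype(int))
        auto = auto_threshold([movie.frame(int(t), channel) for t in sample_idx],
                              det.sigma_px, det.min_separation_px)
        threshold = auto.threshold
        meta.update(f"detect.ch{channel}", {
            "auto_threshold": auto.threshold,
            "auto_threshold_elbow": auto.elbow_threshold,
            "auto_threshold_plateau": auto.plateau_threshold,
        })
    params = DetectionParams(sigma_px=det.sigma_px, threshold=threshold,
                             min_separation_px=det.min_separation_px,
                             cluster_multiplier=det.cluster_multiplier)
    planes = ((t, movie.frame(t, channel)) for t in range(movie.n_frames))
    spots = detect_movie(planes, params, channel=channel)
    if det.drop_clusters and len(spots):
        spots = spots[~spots["is_cluster"].astype(bool)].reset_index(drop=True)
    meta.update(f"detect.ch{channel}", {
        "sigma": det.sigma_px, "threshold": threshold, "channel": channel,
        "min_separation_px": det.min_separation_px,
        "cluster_multiplier": det.cluster_multiplier,
        "n_detections": len(spots),
    })
    return spots


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None) -> Path:
    """Execute the enabled stages; returns the output directory.

    A stage failure writes a ``FAILED`` marker naming the stage, keeps any
    partial outputs, and re-raises the cause.
    """
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = RunMetadata(software_version=__version__, random_seed=config.seed)
    meta.stamp_start()
    meta.update("config", config.flat_parameters())
    stage = "init"
    try:
        movie, truth = _stage_input(config, out, meta)
        # Detection and segmentation run on the raw movie (bleach correction
        # preserves SNR but amplifies late-frame noise, which destabilizes a
        # single global threshold); intensity extraction uses the corrected
        # movie so traces are free of the bleaching decay.
        corrected = movie
        stage = "bleach"
        if config.bleach.enabled:
            channels = (range(movie.n_channels) if config.bleach.channel == "all"
                        else [config.bleach.channel])
            for c in channels:
                model = fit_bleach(movie, channel=c)
                corrected = correct_bleach(corrected, model, channel=c)
                meta.update(f"bleach.ch{c}", {
                    "kb_per_s": model.kb, "amplitude": model.amplitude,
                    "offset": model.offset, "fit_r2": model.fit_r2,
                    "clipped_pixels": model.clipped_pixels,
                })
                logger.info("[bleach] channel %d kb=%.3g 1/s", c, model.kb)
            save_movie(corrected, out / "movie_corrected.tif")
        stage = "segment"
        mask = None
        if config.segment.enabled:
            mask = _stage_segment(config, movie, out, meta)
        stage = "detect"
        spots = pd.DataFrame()
        tracks_by_channel: dict[int, list] = {}
        if config.detect.enabled:
            wanted = {config.detect.channel}
            if config.colocalize.enabled:
                wanted |= {config.colocalize.channel_a, config.colocalize.channel_b}
            if config.correlate.enabled:
                wanted.add(config.correlate.channel)
            channels = sorted(wanted)
            tables = [_detect_channel(movie, config, c, meta) for c in channels]
            spots = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
            if mask is not None and len(spots):
                spots = assign_spots_to_cells(spots, mask)
            logger.info("[detect] %d detections in %d channel(s)", len(spots), len(channels))
        stage = "track"
        if config.track.enabled and len(spots):
            offset = 0
            for channel in sorted(spots["channel"].unique()):
                sub = spots[spots["channel"] == channel]
                tracks = link_spots(sub, config.track.max_disp_px, config.track.memory,
                                    config.track.min_track_len, config.track.method)
                for tr in tracks:
                    tr.track_id += offset
                offset += len(tracks)
                tracks_by_channel[int(channel)] = tracks
            all_tracks = [tr for trs in tracks_by_channel.values() for tr in trs]
            spots = tracks_to_table(spots, all_tracks)
            meta.update("track", {
                "max_disp_px": config.track.max_disp_px, "memory": config.track.memory,
                "min_track_len": config.track.min_track_len, "method": config.track.method,
                "n_tracks": offset,
            })
            summary = pd.DataFrame([{
                "track_id": tr.track_id, "channel": tr.channel,
                "n_points": tr.n_points, "first_frame": int(tr.frames[0]),
                "last_frame": int(tr.frames[-1]), "n_gaps": len(tr.gap_frames),
            } for tr in all_tracks])
            summary.to_csv(out / "tracks.csv", index=False)
            logger.info("[track] %d tracks", offset)
        if len(spots):
            export_table(spots.drop(columns=["peak_response", "footprint_px"],
                                    errors="ignore"), out / "spots.csv", "spots")
        stage = "intensity"
        traces_by_channel = {}
        if config.intensity.enabled and tracks_by_channel:
            all_traces = []
            for channel, tracks in tracks_by_channel.items():
                traces = extract_traces(
                    corrected, tracks, method=config.intensity.method,
                    gap_policy=config.intensity.gap_policy,
                    disk_radius_px=config.intensity.disk_radius_px,
                    ring_width_px=config.intensity.ring_width_px,
                    sigma_px=config.detect.sigma_px,
                )
                traces_by_channel[channel] = traces
                all_traces.extend(traces)
            export_table(traces_to_table(all_traces), out / "traces.csv", "traces")
            meta.update("intensity", {
                "method": config.intensity.method, "gap_policy": config.intensity.gap_policy,
                "ring_width_px": config.intensity.ring_width_px,
                "disk_radius_px": config.intensity.disk_radius_px,
            })
        stage = "colocalize"
        if config.colocalize.enabled:
            ca, cb = config.colocalize.channel_a, config.colocalize.channel_b
            pairs = colocalize_tracks(tracks_by_channel.get(ca, []),
                                      tracks_by_channel.get(cb, []),
                                      d_max_px=config.colocalize.d_max_px,
                                      min_fraction=config.colocalize.min_fraction)
            export_table(pairs_to_table(pairs), out / "coloc.csv", "coloc")
            meta.update("colocalize", {
                "d_max_px": config.colocalize.d_max_px,
                "min_fraction": config.colocalize.min_fraction,
                "n_pairs": len(pairs),
            })
            logger.info("[colocalize] %d track pairs", len(pairs))
        stage = "correlate"
        if config.correlate.enabled:
            traces = traces_by_channel.get(config.correlate.channel, [])
            if not traces:
                raise ValueError(
                    f"correlate stage needs intensity traces for channel "
                    f"{config.correlate.channel}"
                )
            if config.correlate.mode == "ccf":
                ca, cb = config.colocalize.channel_a, config.colocalize.channel_b
                ta = traces_by_channel.get(ca, [])
                tb = traces_by_channel.get(cb, [])
                pairs = colocalize_tracks(tracks_by_channel.get(ca, []),
                                          tracks_by_channel.get(cb, []),
                                          d_max_px=config.colocalize.d_max_px,
                                          min_fraction=config.colocalize.min_fraction)
                by_id_a = {tr.track_id: tr for tr in ta}
                by_id_b = {tr.track_id: tr for tr in tb}
                paired_a = [by_id_a[p.id_a] for p in pairs if p.id_a in by_id_a]
                paired_b = [by_id_b[p.id_b] for p in pairs if p.id_b in by_id_b]
                if not paired_a:
                    raise ValueError("no colocalized track pairs to cross-correlate")
                result = crosscorrelate(paired_a, paired_b,
                                        max_lag_s=config.correlate.max_lag_s)
            else:
                result = autocorrelate(traces, max_lag_s=config.correlate.max_lag_s)
            export_table(result.to_table(), out / "correlation.csv", "correlation")
            meta.update("correlate", {
                "mode": config.correlate.mode, "g0_raw": result.g0_raw,
                "g0_extrap": result.g0_extrap, "n_traces": result.n_traces,
                "n_excluded": result.n_excluded,
                "tau_convention": "linear intercept of central ACF decay",
                "g0_convention": config.correlate.g0_choice,
            })
            kin_payload: dict = {"g0_raw": result.g0_raw, "g0_extrap": result.g0_extrap}
            if config.correlate.mode == "ccf":
                peak_lag = float(result.lags_s[int(np.nanargmax(result.G))])
                kin_payload["peak_lag_s"] = peak_lag
                meta.update("correlate", {"peak_lag_s": peak_lag})
            if config.correlate.mode == "acf" and config.correlate.l_eff_codons is not None:
                tau = decorrelation_time(result)
                est = estimate_rates(result, tau, config.correlate.l_eff_codons,
                                     g0_choice=config.correlate.g0_choice,
                                     rng=np.random.default_rng(config.seed + 7))
                kin_payload.update({
                    "tau_c_s": est.tau_c_s, "ke_codons_per_s": est.ke_codons_per_s,
                    "ki_per_s": est.ki_per_s, "L_eff_codons": est.L_eff_codons,
                    "tau_ci": est.tau_ci, "ke_ci": est.ke_ci, "ki_ci": est.ki_ci,
                })
                meta.update("correlate", {"tau_c_s": est.tau_c_s,
                                          "ke_codons_per_s": est.ke_codons_per_s,
                                          "ki_per_s": est.ki_per_s})
            (out / "kinetics.json").write_text(json.dumps(kin_payload, indent=2) + "\n")
            logger.info("[correlate] g0_raw=%.4g", result.g0_raw)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    meta.stamp_end()
    export_metadata(meta, out / "metadata.json")
    return out


def _stage_input(config: PipelineConfig, out: Path, meta: RunMetadata):
    if config.simulate.enabled:
        params = _simulation_params(config)
        movie, truth = simulate_movie(params)
        save_movie(movie, out / "movie.tif")
        truth.table.to_csv(out / "truth.csv", index=False)
        meta.update("simulate", {
            "ki": params.ki, "ke": params.ke, "L_total": params.L_total,
            "L_eff": params.effective_length, "n_spots": params.n_spots,
            "n_frames": params.n_frames, "frame_interval_s": params.frame_interval_s,
            "spot_amplitude": params.spot_amplitude,
            "background_level": params.background_level,
            "bleach_rate": list(params.bleach_rate),
            "diffusion_px2s": params.diffusion_coeff_px2s, "seed": params.seed,
        })
        logger.info("[simulate] %s", movie.shape)
        return movie, truth
    if config.input.movie is None:
        raise ValueError("input.movie is required when the simulate stage is disabled")
    path = Path(config.input.movie)
    if not path.exists():
        raise FileNotFoundError(f"input movie not found: {path}")
    movie = load_movie(path, axis_order=config.input.axis_order,
                       n_channels=config.input.n_channels,
                       pixel_size_um=config.input.pixel_size_um,
                       frame_interval_s=config.input.frame_interval_s)
    meta.update("input", {"movie": str(path), "axis_order": config.input.axis_order,
                          "pixel_size_um": config.input.pixel_size_um,
                          "frame_interval_s": config.input.frame_interval_s})
    return movie, None


def _stage_segment(config: PipelineConfig, movie: MovieStack, out: Path, meta: RunMetadata):
    seg = config.segment
    if seg.method == "watershed":
        projection = movie.data[:, seg.channel].mean(axis=0)
        mask = watershed_segment(projection, seg.intensity_threshold, seg.min_area_px,
                                 seg.min_peak_separation_px, seg.smoothing_sigma_px)
    elif seg.method == "import":
        if seg.mask_path is None:
            raise ValueError("segment.mask_path is required for method 'import'")
        mask = import_mask(seg.mask_path, movie.shape[2:])
    else:  # polygon-file
        if seg.polygon_path is None:
            raise ValueError("segment.polygon_path is required for method 'polygon-file'")
        vertices = np.loadtxt(seg.polygon_path, delimiter=",", ndmin=2)
        mask = polygon_to_mask(vertices, movie.shape[2:])
    export_mask(mask, out / "mask.tif")
    meta.update("segment", {
        "method": seg.method, "intensity_threshold": seg.intensity_threshold,
        "min_area_px": seg.min_area_px,
        "min_peak_separation_px": seg.min_peak_separation_px,
        "n_cells": mask.n_cells,
    })
    logger.info("[segment] %d cell(s)", mask.n_cells)
    return mask
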