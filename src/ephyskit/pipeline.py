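"""End-to-end orchestration: one call from a recording (or spike table) to a
JSON-ready report of every biomarker the analysis modules compute.

Reports are plain dicts of floats/ints/strings, deterministic given the
inputs, and every number in them is reproducible by calling the underlying
module operations directly. Module errors propagate wrapped with the stage
that raised them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import read_recording, read_spike_table
from .mea import (
    NETWORK_ELECTRODES,
    SpikeRaster,
    burst_metrics,
    detect_network_bursts,
    population_rate,
    select_top_electrodes,
    summarize_activity_scan,
)
from .recording import EEG, TimeSeriesRecording
from .sleep import score_recording, summarize_hypnogram
from .spectral import average_psd, recording_band_powers
from .spikes import detect_spikes, group_spike_trains, summarize_spiking

__all__ = ["PipelineError", "run_eeg_pipeline", "run_mea_pipeline", "write_report"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _stage(name: str):
    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"[{name}] {exc}") from exc
            return False

    return _ctx()


def run_eeg_pipeline(
    recording: TimeSeriesRecording | str | Path,
    config: AnalysisConfig | None = None,
) -> dict:
    """PSD, band powers, spike summary and sleep summary for one recording.

    ``recording`` may be a loaded `TimeSeriesRecording` or a path to an
    EDF/CSV file.
    """
    cfg = config or AnalysisConfig()
    if not isinstance(recording, TimeSeriesRecording):
        with _stage("load"):
            recording = read_recording(recording)

    report: dict = {"duration_s": recording.duration, "config_version": cfg.config_version}

    with _stage("psd"):
        spec = average_psd(
            recording, epoch_length=cfg.psd_epoch_s, artifact_params=cfg.artifact,
            bin_hz=cfg.psd_bin_hz,
        )
        report["psd"] = {
            "frequency_hz": [round(f, 6) for f in spec.frequencies],
            "power_uV2_per_hz": list(spec.power),
            "bin_hz": cfg.psd_bin_hz,
        }

    with _stage("band_powers"):
        report["band_powers"] = recording_band_powers(
            recording, cfg.bands, artifact_params=cfg.artifact,
            epoch_length=cfg.band_epoch_s,
        )

    with _stage("spikes"):
        eeg = recording.require(EEG)
        events = detect_spikes(eeg.samples, eeg.sampling_rate, cfg.spikes)
        trains = group_spike_trains(events, cfg.spikes)
        s = summarize_spiking(trains, events, recording.duration)
        report["spiking"] = {
            "spike_count": s.spike_count,
            "train_count": s.train_count,
            "total_train_duration_s": s.total_train_duration,
            "trains_per_24h": s.trains_per_24h,
            "train_duration_per_24h_s": s.train_duration_per_24h,
        }

    with _stage("sleep"):
        hyp = score_recording(
            recording, anchors=cfg.anchors, artifact_params=cfg.artifact,
            bands=cfg.bands,
        )
        summary = summarize_hypnogram(hyp)
        report["sleep"] = {
            "percent": summary.percent,
            "scored_hours": summary.scored_hours,
            "artifact_fraction": summary.artifact_fraction,
        }
    return report


def run_mea_pipeline(
    raster: SpikeRaster | str | Path,
    config: AnalysisConfig | None = None,
    metadata: str | Path | None = None,
) -> dict:
    """Activity scan, electrode selection (full-chip input) and burst metrics."""
    cfg = config or AnalysisConfig()
    if not isinstance(raster, SpikeRaster):
        with _stage("load"):
            raster = read_spike_table(raster, metadata)

    report: dict = {"n_events": raster.n_events, "duration_s": raster.duration}
    if raster.n_events == 0:
        report.update(
            {"n_bursts": 0, "mean_ibi_s": None, "mean_burst_duration_s": None,
             "mean_spikes_per_burst": None, "warning": "empty spike table"}
        )
        return report

    with _stage("activity_scan"):
        n_active = int(np.unique(raster.electrode_ids).size)
        report["n_active_electrodes"] = n_active
        if n_active > NETWORK_ELECTRODES:
            scan = summarize_activity_scan(raster, raster.duration)
            selected = select_top_electrodes(scan)
            keep = np.isin(raster.electrode_ids, selected)
            raster = SpikeRaster(
                electrode_ids=raster.electrode_ids[keep],
                spike_times=raster.spike_times[keep],
                duration=raster.duration,
                n_electrodes_total=raster.n_electrodes_total,
                selected_electrodes=selected,
            )
            report["n_selected_electrodes"] = int(selected.size)

    with _stage("bursts"):
        rate = population_rate(raster, cfg.bursts)
        bursts = detect_network_bursts(rate, raster, cfg.bursts)
        m = burst_metrics(bursts, raster.duration)
        report.update(
            {
                "n_bursts": m.n_bursts,
                "mean_ibi_s": m.mean_ibi,
                "mean_burst_duration_s": m.mean_burst_duration,
                "mean_spikes_per_burst": m.mean_spikes_per_burst,
                "bursts": [
                    {
                        "peak_s": b.peak_time,
                        "start_s": b.start,
                        "end_s": b.end,
                        "duration_s": b.duration,
                        "n_spikes": b.spike_count,
                        "n_electrodes": b.electrode_count,
                    }
                    for b in bursts
                ],
            }
        )
    if metadata is not None:
        meta = json.loads(Path(metadata).read_text())
        for key in ("div", "genotype"):
            if key in meta:
                report[key] = meta[key]
    return report


def write_report(report: dict, out_dir: str | Path, name: str = "report") -> Path:
    """Write a report dict as JSON (tables also land as tidy CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / f"{name}.json"
    path.write_text(json.dumps(report, indent=2, default=float) + "\n")
    if "psd" in report:
        pd.DataFrame(
            {
                "frequency_hz": report["psd"]["frequency_hz"],
                "power": report["psd"]["power_uV2_per_hz"],
            }
        ).to_csv(out / f"{name}_psd.csv", index=False)
    if "bursts" in report:
        pd.DataFrame(report["bursts"]).to_csv(out / f"{name}_bursts.csv", index=False)
    return path
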