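"""File I/O: EDF and CSV telemetry recordings, MEA spike tables, reports.

EDF (European Data Format) files are read through MNE. No EDF writer is
available as a library dependency, so a minimal EDF+ compatible writer
(ASCII header, int16 records, one-second data records) is implemented here;
it supports integer sampling rates and whole-second durations, which covers
telemetry exports and the synthetic generators. A plain CSV fallback
(time_s, eeg_uV, emg_uV, activity at a single rate) is provided for both
directions. MEA spike data load from two-column CSV/TSV tables or HDF5.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mea import SpikeRaster
from .recording import ACTIVITY, EEG, EMG, Channel, TimeSeriesRecording

__all__ = [
    "read_edf",
    "write_edf",
    "read_csv_recording",
    "write_csv_recording",
    "read_recording",
    "read_spike_table",
]

#: Default mapping from EDF label substrings (upper-cased) to channel roles.
DEFAULT_CHANNEL_MAP = {"EEG": EEG, "EMG": EMG, "ACTIVITY": ACTIVITY, "ACC": ACTIVITY}


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def _fmt8(x: float) -> str:
    for fmt in ("%.8g", "%.6g", "%.4g", "%.2g"):
        s = fmt % x
        if len(s) <= 8:
            return s
    return s[:8]


def write_edf(path: str | Path, recording: TimeSeriesRecording) -> None:
    """Write a recording as 16-bit EDF with one-second data records.

    Sampling rates must be integer Hz; the recording is truncated to whole
    seconds. Physical ranges are per-channel data extrema; EEG/EMG carry a
    "uV" physical dimension.
    """
    path = Path(path)
    n_records = int(np.floor(recording.duration))
    if n_records < 1:
        raise ValueError("recording must span at least 1 s for EDF export")
    chans = recording.channels
    for ch in chans:
        if abs(ch.sampling_rate - round(ch.sampling_rate)) > 1e-9:
            raise ValueError(
                f"EDF writer requires integer sampling rates; {ch.label} has "
                f"{ch.sampling_rate}"
            )

    spr = [int(round(ch.sampling_rate)) for ch in chans]  # samples per record
    phys_min, phys_max, scaled = [], [], []
    dig_min, dig_max = -32768, 32767
    for ch, n in zip(chans, spr):
        x = ch.samples[: n_records * n]
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            hi = lo + 1.0
        # physical range as written (8-char ASCII) must match the scaling
        lo, hi = float(_fmt8(lo)), float(_fmt8(hi))
        if hi <= lo:
            hi = lo + 1.0
        gain = (dig_max - dig_min) / (hi - lo)
        d = np.round((x - lo) * gain + dig_min).astype("<i2")
        phys_min.append(lo)
        phys_max.append(hi)
        scaled.append(d.reshape(n_records, n))

    ns = len(chans)
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (ns + 1)), 8),
            _pad("EDF+C", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    dims = ["uV" if ch.label in (EEG, EMG) else "" for ch in chans]
    fields = [
        [_pad(ch.label, 16) for ch in chans],
        [_pad("", 80)] * ns,
        [_pad(d, 8) for d in dims],
        [_pad(_fmt8(v), 8) for v in phys_min],
        [_pad(_fmt8(v), 8) for v in phys_max],
        [_pad(str(dig_min), 8)] * ns,
        [_pad(str(dig_max), 8)] * ns,
        [_pad("", 80)] * ns,
        [_pad(str(n), 8) for n in spr],
        [_pad("", 32)] * ns,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in fields:
            fh.write(b"".join(group))
        for r in range(n_records):
            for d in scaled:
                fh.write(d[r].tobytes())


def read_edf(
    path: str | Path,
    channel_map: dict[str, str] | None = None,
) -> TimeSeriesRecording:
    """Read an EDF recording via MNE, mapping labels to EEG/EMG/ACTIVITY.

    ``channel_map`` maps EDF label substrings (case-insensitive) to channel
    roles; unmatched channels are dropped. MNE resamples lower-rate channels
    to the common rate on read, so all returned channels share one sampling
    rate. Physical values declared in µV are returned in µV.
    """
    import mne

    channel_map = channel_map or DEFAULT_CHANNEL_MAP
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    orig_units = getattr(raw, "_orig_units", {}) or {}

    channels = []
    for name in raw.ch_names:
        role = None
        for key, r in channel_map.items():
            if key.upper() in name.upper():
                role = r
                break
        if role is None:
            continue
        data = raw.get_data(picks=[name])[0]
        unit = orig_units.get(name, "")
        if unit in ("uV", "µV"):  # MNE rescaled to volts
            data = data * 1e6
        channels.append(Channel(role, data, fs))
    if not channels:
        raise ValueError(f"no mappable channels found in {path}")
    return TimeSeriesRecording(channels)


def write_csv_recording(path: str | Path, recording: TimeSeriesRecording) -> None:
    """CSV fallback: time_s, eeg_uV, emg_uV, activity at the EEG rate.

    The activity channel is held (zero-order) onto the EEG time grid when
    its native rate differs.
    """
    eeg = recording.require(EEG)
    fs = eeg.sampling_rate
    n = eeg.samples.size
    cols = {"time_s": np.arange(n) / fs, "eeg_uV": eeg.samples}
    emg = recording.get(EMG)
    if emg is not None:
        cols["emg_uV"] = emg.samples[:n]
    act = recording.get(ACTIVITY)
    if act is not None:
        idx = np.minimum(
            (np.arange(n) / fs * act.sampling_rate).astype(int),
            act.samples.size - 1,
        )
        cols["activity"] = act.samples[idx]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_csv_recording(path: str | Path) -> TimeSeriesRecording:
    """Read the CSV fallback format; rate inferred from the time column."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns or "eeg_uV" not in df.columns:
        raise ValueError("CSV recording needs at least time_s and eeg_uV columns")
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError("CSV recording too short")
    fs = float(np.round(1.0 / np.median(np.diff(t)), 3))
    channels = [Channel(EEG, df["eeg_uV"].to_numpy(), fs)]
    if "emg_uV" in df.columns:
        channels.append(Channel(EMG, df["emg_uV"].to_numpy(), fs))
    if "activity" in df.columns:
        channels.append(Channel(ACTIVITY, df["activity"].to_numpy(), fs))
    return TimeSeriesRecording(channels)


def read_recording(path: str | Path, channel_map: dict[str, str] | None = None
                   ) -> TimeSeriesRecording:
    """Dispatch on extension: .edf via MNE, anything else as CSV."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path, channel_map)
    return read_csv_recording(path)


def read_spike_table(
    path: str | Path,
    metadata: str | Path | None = None,
) -> SpikeRaster:
    """Load an MEA spike raster from CSV/TSV or HDF5.

    Tables need columns ``electrode_id`` and ``spike_time_s`` (``spike_time``
    accepted); HDF5 files need datasets of the same names. Optional JSON
    metadata supplies ``n_electrodes`` and ``duration_s``; otherwise they
    default to the chip capacity and the last spike time.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as fh:
            ids = np.asarray(fh["electrode_id"])
            key = "spike_time_s" if "spike_time_s" in fh else "spike_time"
            times = np.asarray(fh[key])
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep)
        if "spike_time_s" not in df.columns and "spike_time" in df.columns:
            df = df.rename(columns={"spike_time": "spike_time_s"})
        ids = df["electrode_id"].to_numpy()
        times = df["spike_time_s"].to_numpy()

    meta = {}
    if metadata is not None:
        meta = json.loads(Path(metadata).read_text())
    duration = float(meta.get("duration_s", times.max() if times.size else 0.0))
    n_total = int(meta.get("n_electrodes", SpikeRaster.__dataclass_fields__[
        "n_electrodes_total"].default))
    return SpikeRaster(
        electrode_ids=ids, spike_times=times, duration=duration,
        n_electrodes_total=max(n_total, int(ids.max()) + 1 if ids.size else 1),
    )
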