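"""Multichannel telemetry recordings, epoch grids, and artifact flagging.

A telemetry recording carries EEG and EMG sampled at 500 Hz (band-passed
0.1–100 Hz upstream by the acquisition hardware) plus an accelerometer-derived
activity channel at 200 Hz. All EEG/EMG samples are stored in microvolts;
activity is in arbitrary integrated-accelerometer units.

Analysis proceeds on contiguous, non-overlapping, half-open epochs
``[t, t + L)``: 30-s epochs for spectral estimation and 10-s epochs for band
averaging and sleep staging. Epochs whose peak absolute (mean-removed)
amplitude reaches 0.2 mV on EEG or 1 mV on EMG are flagged as artifact and
excluded from spectral averaging and staging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Channel",
    "TimeSeriesRecording",
    "EpochGrid",
    "ArtifactParams",
    "RecordingTooShortError",
    "segment_epochs",
    "flag_artifacts",
]

logger = logging.getLogger(__name__)

EEG = "EEG"
EMG = "EMG"
ACTIVITY = "ACTIVITY"

#: Default sampling rates by channel role (Hz).
DEFAULT_RATES = {EEG: 500.0, EMG: 500.0, ACTIVITY: 200.0}


class RecordingTooShortError(ValueError):
    """Recording is shorter than a single analysis epoch."""


@dataclass
class Channel:
    """One recorded signal.

    Parameters
    ----------
    label : str
        Channel role: ``"EEG"``, ``"EMG"`` or ``"ACTIVITY"``.
    samples : ndarray
        Signal samples; µV for EEG/EMG, arbitrary units for activity.
    sampling_rate : float
        Sampling rate in Hz; must be positive.
    """

    label: str
    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate <= 0:
            raise ValueError(
                f"channel {self.label!r}: sampling_rate must be > 0, "
                f"got {self.sampling_rate}"
            )

    @property
    def duration(self) -> float:
        """Channel duration in seconds."""
        return self.samples.size / self.sampling_rate


@dataclass
class TimeSeriesRecording:
    """A multichannel recording with per-channel sampling rates.

    Channel durations must agree within one sample of each other; the
    recording duration is taken from the first channel.
    """

    channels: list[Channel]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("recording must contain at least one channel")
        d0 = self.channels[0].duration
        for ch in self.channels:
            if abs(ch.duration - d0) > 1.0 / ch.sampling_rate:
                raise ValueError(
                    f"channel {ch.label!r} duration {ch.duration:.3f} s "
                    f"disagrees with {d0:.3f} s by more than one sample"
                )

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.channels[0].duration

    def get(self, label: str) -> Channel | None:
        """Return the first channel with ``label``, or None."""
        for ch in self.channels:
            if ch.label == label:
                return ch
        return None

    def require(self, label: str) -> Channel:
        """Return the channel with ``label`` or raise ``KeyError``."""
        ch = self.get(label)
        if ch is None:
            raise KeyError(f"recording has no {label!r} channel")
        return ch

    def epoch_samples(self, label: str, start: float, length: float) -> np.ndarray:
        """Samples of channel ``label`` in the half-open window [start, start+length).

        ``start`` is relative to the beginning of the recording. A sample at
        the window boundary belongs to the later epoch.
        """
        ch = self.require(label)
        i0 = int(round(start * ch.sampling_rate))
        i1 = i0 + int(round(length * ch.sampling_rate))
        return ch.samples[i0:i1]


@dataclass
class EpochGrid:
    """Contiguous half-open epochs covering a recording.

    ``artifact_mask[i]`` is True when epoch ``i`` must be excluded from
    spectral averaging and sleep staging.
    """

    epoch_length: float
    epoch_starts: np.ndarray
    artifact_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.epoch_starts = np.asarray(self.epoch_starts, dtype=np.float64)
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.epoch_starts.size, dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.size != self.epoch_starts.size:
            raise ValueError("artifact_mask length must equal epoch count")

    @property
    def n_epochs(self) -> int:
        return self.epoch_starts.size


@dataclass
class ArtifactParams:
    """Amplitude limits (in mV) above which an epoch is artifact."""

    eeg_limit_mv: float = 0.2
    emg_limit_mv: float = 1.0

    def __post_init__(self) -> None:
        if self.eeg_limit_mv <= 0 or self.emg_limit_mv <= 0:
            raise ValueError("artifact limits must be > 0")


def segment_epochs(recording: TimeSeriesRecording, epoch_length: float) -> EpochGrid:
    """Divide a recording into contiguous half-open epochs.

    A trailing partial epoch is discarded. The artifact mask is initialized
    all-False.

    Raises
    ------
    RecordingTooShortError
        If the recording is shorter than one epoch.
    """
    if epoch_length <= 0:
        raise ValueError(f"epoch_length must be > 0, got {epoch_length}")
    n = int(np.floor(recording.duration / epoch_length + 1e-9))
    if n < 1:
        raise RecordingTooShortError(
            f"recording of {recording.duration:.1f} s is too short for a "
            f"single {epoch_length:.0f}-s epoch"
        )
    starts = np.arange(n, dtype=np.float64) * epoch_length
    return EpochGrid(epoch_length=epoch_length, epoch_starts=starts)


def flag_artifacts(
    recording: TimeSeriesRecording,
    grid: EpochGrid,
    params: ArtifactParams | None = None,
) -> EpochGrid:
    """Flag epochs whose mean-removed amplitude reaches the artifact limits.

    An epoch is flagged when ``max|EEG - mean|`` is at or above the EEG limit,
    or — when an EMG channel is present — ``max|EMG - mean|`` is at or above
    the EMG limit. The comparison is inclusive (``>=``) at the limit. Flags
    are OR-ed into any existing mask; a new grid is returned.
    """
    params = params or ArtifactParams()
    recording.require(EEG)
    has_emg = recording.get(EMG) is not None
    if not has_emg:
        logger.info("no EMG channel: EMG artifact rule skipped")

    eeg_limit_uv = params.eeg_limit_mv * 1000.0
    emg_limit_uv = params.emg_limit_mv * 1000.0

    mask = grid.artifact_mask.copy()
    for i, t in enumerate(grid.epoch_starts):
        x = recording.epoch_samples(EEG, t, grid.epoch_length)
        flagged = x.size > 0 and np.max(np.abs(x - x.mean())) >= eeg_limit_uv
        if not flagged and has_emg:
            y = recording.epoch_samples(EMG, t, grid.epoch_length)
            flagged = y.size > 0 and np.max(np.abs(y - y.mean())) >= emg_limit_uv
        mask[i] |= flagged
    return replace(grid, artifact_mask=mask)
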