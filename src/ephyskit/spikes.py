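"""Epileptiform spike detection and spike-train chaining for telemetry EEG.

A spike is a maximal contiguous run of samples whose rectified, mean-removed
amplitude reaches an absolute threshold (default 200 µV) and whose duration
lies within printed bounds (1–200 ms). Spikes chain into trains left to
right: consecutive spikes join when their peak-to-peak interval lies in
[0.05, 0.5] s (inclusive at both ends); a closed chain is a spike train when
it holds at least 3 spikes and spans at least 1 s from first to last peak.
Spike-train count and total duration are the hyperexcitability biomarkers
summarized per recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpikeDetectionParams",
    "SpikeEvent",
    "SpikeTrain",
    "SpikeSummary",
    "detect_spikes",
    "group_spike_trains",
    "summarize_spiking",
]


@dataclass(frozen=True)
class SpikeDetectionParams:
    """Printed spike and spike-train detection rules.

    threshold is on |signal - mean| in µV; durations in ms; intervals and the
    minimum train span in seconds.
    """

    threshold: float = 200.0
    min_spike_dur: float = 1.0
    max_spike_dur: float = 200.0
    isi_min: float = 0.05
    isi_max: float = 0.5
    min_spikes_per_train: int = 3
    min_train_time: float = 1.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if not self.min_spike_dur < self.max_spike_dur:
            raise ValueError("need min_spike_dur < max_spike_dur")
        if not self.isi_min < self.isi_max:
            raise ValueError("need isi_min < isi_max")
        if self.min_spikes_per_train < 2:
            raise ValueError("min_spikes_per_train must be >= 2")


@dataclass(frozen=True)
class SpikeEvent:
    """One suprathreshold spike.

    ``peak_amplitude`` is signed (µV, after mean removal); ``peak_time`` is
    the time of the extremum; ``onset`` the first suprathreshold sample.
    """

    onset: float
    duration: float  # ms
    peak_amplitude: float
    peak_time: float


@dataclass(frozen=True)
class SpikeTrain:
    """A chained run of spikes satisfying the count/interval/span rules.

    ``start``/``end`` are the first and last spike peak times, so
    ``duration`` equals the span checked against the minimum train time.
    """

    spikes: tuple[SpikeEvent, ...]
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def count(self) -> int:
        return len(self.spikes)


@dataclass
class SpikeSummary:
    """Recording-level spiking summary; per-24-h rates when duration allows."""

    train_count: int
    total_train_duration: float
    spike_count: int
    recording_duration: float
    trains_per_24h: float | None = None
    train_duration_per_24h: float | None = None


def detect_spikes(
    eeg: np.ndarray,
    sampling_rate: float,
    params: SpikeDetectionParams | None = None,
) -> list[SpikeEvent]:
    """Detect suprathreshold spike events in one EEG trace.

    The trace mean is removed first, so detection is invariant to DC offset;
    "absolute threshold" applies to the rectified signal, catching both
    polarities. Runs clipped by the recording edge are kept when their
    observed duration already satisfies the minimum.
    """
    params = params or SpikeDetectionParams()
    x = np.asarray(eeg, dtype=np.float64)
    bad = ~np.isfinite(x)
    if bad.any():
        raise ValueError(f"non-finite sample at index {int(np.argmax(bad))}")
    if sampling_rate < 500:
        warnings.warn(
            f"sampling rate {sampling_rate} Hz is below the recommended 500 Hz",
            stacklevel=2,
        )
    x = x - x.mean()
    above = np.abs(x) >= params.threshold
    if not above.any():
        return []
    # run boundaries of the suprathreshold mask
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.insert(starts, 0, 0)
    if above[-1]:
        ends = np.append(ends, above.size)

    events: list[SpikeEvent] = []
    for i0, i1 in zip(starts, ends):
        dur_ms = (i1 - i0) / sampling_rate * 1000.0
        if not (params.min_spike_dur <= dur_ms <= params.max_spike_dur):
            continue
        seg = x[i0:i1]
        pk = i0 + int(np.argmax(np.abs(seg)))
        events.append(
            SpikeEvent(
                onset=i0 / sampling_rate,
                duration=dur_ms,
                peak_amplitude=float(x[pk]),
                peak_time=pk / sampling_rate,
            )
        )
    return events


def group_spike_trains(
    spikes: list[SpikeEvent],
    params: SpikeDetectionParams | None = None,
) -> list[SpikeTrain]:
    """Chain time-ordered spikes into trains, greedily left to right.

    A spike joins the current chain iff its peak-to-peak interval to the
    previous spike lies in [isi_min, isi_max], inclusive at both ends; any
    interval outside the window closes the chain and opens a new one. A
    closed chain is emitted as a `SpikeTrain` iff it holds at least
    ``min_spikes_per_train`` spikes and spans at least ``min_train_time``
    seconds from first to last peak.
    """
    params = params or SpikeDetectionParams()
    eps = 1e-9  # keep the inclusive boundaries inclusive under float error
    trains: list[SpikeTrain] = []
    chain: list[SpikeEvent] = []

    def close() -> None:
        if (
            len(chain) >= params.min_spikes_per_train
            and chain[-1].peak_time - chain[0].peak_time
            >= params.min_train_time - eps
        ):
            trains.append(
                SpikeTrain(
                    spikes=tuple(chain),
                    start=chain[0].peak_time,
                    end=chain[-1].peak_time,
                )
            )

    for sp in spikes:
        if chain:
            gap = sp.peak_time - chain[-1].peak_time
            if gap < 0:
                raise ValueError("spikes must be time-ordered")
            if not (params.isi_min - eps <= gap <= params.isi_max + eps):
                close()
                chain = []
        chain.append(sp)
    if chain:
        close()
    return trains


def summarize_spiking(
    trains: list[SpikeTrain],
    spikes: list[SpikeEvent],
    recording_duration: float,
) -> SpikeSummary:
    """Counts and total train duration; per-24-h rates for >= 24 h recordings."""
    total = float(sum(t.duration for t in trains))
    summary = SpikeSummary(
        train_count=len(trains),
        total_train_duration=total,
        spike_count=len(spikes),
        recording_duration=recording_duration,
    )
    if recording_duration >= 24 * 3600:
        days = recording_duration / (24 * 3600)
        summary.trains_per_24h = len(trains) / days
        summary.train_duration_per_24h = total / days
    return summary
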