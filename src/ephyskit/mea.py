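"""HD-MEA network analysis: activity scans, electrode selection, and
network-burst detection on the Gaussian-smoothed population firing rate.

The workflow mirrors a high-density chip session: a full-chip activity scan
rates each of the 26,400 electrodes from a 30-s window, the 1024 most active
electrodes are recorded simultaneously for 300 s, and synchronized network
bursts appear as peaks of the pooled, Gaussian-convolved spike-time
histogram. The convolution parameters (10-ms bins, 100-ms kernel sd) and the
mean + k·sd peak threshold are configurable; detection pools all selected
electrodes rather than bursting per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "SpikeRaster",
    "ActivityScanResult",
    "BurstDetectionParams",
    "NetworkBurst",
    "BurstMetrics",
    "RateSeries",
    "summarize_activity_scan",
    "select_top_electrodes",
    "population_rate",
    "detect_network_bursts",
    "burst_metrics",
]

CHIP_ELECTRODES = 26_400
NETWORK_ELECTRODES = 1_024


@dataclass
class SpikeRaster:
    """Electrode x spike-time events from an activity scan or network assay."""

    electrode_ids: np.ndarray
    spike_times: np.ndarray
    duration: float
    n_electrodes_total: int = CHIP_ELECTRODES
    selected_electrodes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.electrode_ids = np.asarray(self.electrode_ids, dtype=np.int64)
        self.spike_times = np.asarray(self.spike_times, dtype=np.float64)
        if self.electrode_ids.size != self.spike_times.size:
            raise ValueError("electrode_ids and spike_times must align")
        if self.spike_times.size:
            if self.spike_times.min() < 0 or self.spike_times.max() > self.duration:
                raise ValueError("spike times must lie within [0, duration]")
            if self.electrode_ids.min() < 0 or (
                self.electrode_ids.max() >= self.n_electrodes_total
            ):
                raise ValueError("electrode ids must be < n_electrodes_total")

    @property
    def n_events(self) -> int:
        return self.spike_times.size


@dataclass
class ActivityScanResult:
    """Per-electrode firing rate (Hz) over the scan window."""

    rates: np.ndarray
    scan_duration: float


@dataclass(frozen=True)
class BurstDetectionParams:
    """Population-rate smoothing and burst-peak rules.

    The peak threshold is mean + ``threshold_k`` standard deviations of the
    smoothed rate, with a floor of ``min_participating_spikes`` raw spikes
    per burst; burst edges sit where the rate falls below
    ``boundary_fraction`` of the peak height or below the threshold,
    whichever is crossed first walking away from the peak.
    """

    bin_width: float = 0.01
    gaussian_sigma: float = 0.1
    threshold_k: float = 5.0
    min_participating_spikes: int = 50
    min_peak_separation: float = 0.2
    boundary_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.gaussian_sigma < self.bin_width:
            raise ValueError("gaussian_sigma must be >= bin_width")
        if not (0 < self.boundary_fraction < 1):
            raise ValueError("boundary_fraction must be in (0, 1)")


@dataclass(frozen=True)
class NetworkBurst:
    """One detected population burst."""

    peak_time: float
    start: float
    end: float
    spike_count: int
    electrode_count: int
    peak_rate: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class BurstMetrics:
    """Per-recording burst summary; IBI is peak-to-peak and undefined
    (None) with fewer than two bursts."""

    n_bursts: int
    mean_ibi: float | None
    mean_burst_duration: float | None
    mean_spikes_per_burst: float | None


@dataclass
class RateSeries:
    """Smoothed population firing rate (spikes/s) on a padded time grid."""

    times: np.ndarray
    rate: np.ndarray
    bin_width: float

    def integral(self) -> float:
        return float(self.rate.sum() * self.bin_width)


def summarize_activity_scan(
    raster: SpikeRaster, scan_duration: float = 30.0
) -> ActivityScanResult:
    """Per-electrode firing rate: spike count / scan duration.

    Electrodes without events are present at rate 0, up to the raster's
    total electrode count.
    """
    if scan_duration <= 0:
        raise ValueError("scan_duration must be > 0")
    counts = np.bincount(raster.electrode_ids, minlength=raster.n_electrodes_total)
    return ActivityScanResult(
        rates=counts / scan_duration, scan_duration=scan_duration
    )


def select_top_electrodes(
    scan: ActivityScanResult, n: int = NETWORK_ELECTRODES
) -> np.ndarray:
    """Ids of the n highest-rate electrodes, ascending-id at rate ties.

    Returned sorted by electrode id; exactly n electrodes.
    """
    rates = scan.rates
    if rates.size < n:
        raise ValueError(
            f"only {rates.size} electrodes scanned; cannot select {n}"
        )
    order = np.lexsort((np.arange(rates.size), -rates))
    return np.sort(order[:n])


def population_rate(
    raster: SpikeRaster, params: BurstDetectionParams | None = None
) -> RateSeries:
    """Pooled spike-time histogram convolved with a unit-area Gaussian.

    The grid is padded by 4 kernel sd on both sides so the convolution
    conserves the total spike count; the kernel is truncated at ±4σ and
    renormalized.
    """
    params = params or BurstDetectionParams()
    if raster.duration < 10 * params.gaussian_sigma:
        raise ValueError("raster duration must be >= 10 gaussian_sigma")
    bw, sigma = params.bin_width, params.gaussian_sigma
    pad = int(np.ceil(4 * sigma / bw))
    nbins = int(np.ceil(raster.duration / bw)) + 2 * pad
    edges = (np.arange(nbins + 1) - pad) * bw
    counts, _ = np.histogram(raster.spike_times, bins=edges)

    half = np.arange(-pad, pad + 1) * bw
    kernel = np.exp(-0.5 * (half / sigma) ** 2)
    kernel /= kernel.sum()

    rate = np.convolve(counts, kernel, mode="same") / bw
    centers = (edges[:-1] + edges[1:]) / 2
    return RateSeries(times=centers, rate=rate, bin_width=bw)


def _edges_for_peak(
    rate: np.ndarray, peak_idx: int, level: float
) -> tuple[int, int]:
    # walk outward from the peak to the first bin below the edge level
    i = peak_idx
    while i > 0 and rate[i - 1] >= level:
        i -= 1
    j = peak_idx
    while j < rate.size - 1 and rate[j + 1] >= level:
        j += 1
    return i, j


def detect_network_bursts(
    rate_series: RateSeries,
    raster: SpikeRaster,
    params: BurstDetectionParams | None = None,
) -> list[NetworkBurst]:
    """Network bursts as suprathreshold local maxima of the smoothed rate.

    Peaks must clear mean + k·sd of the rate series and be separated by at
    least ``min_peak_separation``. Each burst extends to where the rate
    falls below ``boundary_fraction`` x peak height or below the threshold
    (whichever edge is nearer the peak); overlapping bursts merge keeping
    the higher peak. Spike and electrode counts are tallied from raw events
    within [start, end]; bursts with fewer than
    ``min_participating_spikes`` spikes are discarded.
    """
    params = params or BurstDetectionParams()
    rate, times = rate_series.rate, rate_series.times
    threshold = float(rate.mean() + params.threshold_k * rate.std())
    min_dist = max(1, int(round(params.min_peak_separation / rate_series.bin_width)))
    peaks, _ = sp_signal.find_peaks(rate, height=threshold, distance=min_dist)
    if peaks.size == 0:
        return []

    # higher peaks claim their extent first; lower overlapping peaks merge away
    order = peaks[np.argsort(rate[peaks])[::-1]]
    claimed: list[tuple[int, int, int]] = []
    for pk in order:
        level = max(params.boundary_fraction * rate[pk], threshold)
        i, j = _edges_for_peak(rate, pk, level)
        if any(i <= b and a <= j for a, b, _ in claimed):
            continue
        claimed.append((i, j, pk))

    t = raster.spike_times
    ids = raster.electrode_ids
    bursts = []
    for i, j, pk in sorted(claimed, key=lambda c: c[2]):
        start, end = times[i], times[j]
        in_burst = (t >= start) & (t <= end)
        n_spikes = int(in_burst.sum())
        if n_spikes < params.min_participating_spikes:
            continue
        bursts.append(
            NetworkBurst(
                peak_time=float(times[pk]),
                start=float(start),
                end=float(end),
                spike_count=n_spikes,
                electrode_count=int(np.unique(ids[in_burst]).size),
                peak_rate=float(rate[pk]),
            )
        )
    return bursts


def burst_metrics(bursts: list[NetworkBurst], duration: float = 300.0) -> BurstMetrics:
    """Burst count, mean peak-to-peak IBI, mean duration, mean spikes/burst."""
    n = len(bursts)
    if n == 0:
        return BurstMetrics(0, None, None, None)
    peaks = np.array([b.peak_time for b in bursts])
    ibi = float(np.diff(np.sort(peaks)).mean()) if n >= 2 else None
    return BurstMetrics(
        n_bursts=n,
        mean_ibi=ibi,
        mean_burst_duration=float(np.mean([b.duration for b in bursts])),
        mean_spikes_per_burst=float(np.mean([b.spike_count for b in bursts])),
    )
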