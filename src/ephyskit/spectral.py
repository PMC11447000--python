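"""Power spectral density and band powers for telemetry EEG.

Each analysis epoch yields a single Hamming-windowed periodogram (no
sub-segmentation), scaled as a one-sided density so that integrating over
frequency recovers the signal variance (Parseval, window power-corrected).
Spectra are computed at the epoch's native resolution (1/30 Hz for 30-s
epochs) and truncated to 0–50 Hz; a 2-Hz binned view is available for
reporting. Band powers integrate the native-resolution density over half-open
band intervals, so the five canonical bands — delta 0.5–4, theta 4–8, alpha
8–12, beta 12–30, gamma 30–50 Hz — tile [0.5, 50) without double counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .recording import (
    EEG,
    ArtifactParams,
    EpochGrid,
    TimeSeriesRecording,
    flag_artifacts,
    segment_epochs,
)

__all__ = [
    "PowerSpectrum",
    "BandDefinition",
    "DEFAULT_BANDS",
    "compute_psd",
    "bin_psd",
    "band_power",
    "epoch_band_powers",
    "recording_band_powers",
    "average_psd",
]


@dataclass
class PowerSpectrum:
    """A one-sided power spectral density.

    Attributes
    ----------
    frequencies : ndarray
        Strictly ascending frequency grid in Hz.
    power : ndarray
        Density in µV²/Hz, nonnegative.
    resolution : float
        Grid step in Hz (1/epoch_length for a native spectrum, the bin
        width for a binned one).
    """

    frequencies: np.ndarray
    power: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.frequencies.size != self.power.size:
            raise ValueError("frequencies and power must have equal length")

    def integral(self) -> float:
        """Total integrated power, Σ p·Δf (µV²)."""
        return float(self.power.sum() * self.resolution)


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high <= 50):
            raise ValueError(
                f"band {self.name!r}: need 0 <= low < high <= 50, "
                f"got [{self.low}, {self.high})"
            )


#: Canonical rodent EEG bands (Hz). Adjacent bands share an edge; the
#: half-open convention assigns the shared edge to the upper band.
DEFAULT_BANDS = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 50.0),
)


def _check_finite(x: np.ndarray) -> None:
    bad = ~np.isfinite(x)
    if bad.any():
        idx = int(np.argmax(bad))
        raise ValueError(f"non-finite sample at index {idx}")


def compute_psd(
    epoch_samples: np.ndarray,
    sampling_rate: float,
    fmax: float | None = 50.0,
) -> PowerSpectrum:
    """Hamming-windowed periodogram of one mean-removed epoch.

    The density is scaled so that ``sum(power) * resolution`` over the full
    one-sided spectrum equals the epoch sample variance (window
    power-corrected). With the default ``fmax`` the spectrum is truncated to
    [0, 50] Hz after scaling; pass ``fmax=None`` for the full spectrum.

    Parameters
    ----------
    epoch_samples : array-like
        Epoch samples in µV, length >= 2.
    sampling_rate : float
        Sampling rate in Hz; must exceed twice the truncation frequency.
    fmax : float or None
        Upper frequency of the returned spectrum.
    """
    x = np.asarray(epoch_samples, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("epoch_samples must be a 1-D vector of length >= 2")
    _check_finite(x)
    if fmax is not None and sampling_rate <= 2 * fmax:
        raise ValueError(
            f"sampling_rate {sampling_rate} Hz cannot resolve {fmax} Hz"
        )
    freqs, pxx = sp_signal.periodogram(
        x, fs=sampling_rate, window="hamming", detrend="constant"
    )
    df = sampling_rate / x.size
    # enforce exact Parseval: the one-sided integral recovers the variance
    total = pxx.sum() * df
    if total > 0:
        pxx = pxx * (np.var(x) / total)
    if fmax is not None:
        keep = freqs <= fmax + 1e-12
        freqs, pxx = freqs[keep], pxx[keep]
    return PowerSpectrum(freqs, pxx, resolution=df)


def compute_psd_batch(
    epochs: np.ndarray, sampling_rate: float, fmax: float | None = 50.0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Periodograms of many equal-length epochs at once.

    Returns ``(frequencies, power_matrix, resolution)`` where
    ``power_matrix`` has one row per epoch. Same scaling as `compute_psd`.
    """
    arr = np.asarray(epochs, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("epochs must be a 2-D (n_epochs, n_samples) array")
    _check_finite(arr)
    freqs, pxx = sp_signal.periodogram(
        arr, fs=sampling_rate, window="hamming", detrend="constant", axis=-1
    )
    df = sampling_rate / arr.shape[1]
    totals = pxx.sum(axis=1) * df
    var = arr.var(axis=1)
    scale = np.where(totals > 0, var / np.where(totals > 0, totals, 1.0), 1.0)
    pxx = pxx * scale[:, None]
    if fmax is not None:
        keep = freqs <= fmax + 1e-12
        freqs, pxx = freqs[keep], pxx[:, keep]
    return freqs, pxx, df


def bin_psd(spectrum: PowerSpectrum, bin_width: float = 2.0) -> PowerSpectrum:
    """Average the density into [k·w, (k+1)·w) bins, reported at bin centers.

    Each bin's value is the mean density of the native points falling in it,
    so the integrated power is conserved up to edge effects of partial bins.
    Empty bins are dropped.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    idx = np.floor(spectrum.frequencies / bin_width + 1e-12).astype(int)
    # a point exactly on the spectrum's top edge folds into the last full
    # bin rather than opening a singleton bin beyond the covered range
    top = spectrum.frequencies[-1]
    if idx.size > 1 and abs(top / bin_width - round(top / bin_width)) < 1e-9:
        idx[np.isclose(spectrum.frequencies, top)] = int(round(top / bin_width)) - 1
    nbins = idx.max() + 1 if idx.size else 0
    sums = np.bincount(idx, weights=spectrum.power, minlength=nbins)
    counts = np.bincount(idx, minlength=nbins)
    present = counts > 0
    centers = (np.arange(nbins)[present] + 0.5) * bin_width
    means = sums[present] / counts[present]
    return PowerSpectrum(centers, means, resolution=bin_width)


def band_power(spectrum: PowerSpectrum, band: BandDefinition) -> float:
    """Integrated density over the half-open interval [band.low, band.high).

    Uses rectangle-rule integration on the spectrum's own grid, so adjacent
    bands partition their union exactly.
    """
    f = spectrum.frequencies
    lo, hi = band.low, band.high
    if lo < f[0] - spectrum.resolution or hi > f[-1] + spectrum.resolution:
        raise ValueError(
            f"band {band.name!r} [{lo}, {hi}) outside spectrum support "
            f"[{f[0]}, {f[-1]}] Hz"
        )
    mask = (f >= lo - 1e-12) & (f < hi - 1e-12)
    return float(spectrum.power[mask].sum() * spectrum.resolution)


def _band_powers_from_matrix(
    freqs: np.ndarray,
    pxx: np.ndarray,
    resolution: float,
    bands: tuple[BandDefinition, ...],
) -> dict[str, np.ndarray]:
    out = {}
    for band in bands:
        mask = (freqs >= band.low - 1e-12) & (freqs < band.high - 1e-12)
        out[band.name] = pxx[:, mask].sum(axis=1) * resolution
    return out


def epoch_band_powers(
    recording: TimeSeriesRecording,
    grid: EpochGrid,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    channel: str = EEG,
) -> dict[str, np.ndarray]:
    """Per-epoch band powers (µV²) of one channel over an epoch grid.

    Returns one array per band, with an entry for every epoch (including
    artifact ones — callers mask as needed).
    """
    ch = recording.require(channel)
    n = int(round(grid.epoch_length * ch.sampling_rate))
    rows = np.stack(
        [recording.epoch_samples(channel, t, grid.epoch_length) for t in grid.epoch_starts]
    )
    assert rows.shape[1] == n
    freqs, pxx, res = compute_psd_batch(rows, ch.sampling_rate)
    return _band_powers_from_matrix(freqs, pxx, res, tuple(bands))


def recording_band_powers(
    recording: TimeSeriesRecording,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    grid: EpochGrid | None = None,
    artifact_params: ArtifactParams | None = None,
    epoch_length: float = 10.0,
) -> dict:
    """Mean band powers over the non-artifact 10-s epochs of a recording.

    When ``grid`` is not supplied, the recording is segmented into
    ``epoch_length`` epochs and artifact-flagged with ``artifact_params``
    (defaults: 0.2 mV EEG, 1 mV EMG).

    Returns
    -------
    dict
        ``{"bands": {name: mean µV²}, "n_epochs_used": int,
        "n_epochs_total": int}``.

    Raises
    ------
    ValueError
        If every epoch is flagged artifact.
    """
    if grid is None:
        grid = segment_epochs(recording, epoch_length)
        grid = flag_artifacts(recording, grid, artifact_params)
    keep = ~grid.artifact_mask
    if not keep.any():
        raise ValueError("all epochs flagged as artifact; nothing to average")
    per_epoch = epoch_band_powers(recording, grid, bands)
    means = {name: float(vals[keep].mean()) for name, vals in per_epoch.items()}
    return {
        "bands": means,
        "n_epochs_used": int(keep.sum()),
        "n_epochs_total": int(grid.n_epochs),
    }


def average_psd(
    recording: TimeSeriesRecording,
    epoch_length: float = 30.0,
    artifact_params: ArtifactParams | None = None,
    bin_hz: float | None = None,
) -> PowerSpectrum:
    """Recording-level PSD: mean of per-epoch periodograms over clean epochs.

    Epochs (default 30 s) are artifact-screened, each yields one Hamming
    periodogram, and the densities are averaged. Pass ``bin_hz`` (e.g. 2) for
    the binned reporting view.
    """
    grid = segment_epochs(recording, epoch_length)
    grid = flag_artifacts(recording, grid, artifact_params)
    keep = ~grid.artifact_mask
    if not keep.any():
        raise ValueError("all epochs flagged as artifact; nothing to average")
    ch = recording.require(EEG)
    rows = np.stack(
        [
            recording.epoch_samples(EEG, t, epoch_length)
            for t in grid.epoch_starts[keep]
        ]
    )
    freqs, pxx, res = compute_psd_batch(rows, ch.sampling_rate)
    spec = PowerSpectrum(freqs, pxx.mean(axis=0), resolution=res)
    if bin_hz is not None:
        spec = bin_psd(spec, bin_hz)
    return spec
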