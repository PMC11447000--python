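"""Ground-truthed synthetic recordings: state-dependent EEG/EMG/activity with
known sleep architecture, planted epileptiform spike trains, and MEA rasters
with planted network bursts.

The sleep generator emits, per 10-s epoch, an EEG that is the sum of a delta
(1.5 Hz) and a theta (6.5 Hz) sinusoid plus broadband Gaussian noise, an EMG
that is white noise scaled by the stage's muscle tone, and an activity trace
at the stage's accelerometer level — all with per-epoch random phases drawn
from a single seeded generator, so identical seeds give bit-identical output.
The default stage signatures keep every clean epoch under the 0.2 mV EEG
artifact limit while separating the four stages at the printed anchors.

Spike plants are biphasic (sharp main lobe, 30%-amplitude undershoot) so the
amplitude detector sees exactly one event per planted spike. MEA rasters are
per-electrode inhomogeneous Poisson processes whose rate is elevated by a
known multiplier inside planted burst windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mea import SpikeRaster
from .recording import ACTIVITY, EEG, EMG, Channel, TimeSeriesRecording
from .sleep import STAGE_ORDER, Hypnogram, Stage

__all__ = [
    "StageSignature",
    "DEFAULT_SIGNATURES",
    "SleepArchitectureSpec",
    "PlantedTrainSpec",
    "RasterSpec",
    "generate_sleep_recording",
    "inject_spike_trains",
    "generate_raster",
    "generate_band_power_cohort",
]

DELTA_HZ = 1.5  # inside the delta band regardless of edge conventions
THETA_HZ = 6.5  # inside 4-8 and 5-9 theta definitions alike


@dataclass(frozen=True)
class StageSignature:
    """Per-stage signal amplitudes: sinusoid/noise sd in µV, activity in
    classifier units."""

    delta_amp: float
    theta_amp: float
    broadband_amp: float
    emg_amp: float
    activity_level: float


#: Default signatures. Chosen so that (a) clean epochs never reach the
#: 200 µV EEG / 1 mV EMG artifact limits and (b) the self-normalized
#: delta/theta:delta/EMG ratios land on the saturated side of the printed
#: anchors for the stage each feature votes for, under roughly balanced
#: stage mixes.
DEFAULT_SIGNATURES: dict[Stage, StageSignature] = {
    Stage.SWS: StageSignature(90.0, 20.0, 15.0, 15.0, 0.0),
    Stage.PARADOXICAL: StageSignature(20.0, 90.0, 15.0, 5.0, 0.0),
    Stage.WAKE: StageSignature(40.0, 40.0, 20.0, 100.0, 0.03),
    Stage.ACTIVE_WAKE: StageSignature(40.0, 50.0, 20.0, 120.0, 0.5),
}

#: A plausible rodent stage-transition matrix (rows/cols in STAGE_ORDER):
#: sticky states with realistic routes (paradoxical entered from SWS,
#: active wake bouts interleaved with quiet wake). Stationary occupancy is
#: sleep-heavy — about 12% active wake, 23% wake, 54% SWS, 11% paradoxical —
#: matching how laboratory mice distribute a 24-h day.
DEFAULT_TRANSITIONS = np.array(
    [
        # AW     W      SWS    P
        [0.60, 0.30, 0.10, 0.00],  # from ACTIVE_WAKE
        [0.15, 0.50, 0.35, 0.00],  # from WAKE
        [0.02, 0.10, 0.78, 0.10],  # from SWS
        [0.05, 0.20, 0.25, 0.50],  # from PARADOXICAL
    ]
)


@dataclass
class SleepArchitectureSpec:
    """Ground-truth sleep architecture and per-stage signal signatures.

    Provide either an explicit ``stage_sequence`` (tiled if shorter than the
    recording) or a first-order Markov ``transition_matrix`` with
    ``initial_stage``.
    """

    epoch_length: float = 10.0
    stage_sequence: list[Stage] | None = None
    transition_matrix: np.ndarray | None = None
    initial_stage: Stage = Stage.WAKE
    signatures: dict[Stage, StageSignature] = field(
        default_factory=lambda: dict(DEFAULT_SIGNATURES)
    )
    noise_sd: float = 5.0
    activity_jitter_sd: float = 0.01
    eeg_rate: float = 500.0
    activity_rate: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage_sequence is None and self.transition_matrix is None:
            self.transition_matrix = DEFAULT_TRANSITIONS
        if self.transition_matrix is not None:
            tm = np.asarray(self.transition_matrix, dtype=np.float64)
            if tm.shape != (4, 4) or not np.allclose(tm.sum(axis=1), 1.0):
                raise ValueError("transition matrix must be 4x4 with rows summing to 1")
            self.transition_matrix = tm


@dataclass
class PlantedTrainSpec:
    """Known spike trains to insert into an EEG trace.

    ``isi`` must lie in the chainable [0.05, 0.5] s window so the plants are
    detectable by design; ``insertion_times`` are first-spike peak times, or
    "uniform" for seeded non-overlapping placement.
    """

    n_trains: int = 10
    spikes_per_train: int = 5
    isi: float = 0.3
    spike_amp: float = 400.0
    spike_dur: float = 10.0  # ms
    insertion_times: list[float] | str = "uniform"
    # undershoot low enough that it stays sub-threshold even when riding on
    # a high-amplitude slow-wave background
    undershoot_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.05 <= self.isi <= 0.5):
            raise ValueError("isi must lie in [0.05, 0.5] s to form chains")

    @property
    def train_span(self) -> float:
        """Peak-to-peak span of one planted train (s)."""
        return (self.spikes_per_train - 1) * self.isi


@dataclass
class RasterSpec:
    """Inhomogeneous-Poisson MEA raster with planted network bursts."""

    n_electrodes: int = 1024
    baseline_rate: float = 0.5
    duration: float = 300.0
    burst_times: list[float] = field(default_factory=list)  # window centers
    burst_duration: float = 0.3
    burst_rate_multiplier: float = 50.0
    n_electrodes_total: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_electrodes < 1:
            raise ValueError("n_electrodes must be >= 1")
        if self.baseline_rate < 0 or self.burst_rate_multiplier < 0:
            raise ValueError("rates must be >= 0")
        for t in self.burst_times:
            if not (0 <= t - self.burst_duration / 2
                    and t + self.burst_duration / 2 <= self.duration):
                raise ValueError(f"burst window at {t} s exceeds the recording")


def _sample_stage_sequence(spec: SleepArchitectureSpec, n_epochs: int,
                           rng: np.random.Generator) -> list[Stage]:
    if spec.stage_sequence is not None:
        seq = []
        for s in spec.stage_sequence:
            stage = Stage(s)
            if stage not in spec.signatures:
                raise ValueError(f"unknown stage label {s!r}")
            seq.append(stage)
        reps = int(np.ceil(n_epochs / len(seq)))
        return (seq * reps)[:n_epochs]
    idx = {s: i for i, s in enumerate(STAGE_ORDER)}
    state = idx[spec.initial_stage]
    out = []
    for _ in range(n_epochs):
        out.append(STAGE_ORDER[state])
        state = rng.choice(4, p=spec.transition_matrix[state])
    return out


def generate_sleep_recording(
    spec: SleepArchitectureSpec, duration: float
) -> tuple[TimeSeriesRecording, Hypnogram]:
    """Synthesize EEG/EMG/activity with a known hypnogram.

    Returns the recording and the ground-truth hypnogram (one label per
    epoch, no probabilities). Identical seeds give bit-identical output.
    """
    L = spec.epoch_length
    n_epochs = int(np.floor(duration / L + 1e-9))
    if n_epochs < 10:
        raise ValueError("duration must cover at least 10 epochs")
    rng = np.random.default_rng(spec.seed)
    stages = _sample_stage_sequence(spec, n_epochs, rng)

    n_eeg = int(round(L * spec.eeg_rate))
    n_act = int(round(L * spec.activity_rate))
    t_eeg = np.arange(n_eeg) / spec.eeg_rate

    eeg = np.empty(n_epochs * n_eeg)
    emg = np.empty(n_epochs * n_eeg)
    act = np.empty(n_epochs * n_act)
    for i, stage in enumerate(stages):
        sig = spec.signatures[stage]
        ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
        noise_sd = float(np.hypot(sig.broadband_amp, spec.noise_sd))
        e = (
            sig.delta_amp * np.sin(2 * np.pi * DELTA_HZ * t_eeg + ph1)
            + sig.theta_amp * np.sin(2 * np.pi * THETA_HZ * t_eeg + ph2)
            + rng.normal(0.0, noise_sd, n_eeg)
        )
        m = rng.normal(0.0, float(np.hypot(sig.emg_amp, spec.noise_sd)), n_eeg)
        a = np.clip(
            sig.activity_level + rng.normal(0.0, spec.activity_jitter_sd, n_act),
            0.0,
            None,
        )
        eeg[i * n_eeg:(i + 1) * n_eeg] = e
        emg[i * n_eeg:(i + 1) * n_eeg] = m
        act[i * n_act:(i + 1) * n_act] = a

    recording = TimeSeriesRecording(
        channels=[
            Channel(EEG, eeg, spec.eeg_rate),
            Channel(EMG, emg, spec.eeg_rate),
            Channel(ACTIVITY, act, spec.activity_rate),
        ]
    )
    truth = Hypnogram(
        stages=stages,
        epoch_length=L,
        epoch_starts=np.arange(n_epochs) * L,
        probabilities=np.full((n_epochs, 4), np.nan),
        override_fired=np.zeros(n_epochs, dtype=bool),
    )
    return recording, truth


def _spike_waveform(amp: float, dur_ms: float, undershoot: float,
                    fs: float) -> np.ndarray:
    """Biphasic interictal-spike template: half-sine main lobe of width
    ``dur_ms`` and amplitude ``amp``, followed by a slow undershoot at
    ``undershoot`` x amp (kept sub-threshold so one plant = one detection)."""
    n_main = max(2, int(round(dur_ms / 1000.0 * fs)))
    n_under = 2 * n_main
    main = amp * np.sin(np.pi * np.arange(n_main) / n_main)
    under = -undershoot * amp * np.sin(np.pi * np.arange(n_under) / n_under)
    return np.concatenate([main, under])


def inject_spike_trains(
    recording: TimeSeriesRecording, spec: PlantedTrainSpec
) -> tuple[TimeSeriesRecording, list[dict]]:
    """Add planted spike trains to the EEG channel.

    Returns a new recording and the exact planted intervals as dicts with
    ``start``, ``end`` (first/last spike peak time) and ``n_spikes``.
    Placement is on a seeded jittered grid for ``"uniform"`` insertion, so
    train windows never overlap and stay at least 2x the maximum chaining
    interval apart.
    """
    eeg_ch = recording.require(EEG)
    fs = eeg_ch.sampling_rate
    duration = recording.duration
    rng = np.random.default_rng(spec.seed)
    span = spec.train_span
    margin = 1.0 + spec.spike_dur / 1000.0  # > 2 * isi_max of clearance

    if spec.n_trains == 0:
        starts: list[float] = []
    elif isinstance(spec.insertion_times, str):
        if spec.insertion_times != "uniform":
            raise ValueError(f"unknown insertion mode {spec.insertion_times!r}")
        slot = duration / spec.n_trains
        slack = slot - span - 2 * margin
        if slack <= 0:
            raise ValueError(
                f"{spec.n_trains} trains of span {span:.2f} s do not fit in "
                f"{duration:.1f} s"
            )
        starts = [k * slot + margin + rng.uniform(0, slack) for k in range(spec.n_trains)]
    else:
        starts = sorted(float(t) for t in spec.insertion_times)
        for a, b in zip(starts, starts[1:]):
            if b - a < span + margin:
                raise ValueError("insertion windows overlap")

    wave = _spike_waveform(spec.spike_amp, spec.spike_dur,
                           spec.undershoot_fraction, fs)
    half_main = int(round(spec.spike_dur / 1000.0 * fs)) // 2
    eeg = eeg_ch.samples.copy()
    truth = []
    for t0 in starts:
        peaks = [t0 + k * spec.isi for k in range(spec.spikes_per_train)]
        if peaks[-1] + spec.spike_dur / 1000.0 * 3 > duration:
            raise ValueError(f"train at {t0:.2f} s extends beyond the recording")
        for pk in peaks:
            i0 = int(round(pk * fs)) - half_main
            eeg[i0:i0 + wave.size] += wave[: max(0, eeg.size - i0)]
        truth.append(
            {"start": peaks[0], "end": peaks[-1], "n_spikes": spec.spikes_per_train}
        )

    channels = [
        Channel(EEG, eeg, fs) if ch.label == EEG else ch for ch in recording.channels
    ]
    return TimeSeriesRecording(channels, start_time=recording.start_time), truth


def generate_raster(spec: RasterSpec) -> tuple[SpikeRaster, list[dict]]:
    """Per-electrode inhomogeneous Poisson raster with planted bursts.

    Rate is ``baseline_rate`` outside burst windows and
    ``baseline_rate * burst_rate_multiplier`` inside them. Returns the
    raster and the ground-truth burst windows (center/start/end dicts).
    """
    rng = np.random.default_rng(spec.seed)
    centers = sorted(spec.burst_times)
    bounds = [0.0]
    rates = []
    for c in centers:
        a, b = c - spec.burst_duration / 2, c + spec.burst_duration / 2
        rates += [spec.baseline_rate, spec.baseline_rate * spec.burst_rate_multiplier]
        bounds += [a, b]
    rates.append(spec.baseline_rate)
    bounds.append(spec.duration)

    ids_parts, times_parts = [], []
    for (a, b), rate in zip(zip(bounds, bounds[1:]), rates):
        seg = b - a
        if seg <= 0 or rate == 0:
            continue
        counts = rng.poisson(rate * seg, spec.n_electrodes)
        total = int(counts.sum())
        ids_parts.append(np.repeat(np.arange(spec.n_electrodes), counts))
        times_parts.append(rng.uniform(a, b, total))

    if ids_parts:
        ids = np.concatenate(ids_parts)
        times = np.concatenate(times_parts)
        order = np.argsort(times, kind="stable")
        ids, times = ids[order], times[order]
    else:
        ids = np.empty(0, dtype=np.int64)
        times = np.empty(0)

    raster = SpikeRaster(
        electrode_ids=ids,
        spike_times=times,
        duration=spec.duration,
        n_electrodes_total=spec.n_electrodes_total or spec.n_electrodes,
    )
    truth = [
        {
            "center": c,
            "start": c - spec.burst_duration / 2,
            "end": c + spec.burst_duration / 2,
        }
        for c in centers
    ]
    return raster, truth


def generate_band_power_cohort(
    n_per_group: int = 8,
    delta_power_multiplier: float = 1.5,
    subject_scale_sd: float = 0.1,
    recording_s: float = 120.0,
    seed: int = 0,
):
    """Two-genotype cohort of per-subject mean delta powers.

    Each subject contributes one short synthetic recording; affected (HET)
    subjects carry the planted delta-power multiplier (amplitude x sqrt of
    it). Between-subject variability is a lognormal scale on all EEG
    amplitudes with sd ``subject_scale_sd`` on the log-amplitude scale.
    Returns a tidy DataFrame with columns subject_id, genotype, metric,
    value suitable for the cohort statistics module.
    """
    import pandas as pd

    from .spectral import recording_band_powers

    rng = np.random.default_rng(seed)
    # run the cohort at 0.6x EEG amplitude so the largest-amplitude subjects
    # stay clear of the 0.2 mV artifact screen (the multiplier is a power
    # ratio, so the group contrast is unaffected)
    amp = 0.6
    rows = []
    for g, (genotype, mult) in enumerate(
        [("WT", 1.0), ("HET", delta_power_multiplier)]
    ):
        for k in range(n_per_group):
            scale = amp * float(np.exp(rng.normal(0.0, subject_scale_sd)))
            sigs = {}
            for stage, s in DEFAULT_SIGNATURES.items():
                sigs[stage] = StageSignature(
                    s.delta_amp * scale * np.sqrt(mult),
                    s.theta_amp * scale,
                    s.broadband_amp,
                    s.emg_amp,
                    s.activity_level,
                )
            spec = SleepArchitectureSpec(
                stage_sequence=[Stage.SWS, Stage.WAKE, Stage.PARADOXICAL, Stage.SWS],
                signatures=sigs,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rec, _ = generate_sleep_recording(spec, recording_s)
            bp = recording_band_powers(rec)["bands"]["delta"]
            rows.append(
                {
                    "subject_id": f"{genotype}{k:02d}",
                    "genotype": genotype,
                    "metric": "delta_power",
                    "value": bp,
                }
            )
    return pd.DataFrame(rows)
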