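"""Ratio-based four-stage rodent sleep scoring from EEG, EMG and activity.

Each 10-s epoch is described by four dimensionless features:

* ``delta_ratio``   — epoch delta power / recording-mean delta power,
* ``theta_delta_ratio`` — epoch theta power / epoch delta power,
* ``emg_ratio``     — epoch EMG power / recording-mean EMG power,
* ``activity``      — mean accelerometer level in the epoch.

Recording-wide means are taken over non-artifact epochs, which makes the
printed anchors (0.5/1 for delta, 1.3/3 for theta:delta, 1/2.4 for EMG)
scale-free. Each feature contributes a piecewise-linear membership vector
over the four stages — Active Wake, Wake, Slow-Wave Sleep (SWS) and
Paradoxical (REM-like) sleep — saturating at the printed anchors; the four
evidence vectors are averaged with equal weights. Two overrides force Active
Wake before the argmax: activity strictly above 0.1, or EMG ratio at or above
1.5x the wake saturation anchor (3.6 by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .recording import (
    ACTIVITY,
    EEG,
    EMG,
    ArtifactParams,
    EpochGrid,
    TimeSeriesRecording,
    flag_artifacts,
    segment_epochs,
)
from .spectral import DEFAULT_BANDS, BandDefinition, epoch_band_powers

__all__ = [
    "Stage",
    "StageFeatures",
    "MembershipAnchors",
    "Hypnogram",
    "SleepSummary",
    "compute_stage_features",
    "stage_probabilities",
    "classify_epoch",
    "score_recording",
    "summarize_hypnogram",
]

logger = logging.getLogger(__name__)


class Stage(str, Enum):
    ACTIVE_WAKE = "ACTIVE_WAKE"
    WAKE = "WAKE"
    SWS = "SWS"
    PARADOXICAL = "PARADOXICAL"
    ARTIFACT = "ARTIFACT"


#: Order of entries in every probability 4-vector.
STAGE_ORDER = (Stage.ACTIVE_WAKE, Stage.WAKE, Stage.SWS, Stage.PARADOXICAL)
_IDX = {s: i for i, s in enumerate(STAGE_ORDER)}
#: Fixed tie-break precedence for the argmax.
TIE_ORDER = (Stage.WAKE, Stage.SWS, Stage.PARADOXICAL, Stage.ACTIVE_WAKE)


@dataclass(frozen=True)
class StageFeatures:
    """Per-epoch staging features; ``theta_delta_ratio`` is NaN when the
    epoch delta power is zero (flagged undefined)."""

    delta_ratio: float
    theta_delta_ratio: float
    emg_ratio: float
    activity: float


@dataclass(frozen=True)
class MembershipAnchors:
    """Saturation points of the piecewise-linear stage memberships.

    Each ratio feature has two anchors: membership for the stage it votes
    for is 0 at or below the first and 1 at or above the second, linear in
    between. Defaults are the printed scoring levels.
    """

    delta_paradoxical_wake_max_at: float = 0.5
    delta_sws_max_at: float = 1.0
    theta_wake_sws_max_at: float = 1.3
    theta_paradoxical_max_at: float = 3.0
    emg_paradoxical_sws_max_at: float = 1.0
    emg_wake_max_at: float = 2.4
    activity_active_wake_above: float = 0.1
    emg_active_wake_factor: float = 1.5

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.delta_paradoxical_wake_max_at, self.delta_sws_max_at, "delta"),
            (self.theta_wake_sws_max_at, self.theta_paradoxical_max_at, "theta"),
            (self.emg_paradoxical_sws_max_at, self.emg_wake_max_at, "emg"),
        ):
            if not (0 < lo < hi):
                raise ValueError(f"{name} anchors must satisfy 0 < low < high")

    @property
    def emg_active_wake_at(self) -> float:
        """EMG ratio at or above which the Active Wake override fires."""
        return self.emg_active_wake_factor * self.emg_wake_max_at


@dataclass
class Hypnogram:
    """Per-epoch stage labels with probabilities and override provenance."""

    stages: list[Stage]
    epoch_length: float
    epoch_starts: np.ndarray
    probabilities: np.ndarray  # (n_epochs, 4) in STAGE_ORDER; NaN rows = artifact
    override_fired: np.ndarray  # bool per epoch

    @property
    def n_epochs(self) -> int:
        return len(self.stages)


@dataclass
class SleepSummary:
    """Stage percentages over scored (non-artifact) epochs."""

    percent: dict[str, float]
    scored_hours: float
    artifact_fraction: float


def _ramp(x: float, x0: float, x1: float) -> float:
    return float(np.clip((x - x0) / (x1 - x0), 0.0, 1.0))


def _vector(weight: float, target: Stage, complement: tuple[Stage, ...]) -> np.ndarray:
    v = np.zeros(4)
    v[_IDX[target]] = weight
    for s in complement:
        v[_IDX[s]] = (1.0 - weight) / len(complement)
    return v


def compute_stage_features(
    recording: TimeSeriesRecording,
    grid: EpochGrid,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> list[StageFeatures | None]:
    """Staging features for every epoch of a 10-s grid.

    Band powers come from the spectral module per epoch; EMG power is the
    epoch variance of the mean-removed EMG trace; activity is the epoch mean
    of the accelerometer channel. Normalizing means are taken over the
    non-artifact epochs of the whole recording. Artifact epochs yield None.
    """
    for label in (EEG, EMG, ACTIVITY):
        if recording.get(label) is None:
            raise KeyError(f"sleep staging requires a {label!r} channel")
    if grid.n_epochs < 6:
        raise ValueError("need at least 6 epochs to self-normalize features")

    band_by_name = {b.name: b for b in bands}
    powers = epoch_band_powers(
        recording, grid, (band_by_name["delta"], band_by_name["theta"])
    )
    delta, theta = powers["delta"], powers["theta"]

    emg_power = np.empty(grid.n_epochs)
    activity = np.empty(grid.n_epochs)
    for i, t in enumerate(grid.epoch_starts):
        y = recording.epoch_samples(EMG, t, grid.epoch_length)
        emg_power[i] = np.var(y)
        a = recording.epoch_samples(ACTIVITY, t, grid.epoch_length)
        activity[i] = a.mean() if a.size else 0.0

    keep = ~grid.artifact_mask
    delta_mean = delta[keep].mean()
    emg_mean = emg_power[keep].mean()

    feats: list[StageFeatures | None] = []
    for i in range(grid.n_epochs):
        if grid.artifact_mask[i]:
            feats.append(None)
            continue
        tdr = theta[i] / delta[i] if delta[i] > 0 else math.nan
        feats.append(
            StageFeatures(
                delta_ratio=delta[i] / delta_mean if delta_mean > 0 else math.nan,
                theta_delta_ratio=tdr,
                emg_ratio=emg_power[i] / emg_mean if emg_mean > 0 else math.nan,
                activity=float(activity[i]),
            )
        )
    return feats


def stage_probabilities(
    features: StageFeatures,
    anchors: MembershipAnchors | None = None,
) -> np.ndarray:
    """Equal-weight average of the four per-feature membership vectors.

    * delta: SWS membership ramps 0→1 between the two delta anchors;
      the complement splits equally between Wake and Paradoxical.
    * theta:delta: Paradoxical ramps between its anchors; complement splits
      between Wake and SWS. An undefined ratio (NaN) contributes a uniform
      vector and is logged.
    * EMG: Wake ramps between its anchors; complement splits between SWS and
      Paradoxical.
    * activity: Active Wake gets weight 1 above the activity threshold and 0
      otherwise; the complement splits over the other three stages.

    Returns the renormalized 4-vector in `STAGE_ORDER`.
    """
    a = anchors or MembershipAnchors()
    f = features

    w_sws = _ramp(f.delta_ratio, a.delta_paradoxical_wake_max_at, a.delta_sws_max_at)
    delta_ev = _vector(w_sws, Stage.SWS, (Stage.WAKE, Stage.PARADOXICAL))

    if math.isnan(f.theta_delta_ratio):
        logger.info("undefined theta:delta ratio; using uniform theta evidence")
        theta_ev = np.full(4, 0.25)
    else:
        w_par = _ramp(
            f.theta_delta_ratio, a.theta_wake_sws_max_at, a.theta_paradoxical_max_at
        )
        theta_ev = _vector(w_par, Stage.PARADOXICAL, (Stage.WAKE, Stage.SWS))

    w_wake = _ramp(f.emg_ratio, a.emg_paradoxical_sws_max_at, a.emg_wake_max_at)
    emg_ev = _vector(w_wake, Stage.WAKE, (Stage.SWS, Stage.PARADOXICAL))

    w_aw = 1.0 if f.activity > a.activity_active_wake_above else 0.0
    act_ev = _vector(w_aw, Stage.ACTIVE_WAKE, (Stage.WAKE, Stage.SWS, Stage.PARADOXICAL))

    p = (delta_ev + theta_ev + emg_ev + act_ev) / 4.0
    return p / p.sum()


def _override_active_wake(features: StageFeatures, anchors: MembershipAnchors) -> bool:
    return features.activity > anchors.activity_active_wake_above or (
        not math.isnan(features.emg_ratio)
        and features.emg_ratio >= anchors.emg_active_wake_at
    )


def classify_epoch(
    probabilities: np.ndarray,
    features: StageFeatures,
    anchors: MembershipAnchors | None = None,
) -> Stage:
    """Stage label for one epoch: overrides first, then tie-broken argmax.

    Active Wake is forced when activity exceeds its threshold or the EMG
    ratio reaches 1.5x the wake saturation anchor. Otherwise the stage with
    the highest probability wins; exact ties resolve in the fixed order
    Wake > SWS > Paradoxical > Active Wake.
    """
    a = anchors or MembershipAnchors()
    if _override_active_wake(features, a):
        return Stage.ACTIVE_WAKE
    best = max(probabilities)
    for stage in TIE_ORDER:
        if probabilities[_IDX[stage]] == best:
            return stage
    raise AssertionError("unreachable")


def score_recording(
    recording: TimeSeriesRecording,
    anchors: MembershipAnchors | None = None,
    artifact_params: ArtifactParams | None = None,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    epoch_length: float = 10.0,
) -> Hypnogram:
    """Score a whole recording into a hypnogram of 10-s epochs."""
    anchors = anchors or MembershipAnchors()
    grid = segment_epochs(recording, epoch_length)
    grid = flag_artifacts(recording, grid, artifact_params)
    feats = compute_stage_features(recording, grid, bands)

    stages: list[Stage] = []
    probs = np.full((grid.n_epochs, 4), np.nan)
    fired = np.zeros(grid.n_epochs, dtype=bool)
    for i, f in enumerate(feats):
        if f is None:
            stages.append(Stage.ARTIFACT)
            continue
        p = stage_probabilities(f, anchors)
        probs[i] = p
        fired[i] = _override_active_wake(f, anchors)
        stages.append(classify_epoch(p, f, anchors))
    return Hypnogram(
        stages=stages,
        epoch_length=epoch_length,
        epoch_starts=grid.epoch_starts.copy(),
        probabilities=probs,
        override_fired=fired,
    )


def summarize_hypnogram(hypnogram: Hypnogram) -> SleepSummary:
    """Stage percentages over scored epochs; artifact fraction separately."""
    scored = [s for s in hypnogram.stages if s is not Stage.ARTIFACT]
    if not scored:
        raise ValueError("no scored epochs in hypnogram")
    n = len(scored)
    percent = {
        stage.value: 100.0 * sum(s is stage for s in scored) / n
        for stage in STAGE_ORDER
    }
    return SleepSummary(
        percent=percent,
        scored_hours=n * hypnogram.epoch_length / 3600.0,
        artifact_fraction=1.0 - n / hypnogram.n_epochs,
    )
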