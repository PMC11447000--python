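"""YAML-backed analysis configuration.

One document carries every tunable of the pipeline, grouped by stage. Any
key omitted from the YAML keeps its default, so a config file only needs the
values it changes. The schema is versioned via ``config_version``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .mea import BurstDetectionParams
from .recording import ArtifactParams
from .sleep import MembershipAnchors
from .spectral import DEFAULT_BANDS, BandDefinition
from .spikes import SpikeDetectionParams

__all__ = ["AnalysisConfig", "load_config"]

CONFIG_VERSION = 1


@dataclass
class AnalysisConfig:
    """All pipeline tunables with printed-rule defaults."""

    psd_epoch_s: float = 30.0
    psd_bin_hz: float = 2.0
    band_epoch_s: float = 10.0
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    artifact: ArtifactParams = field(default_factory=ArtifactParams)
    spikes: SpikeDetectionParams = field(default_factory=SpikeDetectionParams)
    anchors: MembershipAnchors = field(default_factory=MembershipAnchors)
    bursts: BurstDetectionParams = field(default_factory=BurstDetectionParams)
    config_version: int = CONFIG_VERSION


def _build(cls, defaults, section: dict):
    known = {f for f in cls.__dataclass_fields__}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {k: v for k, v in section.items()}
    base = {f: getattr(defaults, f) for f in known}
    base.update(kwargs)
    return cls(**base)


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Load a YAML config, falling back to defaults for missing keys.

    Recognized top-level sections: ``psd`` (epoch_s, bin_hz), ``bands``
    (name -> [low, high]), ``artifact`` (eeg_mV, emg_mV), ``spikes``,
    ``sleep`` (anchor fields), ``bursts``.
    """
    cfg = AnalysisConfig()
    if path is None:
        return cfg
    doc = yaml.safe_load(Path(path).read_text()) or {}
    version = doc.get("config_version", CONFIG_VERSION)
    if version != CONFIG_VERSION:
        raise ValueError(f"unsupported config_version {version}")

    psd = doc.get("psd", {})
    cfg.psd_epoch_s = float(psd.get("epoch_s", cfg.psd_epoch_s))
    cfg.psd_bin_hz = float(psd.get("bin_hz", cfg.psd_bin_hz))
    cfg.band_epoch_s = float(psd.get("band_epoch_s", cfg.band_epoch_s))

    if "bands" in doc:
        cfg.bands = tuple(
            BandDefinition(name, float(lo), float(hi))
            for name, (lo, hi) in doc["bands"].items()
        )
    art = doc.get("artifact", {})
    cfg.artifact = ArtifactParams(
        eeg_limit_mv=float(art.get("eeg_mV", cfg.artifact.eeg_limit_mv)),
        emg_limit_mv=float(art.get("emg_mV", cfg.artifact.emg_limit_mv)),
    )
    if "spikes" in doc:
        cfg.spikes = _build(SpikeDetectionParams, cfg.spikes, doc["spikes"])
    if "sleep" in doc:
        cfg.anchors = _build(MembershipAnchors, cfg.anchors, doc["sleep"])
    if "bursts" in doc:
        cfg.bursts = _build(BurstDetectionParams, cfg.bursts, doc["bursts"])
    return cfg
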