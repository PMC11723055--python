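"""Composite run configuration: epoching, arithmetic mode, notch stage,
threshold multipliers, vote quorum and stimulation shape.

Defaults reproduce the published system: 256-sample epochs at 4 kHz (one
decision per 64 ms), the optimal per-feature (M, N) pairs, a 3-of-4 vote,
and 34 µA / 200 Hz / 5-pulse biphasic stimulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from .detector import DEFAULT_MIN_FEATURES
from .features import DEFAULT_SLP_SUBWINDOW_MS, Mode
from .preprocessing import NotchConfig
from .signal_io import DEFAULT_EPOCH_SAMPLES, DEFAULT_FS
from .stimulation import StimParams
from .thresholding import DEFAULT_PARAMS, ThresholdParams


@dataclass(frozen=True)
class RunConfig:
    fs: float = DEFAULT_FS
    epoch_samples: int = DEFAULT_EPOCH_SAMPLES
    mode: Mode = "float"
    slp_subwindow_ms: float = DEFAULT_SLP_SUBWINDOW_MS
    notch: NotchConfig = field(default_factory=NotchConfig)
    threshold_params: dict[str, ThresholdParams] = field(
        default_factory=lambda: {k: ThresholdParams(*v)
                                 for k, v in DEFAULT_PARAMS.items()})
    vote_min_features: int = DEFAULT_MIN_FEATURES
    freeze_thresholds_during_stim: bool = False
    refractory_epochs: int = 0
    stim: StimParams = field(default_factory=StimParams)

    @property
    def epoch_ms(self) -> float:
        return 1000.0 * self.epoch_samples / self.fs

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    """Build a RunConfig from a (possibly partial) nested mapping."""
    data = dict(data or {})
    kwargs: dict[str, Any] = {}
    for key in ("fs", "epoch_samples", "mode", "slp_subwindow_ms",
                "vote_min_features", "freeze_thresholds_during_stim",
                "refractory_epochs"):
        if key in data:
            kwargs[key] = data[key]
    if "notch" in data:
        kwargs["notch"] = NotchConfig(**data["notch"])
    if "threshold" in data:
        params = {k: ThresholdParams(*v) for k, v in DEFAULT_PARAMS.items()}
        for feat, mn in data["threshold"].items():
            params[feat] = ThresholdParams(int(mn["M"]), int(mn["N"]))
        kwargs["threshold_params"] = params
    if "stim" in data:
        kwargs["stim"] = StimParams(**{
            k: tuple(v) if k == "segment_pattern" else v
            for k, v in data["stim"].items()})
    return RunConfig(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config file; a missing path yields the defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})
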