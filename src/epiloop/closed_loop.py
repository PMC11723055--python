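"""The per-epoch closed-loop state machine.

Every epoch: features are computed, the current feature vector is compared
against thresholds derived from the *previous* four epochs' values, and the
FIFOs are then updated.  The system moves through three phases:

* ``WARMUP`` — the 4-deep FIFOs are still filling; thresholds are undefined
  and detection is disabled (the first four epochs of any run).
* ``DETECT`` — comparators and the 3-of-4 vote are active.
* ``STIMULATE`` — a detection has triggered a stimulation episode; detection
  is locked out until the episode (and any configured refractory period)
  completes, then the system returns to ``DETECT``.

Feature and threshold bookkeeping continues during stimulation by default —
otherwise signal evolution during the episode would be missed — with a
``freeze_thresholds_during_stim`` option to hold the FIFOs instead.

One stimulation episode spans ``ceil(episode_ms / epoch_ms)`` epochs; at the
defaults (25 ms episode, 64 ms epoch) that is a single epoch of lock-out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .config import RunConfig
from .detector import DetectionRecord, FLAG_ORDER, compare, vote
from .features import FeatureVector, compute_features
from .preprocessing import notch_filter
from .signal_io import Epoch, Recording, epoch_matrix
from .stimulation import StimWaveform, make_waveform
from .thresholding import ThresholdState


class Phase(str, Enum):
    WARMUP = "WARMUP"
    DETECT = "DETECT"
    STIMULATE = "STIMULATE"


@dataclass
class SystemState:
    """Mutable controller state carried across epochs."""

    threshold_state: ThresholdState
    stim_remaining_epochs: int = 0
    refractory_remaining_epochs: int = 0

    @property
    def phase(self) -> Phase:
        if self.stim_remaining_epochs > 0:
            return Phase.STIMULATE
        if not self.threshold_state.filled:
            return Phase.WARMUP
        return Phase.DETECT


@dataclass(frozen=True)
class EpochRecord:
    """Everything the controller knew and decided for one epoch."""

    epoch_index: int
    features: FeatureVector
    thresholds: dict[str, float] | None
    detection: DetectionRecord
    phase: Phase


@dataclass(frozen=True)
class StimEpisode:
    onset_epoch: int
    waveform: StimWaveform


@dataclass
class SessionLog:
    """Complete per-epoch trace of one closed-loop run."""

    records: list[EpochRecord] = field(default_factory=list)
    episodes: list[StimEpisode] = field(default_factory=list)
    config: RunConfig = field(default_factory=RunConfig)

    @property
    def det(self) -> np.ndarray:
        return np.array([r.detection.det for r in self.records], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            th = r.thresholds or {}
            rows.append({
                "epoch_index": r.epoch_index,
                "AMP": r.features.amp, "SLP": r.features.slp,
                "LL": r.features.ll, "POWER": r.features.power,
                "AMP_TH": th.get("amp", np.nan),
                "SLP_TH": th.get("slp", np.nan),
                "LL_TH": th.get("ll", np.nan),
                "POWER_TH": th.get("power", np.nan),
                "flags": r.detection.flag_string,
                "DET": int(r.detection.det),
                "state": r.phase.value,
            })
        return pd.DataFrame(rows)


def stim_duration_epochs(cfg: RunConfig) -> int:
    """Epochs of detection lock-out one stimulation episode occupies."""
    return max(1, math.ceil(cfg.stim.episode_span_ms / cfg.epoch_ms))


def step(state: SystemState, e: Epoch, cfg: RunConfig) -> EpochRecord:
    """Advance the controller by one epoch, mutating ``state``."""
    fv = compute_features(e, cfg.fs, cfg.mode, cfg.slp_subwindow_ms)
    phase = state.phase
    thresholds = state.threshold_state.thresholds

    enabled = (phase is Phase.DETECT
               and state.refractory_remaining_epochs == 0)
    if thresholds is not None:
        flags = compare(fv, thresholds)
    else:
        flags = (False, False, False, False)
    det = vote(flags, enabled, cfg.vote_min_features)
    record = EpochRecord(
        epoch_index=e.index, features=fv, thresholds=thresholds,
        detection=DetectionRecord(e.index, tuple(flags), det, enabled),
        phase=phase)

    # FIFO update (optionally frozen while a stimulation episode runs)
    if not (cfg.freeze_thresholds_during_stim and phase is Phase.STIMULATE):
        state.threshold_state.push(fv)

    # countdowns and transitions
    if phase is Phase.STIMULATE:
        state.stim_remaining_epochs -= 1
        if state.stim_remaining_epochs == 0:
            state.refractory_remaining_epochs = cfg.refractory_epochs
    elif state.refractory_remaining_epochs > 0:
        state.refractory_remaining_epochs -= 1
    if det:
        state.stim_remaining_epochs = stim_duration_epochs(cfg)
    return record


def run_epochs(epoch_rows: np.ndarray, cfg: RunConfig = RunConfig()) -> SessionLog:
    """Run the closed loop over an ``(n_epochs, n)`` epoch matrix."""
    epoch_rows = np.asarray(epoch_rows)
    state = SystemState(threshold_state=ThresholdState(cfg.threshold_params))
    log = SessionLog(config=cfg)
    for k, row in enumerate(epoch_rows):
        e = Epoch(row, index=k, n=epoch_rows.shape[1])
        record = step(state, e, cfg)
        log.records.append(record)
        if record.detection.det:
            log.episodes.append(
                StimEpisode(onset_epoch=k, waveform=make_waveform(cfg.stim)))
    return log


def run(rec: Recording, cfg: RunConfig = RunConfig()) -> SessionLog:
    """Run the closed loop over a recording: notch (if enabled), epoch, step."""
    if abs(rec.fs - cfg.fs) > 1e-9:
        raise ValueError(
            f"recording fs={rec.fs} differs from configured fs={cfg.fs}")
    rec = notch_filter(rec, cfg.notch)
    return run_epochs(epoch_matrix(rec, cfg.epoch_samples), cfg)
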