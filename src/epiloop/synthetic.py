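"""Seeded synthetic single-channel EEG with per-epoch ground-truth labels.

Interictal background is band-limited Gaussian noise (default 1–30 Hz)
scaled to a target RMS amplitude in µV.  Ictal spans are either

* ``"spikewave"`` (default): a repeating spike-and-slow-wave complex at
  ~3 Hz — a 20 ms triangular spike followed by a half-sine slow wave —
  scaled by ``ictal_amp_multiplier``, with additive sensor noise; or
* ``"scaled-background"``: the background signal itself multiplied by
  ``ictal_amp_multiplier``.  Degree-1 features (amplitude, slope, line
  length) then scale *exactly* by the multiplier, which makes this mode the
  right construction for planting a known separation between ictal and
  background feature values.

An epoch is labelled positive when at least half of its samples fall inside
a seizure span.  Identical configurations generate bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import signal as sps

from .signal_io import DEFAULT_EPOCH_SAMPLES, DEFAULT_FS, Recording

#: Fraction of an epoch that must lie inside a seizure span to label it ictal.
LABEL_OVERLAP_FRACTION = 0.5

SPIKE_WIDTH_S = 0.020  # triangular spike width within one spike-wave cycle


@dataclass(frozen=True)
class SynthConfig:
    seed: int
    duration_s: float = 10.0
    fs: float = DEFAULT_FS
    background_amp_uv: float = 50.0
    background_band_hz: tuple[float, float] = (1.0, 30.0)
    seizures: tuple[tuple[float, float], ...] = ()  # (onset_s, duration_s)
    ictal_amp_multiplier: float = 4.0
    spikewave_hz: float = 3.0
    noise_sd_uv: float = 5.0
    ictal_waveform: Literal["spikewave", "scaled-background"] = "spikewave"
    epoch_samples: int = DEFAULT_EPOCH_SAMPLES

    def __post_init__(self) -> None:
        if self.ictal_amp_multiplier <= 1:
            raise ValueError("ictal amplitude multiplier must exceed 1")
        spans = sorted(self.seizures)
        for (o1, d1), (o2, _) in zip(spans, spans[1:]):
            if o1 + d1 > o2:
                raise ValueError("seizure spans overlap")
        for onset, dur in spans:
            if onset < 0 or dur <= 0 or onset + dur > self.duration_s:
                raise ValueError(
                    f"seizure ({onset}, {dur}) outside recording duration")


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                        band: tuple[float, float], rms_uv: float) -> np.ndarray:
    low, high = band
    white = rng.standard_normal(n + 2 * int(fs))  # pad against filter edges
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    shaped = sps.sosfiltfilt(sos, white)[int(fs):int(fs) + n]
    return shaped * (rms_uv / np.sqrt(np.mean(shaped ** 2)))


def _spikewave(rng: np.random.Generator, n: int, fs: float, hz: float,
               peak_uv: float) -> np.ndarray:
    """Repeating spike-and-wave complexes: 20 ms triangular spike, then a
    half-sine slow wave filling the rest of the cycle."""
    cycle = int(round(fs / hz))
    spike_len = max(2, int(round(SPIKE_WIDTH_S * fs)))
    wave_len = cycle - spike_len
    one = np.concatenate([
        peak_uv * sps.windows.triang(spike_len),
        -0.6 * peak_uv * np.sin(np.pi * np.arange(wave_len) / wave_len),
    ])
    reps = int(np.ceil(n / cycle)) + 1
    phase = rng.integers(0, cycle)  # random cycle phase at seizure onset
    return np.tile(one, reps)[phase:phase + n]


def seizure_spans_samples(cfg: SynthConfig) -> list[tuple[int, int]]:
    """Seizure intervals as half-open sample index ranges."""
    return [(int(round(onset * cfg.fs)),
             int(round((onset + dur) * cfg.fs)))
            for onset, dur in sorted(cfg.seizures)]


def labels_from_spans(spans: Sequence[tuple[int, int]], n_samples: int,
                      epoch_samples: int) -> np.ndarray:
    """Per-epoch labels: positive iff >= 50% of samples are inside a span."""
    covered = np.zeros(n_samples, dtype=bool)
    for start, stop in spans:
        covered[start:stop] = True
    n_epochs = n_samples // epoch_samples
    per_epoch = covered[: n_epochs * epoch_samples].reshape(n_epochs, -1)
    return per_epoch.mean(axis=1) >= LABEL_OVERLAP_FRACTION


def generate(cfg: SynthConfig) -> tuple[Recording, np.ndarray]:
    """Generate a labelled synthetic recording; deterministic in ``cfg``."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    background = _band_limited_noise(rng, n, cfg.fs, cfg.background_band_hz,
                                     cfg.background_amp_uv)
    x = background.copy()
    for start, stop in seizure_spans_samples(cfg):
        m = stop - start
        if cfg.ictal_waveform == "scaled-background":
            x[start:stop] = background[start:stop] * cfg.ictal_amp_multiplier
        else:
            peak = cfg.ictal_amp_multiplier * cfg.background_amp_uv
            x[start:stop] = (
                _spikewave(rng, m, cfg.fs, cfg.spikewave_hz, peak)
                + cfg.noise_sd_uv * rng.standard_normal(m))
    labels = labels_from_spans(seizure_spans_samples(cfg), n, cfg.epoch_samples)
    rec = Recording(x, fs=cfg.fs, source_id=f"synthetic(seed={cfg.seed})")
    return rec, labels


def quantize(rec: Recording, adc_bits: int = 14,
             full_scale_uv: float = 500.0) -> Recording:
    """Ideal mid-tread ADC: codes = clip(round(x / lsb)) to the signed range.

    ``full_scale_uv`` maps to the positive rail; one LSB is
    full_scale / 2**(adc_bits-1).
    """
    if full_scale_uv <= 0:
        raise ValueError("full-scale voltage must be positive")
    half = 1 << (adc_bits - 1)
    lsb = full_scale_uv / half
    codes = np.clip(np.round(np.asarray(rec.samples, float) / lsb),
                    -half, half - 1).astype(np.int64)
    return Recording(codes, fs=rec.fs, source_id=rec.source_id + "|adc")


# ---------------------------------------------------------------------------
# Reference study fixtures
#
# Detection-level fixtures use fs = 173.61 Hz so one 256-sample epoch spans
# ~1.47 s, matching the public scalp/intracranial archive the detector was
# originally evaluated on; at kHz rates a 64 ms epoch holds under two cycles
# of 1-30 Hz background and epoch statistics become envelope-dominated.
# ---------------------------------------------------------------------------

BONN_FS = 173.61


def _epoch_s(fs: float = BONN_FS, n: int = DEFAULT_EPOCH_SAMPLES) -> float:
    return n / fs


def background_config(seed: int, n_epochs: int = 120) -> SynthConfig:
    """Seizure-free interictal background for false-positive testing."""
    return SynthConfig(seed=seed, fs=BONN_FS,
                       duration_s=(n_epochs + 1) * _epoch_s())


def planted_grid_config(seed: int, n_epochs: int = 420,
                        n_seizures: int = 20,
                        multiplier: float = 2.5) -> SynthConfig:
    """Fixture with a planted single-feature optimum at (M, N) = (2, 1).

    Single-epoch seizures of scaled background place each ictal feature
    value at ``multiplier`` times that epoch's background level: above
    2*AVE + 1*STD of the surrounding background (epoch-to-epoch feature
    scatter is small at ~1.5 s epochs) yet below 3*AVE, so M >= 3 misses
    every event while M = 1 admits background false positives.
    """
    ep = _epoch_s()
    step = n_epochs // n_seizures
    seizures = tuple((k * step * ep, ep)
                     for k in range(2, n_seizures + 2)
                     if (k * step + 1) * ep < (n_epochs + 1) * ep)
    return SynthConfig(seed=seed, fs=BONN_FS,
                       duration_s=(n_epochs + 1) * _epoch_s(),
                       seizures=seizures,
                       ictal_amp_multiplier=multiplier,
                       ictal_waveform="scaled-background")


def single_seizure_config(seed: int, n_epochs: int = 30,
                          seizure_epoch: int = 20) -> SynthConfig:
    """One single-epoch seizure for closed-loop detection tests.

    Uses the scaled-background ictal mode so all four features rise by the
    default multiplier (4): a 3 Hz discharge *replacing* broadband
    background raises amplitude and energy but can lower line length and
    slope, which tests feature contrast rather than the detection logic.
    """
    ep = _epoch_s()
    return SynthConfig(seed=seed, fs=BONN_FS,
                       duration_s=(n_epochs + 1) * ep,
                       seizures=((seizure_epoch * ep, ep),),
                       ictal_waveform="scaled-background")
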