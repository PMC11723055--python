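"""Charge-balanced biphasic stimulation waveform generation.

A detection triggers one stimulation episode: ``pulses_per_cycle`` pulses,
each pulse a fixed sequence of equal-duration current segments.  The default
pulse is cathodic-first — segments of −34, 0, +34, 0, 0 µA at 1 ms each —
giving a 5 ms pulse period (200 Hz repetition rate), 25 ms per episode, and
exactly zero net charge so no charge accumulates in tissue.

The waveform is a simulated output only: a sampled current trace with
segment annotations, not a hardware driver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_AMPLITUDE_UA = 34.0
DEFAULT_PHASE_MS = 1.0
DEFAULT_PULSES = 5
DEFAULT_PATTERN = (-1, 0, 1, 0, 0)
DEFAULT_DT_MS = 0.125


@dataclass(frozen=True)
class StimParams:
    """One stimulation episode's shape parameters."""

    amplitude_ua: float = DEFAULT_AMPLITUDE_UA
    phase_ms: float = DEFAULT_PHASE_MS
    pulses_per_cycle: int = DEFAULT_PULSES
    segment_pattern: tuple[float, ...] = DEFAULT_PATTERN
    #: Require the pattern's positive and negative totals to cancel.
    enforce_charge_balance: bool = True

    def __post_init__(self) -> None:
        if not self.amplitude_ua > 0:
            raise ValueError("amplitude must be positive")
        if not self.phase_ms > 0:
            raise ValueError("phase duration must be positive")
        if self.pulses_per_cycle < 1:
            raise ValueError("need at least one pulse per cycle")
        if self.enforce_charge_balance and abs(sum(self.segment_pattern)) > 1e-12:
            raise ValueError(
                "segment pattern is not charge balanced "
                f"(sum {sum(self.segment_pattern)}); set "
                "enforce_charge_balance=False for deliberately unbalanced pulses")

    @property
    def pulse_period_ms(self) -> float:
        return len(self.segment_pattern) * self.phase_ms

    @property
    def pulse_rate_hz(self) -> float:
        """Pulse repetition frequency: 1000 / (pattern length * phase_ms)."""
        return 1000.0 / self.pulse_period_ms

    @property
    def episode_span_ms(self) -> float:
        return self.pulses_per_cycle * self.pulse_period_ms


@dataclass(frozen=True)
class StimWaveform:
    """Sampled current trace of one episode; current is piecewise constant
    over [t[k], t[k] + dt)."""

    t_ms: np.ndarray
    i_ua: np.ndarray
    dt_ms: float
    episode_span_ms: float
    pulse_onsets_ms: tuple[float, ...] = field(default_factory=tuple)


def make_waveform(p: StimParams = StimParams(),
                  dt_ms: float = DEFAULT_DT_MS) -> StimWaveform:
    """Sample one stimulation episode on a grid of step ``dt_ms``.

    ``dt_ms`` must divide the segment duration exactly so segment edges fall
    on grid points and the discrete charge integral is exact.
    """
    steps_per_phase = p.phase_ms / dt_ms
    if abs(steps_per_phase - round(steps_per_phase)) > 1e-9:
        raise ValueError(
            f"dt_ms={dt_ms} does not divide the {p.phase_ms} ms segment")
    steps_per_phase = int(round(steps_per_phase))
    segs = np.asarray(p.segment_pattern, dtype=float) * p.amplitude_ua
    pulse = np.repeat(segs, steps_per_phase)
    i = np.tile(pulse, p.pulses_per_cycle)
    t = np.arange(i.size) * dt_ms
    onsets = tuple(k * p.pulse_period_ms for k in range(p.pulses_per_cycle))
    return StimWaveform(t_ms=t, i_ua=i, dt_ms=dt_ms,
                        episode_span_ms=p.episode_span_ms,
                        pulse_onsets_ms=onsets)


def charge(w: StimWaveform) -> float:
    """Net delivered charge in µA·ms (discrete integral of the trace)."""
    return float(np.sum(w.i_ua) * w.dt_ms)
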