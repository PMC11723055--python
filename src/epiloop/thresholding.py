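"""Adaptive per-feature thresholds from a 4-deep FIFO of past feature values.

Each of the four features keeps the 4 most recent per-epoch values
(FV1 newest ... FV4 oldest).  Once the buffer is full the threshold is

    TH = M * AVE + N * STD

with AVE the arithmetic mean and STD the population standard deviation
(divisor 4) of the buffer.  Until 4 values have been seen the threshold is
undefined and detection stays disabled — the warm-up state.

Default (M, N) pairs are the grid-search optima of the published system:
AMP (5, 4), SLP (2, 1), POWER (3, 1), LL (2, 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .features import FEATURE_NAMES, FeatureVector

FIFO_DEPTH = 4

#: Optimal (M, N) per feature from the published calibration.
DEFAULT_PARAMS: dict[str, tuple[int, int]] = {
    "amp": (5, 4),
    "slp": (2, 1),
    "power": (3, 1),
    "ll": (2, 1),
}


@dataclass(frozen=True)
class ThresholdParams:
    """Multipliers for the adaptive threshold M*AVE + N*STD."""

    M: int
    N: int

    def __post_init__(self) -> None:
        if self.M < 0 or self.N < 0:
            raise ValueError("threshold multipliers must be non-negative")


def default_params() -> dict[str, ThresholdParams]:
    return {name: ThresholdParams(*mn) for name, mn in DEFAULT_PARAMS.items()}


def ave4(values) -> float:
    """Mean of exactly four feature values."""
    if len(values) != FIFO_DEPTH:
        raise ValueError(f"expected {FIFO_DEPTH} values, got {len(values)}")
    return sum(float(v) for v in values) / FIFO_DEPTH


def std4(values) -> float:
    """Population standard deviation (divisor 4) of exactly four values."""
    if len(values) != FIFO_DEPTH:
        raise ValueError(f"expected {FIFO_DEPTH} values, got {len(values)}")
    mean = ave4(values)
    return math.sqrt(sum((float(v) - mean) ** 2 for v in values) / FIFO_DEPTH)


def threshold(ave: float, std: float, p: ThresholdParams) -> float:
    """Combine sliding statistics into the detection threshold."""
    if not (math.isfinite(ave) and math.isfinite(std)):
        raise ValueError("ave and std must be finite")
    if std < 0:
        raise ValueError("std must be non-negative")
    return p.M * ave + p.N * std


@dataclass
class FeatureFifo:
    """FIFO of the 4 most recent values of one feature, newest first."""

    values: list[float] = field(default_factory=list)

    def push(self, value: float) -> None:
        self.values.insert(0, float(value))
        del self.values[FIFO_DEPTH:]

    @property
    def filled(self) -> bool:
        return len(self.values) == FIFO_DEPTH

    @property
    def ave(self) -> float | None:
        return ave4(self.values) if self.filled else None

    @property
    def std(self) -> float | None:
        return std4(self.values) if self.filled else None


@dataclass
class ThresholdState:
    """Per-feature FIFOs plus the derived thresholds.

    ``thresholds`` maps feature name -> M*AVE + N*STD, or None while the
    FIFOs are still filling (the TH_FINISH gate of the hardware).
    """

    params: dict[str, ThresholdParams] = field(default_factory=default_params)
    fifos: dict[str, FeatureFifo] = field(
        default_factory=lambda: {name: FeatureFifo() for name in FEATURE_NAMES})

    def push(self, fv: FeatureVector) -> None:
        for name, value in fv.as_dict().items():
            self.fifos[name].push(value)

    @property
    def filled(self) -> bool:
        return all(f.filled for f in self.fifos.values())

    @property
    def thresholds(self) -> dict[str, float] | None:
        if not self.filled:
            return None
        return {
            name: threshold(fifo.ave, fifo.std, self.params[name])
            for name, fifo in self.fifos.items()
        }
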