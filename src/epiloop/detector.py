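"""Comparator bank and majority vote producing the per-epoch seizure flag.

Each feature is compared against its adaptive threshold with a strict ">"
(a tie does not fire).  A seizure is declared (DET = 1) when at least
``min_features`` of the four comparators fire in the same epoch — three of
four by default — and detection is enabled (it is disabled during
stimulation and warm-up).
"""

from __future__ import annotations

from dataclasses import dataclass

from .features import FeatureVector

#: Flag serialisation order in traces.
FLAG_ORDER = ("amp", "slp", "power", "ll")

DEFAULT_MIN_FEATURES = 3


@dataclass(frozen=True)
class DetectionRecord:
    """Per-epoch comparator flags and vote outcome."""

    epoch_index: int
    flags: tuple[bool, bool, bool, bool]  # order: FLAG_ORDER
    det: bool
    enabled: bool

    @property
    def flag_string(self) -> str:
        return "".join("1" if f else "0" for f in self.flags)


def compare(fv: FeatureVector, thresholds: dict[str, float] | None) -> tuple[bool, ...]:
    """Strict exceedance flags in :data:`FLAG_ORDER` order."""
    if thresholds is None:
        raise RuntimeError("thresholds not yet available (warm-up)")
    values = fv.as_dict()
    return tuple(values[name] > thresholds[name] for name in FLAG_ORDER)


def vote(flags, enabled: bool = True, min_features: int = DEFAULT_MIN_FEATURES) -> bool:
    """Quorum vote over the comparator flags; disabled detection never fires."""
    return bool(enabled) and sum(bool(f) for f in flags) >= min_features
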