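"""Power-line notch filtering.

The implant filters 50 Hz mains interference digitally, ahead of feature
accumulation.  No coefficients are published for that block, so the software
model uses a standard second-order IIR notch designed from (f0, Q), applied
zero-phase to the whole recording before epoching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_io import Recording


@dataclass(frozen=True)
class NotchConfig:
    """Notch-stage configuration: centre frequency, quality factor, on/off."""

    f0_hz: float = 50.0
    q: float = 30.0
    enabled: bool = False

    def validate(self, fs: float) -> None:
        if not 0 < self.f0_hz < fs / 2:
            raise ValueError(
                f"notch frequency {self.f0_hz} Hz must lie in (0, fs/2) "
                f"for fs={fs} Hz"
            )
        if not self.q > 0:
            raise ValueError(f"quality factor must be positive, got {self.q}")


def notch_filter(rec: Recording, cfg: NotchConfig = NotchConfig(enabled=True)) -> Recording:
    """Apply (or bypass) the power-line notch; length and fs are preserved."""
    if not cfg.enabled:
        return rec
    cfg.validate(rec.fs)
    b, a = sps.iirnotch(cfg.f0_hz, cfg.q, fs=rec.fs)
    filtered = sps.filtfilt(b, a, np.asarray(rec.samples, dtype=float))
    return Recording(filtered, fs=rec.fs, source_id=rec.source_id)
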