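"""Single-channel EEG input/output and epoch segmentation.

Readers accept the two plain-text formats the simulator consumes: the
one-integer-per-line ASCII layout used by the public Bonn EEG archives, and
generic CSV with a header row.  Neither format carries a sampling rate, so
``fs`` is always supplied by the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default epoch length in samples (one detection decision per epoch).
DEFAULT_EPOCH_SAMPLES = 256
#: Default sampling rate in Hz; 256 samples then span 64 ms.
DEFAULT_FS = 4000.0

#: Signed range of a 14-bit ADC code.
ADC_MIN, ADC_MAX = -8192, 8191


class FormatError(ValueError):
    """A file could not be parsed as the requested format."""


@dataclass(frozen=True)
class Recording:
    """A single-channel signal with its sampling rate.

    Samples are microvolts in float mode or integer ADC codes in hardware
    mode; the arithmetic mode of downstream feature computation decides the
    interpretation.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    source_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("Recording requires a non-empty 1-D sample array")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def validate_hardware(self) -> None:
        """Check that every sample is an integer inside the 14-bit signed range."""
        s = self.samples
        if not np.issubdtype(s.dtype, np.integer):
            if not np.all(s == np.floor(s)):
                raise ValueError("hardware mode requires integer samples")
            s = s.astype(np.int64)
        if s.min() < ADC_MIN or s.max() > ADC_MAX:
            raise ValueError(
                f"hardware-mode samples must lie in [{ADC_MIN}, {ADC_MAX}]"
            )


@dataclass(frozen=True)
class Epoch:
    """One fixed-length, non-overlapping analysis window.

    Epoch ``index`` k covers samples ``[k*n, (k+1)*n)`` of the parent
    recording (0-based, half-open).
    """

    samples: np.ndarray
    index: int
    n: int = field(default=DEFAULT_EPOCH_SAMPLES)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples)
        if samples.size != self.n:
            raise ValueError(
                f"epoch {self.index}: expected {self.n} samples, got {samples.size}"
            )
        object.__setattr__(self, "samples", samples)


def read_bonn_ascii(path: str | Path, fs: float = DEFAULT_FS,
                    source_id: str | None = None) -> Recording:
    """Read a Bonn-style ASCII file: one numeric sample per line.

    Blank lines are ignored.  The format carries no sampling rate, so ``fs``
    comes from the caller (the Bonn archives were digitised at 173.61 Hz).
    """
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: cannot parse {text!r} as a number"
                ) from None
    if not values:
        raise FormatError(f"{path}: file contains no samples")
    arr = np.asarray(values)
    if np.all(arr == np.floor(arr)):
        arr = arr.astype(np.int64)
    return Recording(arr, fs=fs, source_id=source_id or str(path))


def read_csv(path: str | Path, value_column: str, fs: float = DEFAULT_FS,
             source_id: str | None = None) -> Recording:
    """Read one signal column from a headered CSV, preserving row order."""
    path = Path(path)
    frame = pd.read_csv(path)
    if value_column not in frame.columns:
        raise FormatError(
            f"{path}: no column {value_column!r}; available: "
            f"{', '.join(map(str, frame.columns))}"
        )
    return Recording(frame[value_column].to_numpy(), fs=fs,
                     source_id=source_id or f"{path}:{value_column}")


def epochs(rec: Recording, n: int = DEFAULT_EPOCH_SAMPLES) -> list[Epoch]:
    """Segment a recording into consecutive non-overlapping epochs.

    A trailing remainder shorter than ``n`` is discarded (padding would bias
    amplitude and energy features downward) and logged.
    """
    matrix = epoch_matrix(rec, n)
    return [Epoch(row, index=k, n=n) for k, row in enumerate(matrix)]


def epoch_matrix(rec: Recording, n: int = DEFAULT_EPOCH_SAMPLES) -> np.ndarray:
    """Like :func:`epochs` but returned as an ``(n_epochs, n)`` array."""
    if n < 2:
        raise ValueError(f"epoch length must be >= 2, got {n}")
    total = len(rec)
    n_epochs = total // n
    remainder = total - n_epochs * n
    if remainder:
        logger.info("discarding trailing partial epoch of %d samples", remainder)
    return rec.samples[: n_epochs * n].reshape(n_epochs, n)


def write_trace(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a per-epoch session trace to CSV (see SessionLog.to_frame)."""
    frame.to_csv(path, index=False)


def write_waveform_csv(t_ms: Sequence[float], i_ua: Sequence[float],
                       path: str | Path) -> None:
    """Export a stimulation current trace as two-column CSV (t_ms, i_ua)."""
    pd.DataFrame({"t_ms": t_ms, "i_ua": i_ua}).to_csv(path, index=False)
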