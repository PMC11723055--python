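"""Per-epoch time-domain features: amplitude, slope, line length, energy.

Each feature exists in two arithmetic modes:

* ``float`` — exact floating-point means, for algorithm exploration;
* ``hardware`` — the integer datapath of the detection ASIC: the per-epoch
  sums of |x| and x**2 are divided by 256 with an 8-bit right shift, slope
  uses truncating integer division per subwindow, and samples must be 14-bit
  signed ADC codes.

Feature definitions over an epoch x(0..N-1):

* ``LL   = sum_i |x(i+1) - x(i)|``           (no normalisation)
* ``AMP  = (1/N) sum_i |x(i)|``
* ``SLP  = mean over subwindows of (max - min) / |i_max - i_min|``
* ``POWER = (1/N) sum_i x(i)**2``
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .signal_io import ADC_MAX, ADC_MIN, Epoch

Mode = Literal["float", "hardware"]

#: Canonical feature order used in traces and feature matrices.
FEATURE_NAMES = ("amp", "slp", "ll", "power")

#: Epoch length the hardware accumulate-and-shift datapath is built for.
HARDWARE_EPOCH_SAMPLES = 256

#: Default slope subwindow duration in milliseconds.
DEFAULT_SLP_SUBWINDOW_MS = 2.0


@dataclass(frozen=True)
class FeatureVector:
    """The four per-epoch scalars, all non-negative."""

    amp: float
    slp: float
    ll: float
    power: float
    epoch_index: int = 0

    def as_dict(self) -> dict[str, float]:
        return {"amp": self.amp, "slp": self.slp, "ll": self.ll,
                "power": self.power}


def _check_hardware_input(x: np.ndarray) -> np.ndarray:
    if not np.issubdtype(x.dtype, np.integer):
        if not np.all(x == np.floor(x)):
            raise ValueError("hardware mode requires integer samples")
    xi = x.astype(np.int64)
    if xi.size and (xi.min() < ADC_MIN or xi.max() > ADC_MAX):
        raise ValueError("hardware mode requires 14-bit signed samples")
    return xi


def line_length(x: np.ndarray) -> float:
    """Sum of absolute consecutive differences; identical in both modes."""
    x = np.asarray(x)
    if x.size < 2:
        raise ValueError("line length needs at least 2 samples")
    return float(np.abs(np.diff(x.astype(np.int64) if
                                np.issubdtype(x.dtype, np.integer) else x)).sum())


def amplitude(x: np.ndarray, mode: Mode = "float") -> float:
    """Mean absolute amplitude; hardware mode floors Σ|x| >> 8 at n = 256."""
    x = np.asarray(x)
    if mode == "hardware":
        if x.size != HARDWARE_EPOCH_SAMPLES:
            raise ValueError(
                f"hardware amplitude requires n={HARDWARE_EPOCH_SAMPLES}, "
                f"got {x.size}")
        xi = _check_hardware_input(x)
        return float(int(np.abs(xi).sum()) >> 8)
    return float(np.mean(np.abs(x)))


def power(x: np.ndarray, mode: Mode = "float") -> float:
    """Mean squared value; hardware mode floors Σx² >> 8 at n = 256."""
    x = np.asarray(x)
    if mode == "hardware":
        if x.size != HARDWARE_EPOCH_SAMPLES:
            raise ValueError(
                f"hardware power requires n={HARDWARE_EPOCH_SAMPLES}, "
                f"got {x.size}")
        xi = _check_hardware_input(x)
        return float(int((xi * xi).sum()) >> 8)
    x = x.astype(float)
    return float(np.mean(x * x))


def slope_subwindow_samples(fs: float, subwindow_ms: float = DEFAULT_SLP_SUBWINDOW_MS) -> int:
    """Slope subwindow length in samples for a sampling rate."""
    return int(round(fs * subwindow_ms / 1000.0))


def slope(x: np.ndarray, w: int, mode: Mode = "float") -> float:
    """Mean over non-overlapping subwindows of (max−min)/|i_max − i_min|.

    ``w`` is the subwindow length in samples and must tile the epoch.
    Extremum ties resolve to the first occurrence; a constant subwindow
    contributes 0.  Hardware mode truncates the per-subwindow division and
    divides the accumulated sum by the subwindow count (a right shift when
    the count is a power of two).
    """
    x = np.asarray(x)
    if w < 2:
        raise ValueError(f"slope subwindow must span >= 2 samples, got {w}")
    if x.size % w:
        raise ValueError(
            f"epoch of {x.size} samples is not tiled by subwindows of {w}")
    n_sub = x.size // w
    if mode == "hardware":
        xi = _check_hardware_input(x).reshape(n_sub, w)
        acc = 0
        for sub in xi:
            i_max = int(np.argmax(sub))
            i_min = int(np.argmin(sub))
            gap = abs(i_max - i_min)
            if gap:
                acc += (int(sub[i_max]) - int(sub[i_min])) // gap
        return float(acc // n_sub)
    subs = x.astype(float).reshape(n_sub, w)
    i_max = np.argmax(subs, axis=1)
    i_min = np.argmin(subs, axis=1)
    gap = np.abs(i_max - i_min)
    rng = subs[np.arange(n_sub), i_max] - subs[np.arange(n_sub), i_min]
    vals = np.zeros(n_sub)
    nz = gap > 0
    vals[nz] = rng[nz] / gap[nz]
    return float(vals.mean())


def compute_features(e: Epoch, fs: float, mode: Mode = "float",
                     slp_subwindow_ms: float = DEFAULT_SLP_SUBWINDOW_MS) -> FeatureVector:
    """Bundle the four features for one epoch."""
    x = e.samples
    w = slope_subwindow_samples(fs, slp_subwindow_ms)
    return FeatureVector(
        amp=amplitude(x, mode),
        slp=slope(x, w, mode),
        ll=line_length(x),
        power=power(x, mode),
        epoch_index=e.index,
    )


def feature_series(epoch_rows: np.ndarray, name: str, fs: float,
                   mode: Mode = "float",
                   slp_subwindow_ms: float = DEFAULT_SLP_SUBWINDOW_MS) -> np.ndarray:
    """One named feature for every row of an epoch matrix."""
    epoch_rows = np.asarray(epoch_rows)
    if name == "amp":
        return np.array([amplitude(r, mode) for r in epoch_rows])
    if name == "power":
        return np.array([power(r, mode) for r in epoch_rows])
    if name == "ll":
        return np.array([line_length(r) for r in epoch_rows])
    if name == "slp":
        w = slope_subwindow_samples(fs, slp_subwindow_ms)
        return np.array([slope(r, w, mode) for r in epoch_rows])
    raise ValueError(f"unknown feature {name!r}; choose from {FEATURE_NAMES}")


def feature_matrix(epoch_rows: np.ndarray, fs: float, mode: Mode = "float",
                   slp_subwindow_ms: float = DEFAULT_SLP_SUBWINDOW_MS) -> np.ndarray:
    """Features for every row of an ``(n_epochs, n)`` epoch matrix.

    Columns follow :data:`FEATURE_NAMES` order (amp, slp, ll, power).
    """
    epoch_rows = np.asarray(epoch_rows)
    if epoch_rows.ndim != 2:
        raise ValueError("expected a 2-D (n_epochs, n) epoch matrix")
    out = np.empty((epoch_rows.shape[0], 4))
    w = slope_subwindow_samples(fs, slp_subwindow_ms)
    for k, row in enumerate(epoch_rows):
        out[k] = (amplitude(row, mode), slope(row, w, mode),
                  line_length(row), power(row, mode))
    return out
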