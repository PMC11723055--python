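"""Optional: run the detector and (M, N) calibration on downloaded Bonn EEG.

The public Bonn archive (sets A-E, 100 single-channel ASCII segments each,
4097 samples at 173.61 Hz) is not bundled; download and unpack it yourself,
then point this script at one interictal directory (e.g. Z/ or O/) and one
ictal directory (S/).  Segments are concatenated interictal-then-ictal and
labelled per epoch, the per-feature grids are swept, and the closed-loop
detector is scored — the same metric table layout the calibration CLI
writes.  Results depend on the subset and ordering chosen; this script is
illustrative and sits outside the test suite.

Usage:
    python scripts/run_bonn.py --interictal path/to/Z --ictal path/to/S \
        --out bonn_grid.csv
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from epiloop.closed_loop import run
from epiloop.config import RunConfig
from epiloop.evaluation import confusion, grid_search, metrics
from epiloop.features import FEATURE_NAMES
from epiloop.signal_io import Recording, read_bonn_ascii

BONN_FS = 173.61
EPOCH = 256


def load_dir(path: Path, limit: int | None) -> np.ndarray:
    files = sorted(p for p in path.iterdir() if p.is_file())[:limit]
    if not files:
        raise SystemExit(f"no segment files found under {path}")
    return np.concatenate([read_bonn_ascii(p, fs=BONN_FS).samples
                           for p in files])


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--interictal", type=Path, required=True)
    ap.add_argument("--ictal", type=Path, required=True)
    ap.add_argument("--limit", type=int, default=None,
                    help="use at most this many segments per class")
    ap.add_argument("--out", type=Path, required=True)
    args = ap.parse_args()

    inter = load_dir(args.interictal, args.limit)
    ictal = load_dir(args.ictal, args.limit)
    samples = np.concatenate([inter, ictal])
    labels = np.zeros(samples.size // EPOCH, dtype=bool)
    labels[inter.size // EPOCH:] = True
    rec = Recording(samples, fs=BONN_FS, source_id="bonn")
    cfg = RunConfig(fs=BONN_FS, slp_subwindow_ms=8 / BONN_FS * 1000)

    tables = []
    for name in FEATURE_NAMES:
        res = grid_search(rec, labels, name, cfg=cfg)
        tables.append(res.table)
        print(f"{name}: best (M, N) = {res.best}")
    pd.concat(tables, ignore_index=True).to_csv(args.out, index=False)

    log = run(rec, cfg)
    keep = np.arange(labels.size) >= 4
    rep = metrics(confusion(labels[keep], log.det[keep]))
    for metric in ("precision", "accuracy", "recall", "f2"):
        value = getattr(rep, metric)
        print(f"closed-loop {metric}: "
              f"{'n/a' if value is None else f'{value:.4f}'}")


if __name__ == "__main__":
    main()
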