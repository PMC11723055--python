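# Methods

## System model

The package models the digital half of a closed-loop seizure-control
implant as a per-epoch state machine. An analog front end (amplifier,
100 Hz low-pass, 14-bit SAR ADC) is abstracted to "a single-channel sample
stream plus an optional ideal quantizer"; everything downstream of the ADC
is modelled explicitly:

1. **Optional mains notch.** The hardware removes 50 Hz interference
   digitally, but no filter topology is published; a second-order IIR
   notch designed from (f0 = 50 Hz, Q = 30) and applied zero-phase to the
   whole recording is the minimal stand-in. It is off by default for
   synthetic input (which contains no mains tone) and is a config switch
   for file input.
2. **Epoching.** Non-overlapping 256-sample windows; a trailing remainder
   is discarded rather than zero-padded, because padding biases AMP and
   POWER downward. Indexing is 0-based and half-open.
3. **Features.** LL, AMP, SLP, POWER as defined in the README. SLP's
   printed definition `(max x_i − min x_j)/(i − j)` can be negative or
   undefined; since it is compared against a non-negative threshold it is
   implemented as `(max − min)/|i_max − i_min|`, ties resolved to the first
   occurrence, constant subwindows contributing 0. LL carries no 1/N
   normalisation. Slope subwindows must tile the epoch exactly
   (default 2 ms → 8 samples → 32 subwindows at 4 kHz).
4. **Adaptive thresholds.** Per feature, a 4-deep FIFO of past epoch
   values; TH = M·AVE + N·STD with STD the population form (divisor 4),
   exactly as the threshold datapath computes it. The current epoch's
   feature is compared against the threshold of the *previous* four values
   and then pushed — so the first four epochs of any run are a warm-up
   with no detection (the hardware's zero-initialised thresholds and
   TH_FINISH gate), and from epoch 4 onward the threshold is a strict
   function of the trailing window.
5. **Detection.** Strict `feature > TH` comparators (ties do not fire) and
   a quorum vote, 3-of-4 by default (`vote_min_features` exposes the
   quorum for sensitivity sweeps). Exactly 5 of the 16 flag patterns can
   fire.
6. **Stimulation and state control.** A detection starts one episode
   (5 pulses × 5 segments × 1 ms = 25 ms) and disables detection for
   `ceil(25 ms / epoch_ms)` epochs — one epoch at the defaults. Feature
   and threshold updates *continue* during stimulation — otherwise signal
   evolution during the episode would be missed; published accounts of the
   reference controller are inconsistent on this point, so the behaviour
   is a flag (`freeze_thresholds_during_stim`, default off, i.e. keep
   updating).
   No debouncing and no refractory period beyond the episode are applied
   (none are described); `refractory_epochs` exists for experimentation.

## Hardware (integer) arithmetic mode

The ASIC divides the 256-term accumulations by right-shifting 8 bits.
Hardware mode reproduces this exactly: AMP = (Σ|x|) >> 8,
POWER = (Σx²) >> 8, per-subwindow slope by truncating integer division and
the subwindow mean by dividing the accumulated sum by the subwindow count
(a shift when the count is a power of two, e.g. >> 5 for 32 subwindows).
Inputs must be integers within the signed 14-bit ADC range [−8192, 8191].
The floor-shift construction guarantees `0 ≤ float − hardware < 1` unit
for AMP and POWER, which the tests and the acceptance script verify on
random 14-bit epochs.

## Calibration

`grid_search` scores each feature as a *single-feature* detector (its own
threshold exceedance, no vote) for every (M, N) in {1..5}², tallying
precision, accuracy, recall and F2 per epoch on post-warm-up epochs. The
best cell maximises F2, with accuracy, recall, then smallest (M, N)
(lexicographic) breaking ties deterministically. The composed system then
uses the per-feature optima with the 3-of-4 vote. Published descriptions
of this calibration print a recall formula reading TP/(TP+TN), which
contradicts both the accompanying prose and result tables that reach a
recall of 1.00; the standard TP/(TP+FN) is used, with
`recall_formula="as_printed"` available for comparison. Metrics with
zero denominators are reported as absent, never coerced to 0.

## Synthetic data: what it emulates and what it does not

The generator produces band-limited Gaussian background (default 1–30 Hz,
50 µV RMS — interictal scalp-EEG scale) and labelled ictal spans in two
morphologies: a ~3 Hz spike-and-slow-wave complex (20 ms triangular spike
plus half-sine wave, amplitude = multiplier × background, default 4), or
the background itself scaled by the multiplier. An epoch is labelled ictal
when ≥ 50 % of its samples lie inside a seizure span — a stated convention,
since none is published. Output is bit-reproducible from the config
(mandatory seed). An ideal mid-tread 14-bit quantizer (default full scale
±500 µV; the real ADC's full scale is unpublished) converts µV traces to
ADC codes for hardware-mode runs.

Two deliberate simplifications matter for interpreting test results:

- **Epoch duration for detection-level fixtures.** The published detector
  was evaluated on archive recordings sampled at 173.61 Hz, where a
  256-sample epoch spans ~1.47 s and epoch features of 1–30 Hz background
  are statistically stable (hundreds of effective degrees of freedom). At
  the default 4 kHz a 64 ms epoch holds under two cycles of that band and
  epoch features become envelope-dominated. Detection-level fixtures
  (background false-positive, planted grid, injected seizure) therefore
  run at 173.61 Hz with an 8-sample (46.08 ms) slope subwindow; feature-
  and timing-level checks use the 4 kHz defaults.
- **Ictal morphology for detection-logic fixtures.** A 3 Hz discharge that
  *replaces* broadband background raises AMP and POWER but lowers LL and
  SLP — a genuine property of line length at this sampling rate. The
  spike-wave mode is therefore used to test feature contrast (energy and
  amplitude elevation), while fixtures that exercise the detection logic
  use the scaled-background mode, in which every degree-1 feature rises by
  exactly the multiplier.

The planted-calibration fixture uses scaled-background seizures, each one
epoch long, at multiplier 2.5: ictal feature values then sit above
2·AVE + 1·STD of background (epoch-to-epoch feature scatter at 1.47 s
epochs is a few percent) but below 3·AVE, so M ≥ 3 misses every event,
M = 1 admits background false positives, and (2, 1) wins the F2 grid — a
known ground truth the grid search must recover.

Passing on this generator shows the pipeline's logic and arithmetic are
correct under its stated statistical structure. It does not demonstrate
clinical performance: real EEG has non-stationary background, artifacts,
electrode drift and heterogeneous seizure morphologies that the generator
does not emulate, and the published accuracy figures on the Bonn archive
depend on subset and windowing choices that are not stated; reproducing
those numbers is explicitly out of scope (`scripts/run_bonn.py` runs the
pipeline on user-downloaded data for comparison).

## Numerical and design choices

- Sampling rate is a free config; the 4 kHz default is the rate at which
  a 256-sample epoch matches the stated 64 ms decision cadence.
- Thresholds use float arithmetic even over integer features; only the
  feature datapath has a specified integer form.
- The stimulation waveform is sampled piecewise-constant with a grid step
  that must divide the 1 ms segment (default 0.125 ms), making segment
  edges exact and the zero-net-charge integral exact in integer µA·ms.
- Cathodic-first segment order (−34 before +34) as the published pulse
  diagram shows.
- Problem sizes in tests and the acceptance script (tens to hundreds of
  epochs, ~10⁵ samples) are desk-scale choices that keep every statistical
  check well-powered while running in seconds.

## Known limitations

- Single channel only; no montages, no EDF/BDF input.
- The notch stage is a behavioural stand-in, not a bit-true model of the
  chip's filter.
- Per-epoch (not per-event) scoring throughout; event-level latency is
  reported only as the epoch offset of the stimulation episode.
- The SPI/ADC serial protocol, clock domains and counter word widths of
  the hardware are out of scope; timing is modelled at the epoch and
  millisecond level.
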