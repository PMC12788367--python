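# Methods

This note documents the models, parameters and design choices behind
`thermobreath`, and what the synthetic evaluation does and does not show.

## Signal physics and model

Nasal airflow modulates the temperature of the nostril rim: inhaled ambient
air cools it, exhaled air warms it. With a radiometric camera the coldest
pixel inside a nostril bounding box is a robust scalar proxy of this
modulation — colder than surrounding skin, and insensitive to exactly which
rim pixel is coldest in a given frame.

The synthetic generator models the extracted sequence as

    T(t) = T0 + A·sin(2π f_RR t + φ) + d_low(t) + n_high(t)

with baseline `T0` (default 29 °C), oscillation amplitude `A` (1.5 °C),
respiratory frequency `f_RR`, a slow drift `d_low` and white noise `n_high`.
Defaults are plausible magnitudes for a close-range nostril signal, not
measured constants. The drift is modeled as a slow sinusoid (amplitude
0.3 °C, period 120 s) standing in for posture and ambient trends; real drift
is aperiodic, but anything this far below the 0.08 Hz band edge is removed by
the filter regardless of its exact shape. Ground-truth phase is the sign of
the noiseless oscillation derivative (warming = exhale); the drift is
excluded from the truth so labels refer to the breath, not the trend.

## Frame format and codec

The raw dual-stream frame layout is defined by this package (`.trf`): a
16-byte header (magic, H, W, f_cam, frame count) followed per frame by an
H×W single-byte display plane and an H×W×2 radiometric plane, row-major, MSB
first. A pixel decodes as `(256·MSB + LSB)/64 − 273.15` °C (counts are
Kelvin × 64) followed by a linear calibration `T = gain·R + offset`
(defaults 1.0 / 0.0). Encoding rounds to the nearest count, so a
decode–encode round trip is exact to 1/64 K·gain — a property test holds
this bound. Coordinates are 0-based, x = column, y = row; extrema break ties
to the first pixel in row-major order. The display plane is stored as
grayscale; the color display path (contrast ×1.0, 3× bicubic upscale, false
color) carries no quantitative role.

## Detection and tracking

The detector contract is a single call per scheduled frame returning at most
one box with a confidence; multiple candidates are reduced to the highest
confidence above a configurable floor (default 0.25). Detection runs on
every `stride`-th frame (default 2); the constant-velocity Kalman filter
runs every frame, updating only on scheduled frames that produced a
detection.

State: `(c_x, c_y, w, h)` and their velocities; `F = [[I₄, Δt·I₄],[0, I₄]]`
with `Δt = 1/f_cam`; `H = [I₄ | 0]`. All eigenvalues of `F` are 1 (marginal
stability is expected of a constant-velocity model) and `(F, H)` is
observable for any `Δt > 0` — both asserted numerically in tests. Noise
magnitudes are design choices, configurable and not claimed from data:

- `Q`: white-acceleration discretization, per-axis blocks
  `q·[[Δt⁴/4, Δt³/2],[Δt³/2, Δt²]]` with `q = 1 px²/s³`;
- `R = 4 px²·I₄` (≈ 2 px detector jitter);
- initial `P = diag(10² px², 25² (px/s)²)`, velocities initialized to zero
  from the first detection;
- a track coasting more than 25 frames (≈1 s at 25 Hz) is dropped and
  re-initialized by the next detection.

The ROI handed downstream on a scheduled frame with a detection is the
detection itself; otherwise the tracker prediction. Real-valued corners are
rounded half-away-from-zero, clipped to the frame, and the inclusive integer
pixel set is scanned for its minimum. ROIs partially outside the frame are
clipped rather than rejected; a fully outside ROI yields no sample for that
frame. No cold-outlier guard is applied by default (the raw minimum is the
method); `extraction.percentile` enables a robust variant.

## Phase detection

The buffered sequence is band-pass filtered at 0.08–0.7 Hz (5–42 breaths/min)
with a 4th-order Butterworth applied forward–backward (zero phase, so breath
timing is preserved; the effective magnitude response is squared). `order=4`
is the overall pole count — the design uses an order-2 low-pass prototype,
since a band-pass doubles it. The offline entry point filters the complete
sequence in one pass; a streaming deployment would re-filter its ~20 s buffer
per sample, which is equivalent at the newest sample up to edge effects.

The velocity surrogate is the difference of two adjacent length-W moving
averages (W = 3 samples); on a ramp of slope m per sample it equals m·W, and
its sign follows physiology (positive = warming = exhale). The threshold
`θ[n] = 0.6·MAD(v[n−20..n]) + ε` adapts to amplitude and noise; `ε = 10⁻⁴` °C
per window guards degeneracy on near-constant signals. The MAD history
(21 samples ≈ 0.84 s at 25 Hz) spans much less than a breath, so θ tracks
local dispersion — this is what makes the labeling scale-invariant (tested at
×0.1 and ×10 amplitude), at the cost of θ reflecting mostly noise dispersion
at very slow rates (see Limitations).

Labels follow a hysteresis state machine: a crossing `v ≥ θ` (or `≤ −θ`;
ties inclusive) switches the label only if the outgoing state has persisted
at least `⌊0.15 s·f_cam⌋` samples. The dwell gates the *outgoing* state, as
specified, which can delay a legitimate transition immediately after a
change; the alternative (entry dwell) was not adopted. The initial state is
neutral with its persistence counter pre-loaded, so the first genuine
crossing can fire immediately; samples before the velocity is defined keep
the initial state. The optional neutral band (|v| < θ → hold) is implemented
but disabled by default — downstream events only need entries into exhale.
Finally, interior A→B→A segments shorter than `⌊0.3 s·f_cam⌋` are merged
into their flanking phase, iterated to a fixed point.

## Rate estimation

Exhalation onsets are samples where the label enters +1. One subtlety: the
onset that terminates the *initial* neutral segment is a first classification
rather than a breath transition — the interval it would open spans an
unknown fraction of a breath and systematically inflates the rate (measurably
+0.5 BPM on clean signals). That anchor event is excluded from interval
computation; all subsequent onsets are used as-is.

Consecutive onsets give IBIs `Δt_i = (k_i − k_{i−1})/f_cam`, accepted iff
`60/42 ≤ Δt_i ≤ 60/5` s (bounds inclusive). Invalid intervals are dropped,
not clamped, and do not touch the smoothers; the displayed rate holds its
last value until the next valid interval, and nothing is reported before the
first one. Validated rates pass through the weighted update
(0.6 new / 0.4 previous) and the EMA (α = 0.7), both convex, so the final
rate cannot leave the 5–42 BPM band its inputs are confined to.

## Baselines and benchmark design

Two classical single-number estimators serve as comparison baselines, defined
by this package (no reference implementation exists to mirror):

- **Peak counting**: local maxima of the band-passed signal with prominence
  ≥ 0.2 × its standard deviation and separation ≥ 60/42 s;
  rate = peaks/duration.
- **Spectral argmax**: Hann-windowed periodogram of the linearly detrended
  signal, argmax restricted to 0.08–0.7 Hz, ties broken toward the lower
  frequency; a not-ready sentinel is returned for records under 20 s or with
  under 5 % of spectral energy in-band (e.g. pure sub-band drift).

The default comparison benchmark draws true rates *continuously* from
8–30 BPM rather than from an integer grid. Over a 60-s record both baselines
have integer-BPM resolution (a tally counts whole breaths; periodogram bins
are 1/60 Hz apart), so integer target rates sit exactly on their quantization
points and make the spectral baseline trivially exact — a degenerate matchup
that measures nothing about the methods. Continuously sampled rates probe the
timing resolution in which the methods genuinely differ; there the IBI-based
pipeline is roughly eight-fold more accurate. The accuracy-bound benchmarks
(`scripts/acceptance.py`) use the fixed protocol grid 8/12/18/24/30 BPM, six
60-s signals each at 25 Hz, with moderate noise + drift and with clean
settings respectively.

## What the synthetic evaluation does and does not show

The generator produces stationary (or block-stepped) sinusoidal breathing
with additive white noise and slow drift, rendered — for the frame-level
path — as a rigid warm ellipse with a cold blob on a prescribed trajectory
and a detector that jitters and misses at configured rates. Passing tests
therefore demonstrate the internal correctness of the chain (codec fidelity,
tracker algebra, filter behavior, labeling logic, interval bookkeeping) and
accuracy under the modeled disturbances. They do not demonstrate robustness
to articulation and facial deformation, true apnea or mouth breathing,
detector failure modes of a trained model, aperiodic breathing waveform
shapes, or emissivity/ambient-temperature effects — none of which the
generator emulates.

## Numerical choices

- Resizing uses bilinear interpolation with pixel-center alignment
  (`x_in = (x_out + 0.5)·W/W_out − 0.5`, edges clamped); constant maps stay
  constant and same-size resizing is the identity.
- The band-pass requires a record longer than the forward–backward padding
  (~15 samples); phase detection additionally requires 10 s of buffer — one
  breath at the slow end of the band — before reporting anything.
- Velocity is undefined for the first 2W−1 samples and the threshold wherever
  velocity is; both are carried as NaN and the state machine holds its state
  across them. The MAD window expands from 1 to L at the start of the valid
  region.
- Exact threshold ties (v = ±θ) count as crossings (inclusive comparisons).
- Rounding of ROI corners is half-away-from-zero, so a box is never shrunk
  by the rasterization of a .5 coordinate.
- Consolidation rescans from the start after every merge, guaranteeing a
  fixed point free of short flickers regardless of merge order.

## Known limitations

- At slow rates (≲10 BPM) the MAD history is a small fraction of the breath
  period, so θ adapts to noise dispersion rather than breath amplitude;
  sustained in-band noise excursions near velocity zero-crossings can then
  split a breath into two plausible intervals. The validation band cannot
  reject these (half of a 7.5-s interval is still physiological).
- Short transient artifacts (1–3 frames, e.g. a tracking slip onto skin) are
  smeared by the 0.7 Hz band edge to ≈1.4 s — longer than the 0.3-s
  consolidation window — so the label-level flicker suppression does not
  remove them; upstream tracking quality is the real defense.
- The dwell gates the outgoing state, so a legitimate reversal within
  0.15 s of a transition is delayed by design.
- The per-recording rate is the mean of the final smoothed rate over emitted
  events; on rate-modulated breathing this arithmetic mean across intervals
  sits slightly above a duration-weighted tally of the same record.
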