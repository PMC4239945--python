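# Methods

## Signals and conventions

The canonical internal unit is g (1 g = 9.80665 m/s²); m/s² input is divided
by 9.80665 on load. All windows are trailing (causal) windows ending at the
current sample, because the algorithms are meant to run in real time on a
phone. The default sampling rate is 50 Hz — a typical Android game-class
sensor rate, dense enough to resolve 100–200 ms impact pulses — and is
configurable everywhere.

Three derived signals drive the detectors:

- **Total acceleration** `|A_T|`: per-sample Euclidean norm of the three
  axes.
- **Fall Index**: the root of the summed squared consecutive-sample
  differences of the three axes over a trailing 20-sample window. For the
  first `window − 1` samples the sum runs over the differences available so
  far, keeping the output aligned with the input (`FI_0 = 0`).
- **Vertical acceleration** `|A_v| = |A_x sin θ_z + A_y sin θ_y −
  A_z cos θ_y cos θ_z|`, with `θ_y` the pitch (rotation about device y) and
  `θ_z` the roll (rotation about device z), radians internally.

### Orientation from gravity

When no pitch/roll stream exists, orientation is estimated from the
low-pass-filtered acceleration (first-order exponential filter, default time
constant 0.5 s), normalised to a unit gravity direction `u` and inverted to
angles. The inversion is chosen so that the vertical-acceleration formula is
*exactly* self-consistent: pitch is fixed as `arcsin(u_y)` and roll solves
the remaining trigonometric equation (smallest-magnitude branch), which
guarantees `u · v(pitch, roll) = 1` — a static pose always reproduces
`|A_v| = 1 g` to machine precision. Independent per-axis `arcsin` extraction
cannot do this: for diagonal poses its error reaches ~0.16 g.

A caveat inherited from the formula itself: the projection axis
`v = (sin θ_z, sin θ_y, −cos θ_y cos θ_z)` has norm
`sqrt(1 + sin²θ_y sin²θ_z) ≥ 1`, so `|A_v|` can slightly exceed `|A_T|` when
both angles are large; `|A_v| ≤ |A_T|·|v|` is the bound that always holds.
Posture tilt (used by the post-fall check) is the angle between the
normalised `v` at each sample and at the recording's start; it mildly
overstates mid-rotation tilt for diagonal poses but is exact at the upright
and lying endpoints that the decision compares.

## Detector semantics

All detectors merge repeat threshold crossings within a **refractory period**
(default 2 s, measured from the event's trigger) into one event, so a single
physical impact cannot inflate the event count.

- **basic / fall_index**: an event per refractory-merged excursion of the
  scalar above its threshold; the score is the peak value over the merged
  excursions. The published comparison ties the Fall Index decision to the
  same 3.5 g limit; since it is ambiguous whether that limit applies to `FI`
  itself or to `|A_T|` behind an `FI` gate, both are implemented
  (`mode="fi"`, the default, and `mode="magnitude_gated"`).
- **perfalld**: per channel (total, vertical), the (max − min) range over a
  trailing triggering window (`win_t·`, 4 s) above `Th_t·` opens a candidate.
  The first-phase "difference" operator is read as the same max − min range
  that the second phase states explicitly. The other channel must trigger
  before the first channel's checking window (`win_c·`, 4 s) expires; each
  channel's check passes iff the range over the window after its trigger
  does **not** exceed `Th_c·`. The event is emitted when the later check
  window closes with both checks passed; `t_trigger` is the later trigger,
  `t_confirm` the close of the later check. Candidates are serialised: no
  new trigger while a check is pending, and data ending mid-check yields no
  event. A consequence worth knowing: a multi-sample impact always spoils
  its own first checking window (the pulse tail lies inside it), so on
  realistic falls the *successful* candidate is the retrigger once the
  impact has left the trailing window — detection lags the fall by roughly
  one checking window. The evaluation helper `suggested_tolerance` accounts
  for this.
- **ifall**: a candidate opens when `|A_T|` exceeds the upper threshold
  within `crossing_window` (default 1 s — bracketing the ~0.5 s physics of a
  fall) of a sample below the lower threshold. Over the post-fall window
  (default 5 s — long enough for a deliberate recovery) the tilt must pass
  `horizontal_angle` (default 60°) and stay beyond it until expiry; samples
  before lying first begins are a grace period for the body's rotation.
  Upright recovery after lying began, never lying at all, or truncated data
  all discard the candidate.

Streaming and batch forms are independent implementations (monotonic deques
vs pandas rolling windows) with identical decision rules; their equivalence
is asserted on 200 seeded sessions. Scores may differ in the last ulp
(summation order), so score comparisons use a 1e-9 relative tolerance.

## Parameter profiles

Profile `paper` carries the published comparison settings verbatim: basic
3.5 g; Fall Index window 20, threshold 3.5; iFall 1 g / 3.5 g; two-channel
thresholds 150 / 50 (total trigger/check), 6 / 2 (vertical trigger/check)
with 4 s windows. The source states no units for the raw two-channel
numbers, and no single unit is coherent: the 150:2 trigger-to-check ratio
exceeds any plausible signal-range-to-noise-range ratio on the g scale, so
on g-scale data this profile simply never triggers (surfacing, rather than
hiding, the ambiguity). Profile `g-scaled` is this package's calibrated
reinterpretation: the total-acceleration values are taken as counts of a
64 LSB/g MEMS accelerometer (150→2.344 g, 50→0.781 g) and the vertical ones
as m/s² (6→0.612 g, 2→0.204 g). Under that reading every threshold sits on
the correct side of the simulated signal and noise ranges (impact ranges
2–6 g vs 2.34; rest noise range ≈0.17 g vs checks 0.78/0.204). Custom YAML
profiles can override any field.

## The synthetic generator

The generator emulates a test-bed protocol — simulated falls in three
directions at different speeds plus five ADL kinds, worn at the waist or
thigh — not any particular volunteer's physiology. Mounting: waist wear puts
device y vertical and x anterior; thigh wear applies a random fixed rotation
per recording and multiplies noise by 1.4. Noise is white Gaussian per axis,
σ = 0.03 g at rest, mildly activity-scaled; no bias or drift is modelled.

A fall is quiet (U(2,4) s), a free-fall ramp down to U(0.1,0.4) g over
U(0.3,0.5)/intensity s, a half-sine impact pulse of U(0.1,0.2) s peaking at
U(2.5,6)·min(intensity,1.5) g along a direction-specific axis (forward→+x,
backward→−x, lateral→±z, with small off-axis mix), then ≥10 s of damped
ringing settling to 1 g with the posture rotated 80–100° from upright. The
impact-pulse samples carry the designed profile exactly (0.03 g sensor noise
is negligible against a multi-g transient and is omitted there); the sample
nearest the pulse midpoint is set to the drawn peak so the discrete maximum
equals it. The ground-truth interval spans free-fall through the first
second of the aftermath.

ADLs: walk `1 + 0.25·i·sin(2π·2t)` g; jog `1 + 0.8·i·sin(2π·2.8t)` g with
occasional heel-strike spikes capped below 3 g; stand 1 g + noise; sit one
1.5–2 g seat-contact transient then rest with a ≤30° recline; answer_phone
1 g with a smooth 30–60° rotation out and back. Sessions concatenate
movements with quiet 1–3 s bridges that rotate the posture smoothly back
upright, so orientation is continuous across joins. All randomness flows
through one PCG64 generator per call: a fixed seed reproduces a recording
bit for bit across platforms.

What passing tests on this generator do **not** show: real falls have
far messier kinematics (pre-impact flailing, multi-impact tumbles, soft
landings), real ADLs include transitions the five stylised kinds omit, and
real sensors saturate, drift and alias. Results here characterise the
algorithms' logic under their own assumed signal model, not clinical
performance.

## Evaluation protocol

A fall interval counts as detected iff at least one detection *triggers*
within `[t_start, t_end + tolerance]` (default tolerance 2 s; for the
two-phase detector `suggested_tolerance` adds its checking window, matching
the documented decision latency). Detections matching no fall are false
positives attributed to the enclosing, else nearest, ADL interval, at most
one per interval so FP% stays in [0, 100]. FN% per direction is
`100·missed/simulated`; FP% is `100·alarmed ADL intervals/ADL intervals`;
user-cancelled alarms still count as false positives. `threshold_sweep`
re-runs detection and scoring on one fixed dataset per parameter value,
tracing the FN-vs-FP tradeoff; for the basic detector the curve is exactly
monotone on sessions whose excursions are separated by more than the
refractory period.

## Alerting

The confirmation workflow is a four-state machine (monitoring → stationary →
alarm → alert emitted / cancelled). The stationary duration defaults to 0 —
the two-phase detectors have already consumed their observation window — but
can be raised to re-check quiescence. The acoustic-alarm countdown defaults
to 15 s (a design choice; the length is not prescribed by the algorithms).
The alert timestamp is computed analytically as `t_detect + stationary +
alarm`, so tick granularity does not skew it. Location is a pluggable
provider; the default reports no coordinates.

## Problem sizes and numerical choices

The shipped tests run 200-series formula-oracle checks (50–1000 samples
each), 200-session batch/stream equivalence (~2 minutes of 50 Hz data per
session), a 100-seed fall-signature audit and one 700 s end-to-end session
with a 10-value sweep — sizes chosen to exercise every code path while
keeping the whole suite around ten seconds. Window lengths in samples are
`round(duration·fs)` (minimum 1; sub-sample windows are rejected). Threshold
comparisons are strict (`>`); checking-phase comparisons are inclusive
(`≤`), so a constant signal never triggers and an exactly-at-threshold check
passes. Degenerate gravity estimates during deep free fall hold the last
valid direction instead of emitting undefined angles.

## Known limitations

- The two-channel detector's raw thresholds are unit-ambiguous at the
  source; `g-scaled` is one defensible reading, not a calibration against
  ground truth.
- The pitch/roll convention is fixed by the package (the source formula
  states none); data from devices with a different convention must be
  converted on ingest.
- The generator's phase parameters are plausibility choices, not fits to
  biomechanical data; FN%/FP% values computed here characterise algorithm
  logic, not field performance.
- Gyroscope fusion, sensor calibration and grossly irregular sampling are
  out of scope; sessions with >10 % timing jitter are rejected on load.
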