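# Methods

## Sensing model

A VR tracker mounted on the instep of each shoe reports world-frame position
and orientation at a nominal 90 Hz. Because Lighthouse tracking measures
displacement directly (unlike inertial sensors, which integrate), foot
trajectories can be treated like marker trajectories from optical motion
capture. Gait features are conventionally referenced to the heel, so tracker
poses are mapped through a rigid transformation

    heel(t) = p(t) + R(q(t)) · o

with `p` the tracker position, `q` the scalar-first world-from-tracker unit
quaternion and `o` a fixed tracker-frame offset measured once per subject
and shoe (looked up by shoe-size label; no interpolation between sizes).
Quaternions with norm within 1e-3 of unity are renormalized; anything worse
is rejected. The transformation preserves `‖heel − p‖ = ‖o‖` and is
equivariant under global rigid motions — both are enforced by tests.

## Preprocessing

Raw tracker channels are smoothed with a third-order Butterworth low-pass
filter at 12 Hz applied forward-backward (zero phase). The cascade's
magnitude response is the squared single-pass response, so the amplitude
ratio at the design cutoff is exactly 1/2 — the filter-contract test probes
this with a 12 Hz sinusoid at 90 Hz, and checks that a symmetric pulse's
argmax does not move. Edge effects are handled by odd-reflection padding of
`3·(order+1)` samples. The vertical channel is then linearly detrended over
the whole contiguous recording (removing calibration offset and slow drift
of the tracking volume's ground level).

Reference (walkway) event tables arrive at their own rate (120 Hz). When a
common grid is needed the events are snapped to the nearest target-grid
instant; pose streams are resampled by linear interpolation with
componentwise quaternion renormalization.

## Event detection

During walking, the vertical trajectory of a foot tracker traces one
double-peaked hump per stride: it leaves the stance baseline as the heel
lifts, peaks as the foot pushes off (toe off), dips during mid-swing, peaks
again as the foot reaches the ground (heel strike), and settles back during
the next stance. The detector:

1. **levels the stance baseline.** A least-squares detrend is pulled toward
   the swing humps, which leaves the stance floor offset and, on short
   recordings, visibly tilted. The detector therefore fits a line to the
   lower half of the samples (stance is the signal's floor) and refines it
   once on the samples within the baseline band of the fitted line. After
   subtraction the stance level sits at zero regardless of record length.
2. **segments swing excursions** as maximal runs of samples above a band of
   `0.5 · min_prominence` over the levelled baseline. Runs touching either
   end of the recording are discarded (transitional strides).
3. **picks peaks** inside each excursion with prominence ≥ `min_prominence`
   (default 1 cm — foot clearance is multi-centimeter, sensor jitter is not)
   and separation ≥ `min_peak_separation_s` (default 100 ms).
4. **labels events.** An excursion with exactly two qualifying peaks yields
   TO (earlier) and HS (later), timed at the peak sample — deliberately no
   sub-sample refinement, so the event grid is the sampling grid. Excursions
   with one or ≥3 qualifying peaks are discarded with a warning (a malformed
   hump produces no events rather than wrong ones); runs with no qualifying
   peak are baseline jitter and are ignored silently.

Cycles are consecutive (HS, TO, HS) triples of one foot with total duration
inside `[min_cycle_s, max_cycle_s]` (defaults 0.4–2.5 s, bracketing plausible
walking cadences). When a walkway bounding box is configured, cycles whose
bounding heel strikes fall outside it (closed boundaries) are excluded —
this is how turnaround strides beyond the walkway are removed.

The detector targets healthy gait: it assumes one clean two-peaked excursion
per stride and will discard, not reinterpret, atypical morphologies
(shuffling, foot drop, very slow gait).

## Stride features

Features are computed in 2D (the horizontal plane), matching what a pressure
walkway can measure, from heel positions at the event samples (no
interpolation). Stride width pairs the cycle's closing same-foot heel strike
with the latest contralateral heel strike inside the cycle and evaluates
`SW = √(d² − (SL/2)²)` exactly as the width formula is stated, including its
implicit assumption that the contralateral step lands near the stride
midline. A negative radicand (the assumption failed) yields `NaN` with
`valid_SW = False` rather than a silently clamped zero; radicands within
1e-12 of zero are treated as zero so the exactly collinear case returns 0.
The mirrored pairing is used for left-foot strides.

Error geometry worth knowing: `∂SW/∂d = d/SW`, which is ≈ 6 at a typical
1.25 m stride with 10 cm width, so millimeter-level heel-position error
becomes centimeter-level width error. Stride width is structurally the least
accurate feature of this family — consistent with walkway-validation
experience — and the stochastic-recovery test therefore bounds SL and ST,
not SW.

## Validation layer

Reference timestamps are brought onto the detector clock by subtracting a
configured `sync_offset_s` (the clock offset is an input; how it was
measured — e.g. a UDP synchronization packet — is outside this toolkit's
scope). Matching is greedy one-to-one per (foot, kind) stream: candidate
pairs within the tolerance window (default 3 samples at 90 Hz = 33.3 ms) are
accepted in order of ascending |Δt|, with deterministic tie-breaks. On
realistic event streams (spacing ≫ tolerance) this equals the exhaustive
optimal assignment, which the tests verify by brute force on instances with
≤ 8 events per side.

Sensitivity is `100·TP/(TP+FN)` over reference events; false positives are
counted and reported but do not enter sensitivity. Matched offsets are
pooled per kind across feet; offsets further than `outlier_k` (default 3.5)
scaled MADs from the median are removed before statistics (scaled MAD =
1.4826·MAD, the normal-consistent convention — the unscaled variant would
flag far too many events). With a zero MAD, any value different from the
median is flagged. Reported statistics: mean ± SD (n−1 denominator),
absolute mean ± SD, RMSE, and limits of agreement mean ± 1.96·SD (1.96, the
95% normal quantile, is used everywhere). Outlier removal happens at event
level, so outlier events also never contribute strides to feature agreement.

Strides are paired across systems through their matched heel strikes: the
closing HS times must match within tolerance and the opening HS times must
agree within the same tolerance, so both systems describe the same stride.
Per feature, strides with an invalid or non-finite value on either side are
skipped, and Pearson r is reported as undefined (None) when either side has
zero variance.

## Synthetic generator

The generator emulates a straight walkway pass with exact ground truth.
Defaults describe an unremarkable healthy adult at comfortable pace and are
the conditions under which the pipeline is tested:

| parameter | default | meaning |
|---|---|---|
| `SL_true` | 1.25 m | stride length |
| `ST_true` | 1.1 s | stride time (SV ≈ 1.14 m/s) |
| `SW_true` | 0.10 m | stride width |
| `stance_fraction` | 0.62 | stance share of the cycle |
| `clearance_peak1/2` | 0.12 / 0.08 m | push-off / landing peak heights |
| `peak1_frac/peak2_frac` | 0.2 / 0.8 | peak positions within the excursion |
| `fs_vr` / `fs_ref` | 90 / 120 Hz | tracker / walkway rates |
| `noise_sd_pos` | 0 m | white Gaussian tracker-position noise |
| `clock_offset_s` | 0 s | reference-minus-VR clock offset |

Feet alternate with a 50% cycle phase shift; the right foot's strikes land
midway between consecutive left strikes in both time and walking direction,
so the true width equals `SW_true` for every stride. Heel X advances one
stride length between TO and HS with a cosine ease — zero velocity at both
ends, so the position read at the detected HS sample is insensitive to ±1
sample of timing error. The vertical excursion is a C¹ curve with
analytically exact extrema: a flat-topped plateau (raised-cosine edges)
carrying the mid-swing clearance floor (0.35 × the lower peak), plus two
symmetric raised-cosine bumps centered exactly on the TO and HS instants.
Because the plateau is flat and the other bump zero at each peak, peak
positions and heights are exact, and the waveform is locally symmetric
around each event — so the zero-phase filter cannot bias the detected
times. The excursion extends `peak1_frac·L` before TO (heel-off) and
`(1−peak2_frac)·L` after HS (foot-flat), with `L = swing/(peak2_frac −
peak1_frac)`; the spec validator rejects shoulder geometries that would
overlap the neighbouring stance.

Tracker poses are obtained by inverting the heel transformation with the
configured offset (identity orientation plus an optional fixed yaw), after
which i.i.d. Gaussian noise is added to tracker positions. Reference events
are the exact event times snapped to the 120 Hz grid and shifted by the
clock offset. Two feature tables accompany each trial: the analytic truth,
and a walkway-style table whose temporal values are recomputed from the
snapped reference times (as the real device would report them).

What the generator does **not** emulate: gait variability (every stride is
identical up to noise), turnarounds and curved paths, tracking dropouts
beyond simple sample-deletion windows, orientation noise, soft-tissue/strap
artifacts, and the walkway's own footfall-segmentation errors. Passing tests
therefore demonstrate correctness of the algorithms under the stated noise
model, not hardware-grade accuracy claims.

## Test problem sizes and tolerances

The randomized phase-conservation check runs 1,000 trials of 4 strides each
(a walkway-length pass at default stride length is ~5 strides). Noiseless
recovery uses 20 strides; stochastic recovery uses 200 strides at 3 mm noise
with bounds SL RMSE < 1 cm and ST RMSE < 15 ms — comfortably inside the
error scale hardware validations report, as befits a noise-only simulation.
Noiseless feature bounds are propagated grid-quantization limits: ≤ 1 mm for
SL (the heel is parked at HS), one sample period for ST, and the
corresponding propagated bounds for SV, STC% and SW (the latter inflated by
the `d/SW` factor above). Matching-oracle equivalence uses 500 random
instances with ≤ 8 events per side, generated as jittered shared event
streams with drops and occasional spurious detections — the regime the
matcher is specified for.

## Known limitations

* Event times are sample-quantized by design; sub-sample refinement would
  change the offset statistics and is deliberately not implemented.
* The width formula is evaluated as printed; geometries violating its
  midline assumption are flagged invalid, not corrected.
* The detector is tuned for healthy adult gait; pathological waveforms are
  conservatively discarded.
* Synchronization between systems is consumed as a known constant offset;
  drift between clocks over a session is not modelled.
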