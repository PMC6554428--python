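# Methods

`mmbci` implements the decoding stack of a multi-modal EEG brain-computer
interface for three-dimensional device control. Three recognition channels
run on 1.5 s EEG blocks delivered every 1 s: a counting-trough blink
detector (mode switch), a CICSP + linear-SVM motor-imagery classifier
(horizontal steering), and a CCA-based SSVEP classifier (vertical
steering). This note records the models, their assumptions, the free
parameters and their defaults, the numerical choices, and what the
synthetic-data studies do and do not establish.

## Signal model and montage

Recordings are channels × samples matrices in µV at a nominal 1000 Hz,
12 electrodes (CP1 CP2 FC1 FC2 FC3 FC4 C1 C2 C3 C4 Oz Fp2, reference Cz).
The 10 fronto-central/central electrodes carry motor-imagery information,
Oz the visual steady-state response, Fp2 the blink artifact. Input data
are assumed to be already acquisition-filtered (0.3–100 Hz); the package
does not re-apply that stage.

All band-pass filtering uses a 4th-order Butterworth applied
forward–backward (`scipy.signal.sosfiltfilt`), i.e. zero phase, so blink
trough positions and oscillation phases are not delayed; edges are handled
by scipy's default odd-reflection padding. The pass-bands are 0.3–30 Hz
(blink), 5–40 Hz (SSVEP, spanning both stimulus fundamentals and their
first harmonics), and 9–12 Hz (mu band, motor imagery).

Decoding windows are 1.5 s long with a 1 s stride; consecutive windows
therefore overlap by 0.5 s, which is the only reading consistent with a
1.5 s analysis window and a 1 Hz command cadence.

## Blink detection (counting-trough method)

A voluntary double blink produces two large negative deflections at Fp2.
After 0.3–30 Hz filtering, local minima at or below −h are accepted
greedily left to right subject to a minimum separation of β·d seconds,
and a count ≥ 2 within the block signals the hover-and-switch gesture.

Parameters:

- `d_s = 0.75 s` — the trained inter-blink distance.
- `h` (µV) — calibrated as α times the mean over calibration blink trials
  of the per-trial deepest trough, α = 0.5. The halving means blinks at
  least as strong as the trained ones are reliably caught. The averaging
  rule is one reading of an underdetermined calibration description;
  per-trial max depth followed by the mean across trials is the simplest
  estimator of "typical trained blink depth".
- `β = 0.6` — an exact average-distance constraint cannot be enforced on
  two troughs, so it is relaxed to a minimum spacing of β·d.
- `count_threshold = 2`. The source description is self-contradictory
  ("blinking twice" as the gesture vs. a count "> 2" as the trigger); a
  strictly-greater-than-2 rule would make a two-blink gesture
  undetectable, so detection fires at count ≥ 2 and the threshold is
  exposed in configuration.

A trough is a sample strictly lower than both neighbours; a plateau
minimum is credited to its first sample.

## SSVEP recognition (CCA)

For each candidate stimulus frequency f ∈ {12.4, 18} Hz a reference set
Y_f of sin/cos pairs at k·f, k = 1..Nh with Nh = 2, is built at the
window's sampling grid. The first canonical correlation ρ between the Oz
trace and Y_f is the largest singular value of the whitened
cross-covariance C_xx^{-1/2} C_xy C_yy^{-1/2}; a ridge of 1e-8 × trace is
added to the auto-covariances so near-rank-deficient references (e.g.
near-integer-period windows) stay invertible. The frequency with the
largest ρ wins; exact ties go to the lower frequency (arbitrary but
fixed). There is no reject/idle class: the SSVEP mode always emits rise
or fall, mirroring the two-LED control scheme.

Tests verify the SVD route against two independent oracles: a direct
multi-start Nelder-Mead maximization of |corr(aᵀX, bᵀY)| and sklearn's
iterative CCA.

## Motor imagery (CICSP)

Trials are band-passed 9–12 Hz, common-average-referenced over the 10
motor electrodes, and restricted to those electrodes (the CAR therefore
leaves the data rank-9; the eigen-solver ridge absorbs this). Each
trial's spatial covariance XXᵀ is trace-normalized and averaged within
class; the spatial filters W solve C̄₁w = λ(C̄₁+C̄₂)w with a ridge of
1e-9 × trace on the composite, giving W(C̄₁+C̄₂)Wᵀ = I and rows sorted by
λ descending. Filter signs are fixed by making each row's
largest-magnitude coefficient positive.

Features per projection are normalized log-variances
λ_i = log((ZZᵀ)_ii / tr(ZZᵀ)) (natural log; the base is unstated in the
method's original description, and only shifts/scales the features seen
by a linear classifier). The m first and m last filters (Q₁) give the
2m-dimensional edge feature f₁; the remaining C−2m intermediate filters
(Q₂) give log-variance vectors that PCA — fitted jointly on both classes'
training vectors — reduces to k dimensions, f₂′. The classifier is a
linear-kernel SVM (C = 1.0, no probability calibration) on F = [f₁, f₂′].

Defaults: `m = 2` (standard CSP practice with 10 channels, leaving 6
intermediate filters; the original description never states m), `k = 1`
(the online description reduces the intermediate features "to one
dimension").

Online, a 1.5 s window is decoded with f₁ from the full window and f₂′ as
the average of the three 0.5 s sub-windows' PCA-reduced intermediate
features. The full-window f₁ and the averaging fusion are design choices
(the original text describes only the Q₂ sub-window path); per-sub-window
voting is the obvious alternative and the batch path (`predict_mi`) is
also exposed.

## Controller

A two-state machine (MI mode, SSVEP mode). On every window the blink
check runs first; a detection emits HOVER_SWITCH (all-zero payload) and
toggles the mode. Otherwise the active mode's decoder runs and emits its
command with a fixed payload: left-forward (−42° yaw, 0.25 m/s forward),
right-forward (+42°, 0.25 m/s), rise (+0.2 m/s vertical), fall
(−0.3 m/s vertical).

Because windows overlap by 0.5 s, one physical double blink can appear in
two consecutive windows; a refractory period of one stride after a
HOVER_SWITCH suppresses the second detection, without which the gesture
would undo itself. The initial mode at takeoff is configurable and
defaults to SSVEP (takeoff leads to hovering and vertical adjustment);
the original protocol never states it.

## Flight-performance metrics

For a task with start-to-gate distance D and gate width W, the Fitts-law
index of difficulty is log₂(D/W + 1); with the study geometry
(D = 4.75 m, W = 3.5 m) this is 1.237 bits. AGAT = total flight time /
gates passed (min/gate); analogous ITR = index of difficulty / AGAT
(bit/min), always computed from the unrounded AGAT; PTC = gates /
(gates + failures), where the two-gate task counts failures as
2·trials − gates (success = 2 gates, half success = 1).

OBUT as written — crossings / (total time / average trial time) —
algebraically reduces to crossings per trial, which contradicts every
published per-subject value; those values all equal crossings per minute
of total flight time. Both variants are implemented; the time-rate
("table") variant is the default. Two published ITR cells (Sub8, Sub9)
and the Average AGAT derive from rounded intermediates; the reproduction
tests carry ±0.02 (ITR) and ±0.01 (AGAT) for exactly those cells. Two
further inconsistencies in the source are recorded but not resolvable
from raw counts: the remote-control ITR appears as both 3.69 and 3.90,
and the claimed average CICSP-over-CSP improvement (+4.45%) does not
match the column-mean difference (3.43).

The paired comparison of CSP vs CICSP calibration accuracies is a routine
two-sample statistic and is out of scope; the per-subject accuracy tables
are shipped as data (`mmbci.datasets`) because they are inputs to the
summary reproduction, not outputs of this package.

## Synthetic EEG

No public recordings exist for this paradigm, so every decoder is
validated on synthetic EEG with the structure it assumes:

- background: per-channel pink noise (1/f amplitude spectrum, DC
  removed), RMS-normalized to `noise_scale`, plus a common 10 Hz mu
  oscillator weighted by a fixed sensorimotor topography (strongest at
  C3/C4, zero outside the 10 motor channels);
- motor imagery: the 9–12 Hz component of the hemisphere contralateral
  to the imagined hand is scaled by (1 − depth) and the ipsilateral by
  (1 + 0.5·depth) — standard ERD/ERS contralaterality; the channel map
  (left-hand imagery ↔ {FC2, FC4, C2, C4, CP2}) is a design choice since
  only the laterality, not a map, is described;
- SSVEP: amp·sin(2πft) + 0.5·amp·sin(2π·2f·t) added to Oz only;
- blinks: raised-cosine (Hann) negative pulses of 0.2 s width subtracted
  from Fp2 only; any smooth unimodal pulse satisfies the detector's
  contract.

The study reports no SNR or amplitude figures, so the generator's
defaults are chosen once as field-realistic calibration-quality values:
10 µV RMS noise, 8 µV mu amplitude, 4 µV SSVEP with harmonic ratio 0.5,
ERD depth 0.8, 120 µV blink troughs. Decoder accuracies on this synthetic
data are therefore calibration checks of the pipeline, not reproductions
of the human-subject accuracy tables: passing them shows the
implementation recovers the structure it was built for at realistic
amplitudes, not that it would achieve any particular accuracy on real
EEG, which additionally contains volume-conducted artifacts, non-
stationarity, eye-movement dipoles and inter-subject variability that the
generator deliberately omits.

Determinism: all randomness flows through `numpy.random.default_rng`
seeded from the configuration, so identical (config, seed) gives
bit-identical recordings, and the full decode pipeline is deterministic.

## Problem sizes and numerical choices

The test suite and the acceptance script run the generator at 250 Hz (the
provided fast mode); every decoder depends only on band ratios relative
to the sampling rate, so results are statistically equivalent to the
1000 Hz default. Simulation studies use 40 trials/class for
motor-imagery recovery, 100 windows for SSVEP, 50 windows for blink
detection, and a 17.5 s five-intent scripted session for the end-to-end
controller check. Degenerate inputs are handled explicitly: zero-power
projections clamp log-variances at log(1e-12) , zero-variance CCA inputs
return ρ = 0 with a warning, and a recording shorter than one window
yields an empty (not erroneous) command stream.

## Known limitations

- No idle/reject class in either decoding mode: every non-blink window
  emits a command, as in the original protocol.
- The blink detector distinguishes conscious double blinks only by depth
  and spacing; spontaneous single blinks are ignored by design, but two
  strong spontaneous blinks 0.45–1.5 s apart would trigger a switch.
- The EDF writer is minimal (int16, per-channel symmetric physical
  range); it is round-trip-tested against mne's reader but does not aim
  at full EDF+ compliance.
- Transport to an actual vehicle, stimulus hardware, and camera
  telepresence are out of scope; the controller stops at the command
  stream.
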