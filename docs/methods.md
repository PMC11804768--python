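# Methods

This note documents the models, numerical choices and limitations behind
posturekit, in the order data flows through the toolkit.

## Devices, frames and units

Two devices measure the same stance simultaneously: a consumer balance
board with four vertical corner sensors (index device, nominal 40 Hz)
placed on top of a laboratory force plate measuring the full
force/moment wrench (reference device, nominal 100 Hz). Everything is
expressed in one internal frame: `ml` = x, positive toward the subject's
right; `ap` = y, positive anterior; z up, right-handed; moments about
the plate origin; COP in cm, forces in N, moments in N·m, time in s.
Units are fixed at the file boundary and never converted by readers.

Sensor spans (43.3 × 23.8 cm), board mass (3.9 kg) and the vertical
offset between plate origin and board surface (5.3 cm) are configuration
values with defaults matching the common hardware, not constants.

## Calibration

The board is calibrated per sensor by a two-point affine map fitted from
a zero-load recording and a recording with a known mass centred on the
board: offset = zero-load channel mean, gain = (m·g/4) / (loaded mean −
offset). The centred-mass assumption distributes the load equally; a
channel whose loaded mean does not exceed its zero mean is a hard error.
Means (not medians) over the full calibration windows are used; the
calibration recording rate is metadata only. Cross-talk between sensors
is not modelled.

## Signal pipeline

1. **Filtering.** Zero-phase low-pass Butterworth, design order 4,
   cutoff 10 Hz, applied forward and backward (`sosfiltfilt`). "Order 4"
   refers to the design order per pass, so the effective magnitude
   response is the squared single-pass response (−6 dB at the cutoff);
   the phase response is identically zero. This matches common
   posturography practice.
2. **Decimation.** Downsampling keeps every k-th sample and requires an
   integer rate ratio (40→20, 100→20); interpolation-based resampling is
   deliberately out of scope. Callers must filter below the output
   Nyquist first.
3. **Alignment.** The two devices run on separate clocks and start at
   different moments. The lag is estimated at the 20 Hz common rate by
   normalised cross-correlation of the two bottom-left sensor signals
   (ties broken toward zero lag; an anticorrelated best match is
   reported with a warning since it indicates a sign-convention
   mismatch). The wrench plate has no physical corner channels, so a
   virtual bottom-left load is reconstructed from the wrench COP by the
   bilinear corner decomposition `F_corner = F(a∓x)(b∓y)/(4ab)` — the
   exact inverse of the board's COP formula. The estimated lag is
   rescaled to each native rate by rounding, the later-starting
   recording wins its head, and both tails are cut to the common
   duration. Resolution is therefore one common-rate sample (50 ms,
   i.e. ±25 ms after rounding); sub-sample alignment is out of scope. A
   lag that is a multiple of 50 ms (such as the 0.65 s used throughout
   the tests) is removed exactly.
4. **Onset and segments.** The stable-stance onset is the first index
   from which total vertical force stays within ±5% of the series
   median for a continuous 2 s — a concrete rule chosen here for a
   criterion usually left informal; it falls back to index 0 with a
   warning. The analysis segment is the central window of the
   post-onset span: 20 s for bipedal, 15 s for unipedal tasks.

Sampling-interval jitter (per-recording SD of Δt in ms, with a group
t-interval across recordings) is reported as a diagnostic but never
corrected: series are treated as uniformly sampled at the nominal rate,
on the grounds that ~1 ms interval noise is negligible against 25/10 ms
sampling periods for these metrics.

## COP computation

Corner board: `ml = a((tr+br)−(tl+bl))/F`, `ap = b((tl+tr)−(bl+br))/F`
with `a, b` the half-spans and `F` the total force. Wrench plate:
`ml = (−my − fx·d)/fz'`, `ap = (mx − fy·d)/fz'` with `fz' = fz −
m_board·g` (the board's dead weight) and `d` the top offset (the
moment-arm correction for shear forces introduced by the stacked board).
Frames with total force at or below a floor (default 50 N) raise an
unloaded-plate error rather than producing 0/0 garbage.

## Sway metrics

Per segment: sample SDs (n−1 denominator — numerically irrelevant at
n = 300–800 but fixed for reproducibility), mean per-axis velocity
Σ|Δx| / ((n−1)/rate), Euclidean pathlength, and the 95% prediction
ellipse area `π·c(n)·√det S` with the small-sample prediction factor
`c(n) = ((n+1)/n)·(2(n−1)/(n−2))·F₀.₉₅(2, n−2)` (a prediction, not a
confidence, ellipse; `c(n) → χ²₀.₉₅(2) = 5.9915`). SDs, velocities and
pathlength are computed at the segment's native rate; the PEA is
computed on the 20 Hz decimated segment, the convention used for
dual-device comparison. A rank-deficient covariance yields area 0 with a
degenerate-ellipse warning.

## Spectra

Welch estimates: Hann window, 5 s windows, 50% overlap, per-window mean
removal, density scaling (cm²/Hz), on the 20 Hz signals; group averages
are bin-wise arithmetic means over participants. Window parameters live
in the run configuration; spectra are meant for qualitative device
comparison (where does the index device carry excess power?), not for
statistical testing.

## Clinimetrics

ANOVA mean squares are computed by explicit sums of squares (one-way:
MSR, MSW; two-way: MSR, MSC, MSE). Single-measure ICCs:

* ICC(1) = (MSR − MSW) / (MSR + (k−1)MSW), one-way random;
* ICC(C,1) = (MSR − MSE) / (MSR + (k−1)MSE), two-way consistency;
* ICC(A,1) = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE)),
  two-way absolute agreement.

CIs are exact F-pivot intervals for ICC(1) and ICC(C,1) and the
Satterthwaite approximation for ICC(A,1); p-values come from
F = MSR/MSW resp. MSR/MSE. Negative estimates are reported as computed,
not truncated. When the three forms differ by less than 0.01 in every
pairwise comparison (agreement at the second decimal), reports carry the
one-way form alone; larger discrepancies flag non-negligible measurement
bias and both two-way forms are reported.

SEM = SD·√(1−ICC) and MDC = SEM·1.96·√2. The SD feeding the SEM is, by
default, the SD of all n·k observations about the grand mean; published
SEM/ICC pairs do not always identify their SD source, so this choice is
configurable (`sd_source="session1"`) and recorded in the report.
Between-device agreement is absolute (reference − index; mean and SD
over subjects) and relative (100·(reference − index)/reference %);
subjects with |reference| below 1e-6 are excluded from the relative part
with a warning. Subjects missing any session are dropped listwise and
counted.

## Synthetic data

Ground-truth sway is a per-axis stationary Ornstein–Uhlenbeck process,
simulated by exact discretisation at a 200 Hz master rate. This is the
simplest mean-reverting Gaussian process whose power concentrates below
~1 Hz, where quiet-stance postural adjustment lives; it is a statistical
stand-in, not a biomechanical claim — it has no inverted-pendulum
dynamics, no intermittent control, and Gaussian increments.

Default study conditions (chosen once): stationary SDs 0.17 cm ML /
0.42 cm AP (typical bipedal eyes-open device means), time constants
1.0 s per axis (spectral corner ≈ 0.16 Hz), subject mass 79.4 kg,
timestamp jitter SD 1 ms (observed interval-SD confidence bounds for
such boards are roughly 0.7–1.3 ms), board channel noise 0.5 N, plate
channel noise 0.05 N, and a broadband ML noise term of 2.0 N SD
high-passed above 2.5 Hz and injected antisymmetrically at sensor level
(left pairs −n/2, right pairs +n/2), i.e. ≈0.06 cm of COP noise at
780 N load — consistent with the millimetre-level noise floor reported
for consumer boards, and injected pre-COP so its propagation through the
force quotient is exercised. The renderer distributes the subject's
weight over the corner sensors by the exact bilinear decomposition, adds
the board's dead weight and the moment-arm terms to the wrench channels,
applies the configured inter-device start lag (the plate starts late)
and jitters timestamps. Noise-free rendering inverts exactly. All
randomness flows from a single seed; equal configurations reproduce
bit-identical recordings.

Cohort simulation draws per-trial ML sway SDs as
`σ_ij = σ₀(1 + u_i + e_ij)` with subject effects `u ~ N(0, b²)` and
session effects `e ~ N(0, w²)`, and realizes the metric as the sample SD
of a 20 s OU segment at the board rate. Because OU samples are strongly
autocorrelated, the segment-SD estimator is itself noisy and biased:
for the AR(1) covariance C and centering matrix A, `E[s²] = tr(AC)` and
`Var[s²] = 2·tr((AC)²)`, giving `Var[s] ≈ Var[s²]/(4E[s²])` by the delta
method. The induced population ICC of the realized metric —
`(q−v)b² / ((q−v)b² + qw² + (1+b²)v)` with `q = E[s²]`, `v = Var[s]` —
is therefore computable in closed form and is reported as
`derived_true_icc`; `solve_within_rel_sd` inverts it so a cohort can be
generated for a target ICC. Simulation confirms the derivation: realized
one-way ICCs match the derived value to within the small-sample
estimator bias (~0.005 at n = 30). The default between-subject relative
SD of 0.35 matches the coefficient of variation of displacement metrics
across healthy adults in published cohort tables.

Direct two-way random-effects matrices (`simulate_two_way_matrix`) serve
the statistics-level recovery checks, where the population ICC(A,1) is
exactly σ²_subject / (σ²_subject + σ²_session + σ²_error).

## Problem sizes and verification

The test suite and `scripts/acceptance.py` use: 500 random matrices
(n ∈ [3,50], k ∈ [2,5]) for ICC oracle equivalence against independent
implementations (agreement ≈ 1e-15); 1000 replicates of n=30, k=2
cohorts at true ICC(A,1) = 0.8 for recovery (mean ≈ 0.79) and 95% CI
coverage (≈ 95%); 10⁵ bivariate normal samples for the prediction-ellipse
Monte Carlo (≈ 18.8 cm² against the asymptotic 18.82); 100 noise-free
trials for lag recovery (0.65 s removed exactly in all of them) and 3–5
for pipeline closure (device metrics equal ideal-device metrics to
machine precision); 20-subject cohorts for the spectral comparison
(index power strictly above reference power in every bin ≥ 2.5 Hz).
These sizes make every check reproducible in seconds while leaving
comfortable statistical margins.

Published SEM→MDC and device-mean→agreement reproductions are limited by
the three-decimal rounding of the source tables: SEM and MDC were
rounded independently, so recomputing MDC from a printed SEM can differ
from the printed MDC by up to `0.0005·(1 + 1.96√2)` ≈ 0.0019 in absolute
terms. Pathlength rows are large enough that this effect is below 0.02%
relative and are checked at that tolerance; all rows are checked against
the rounding bound.

## What passing tests do and do not show

The synthetic generator reproduces the variance structure, bandwidth,
device geometry, clock lag, jitter and noise asymmetry of real
dual-device recordings, so green tests demonstrate that the *machinery*
(formulas, alignment, segmentation, statistics) is correct and
internally consistent. They do not validate the OU model as a model of
human sway, nor device behaviours it omits: sensor nonlinearity and
hysteresis, temperature drift, load-dependent calibration error,
clock *skew* (as opposed to offset), packet loss, or weight shifts of a
restless subject. Real recordings with such artifacts may need the
configurable force floor, onset rule and lag bounds adjusted.

## Known limitations

* Alignment is quantised to the 20 Hz grid; lags off that grid leave up
  to ±25 ms of residual offset (≈1 board sample).
* Velocity and pathlength are computed at native device rates, so the
  two devices' values are not expected to coincide exactly even
  noise-free (different rates sample different amounts of path).
* The relative-agreement statistic is undefined near zero reference
  values and excludes such subjects rather than winsorising.
* ICC CIs assume Gaussian effects; heavy-tailed metric distributions
  (PEA in small segments) may under-cover.
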