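# posturekit

A posturography toolkit: from raw balance-platform force signals to
center-of-pressure (COP) trajectories, sway parameters, and the
clinimetric statistics used to establish concurrent validity and
test–retest reliability of a low-cost device against a laboratory-grade
force plate.

It is written for movement scientists and clinician-researchers who
record quiet-stance balance trials on a consumer four-corner-sensor
balance board (40 Hz, one vertical force per corner) stacked on a
six-component force plate (100 Hz, full force/moment wrench), and who
need a reproducible path from those raw channels to the numbers that go
into a validity/reliability table.

## What it computes

**COP.** For the corner board, with corner forces `tl, tr, bl, br` and
sensor spans `2a × 2b`:

    ml = a · ((tr + br) − (tl + bl)) / F,   ap = b · ((tl + tr) − (bl + br)) / F

with `F` the total vertical force. For the wrench plate, with the board's
dead weight removed from `fz` and the board's height `d` correcting the
shear moment arm:

    ml = (−my − fx·d) / (fz − m_board·g),   ap = (mx − fy·d) / (fz − m_board·g)

**Preprocessing.** Zero-phase 4th-order Butterworth low-pass at 10 Hz,
decimation to a common 20 Hz rate, inter-device lag estimation by
normalised cross-correlation of the bottom-left sensor signals,
stable-onset detection on total vertical force, and selection of the
central 20 s (bipedal) / 15 s (unipedal) analysis segment.

**Sway parameters.** SD of ML/AP displacement (cm), mean velocity per
axis (cm/s), pathlength (cm), and the 95% prediction ellipse area

    PEA95 = π · c(n) · √det S,   c(n) = ((n+1)/n) · (2(n−1)/(n−2)) · F₀.₉₅(2, n−2)

with `S` the 2×2 ML/AP sample covariance (`c(n) → χ²₀.₉₅(2) = 5.9915`).

**Clinimetrics.** The single-measure ICC family from ANOVA mean squares
— one-way random ICC(1), two-way absolute agreement ICC(A,1), two-way
consistency ICC(C,1) — with F tests and 95% CIs; SEM = SD·√(1−ICC);
MDC = SEM·1.96·√2; absolute (reference − index) and relative
(100·(reference − index)/reference %) agreement; Welch power spectra
with group averaging for device comparison.

**Synthetic data.** A seeded Ornstein–Uhlenbeck sway simulator with an
exact dual-device renderer (bilinear corner-load decomposition, device
lag, timestamp jitter, per-device noise including a broadband ML noise
term for the index device), so every stage is testable with known ground
truth and no hardware.

## Worked example

```bash
posturekit simulate --seed 3 --duration 30 --lag 0.65 --out-dir trial/
posturekit preprocess --index trial/board.csv --reference trial/plate.csv \
    --task bipedal --out-dir pre/
posturekit metrics --cop pre/index_cop.csv --task bipedal --out metrics.json
```

The last command prints (seed 3):

```json
{
  "sd_ml_cm": 0.15458996719331747,
  "sd_ap_cm": 0.3860344683669529,
  "v_ml_cm_s": 2.40341642716319,
  "v_ap_cm_s": 2.0936019764766485,
  "pathlength_cm": 70.63878348925078,
  "pea95_cm2": 1.1407743058721733,
  "segment_rate_hz": 40.0,
  "segment_duration_s": 20.0
}
```

i.e. over the central 20 s segment this simulated subject's COP wandered
with an SD of 0.15 cm side-to-side and 0.39 cm front-to-back, travelled
70.6 cm in total, and 95% of future COP positions are predicted inside a
1.14 cm² ellipse. The ML velocity (2.4 cm/s) is inflated relative to the
reference device because the simulated board carries broadband ML sensor
noise — the same signature a real consumer board shows in
low-challenge tasks. `pre/jitter.json` reports the sampling-interval SD
(~1 ms here), and `pre/manifest.json` records config, digests and
warnings for the run. Paired per-subject metric tables then go through
`posturekit validity` / `posturekit reliability` to produce ICC, SEM,
MDC and agreement reports.

The same operations are available as a library
(`import posturekit as pk`): `pk.simulate_sway`, `pk.cop_from_wrench`,
`pk.compute_all`, `pk.icc`, `pk.sem_mdc`, `pk.agreement`, ….

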