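# Methods

## The physical model

An orbital shaker translates its plate, without rotating it, around a
horizontal circle of radius *r* = 0.95 cm at a set frequency *f* (rotations
per second). A device clamped to the plate therefore experiences a
constant-magnitude centripetal acceleration rotating once per cycle, plus
the 1 g gravity reaction. Two frequency-to-acceleration conversions are
provided:

* `as_printed`: *a* = 4π²·*r*·*f*² (the textbook centripetal expression),
* `as_used` (default): *a* = 4π·*r*·*f*², which reproduces the published
  reference anchors for this protocol (4.4 mg at 0.6 Hz, 124.7 mg at
  3.2 Hz, orbit diameter 1.9 cm, g = 980 cm/s²).

The two differ by exactly π at every frequency; both are retained because
the anchors and the textbook formula cannot both be right, and the package
does not guess which the protocol's authors intended. g defaults to
980 cm/s² (9.8 m/s²) because that value reproduces the anchors to one
decimal; it is configurable.

Trial timelines follow the validation protocol: the validity trial is a
15 s rest, seven 120 s oscillation blocks at 3.2, 2.8, 2.4, 1.9, 1.5, 1.0,
0.6 Hz, and a closing 15 s rest (870 s total); a reliability batch is a
15 s rest, *n* back-to-back 120 s trials at one speed, and a closing 15 s
rest (630 s for five trials). The bookend-rest layout is used because it is
the only reading consistent with the published 10 min 30 s batch duration;
a rest-per-trial variant is available. Spin-up/spin-down transients between
blocks are not modelled — each block is treated as steady state, and the
middle-minute extraction (below) discards the boundary minutes anyway.
Seconds are 0-based half-open intervals [s, s+1) on the protocol clock.

## Mounting geometry

ENMO depends only on the vector norm of the measured specific force, and a
rigid rotation of the whole signal leaves the norm unchanged — so "mounting
orientation" can only matter through the angle between gravity and the
orbit plane. The simulator therefore applies the mounting rotation to the
orbital (motion) component while gravity stays on the device z-axis,
which is equivalent to tilting the orbit plane relative to gravity:

* **perpendicular** (identity rotation): signal (a·cosθ, a·sinθ, 1), ENMO
  constant at √(1+a²) − 1 ≈ a²/2 — at most ~7.7 mg at 3.2 Hz;
* **in-plane** (90° tilt, the default): norm √(1 + 2a·cosθ + a²), ENMO
  oscillating once per cycle with cycle mean ≈ a²/4 and RMS ≈ a/√2.

The in-plane geometry is the default because its per-second RMS ENMO
(≈ 88 mg at 3.2 Hz) is the magnitude regime the validation literature
reports for devices on a shaker, whereas the perpendicular geometry's
few-mg signal is not. An `in_plane_fraction` between 0 and 1 follows from
any intermediate rotation.

A closed-form/quadrature oracle (`ideal_enmo_stats`) gives the cycle-mean
and cycle-RMS ENMO for any tilt; the uniform-grid quadrature over one cycle
is spectrally accurate for this smooth periodic integrand. The seven
protocol frequencies all complete an integer number of cycles in 60 s, so
middle-minute averages of noiseless simulated streams match the oracle
essentially to machine precision regardless of the (seeded, per-segment)
random phase; the fidelity tests require 0.5% relative agreement.

## The device model

Each simulated device applies, in order: mounting rotation, per-axis gain,
per-axis bias, additive white Gaussian noise, hard clipping at ± the
dynamic range, and whole-second dropout. Brand presets carry the recorded
sampling rates (ActiGraph and Apple 100 Hz, Fitbit 50 Hz, Garmin 25 Hz)
and dynamic ranges (±8 g ActiGraph, ±4 g Fitbit; ±8 g is a package default
for Apple and Garmin, whose ranges are not published). Defaults:

* noise σ = 0.01 g per axis — a typical MEMS accelerometer noise scale;
* per-device gain ~ N(1, 0.001) and bias ~ N(0, 1 mg) per axis in the
  study configuration — sized as post-factory-calibration residuals.
  This is deliberate: the mean-aggregate ENMO of a clean orbital signal is
  only 0–4 mg, so a net negative z-calibration of more than a few mg
  pushes *every* per-second mean below zero and triggers the faulty-device
  exclusion rule on a healthy unit. With ~1 mg residuals the rule fires
  essentially only on the simulated fault.
* `fault_mode="all_negative_enmo"` halves the clean signal (norm ≈ 0.5 g),
  so every sample's ENMO is negative — the signature of the faulty unit
  the exclusion rule exists for;
* dropout removes whole 1 s blocks (default 0.05/s for Fitbit only), so
  downstream listwise handling of missing seconds is exercised. The real
  Fitbit missingness count is not derivable and is not targeted.

No anti-alias filter is simulated (none is documented); at 25 Hz sampling
the 0.6–3.2 Hz motion is far below Nyquist. Firmware behaviours (onboard
filtering, idle modes, timestamp jitter), temperature and battery effects
are out of scope. Simulator parameters are structural stand-ins — the
noise spectra and orientations of the real devices are not published — so
passing tests demonstrate the pipeline and the statistics, not calibrated
replicas of any physical device.

## Signal pipeline

Per-sample ENMO is (‖(x,y,z)‖ − 1)·1000 mg with negatives retained: the
exclusion rule "every ENMO value below zero" presupposes representable
negative ENMO, so GGIR-style truncation at zero is available but off by
default. Per-second aggregation takes the arithmetic mean and the RMS of
the per-sample ENMO within each whole second (RMS of ENMO, not per-axis
RMS); partial boundary seconds are dropped, absent seconds stay absent (no
imputation). Middle-minute extraction keeps seconds [30, 90) of each 120 s
oscillation block — the unique centred minute — giving 60 epochs per block,
420 per device through the validity trial, and the count law D devices →
D × 420 rows. Streams are assumed pre-aligned to the protocol clock; a
nominal recording span on each stream lets coverage checks tolerate
dropout at the stream tail.

## Statistics

**ICC(2,1).** Two-way random effects, single measure, absolute agreement,
from the two-way ANOVA mean squares; 95% CI by the McGraw–Wong exact-F
method. Subjects are middle-minute seconds, raters the five co-mounted
devices; the two five-device batches per brand are stacked as additional
subjects with columns indexed by clamp position 1–5, yielding one ICC per
brand per aggregation. The source protocol never states how ten devices
tested five at a time produce a single ICC — this stacking is this
package's documented choice, and a batch left undersized by a device
exclusion is omitted from the stack rather than padded. Rows with missing
values are deleted listwise. Interpretation bins are lower-inclusive:
< 0.50 poor, [0.50, 0.75) moderate, [0.75, 0.90) good, ≥ 0.90 excellent
(the verbal bin definitions in the literature leave the boundaries
ambiguous). Constant matrices raise (ICC undefined); a perfect-agreement
matrix returns a degenerate CI at 1.

**Pearson r / Lin's CCC.** CCC uses population (1/n) moments per Lin's
original estimator; its CI applies the Fisher z-transform with the
corrected (2000) asymptotic variance — the 1989 printing's variance has
known typographical errors. Degenerate cases (|ρ_c| = 1, r = 0, a constant
series) collapse the CI onto the estimate. CCC interpretation: < 0.20
poor, ≥ 0.80 excellent, with the conventional fair/moderate/good ladder
between; |CCC| ≤ |r| always (CCC = r·C_b with C_b ∈ (0, 1]).

**Error and bias.** MAE = mean |device − reference|; mean bias with 95%
limits of agreement bias ± 1.96·SD(differences). The published tables
label LoA-width intervals "95% confidence intervals"; both the LoA and the
SE-based CI of the mean are computed and separately labelled, with LoA
used for table reproduction. Validity statistics pool all middle-minute
seconds across devices and frequencies per brand (pairwise-complete);
per-speed summaries give MAE and bias within each frequency with standard
errors.

**TOST.** One-sample two one-sided t-tests on the pooled per-second
differences per brand, α = 0.05, so the decision matches the 90% CI lying
strictly inside (−bound, +bound). The default bound is the fixed 6.3 mg
half-width used in the published table; the stated "10% of the shaker
speed" rationale gives ≈ 5.4 mg when applied to the mean reference over
the seven speeds (as-used conversion), and the discrepancy is documented
rather than reconciled. Pooling per-second observations ignores
within-device clustering — the per-second differences are not independent,
so the TOST (and CCC) CIs are anti-conservative for the synthetic fleet in
the same way they are for the original design; this is mirrored, not
fixed. Zero-spread inputs collapse the CI onto the mean and the interval
rule decides.

## What the synthetic study does and does not show

The default study configuration (ten devices per brand, one faulty
ActiGraph, Fitbit dropout, seed-controlled) reproduces the *derivable*
structure of the validation design: the reference anchors, the 870 s and
630 s timelines, the 80-trial reliability bookkeeping, the 4,200 / 3,780
observation counts, and a full Tables-1/2/3-shaped report. It does not —
and cannot — reproduce the published device-specific coefficients, which
depend on real recordings: under the clean orbital signal model the mean
aggregation carries almost no signal (cycle-mean ENMO 0–4 mg, so its
validity statistics are dominated by calibration noise), while the RMS
aggregation shows the strong correlations and negative biases
qualitatively consistent with the published pattern that RMS is the more
reliable aggregate. Conclusions about real devices require real streams,
which the `ColumnDialect` readers ingest into the identical pipeline.

## Numerical and testing choices

* ICC is verified against an independently coded brute-force two-way
  ANOVA (explicit loop sums) to 1e-10 on random matrices, and against
  pingouin's ICC(A,1) on a fixture; CCC against direct moment computation.
* TOST type-I calibration: with the true mean difference exactly on the
  bound, the declaration rate over 10⁴ seeded replicates (n = 100) must be
  0.05 ± 0.01.
* ICC parameter recovery: with known variance components
  (σ_r², σ_c², σ_e²) = (1.0, 0.3, 0.2) the estimator must recover
  σ_r²/(σ_r²+σ_c²+σ_e²) within 0.02 at n = 10⁴ subjects. Because only
  k − 1 degrees of freedom inform the rater (column) component, a single
  matrix's estimate scatters more than 0.02 regardless of n; the check
  averages 100 replicate matrices (k = 10), which tests the same
  consistency property with the column noise averaged out.
* Problem sizes throughout (10-device fleets, 25–100 Hz, 10⁴-replicate
  calibrations) are chosen so the full suite runs in well under a minute
  of CPU apiece while leaving Monte-Carlo error comfortably inside each
  tolerance.
* Determinism: every random draw descends from a declared seed via
  `numpy` seed sequences; identical configs produce byte-identical epoch
  tables, and the run log records version, config hash, seeds, conversion
  variant and exclusions.

## Known limitations

* The simulator's device parameters are structural, not calibrated; brand
  differences in the synthetic study come only from sampling rate, range,
  dropout and the seeded calibration draws, so simulated brands look more
  alike than real ones.
* The clean orbital signal model under-drives the mean aggregation (see
  above); real shaker recordings contain harmonics and clamp vibration
  that raise mean ENMO substantially.
* ICC batch stacking and TOST pooling are documented design choices where
  the original analysis is under-specified; alternative choices (e.g.
  per-batch ICCs, cluster-robust TOST) would give different numbers.
* The optional XLSX ingestion of externally aggregated tables requires a
  user-supplied column mapping; no proprietary format is parsed.
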