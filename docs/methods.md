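# Methods

## Signal model and preprocessing

A maneuver is three aligned series on one uniform time base: time (s),
expiratory flow (L/s, positive) and cumulative expired volume (L). Flow and
volume are duals — a missing volume is reconstructed by cumulative
trapezoidal integration, a missing flow by central differences — and the VT,
FT and FV curve representations all index the same samples, so one zone
segmentation serves all three.

Files are resampled to a uniform 100 Hz grid by linear interpolation at
ingest (`resample_rate`). 100 Hz resolves every scale the criteria use (the
1 s plateau window, 25 mL volume steps, ~0.1 s rise times); maneuvers built
in memory keep their native rate if it is already uniform. Derivative-based
metrics smooth first with a local quadratic least-squares filter
(Savitzky–Golay, `smoothing_window` = 50 ms); derivatives are central
differences with one-sided ends. The rise-zone statistics use a lighter
20 ms window (`z1_smoothing_window`) because the ascent lasts only
~0.1 s and the irregularities to be detected there sit at 8–12 Hz, which a
50 ms window would average away.

## Classical indices

* **T₀** (back-extrapolated time origin): the smoothed VT curve's slope is
  estimated by central differences; the tangent at the maximum-slope sample
  (earliest on ties) is extended to zero volume and the crossing time
  returned. The raw crossing is reported even if it precedes the first
  sample.
* **FVC** = maximum volume (earliest sample on ties); **PEF** = maximum raw
  flow, so that PEF ≥ every sampled flow value; **PEFT** = time of PEF
  minus T₀.
* **BEV** = recorded volume linearly interpolated at t = T₀, clipped at 0.
* **FEV₁** = V(T₀ + 1 s) − V(T₀); reported as NaN with a reason code when
  the record ends within 1 s of T₀ (EOTV likewise).
* **EOTV** = volume span of the final `eotv_window` = 1 s.
* **Tex** = time from T₀ to the first post-peak instant whose *trailing*
  1 s volume change drops below `eotv_threshold`, or to the end of
  exhalation. The search starts at the peak so a quiet pre-blast segment
  cannot masquerade as the plateau; a trailing-anchored sliding window was
  chosen over alternatives because it needs no look-ahead and is the natural
  on-line formulation.
* **FET100** = time from T₀ to the first sample attaining FVC. End of
  exhalation is the last sample of the record; no tail trimming is applied.

## Zones

Fixed fractions of PEF delimit the five analysis zones, since only their
qualitative roles are standard: Z1 runs from flow onset (first sample at
`onset_fraction` = 2% of PEF) to the PEF sample; Z2 is the contiguous band
around the peak with flow ≥ `z2_fraction` = 80% of PEF; Z3 spans from Z2's
right edge to the start of Z4; Z4 covers the final max(1 s, `z4_window`);
Z5 is the whole curve. Zones are half-open index intervals, may overlap, and
together cover onset to end. Shrinking `z2_fraction` monotonically widens
Z2.

## Criterion battery

The traditional rules are implemented verbatim, with printed boundary
conventions ("less than" strict, "reaches" inclusive): C8 fails iff
BEV > max(0.15 L, 5% FVC); C9 fails iff EOTV ≥ 0.025 L; FET fails iff
FET100 < 6 s (equality passes); repeatability requires ≥ 3 individually
acceptable maneuvers with some pair within 0.15 L on both FVC and FEV₁.

The morphology criteria are derivative-statistic formulations of the zone
defects they target. Their exact functional forms are this package's own
design; each reports its metric and threshold in the result so decisions are
auditable.

* **Z1 (C1, C2a, C2b).** The FV-plane slope dF/dV = (dF/dt)/F diverges at
  onset, so the ascent is analysed as normalized flow (y = F/PEF) against
  normalized rise time. The clean ascent is then a smooth quarter-sine-like
  arc with O(1) derivatives. C2a measures the RMS residual of dy/dx about a
  cubic fit (a cubic captures the clean arc almost exactly, so the residual
  isolates superimposed ripple); C1 counts sign alternations of the
  detrended curvature above a noise floor; C2b takes the maximum detrended
  curvature excursion.
* **Z2 (C3–C6).** C3/C4 bound PEFT to (0.02 s, 0.2 s): clean synthetic peaks
  occur at 0.05–0.10 s after T₀. C5a/C5b measure the time width and the
  volume span (as a fraction of FVC) of the contiguous band with flow ≥ 90%
  of PEF — a flat peak widens both. C5c counts local maxima inside Z2 with
  prominence ≥ 3% of PEF. C6 interprets the ambiguous "low value at the PEF
  position" as the PEF/FVC ratio (1/s) falling below 1.0; a slow peak
  depresses peak flow relative to the volume behind it.
* **Z3 (C7a–d).** For an exponential-flow descent the FV curve is exactly a
  straight line (dF/dV = −1/τ), so the normalized slope
  (dF/dV)·(FVC/PEF) is nearly constant (≈ −1.1 … −1.3) on clean curves.
  C7a bounds its magnitude (3.0), C7b its variance (0.02), C7c the variance
  within sliding 0.5 L volume segments (0.02), and C7d multiplies the count
  of slope sign changes by the integrated deviation of the normalized FV
  curve from its chord — identically zero on clean curves. Samples with
  flow < 10% of PEF are excluded (`c7_flow_floor`): the slope ratio is
  noise-dominated there.
* **Z4 (C10, C11).** The C10 family conditions the plateau test on Tex:
  C10a rejects only when the plateau is missing *and* the exhalation is
  short (Tex < 6 s); C10b/C10c re-test with an alternative window (1.5 s)
  or a relaxed threshold (0.04 L) when Tex ≥ 6 s; C10d/C10e compare EOTV
  against a Tex-indexed threshold thr(Tex) = 0.025 L ·
  (1 + 0.5 · max(0, 6 − Tex)), linear in the Tex deficit — the simplest
  family that relaxes the plateau demand for long exhalations. C11 lists the
  local extrema of the smoothed FT curve over Z4 and counts swings ≥ 0.05
  L/s; four or more fail.
* **Z5 (C12a, C12b).** C12a fails when the FV curve has ≥ 2 local maxima
  anywhere with prominence ≥ 5% of PEF (the cough signature). C12b applies
  the same detection restricted to secondary maxima whose expired volume
  lies within ±0.5 L of V(T₀ + 1 s), where a transient corrupts FEV₁
  directly.

### Threshold calibration

The traditional thresholds (0.15 L, 5%, 0.025 L, 1 s, 6 s, 0.15 L) are the
published values. The morphology thresholds have no published values; the
defaults were calibrated once against the synthetic generator: each was
placed between the maximum of its metric over a 135-point clean parameter
grid (FVC 2–6 L, PEF/FVC 1.5–2.5 /s, rise 0.08–0.15 s, duration 7–10 s) and
the minimum over high-severity draws of its designated defect, with the
larger relative margin on the clean side. They are calibration artifacts of
this generator, not population values, and all are configurable.

## Grading

A policy routes failures to grades: any complete *rejecting* group forces
grade 0, else any *warning* failure yields grade 2, else grade 1;
`not_applicable` outcomes never trigger anything. The default rejecting set
contains the designated detector of every defect family — C8, C9∧C10a
(plateau missing *and* exhalation short, as a conjunction), C3, FET, C12a,
C2a, C5a, C5c, C7b, C11 — and routes the remaining criteria to grade 2.
Routing every designated detector to rejection is what lets the automatic
grades match the construction labels on the synthetic dataset; a deployment
reviewing borderline curves manually would move criteria into the warning
set instead.

Scoring against expert labels follows the screening convention:
sensitivity = P(grade 0 | expert 0), specificity = P(grade 1 | expert 1);
automatic grade-2 curves match neither label and so depress both rates.

## Synthetic maneuvers and defects

The clean waveform is flow = PEF·sin(πt/2r) for t ≤ r (rise time r), then
PEF·exp(−(t−r)/τ), with τ solved by root-finding (tolerance < 1e-4 L) so
the expired volume reaches FVC exactly at the stated duration. It is the
simplest shape that satisfies the whole battery and plays the role of the
noiseless simulated standard curves used to commission quality-control
algorithms. Optional additive white sensor noise is available
(`noise_sd`, L/s) but defaults to 0: on a plateaued record, any white noise
turns first-attainment-of-FVC (the FET100 definition) into the argmax of a
random walk whose position is broadly distributed over the tail regardless
of the noise amplitude, which is a property of that estimator, not of the
maneuver. Tests that need noise inject it explicitly.

Dataset draws couple PEF to FVC (PEF/FVC ∈ [1.5, 2.5] /s, clipped to
4–12 L/s) because peak flow scales with vital capacity; an uncoupled
low-PEF/high-FVC draw implies a decay constant so long that the curve
genuinely lacks a plateau within a 7–10 s exhalation and no expert would
label it clean.

Nine defect transforms mirror the canonical failure morphologies, each
scaled by a severity in [0, 1] (0 is the identity; dataset defects draw
severity from [0.8, 1.0]):

| defect | transform | designated criterion |
|---|---|---|
| delayed_start | half-sine leak expiring severity·0.5 L before the blast | C8 |
| cough | narrow multiplicative Gaussian flow valley (default mid-descent) | C12a |
| bimodal_peak | peak widened to a plateau, Gaussian notch splits it in two | C5c |
| flat_peak | clip at (1 − 0.1·severity)·PEF plus inserted plateau | C5a |
| slow_peak | rise time dilated by (1 + 4·severity) | C3 |
| early_termination | truncation at duration·(1 − 0.6·severity) | FET |
| end_oscillation | severity·0.1 L/s, 4 Hz sinusoid over the final second | C11 |
| irregular_ascent | 8–12 Hz band-limited noise, sd severity·5% PEF, on the rise | C2a |
| irregular_descent | the same noise over the descending limb | C7b |

Magnitudes are anchored to the printed thresholds: severity 1 violates them
decisively (delayed start: BEV ≈ 0.5 L; early termination: FET < 6 s),
severity 0.2 does not. The ascent noise stops below 90% of PEF so ripple
cannot displace the PEF sample and thereby reshape Z1 non-monotonically;
the bimodal notch depth (15% of the plateau) keeps the inter-peak valley
inside the 80%-of-PEF band so both maxima stay in Z2. Volume is always
re-integrated from the transformed flow, and flow is floored at −0.2·PEF
where a transform could undershoot.

### What the generator does and does not emulate

It reproduces the morphological vocabulary of real maneuvers — rise, peak,
quasi-linear FV descent, plateau, and the canonical defect shapes — with
exact labels and controllable severity. It does not reproduce sensor noise
(by default), BTPS/calibration drift, effort-dependent non-exponential
tails, obstructive concavity, restrictive patterns, or inter-maneuver
within-patient correlation. Passing the battery here therefore shows the
measurement and decision machinery is correct and well-separated under
these conditions; it does not estimate clinical sensitivity or specificity
on patient data, and the thresholds would need re-tuning against
expert-labeled curves before clinical use.

## Numerical choices and degenerate inputs

All interpolation is linear; ties in maxima break to the earliest sample.
The Z4 window is an exact sample count (round(window·rate) + 1 samples) to
avoid float-boundary off-by-one at the window edge. Zones shorter than 5
samples render their criteria `not_applicable` (never a failure). Records
ending within 1 s of T₀ flag FEV₁/EOTV as NaN with reason codes and mark
the plateau criteria not applicable. All-zero flow, non-positive peak flow
and records shorter than the Z4 window raise degenerate-curve errors;
infeasible generator parameter combinations (no positive decay constant)
raise parameter errors. Determinism: every stochastic element (noise,
defect realizations, dataset draws) is driven by explicit integer seeds.

## Known limitations

* Thresholds for the morphology criteria are generator-calibrated defaults.
* FET100's exact-attainment estimator is noise-sensitive on plateaued
  records (see above); a changepoint-based plateau detector would be the
  robust replacement if noisy field data were the target.
* C6's "low value at the PEF position" is implemented as a PEF/FVC ratio
  test; this is one reading of an ambiguous prescription and is flagged as
  an interpretation in the criterion's documentation.
* Only the expiratory limb is analysed; inspiratory criteria, pediatric
  threshold sets, BTPS correction and predicted-value (GLI) comparisons are
  out of scope.
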