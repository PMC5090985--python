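# Methods

This note documents the models, estimators and numerical choices behind
`xlf`, the assumptions they rest on, and what the synthetic-data tests do and
do not demonstrate about real data.

## Signal model

The x-ray transmission of the chest region oscillates with breathing: at peak
inspiration the air-filled lung attenuates less, so transmission rises.  For
a movie of frames at a fixed rate, with pooled lung-ROI mean transmission
L(t), background mean B(t) and its time average ⟨B⟩, the x-ray transmission
function is

    XTF(t_k) = (L(t_k) − B(t_k)) / ⟨B⟩ .

Normalizing by the *average* background (not per-frame B) makes the XTF
unitless and cancels any global detector/tube gain, while per-frame
tube-intensity fluctuations still enter through the numerator difference.
Frame times are uniform, t_k = k/rate; left and right lung ROIs are pooled
into one area-weighted mean so each scan yields one XTF.

Numerically the ratio is evaluated as
`T·(aB·SL − aL·SB) / (aL·ΣSB)` from exact ROI pixel sums (float64
accumulation).  This single-division form is algebraically identical to the
definition, and for integer-valued detector counts every intermediate is
exact, so a constant gain g rescales numerator and denominator by exactly g
and the quotient is bit-for-bit unchanged.  The documented offset behavior
follows from the definition: adding a constant c to every pixel leaves the
numerator unchanged and rescales the XTF by ⟨B⟩/(⟨B⟩+c).

## Detrending

Slow drift (tube warm-up, anesthesia depth) is modeled as an additive
polynomial of order ≤ 2.  The pipeline: (1) centered moving average of the
XTF, window 200 samples (≈6.7 s at 30 frames/s — long against the 1.4 s
breath, so breathing is averaged out), reflect-padded to preserve length;
(2) ordinary least-squares polynomial fit, on time in seconds centered at the
trace midpoint for conditioning, using only the filter's interior samples
(where no padding enters); (3) inversion of the filter's action on
polynomials; (4) subtraction of the recovered trend from the original XTF.

Step (3) matters: a uniform filter maps a polynomial p(t) to mean_j p(t+δ_j)
over its window offsets, which on power-basis coefficients is an
upper-triangular moment map (e.g. it adds a·m₂ to the constant term of a
quadratic a·t²+…, m₂ the window's second moment).  Fitting the smoothed
series and subtracting the fit directly would therefore leave a constant
residue on a purely quadratic input.  With the moment map inverted, any
polynomial input of degree ≤ the fit order is annihilated to machine
precision, and detrending is exactly idempotent (both properties are tested).
The window's first moment is likewise accounted for, so even window lengths
(the default 200 included) introduce no half-sample bias.

Detrending subtracts the trend's constant term along with the drift, so
fitted b5 values are expressed relative to the detrended baseline.  Within a
study this is a common offset; comparisons between scans and groups are
unaffected.

## Breath detection

The scan line sits at mean + 0.33·SD of the trace (sample SD, n−1
denominator; 0.33 taken literally rather than 1/3).  Breathing events are
maximal runs of samples *strictly* above the line; run boundaries are refined
to the linearly interpolated crossing times of the bracketing sample pair.
Two guards keep events interpretable: runs touching the first or last sample
are incomplete breaths and are discarded, and runs with fewer than five
interior samples are rejected (a cubic fit needs at least five points to
leave a residual; shorter runs at this threshold are noise).  Detection is
deliberately elementary and is verified against an independent brute-force
run finder on random traces.

## The shifted-cubic breath model

Each event is modeled as P(x) = b2·(x−b1)³ − b3·(x−b1)² − b4·(x−b1) + b5 on
normalized event time.  Two conventions required a decision:

* **Orientation.**  b1 is the shift of the breathing-peak maximum and must
  *increase* when the relative inspiration time shortens (its physiological
  reading as an expiratory-limitation marker, and the direction in which the
  inflamed group differs from controls).  The model is therefore expressed in
  reversed normalized event time — x runs 1→0 from event start to end — so
  that an earlier peak means a larger b1, and t_in[%] = 100·(1−b1).

* **Identifiability.**  A cubic has four degrees of freedom; jointly fitting
  five parameters is underdetermined.  The fit is staged and deterministic:
  b1 is initialized at the position of the maximum sample (ties broken toward
  the earlier sample), the remaining four coefficients are ordinary least
  squares on the basis {(x−b1)³, −(x−b1)², −(x−b1), 1}, and b1 is then
  refined once to the stationary maximum of the fitted cubic (re-estimating
  the coefficients at the refined center).  When the true peak lies on a
  sample and the data are noiseless the refinement is an exact no-op, so
  model-generated events are recovered to machine precision; under detector
  noise it replaces the multi-sample jitter of a raw argmax on a flat peak
  (which at 5% noise can wander several samples) by the far steadier
  stationary point of the whole-event fit.  The refinement is only accepted
  inside the open unit interval; otherwise the argmax stands.

The two interpolated boundary crossings are stored with the event and define
its duration, but are excluded from the least-squares fit: they are artifacts
of linear interpolation at the scan line, not measurements, and carry an
O(h²) systematic error that would otherwise contaminate the coefficients.

Per-scan summaries average b1…b5 and t_in over all events and add the
respiratory rate (events per covered trace duration — span plus one sample
interval, so a 1024-sample scan at 30 frames/s is 34.13 s and 24 events give
42.19 BPM), the extrema of the first central-difference derivative (per
second), and the mean event maximum above the scan line.

For plethysmography-style pressure traces an optional zero-phase 4th-order
Butterworth band-pass (0.5–20 Hz, applied forward-backward after mean
removal) provides the equivalent preprocessing; the same event detection and
summary metrics then apply.

## Statistics

Welch's unpaired two-sided t-test with Welch–Satterthwaite degrees of
freedom, flagged at p < 0.1 and p < 0.05.  No multiple-testing correction is
applied by default (matching common practice in this assay); Holm step-down
adjustment is available behind a flag.  Degenerate inputs follow documented
conventions: two zero-variance samples give p = 1 when means agree and p = 0
otherwise.  The implementation is validated against an independent reference
(1e-10 in t, 1e-8 in p) and its null rejection rate at n = 6 vs 6 is checked
to be ≈5%.

Dose–response analysis pairs each animal with its own 0 mg/ml baseline:
relative change = 100·(v − v₀)/v₀ per animal, parameter and dose, with a
per-dose Welch test of the changes against the identically-zero baseline
changes.  This per-animal contrast is this package's defined construction for
"change relative to baseline".

## Synthetic data

The generator emulates the acquisition protocol: 1024 samples at 30 Hz
(34.13 s) and one breathing event per 1400 ms, i.e. 24 complete events per
scan at defaults.  Each cycle consists of an **active pulse** over half the
cycle (`active_fraction = 0.5`) followed by an end-expiratory baseline —
anesthetized mice rest between breaths, and this is what lets the scan line
separate events near the pulse base rather than across their tops.

The pulse is the analysis model itself: a cubic with a stationary maximum
(the b4 = 0 case), so exact recovery is well defined.  Its four degrees of
freedom are pinned by: value −d·A at both window edges (the inter-breath
baseline, continuous join; edge depth d = 0.4 by default), peak value A
(`peak_amplitude`), and a stationary maximum at the inspiration fraction of
the window.  Peak positions are snapped to the sample grid so the true
maximum is a sample point.  A "steepness" control acts through the effective
edge depth ((1+d)·s − 1, clipped ≥ 0.05): a deeper peak-to-baseline drop
steepens the peak at constant amplitude.  Quadratic additive drift and
i.i.d. Gaussian detector noise are added last and are not part of the ground
truth.

**Ground truth frame.**  True parameters are expressed in the detection frame
of the clean (noise- and drift-free) trace: if the clean-trace crossings of
an event are (t0, t1) and the nominal pulse window is D long, the generating
cubic re-expands over [t0, t1] by a pure affine coefficient transform
(β = (t1−t0)/D): b2 = −c₃β³, b3 = (−Q″(f)/2)·β², b4 = 0, b5 = A,
b1 = (t1 − t_peak)/(t1 − t0).  No fitting enters the ground truth; the
least-squares path is checked against closed-form algebra.

The stack simulator forward-models frames as background B₀·g(t) and lung
B₀·g(t)·(1+s(t)) with an optional linear tube-gain drift g and Gaussian pixel
noise, so that XTF extraction reproduces s(t) exactly at zero noise and unit
gain.  The cohort simulator draws per-animal amplitude, steepness and
inspiration-fraction multipliers from lognormal(0, 0.08) (multiplicative,
positive — physiological) around group presets chosen for the disease's
effect directions: controls (amplitude 1.0, inspiration 0.45, steepness 1.0),
inflamed (0.6, 0.35, 0.85 — less air, slower exchange, shortened relative
inspiration), treated (0.85, 0.41, 0.95 — intermediate, amplitude closest to
healthy).  The methacholine simulator holds each animal's physiology fixed
across doses and applies dose-wise steepness factors (1, 0.95, 0.88, 0.78)
and inspiration factors (1, 0.97, 0.94, 0.90) — a monotone bronchoconstriction
ramp.

**What the simulations do not show.**  Pulses are drawn from the fitting
model, so exact-recovery results demonstrate correctness of the estimator,
not robustness to waveform mismatch (an asymmetric real breath is not a
cubic; sniffing, cardiac motion, body movement and per-frame ROI misalignment
are absent).  Noise is i.i.d. Gaussian, not correlated detector noise or
scatter.  Effect-direction results show the statistical pipeline resolves
effect sizes of the simulated magnitude at n = 6 — not that real cohorts have
those magnitudes.

## CT quantification

Phase-contrast CT volumes (δ-value maps, 9 µm voxels by default) are
quantified in axis-aligned cubic VOIs (2 mm edge; edge in voxels =
round(edge_mm·1000/voxel_size_µm)).  Voxels above a threshold are non-air
(soft tissue and liquids): vol_ratio is their fraction of the VOI and
mean_delta their mean value; an all-air VOI reports mean_delta as NaN, never
zero.  The default threshold is Otsu's method on the global volume histogram,
with a manual override for reproducibility.  vol_ratio is invariant under any
strictly increasing intensity transform with a correspondingly transformed
threshold.

Automatic placement of n = 8 VOIs in the peripheral lung is a deterministic
greedy procedure: candidate cubes on a regular grid (stride = half edge)
whose centers fall in the outer 30% of the mask by Euclidean
distance-to-boundary, ranked by in-mask fraction (ties by origin), accepted
while non-overlapping.  "Peripheral" has no canonical definition at this
resolution; the 30% shell is this package's operationalization, and manually
supplied VOI lists remain the primary path.  δ-values are reported in
absolute terms; a relative δ normalization requires a user-designated control
group.

## Defaults at a glance

| parameter | default | meaning |
|---|---|---|
| frame rate | 30 Hz | acquisition rate; 1024 frames ≈ 34.13 s |
| breath period | 1400 ms | one event per cycle under anesthesia |
| active fraction | 0.5 | fraction of the cycle occupied by the pulse |
| inspiration fraction | 0.45 | relative time to peak within the pulse |
| edge depth | 0.4 | inter-breath baseline at −0.4·amplitude |
| detrend window / order | 200 samples / 2 | drift model |
| scan line | mean + 0.33·SD | event detection threshold |
| noise SD | 0.02 | detector noise in XTF units |
| cohort variability | lognormal σ = 0.08 | inter-animal spread |
| band-pass | 0.5–20 Hz, order 4 | plethysmography preprocessing |
| VOI edge / count | 2 mm / 8 | CT quantification |

## Known limitations

* Fixed ROIs: no motion correction or per-frame ROI tracking; gross body
  movement corrupts the XTF.
* The five-parameter printed model is resolved by fixing b1 to the peak
  position; a different (nonlinear, degenerate) resolution would yield
  different b1/t_in numerically, though not their ordering across groups.
* Detrending assumes drift is polynomial after smoothing; steps or abrupt
  gain changes are not modeled.
* b5 is measured relative to the detrended baseline (see Detrending).
* The CT module quantifies given volumes and masks; it does not segment the
  lung or reconstruct/phase-retrieve raw projections.
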