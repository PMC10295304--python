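# Methods

## Signal model

A breathing rat seen from above presents a thorax/abdominal region whose
projected area oscillates at the respiratory frequency. The camera branch
models the per-frame segmented area as

    R[n] = A(t_n) + m[n] + e[n]

where `A(t)` is the true area, slowly amplitude-modulated by breathing in
the 1–3.3 Hz band (60–200 breaths/min), `m[n]` is a motion/tracking
nuisance component and `e[n]` broadband noise. The key assumption,
inherited from linear denoising of remote-photoplethysmography signals,
is that the tracking nuisance is *linearly* expressible in the region's
center-of-mass (COM) trajectory: translation of the animal does not
change its true area, but it drags segmentation and cropping errors with
it. Collecting the linearly detrended COM x/y series and their first
differences as columns of `Q` (each column re-detrended so every
regressor has zero best-fit line), the denoised signal is the orthogonal
projection onto the complement of that noise subspace:

    Z = R − Q (QᵀQ)⁺ Qᵀ R

The pseudoinverse keeps the projection defined when `Q` is rank-deficient
(a motionless animal yields all-zero columns, and then Z = R exactly).
Projection is idempotent and leaves QᵀZ = 0 to numerical tolerance; both
are asserted as tests.

`Z` is then band-passed with a second-order Butterworth filter, 1–3.3 Hz,
applied forward–backward. Zero-phase filtering is a deliberate choice:
the rate estimator consumes crest *timing*, and a causal filter's group
delay would bias `d_peak` at band edges. The zero-phase magnitude
response is the square of the single-pass response, so each −3 dB corner
becomes a gain of 0.5; the tests verify both edges against the analytic
response.

### Gradient clipping

Residual motion spikes are removed by clipping wherever the
sample-to-sample gradient exceeds 1.5, refilling clipped samples by
linear interpolation between surviving neighbors. The limit is a bare
number, so the pipeline standardizes the band-passed signal to unit
variance first: 1.5 then means "1.5 standard deviations per sample",
which a clean breathing sinusoid (slope ≲ 0.25 SD/sample at 60 fps)
never reaches while step artifacts do. On a raw pixel-area signal the
same number would flag every sample. `clip_gradient` itself is
unit-agnostic; the standardization is a pipeline step, and peak
detection is scale-invariant, so the rescaling cannot change the
estimated rate.

## Breath-peak detection and rate

The estimator detrends the conditioned signal by subtracting its
least-squares line, finds zero crossings, and takes the extreme sample
inside every constant-sign lobe — including the partial lobes before the
first and after the last crossing, so a recording that starts or ends
mid-breath still contributes its crest. Outlier rejection then drops
peaks whose spacing from a neighbor falls below `outlier_frac` (default
0.3) of the median inter-peak interval; of the two peaks bounding a
too-short interval, the less extreme one is discarded and the median is
recomputed, which removes double-peaks without losing the true crest.
Survivors are re-paired so maxima and minima strictly alternate.

Rates use inhale crests (maxima) only: `f_RR = 60/d_peak`, stamped at
each interval's midpoint; the recording's rate is the arithmetic mean
over intervals. Minima are retained for waveform QC.

## ECG reference branch

Rat ECG morphology departs sharply from human: QRS complexes a few
milliseconds wide, cardiac fundamental at 5–7 Hz. R peaks are detected
from gradient steepness: the absolute gradient is boxcar-smoothed
(0.05 s), compared against 1.5× its own moving average (0.1875 s), and
each supra-threshold region contributes its signal maximum; peaks closer
than 0.1 s merge, keeping the larger.

Three numerical choices deserve note:

* **Minimum QRS length is relative.** Regions shorter than 0.1× the
  *mean candidate-region length* are discarded. An absolute 0.1 s
  minimum would exceed half the cardiac cycle at 360 bpm and reject
  every beat; the relative rule keeps the intended spurious-region
  filter functional at rat heart rates.
* **Gradient-path conditioning.** Before differentiation the signal is
  low-passed at 60 Hz (zero-phase); wideband noise otherwise dominates a
  raw derivative at 500 samples/s. Peak *positions* are still read from
  the unconditioned (notched-only) signal, preserving ±1-sample accuracy
  on clean records. This is detector conditioning, distinct from the
  4 Hz low-pass below.
* **The 4 Hz low-pass lives on the EDR branch.** A 4 Hz cutoff ahead of
  QRS detection would erase the rat QRS entirely; it is coherent,
  however, with the 3.3 Hz respiration ceiling, so it is applied to the
  EDR signal only. The placement is configurable.

The EDR itself is the R-amplitude modulation: beat amplitudes,
mean-removed, linearly resampled to a uniform 20 Hz, low-passed at 4 Hz
and band-passed to the respiration band. The beat sequence samples the
modulation at the heart rate, so the usable band top is capped at 0.45×
the mean beat rate (at 360 bpm: 2.7 Hz ≈ 162 breaths/min); if the cap
reaches the band floor the EDR is undersampled and extraction refuses.
An interval-based EDR could substitute where amplitude telemetry is
unreliable; amplitude modulation is the default because it is what the
synthetic truth and the reference studies pin down.

Spectra use Welch averaging with 10 s segments: 6 breaths/min bins, and
enough averaging that noise-only input stays below the 3×-median
dominance flag used to report "no dominant rate".

## Evaluation arithmetic

Each recording contributes one mean camera rate and one mean EDR rate;
relative error is 100·|cam − edr|/edr and absolute error |cam − edr|.
Study summaries are unweighted means over recordings, with min/max and
sample SD (n−1) of the reference column. All arithmetic is carried at
full precision; presentation rounds to 2 decimals, half-even.
Count-weighted means aggregate per-group IoU summaries
(Σ nᵢ·meanᵢ / Σ nᵢ). IoU of two empty masks is defined as 0 so total
detection failure earns no credit.

The package bundles the published per-recording reference tables
(`ratresp.reference`): 36 (mean EDR, mean camera) pairs and three
per-rat IoU rows. Recomputing each row's errors from its two means
reproduces the printed 2-decimal values for 35 of 36 rows; the remaining
row appears to carry a truncated mean in the source table, and the test
allows two such rows.

## Synthetic data: what it emulates, what it does not

`BlobSpec` renders an axis-aligned ellipse (aspect 1.6) whose rasterized
area tracks `area_mean·(1 + frac·sin(2π(rr/60)t))`, with pixel-center
rasterization (a pixel is inside iff its center satisfies the ellipse
inequality — deterministic and orientation-free). Defaults: 30 s at
60 fps, 120×160 px frames, 2500 px mean area, 5% area modulation —
a small, physiologically plausible visible breathing excursion —
0.2 Hz sinusoidal drift of 6 px amplitude, and area noise of 10 px²
applied by jittering both semi-axes jointly so masks stay valid
ellipses. Motion artifacts are *step displacements of the center*
(default 10 px, persistent, random direction per event): motion corrupts
the signal through tracking, never through true thorax size. The exact
analytic area and center are returned as ground truth; rasterization
error is bounded by the perimeter and is asserted as a test.

`EcgSpec` sums biphasic QRS-like pulses (8 ms Gaussian R wave with a
trailing S dip) at exact cardiac intervals — 360 bpm default, inside the
rat's 300–420 range — with R amplitudes scaled by
`1 + am_depth·sin(2π(rr/60)t)` (default depth 0.3), plus a 0.05-amplitude
50 Hz powerline tone and white noise (SD 0.02; the robustness test
raises this to 0.1, roughly 10 dB against the unit R peak).

Not emulated: fur texture and photometric appearance, segmentation-score
fluctuation of a trained network (synthetic scores are 1.0), heart-rate
variability, QT morphology, respiratory sinus arrhythmia, baseline
wander, and occlusion. Passing tests therefore demonstrate the signal
path — geometry extraction, projection denoising, filtering, peak logic,
EDR arithmetic — under controlled corruption, not segmentation quality
on real video; the published IoU table is data, not something the
bundled threshold segmenter can reproduce. The threshold segmenter's
certainty surrogate (1 − spurious/total foreground area) is likewise not
comparable to a network's softmax score.

## Degenerate inputs and edge policy

Invalid-frame runs up to 0.5 s are bridged by linear interpolation of
area and COM; longer runs (and invalid edges) split the recording into
independent segments, each conditioned and peak-detected separately,
with rates pooled over all intervals. Signals without zero crossings
yield empty peak sets, not errors; series too short for stable zero-phase
filtering, all-invalid mask stacks, all-flagged clipping and nonpositive
reference rates raise with specific messages. Ellipses leaving the frame
name the first offending frame.

## Problem sizes

Tests and the acceptance script run on 30 s blob recordings (1800 frames,
120×160 px) per rate in {70, 96, 150, 190} breaths/min, one 5-minute
48×64 px recording for frame bookkeeping (18,000 frames), and 60 s ECGs
at 500 Hz — sizes at which every stage's behavior is already asymptotic
while a full run stays in seconds.

## Known limitations

The COM-based noise subspace only captures translation-correlated error;
scratching or sniffing that deforms the region without moving its COM
passes through, as does any area error correlated with breathing itself.
The COM-alignment image shift of the original processing chain is
implemented (`align_to_com`) but is provably a no-op for the area signal
— translation preserves pixel counts — and is retained for mask-stack
export and visual QC only; a test asserts bit-identical areas. Outlier
rejection presumes roughly regular breathing, so complex patterns
(apnea, sighs) are out of scope. Video-file input requires an imageio
backend with video support; directories of PNG frames (with an explicit
`--fps`) and mask directories are the first-class inputs.
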