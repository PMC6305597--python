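# Methods

## Registration model

The correction model is a per-frame rigid lateral translation. A frame is
assumed to be the template scene translated by an unknown (dx, dy), plus
intensity changes from calcium activity and sensor noise; rotation, scaling
and within-frame scan distortion are out of scope. The similarity objective
is the Pearson correlation coefficient between the template's **fixed
central crop** and the frame window at the candidate shift — not the full
moving overlap — with both windows mean-subtracted. Zero-variance windows
are defined to have correlation 0, never NaN; all correlation values are
clipped to [−1, 1].

Coordinates are 0-based (row, col) with x = column (rightward) and
y = row (downward). A `ShiftEstimate` is the displacement of the frame's
*content* relative to the template; correction translates the frame by the
negation. Vacated border pixels are set to 0 and the unpadded rectangle is
recorded with each shift so that downstream ROI means can mask the padding.

**Margins.** The per-axis maximum searched shift is mx = ⌊w·f⌋,
my = ⌊h·f⌋ with margin fraction f = 0.25 by default, so the compared crop is
(h − 2my) × (w − 2mx). At pyramid level k (or downscale factor c) the
margins scale as max(⌊m/2ᵏ⌋, 1); a configuration is rejected if the
downscaled crop would fall below 8 px per side.

**Template.** Built from an even number N of pre-experiment frames in two
passes: the mean of the last N/2 raw frames aligns (exhaustive search,
factor 1, integer correction) the first N/2; their corrected mean aligns the
last N/2; the final template is the mean of all N corrected frames.

**Search strategies.**

* *Hill climbing* evaluates the four axial neighbors of the current shift
  and moves to the best strictly-improving one (ties broken in the order
  +x, −x, +y, −y); it terminates at a local maximum, so the returned
  correlation is monotonically ≥ the value at the initialization. With an
  image pyramid, the coarsest-level search starts from zero shift and each
  finer level doubles the shift and refines by hill climbing.
* *Dense search* replaces the coarsest-level hill climb with a naive
  exhaustive scan over all shifts within the scaled margins (row-major
  first-maximum tie-break), then refines per level as above.
* *Full search* computes the complete correlation surface with
  FFT-accelerated zero-mean normalized cross-correlation
  (`skimage.feature.match_template`, mathematically identical to the naive
  per-shift Pearson evaluation; the test suite asserts agreement to ≤ 1e-6),
  optionally after block-mean downscaling of both images, and takes the
  global argmax. No hill climbing is applied; with downscaling, the
  (integer + subpixel) coarse shift is multiplied by the factor and
  re-normalized so the fractional part stays in [−0.5, 0.5].

**Downscaling** is the non-overlapping block mean; trailing rows/columns
that do not fill a block are dropped; factor 1 is the identity. Block means
were chosen (over decimation or Gaussian pyramids) because the estimate then
depends only on how pixels are grouped into blocks, which is the mechanism
behind the instability of heavily downscaled correction that the evaluation
protocol reproduces.

**Subpixel refinement** fits, per axis, a parabola through the peak
correlation and its two axial neighbors; the vertex offset
(a − c) / (2(a − 2b + c)) is clamped to [±0.5] and set to 0 when the triple
is flat or non-concave (denominator ≥ −1e-12) or the peak lies on the search
border. The default configuration — full search, factor 2, subpixel on — is
the recommended speed/accuracy operating point.

## Baseline estimation and ΔF/F

Traces are ROI means over the valid (unpadded) region of each corrected
frame. Every `update_every` = 20 frames, the trailing
min(`window_frames` = 2000, available) frames — truncated to a multiple of
`bin_frames` = 20 — are reduced to per-bin averages and fed to one of three
estimators:

* **percentile** — the p-th percentile (default 20) with linear
  interpolation between order statistics (the exact interpolation rule is
  fixed so comparisons are reproducible);
* **robust mean** — iterate: mean μ and sample SD σ (ddof = 1) of the
  included set, exclude values with |v − μ| > 2σ; the inclusion mask shrinks
  monotonically and iteration stops when unchanged (cap 100); σ = 0 returns
  μ immediately;
* **KDE peak** — Gaussian kernel density with normal-reference bandwidth
  bw = σ̂ (4/3n)^{1/5}, σ̂ = min(sample SD, IQR/1.349), evaluated on a
  512-point grid over [min − 3bw, max + 3bw]; the grid argmax (ties to the
  smallest value) is refined with the same 3-point parabola fit used in
  registration. The bandwidth rule is this package's stand-in for a
  "width optimized to the samples"; it is deliberately simple and stated so
  results are reproducible.

ΔF/F = (raw − baseline)/baseline, with NaN where the baseline is not
positive. The rolling-baseline warm-up is a design choice the steady-state
description leaves open: the library function backfills the first computed
value over the warm-up frames, while the streaming pipeline emits NaN ΔF/F
until the first update (no guess is published in real time); with backfill
disabled the two paths are numerically identical, and the test suite asserts
this.

## Evaluation protocol

For each evaluated frame, `n_repeats` = 100 integer shifts are drawn
uniformly on [−max, +max]² (one seeded generator per run), the frame content
is displaced (zero padding), the configured correction runs, and the *net
translation* — estimated minus injected shift, i.e. the recovered underlying
motion — is recorded. The frame is flagged as an error frame when at least
`min_outliers` = 5 nets lie more than `deviation_threshold` = 10 px from the
component-wise median. The distance metric is Euclidean by default, with a
per-axis variant available behind a switch. Error frequencies are compared with a Pearson
chi-square test on the 2×2 table, 1 df, **no continuity correction** — the
variant under which the worked example [[4, 996], [0, 1000]] gives
p = 0.0453; tables with an all-zero margin return (statistic 0, p 1).

The percentile-lag demonstration uses the midpoint quantile convention
(the mean of the two straddling order statistics when the target rank is
fractional) with ties resolved to the earlier bin; on 100 noiseless
monotone values this places the 20th percentile at bin 20 (rising) and
bin 80 (falling) — a 60-bin lag. The more common linear-interpolation rule
would give bins 21/80; the midpoint rule is the one consistent with the
textbook statement of the lag and is used only in this demonstration
(`percentile_baseline` keeps linear interpolation).

## Synthetic data: what it emulates, and what it does not

Scenes place smooth Gaussian blobs (somata, σ = `radius`) or thin
random-walk curves (dendrites, 1 px by default, lightly smoothed) over a
constant background, confined to the central half of the field so maximal
shifts never move structures out of frame. Motion is a sinusoidal drift plus
integer-rounded Gaussian jitter, optional fixed offsets (for the
large-offset failure construction) and per-frame uniform random shifts.
Calcium transients are Bernoulli events per frame convolved with an
instant-rise/exponential-decay kernel; each structure is scaled by
(1 + ΔF/F) before translation. Noise is additive zero-mean Gaussian.
Rendering shifts are integer-valued so exact recovery is assertable;
fractional shifts for subpixel tests are rendered by bilinear resampling.
All generators are seeded and byte-reproducible.

Not modeled: photon shot noise and its intensity dependence, photobleaching,
slow baseline drift, within-frame scan distortion, neuropil contamination,
and non-rigid tissue deformation. Passing tests therefore demonstrate the
correctness and the qualitative failure modes of the algorithms, not
performance on any particular biological recording.

## Study conditions used by the tests and the acceptance script

* **Error-frame protocol** (≈ the dominant cost): 256 × 256 px, 200-frame
  movies; the 100-injection protocol runs on every 4th frame (50 frames per
  configuration), a problem size chosen to keep the full suite fast while
  leaving the per-frame statistics at the original 100 repeats. The soma
  scene has 30 blobs (σ = 3, amplitude 150, background 20, noise SD 10,
  per-pixel SNR 15); the dendrite scene is sparse and weak — three ~50 px,
  1-px-thin curves, amplitude 50, noise SD 18 (SNR ≈ 2.8) — which is what
  makes correction collapse at downscale factor 16 while remaining exact at
  factors 1–2, mirroring weakly labeled dendritic data.
* **Four-condition baseline comparison**: two 2000-frame windows (low
  activity 0.002, high 0.012 events/frame), transient ΔF/F 0.12 with
  25-frame decay (single-action-potential scale at ~28 Hz), baseline 100,
  noise SD 2.5, binned by 20 both ways (averaged and downsampled). Because
  the KDE-peak and robust-mean spreads are close in any single realization,
  the comparison is made on the **mean spread over 24 seeded replicates**,
  where the ordering (KDE < robust mean < percentile here, with KDE smallest)
  is stable; this replicated design is a deliberate strengthening of a
  single-recording comparison.
* **End-to-end recovery**: 1200-frame, 256 × 256 soma movie with 10 ROIs,
  known trajectory (|shift| ≤ 16 px) and transients (rate 0.005/frame,
  ΔF/F 0.5, decay 10); exhaustive factor-1 search must recover every integer
  shift exactly, and the regression slope of measured on ground-truth ΔF/F
  across event frames must be within 10 % of 1 using the KDE baseline.

## Numerical and degenerate-input choices

* Exhaustive argmax ties: row-major first occurrence (smallest dy, then dx).
* Hill-climb ties among equally improving neighbors: first in +x, −x, +y, −y.
* Correlation of any zero-variance window: 0.
* Robust mean with everything excluded: return the last mean, warn.
* KDE of a zero-spread sample: the common value; < 5 values: rejected.
* `dff` with baseline ≤ 0: NaN with a warning, never an exception.
* Movie frames must be ≥ 8 px per side; template margins must satisfy
  0 < m < half the image size and leave a crop with nonzero variance.

## Known limitations

* Rigid translation only; piecewise-rigid or non-rigid correction is not
  attempted, so large-field tissue deformation is uncorrected.
* The hill-climbing searches inherit the local-maximum failure under large
  offsets by design; this is surfaced, not hidden, by the evaluation module.
* The KDE bandwidth rule is a fixed normal-reference formula; heavily
  contaminated windows (activity in most bins) inflate it and bias the peak.
* Wall-clock latency is recorded per frame for information but is
  hardware-dependent and never asserted.
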