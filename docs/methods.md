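# Methods

## Signal model

Abdominal channels are modelled as an instantaneous, time-invariant linear
mixture x = A s of a maternal ECG source, a fetal ECG source and additive
white Gaussian sensor noise. The mixing matrix A is assumed constant over
a record and of full column rank; propagation delays, volume-conductor
effects and uterine EMG are not modelled. Under this model, blind source
separation is identifiable up to sign, order and scale, provided at most
one source is Gaussian — which holds here, since ECG waveforms are
strongly super-Gaussian.

## Separation stages

**Preprocessing.** Baseline wander is removed with a linear-phase
windowed-sinc FIR bandpass (Hamming window), default band 3–150 Hz,
default order ≈ fs (≈1000 taps at 1 kHz, ~3 Hz transition), applied
forward-backward so the net group delay is zero and annotation indices
remain valid. Centering subtracts per-channel means. Whitening uses the
eigendecomposition of the population (1/N) covariance; by default a
rank-deficient covariance is an error, while `reduce=True` (used by the
pipeline, and required for noise-free mixtures where rank < channels)
drops directions with eigenvalue below 1e−12·λmax with a logged warning.

**ICA.** Symmetric fixed-point iteration with the log-cosh (tanh)
contrast and symmetric decorrelation after each sweep. Initial unmixing
matrix: orthonormalized seeded Gaussian. Convergence: max
| |diag(W_new W_old^T)| − 1 | < 1e−6, at most 500 sweeps; a
non-converged fit is returned flagged, with a warning. Identical (data,
seed) gives bit-identical results.

**PCA.** Eigendecomposition of the channel covariance (same 1/N
normalization), eigenvalues sorted descending with stable tie-breaking by
channel order, each axis sign-fixed so its largest-magnitude entry is
positive. PCA separates this problem surprisingly well because the
maternal source dominates the abdominal power: the first principal axis
aligns with the maternal mixing column, and the fetal content concentrates
in the orthogonal axes. White sensor noise shifts all eigenvalues equally
and leaves the axes unchanged.

**Role labeling (ambiguity resolution).** Each component is classified by
the fundamental period of its energy autocorrelation: the smallest-lag
peak whose height reaches 70% of the strongest peak in the 45–230 bpm lag
range. Components whose implied rate falls in 50–110 bpm are
maternal-dominant candidates, 110–220 bpm fetal-enhanced; the highest
periodicity score wins within each band, everything else is noise. Signs
are flipped so each component correlates positively with its
best-matching raw channel; when that correlation is negligible (<0.05)
the spikier tail (positive third moment) is made positive instead. If no
component shows periodicity in either band the pipeline aborts with a
diagnostic rather than guessing.

**Compensation and subtraction.** The maternal-dominant estimate is
aligned to the maternal content of the fetal-enhanced component by a
single integer lag maximizing |normalized cross-correlation| within
±50 ms (ties toward zero lag; sub-sample lags are not modelled — 1 ms at
1 kHz is small against a 100 ms maternal QRS). Polarity is taken from the
sign of the correlation at that lag, so the gain stays positive. The gain
is per-window least squares g = ⟨a,b⟩/⟨b,b⟩ on 2 s windows with 50%
overlap, clipped to (0, 10), linearly interpolated between window
centers; windows whose normalized correlation is below 0.05 get gain 0,
because a least-squares fit there would only track noise and the
subtraction would inject interference instead of removing it. Degenerate
windows (⟨b,b⟩ = 0) carry the previous gain with a warning. Whether the
original enhancement adapts per beat or per window is not documented
anywhere; per-window is this package's choice and is config-exposed.

## Detection and evaluation

**Pan–Tompkins detector.** Bandpass (5–15 Hz maternal, 10–40 Hz fetal,
zero-phase) → five-point derivative → squaring → moving-window
integration (100 ms maternal / 40 ms fetal, mirroring the QRS widths) →
adaptive double threshold with running signal/noise peak estimates,
search-back at half threshold when a beat is overdue (>1.66× the running
RR mean), refractory 300 ms maternal / 200 ms fetal. Accepted peaks are
refined to the apex of |bandpassed signal|, so indices land on the R wave.
A 2 s learning phase initializes the thresholds; shorter signals are
rejected.

**CWT detector.** Mexican-hat wavelet coefficients at 8 log-spaced scales
spanning the mode's QRS band, averaged into an energy envelope and
smoothed over 20 ms. Peaks above median + 7·(1.4826·MAD) with the same
refractory and apex refinement. The 7-sigma robust threshold keeps
false-alarm windows on stationary noise essentially at zero while QRS
energy on any usable channel exceeds it by an order of magnitude.

**fHR.** Instantaneous rate 60·fs/RR per beat; the "beats per minute"
reading of the rate is the equivalent per-minute count of RR intervals.
Smoothing is a centered moving average over a window counted in beats
(default 10 for 5-min records, 30 for hour-scale overviews), shrinking at
the edges.

**Beat matching.** One-to-one pairing within ±50 ms (config-exposed) via
optimal assignment: maximum pair count, ties broken by minimal total
|Δt|. Greedy nearest-neighbour matching is not always maximum-cardinality,
so the assignment formulation is used and is verified against exhaustive
enumeration in the tests. Percentages are rounded half-up to two decimals.
Aggregation over recordings is provided both by pooling counts and by
averaging per-recording percentages; the two differ, and both appear in
published tables, so both are explicit functions.

**Bland–Altman.** Differences of two fHR series on a common time base
(direct differencing when beat times coincide, otherwise linear
interpolation to a 4 Hz grid over the overlap); bias, SD (ddof = 1) and
limits of agreement at bias ± 1.96 SD, plus the percentage of differences
inside the limits.

**Quality indices.** QRS windows are inclusive symmetric windows of
round(width·fs/1000) + 1 samples (100 ms maternal, 40 ms fetal); the
"+1" is the odd sample count of the inclusive window. Complexes whose
windows overlap a complex of the other class are excluded from the power
sums (feto-maternal coincidence: |Δ| ≤ 70 ms at these widths); all
complexes, coincident or not, shadow the noise region. PN is the mean
power outside every window; PM and PF are in-window mean powers minus PN,
floored at zero with a warning (the estimator assumes signal and noise
uncorrelated and neglects P/T-wave power, which biases PN slightly
upward). WM, WF, WMF follow; WMF = WM − WF is an exact identity.

**T/QRS.** Template = mean of 30 R-aligned beats (window −100…+400 ms,
truncated at 80% of the median RR). QRS amplitude = R apex − S trough
within ±60 ms of R (R−S, matching an R-and-S localization step, rather
than R−baseline). T amplitude = template maximum 120–350 ms after R minus
the mean of the 60–80 ms isoelectric segment. The ratio is exactly
invariant under positive rescaling, which is what makes it transferable
from the attenuated abdominal extraction to the direct signal.

## Synthetic generator

Each heart is a quasi-periodic beat train; one beat is a sum of five
Gaussians (P, Q, R, S, T) — the standard synthetic-ECG parameterization —
with maternal QRS support ≈100 ms and fetal ≈40 ms. Default rates:
maternal 70 bpm (±3 bpm sinusoidal modulation, 30 s period), fetal
140 bpm (±7 bpm, 20 s period), i.e. the typical 2:1 fetal-to-maternal
ratio. R apexes are snapped to the sample grid, so the returned
annotations are exact. Four abdominal channels mix the two sources
through a fixed full-rank matrix with the maternal column dominant; a
fifth "direct" channel (clean fetal + tiny noise) stands in for the FSE
reference. When dB targets are given, the noise SD (for WM) and the fetal
amplitude (for WF) are solved by bisection against the quality-index
module itself, alternating three times because the fetal P/T waves leak
into the noise region; internal tolerance 0.1 dB, documented contract
±1 dB. The canonical fixture targets WM = 10.9 dB and WF = 3.9 dB, the
reported mean operating point of real labor-ward recordings.

What the generator does *not* emulate: powerline interference, motion
artifacts and electrode pops, uterine EMG, time-varying mixing
(fetal movement), FSE signal-loss episodes, and pathological rhythms.
Passing tests therefore demonstrate correctness of the algorithms under
the stated mixture model at a realistic SNR — not clinical performance on
real recordings, where those artifacts dominate the failure modes. The
mixture equations allow time-varying weights in principle; the generator
uses a constant matrix, consistent with the separation model.

One consequence of the exact 2:1 rate ratio is worth noting: maternal and
fetal beats coincide quasi-periodically, which produces genuine short-term
correlation between the separated components even when separation is
perfect. The compensation stage's correlation gate keeps the resulting
spurious gains small, but a ~1% ceiling on noise-free fetal correlation
remains; it is inherent to the harmonic fixture, not an estimation error.

## Problem sizes and defaults

Test and acceptance runs use a 60 s, 1 kHz, 4+1-channel calibrated
fixture (≈140 fetal beats) for end-to-end checks and 20 s, 500 Hz
noise-free mixtures for separation-fidelity checks across seeds; these
sizes give stable statistics (beat counts in the hundreds, correlation
standard errors < 1e−3) while keeping the whole suite in seconds. All
stochastic steps are driven by explicit seeds; detectors contain no
randomness at all.

## Known limitations

* Instantaneous mixing only; no online/adaptive variant of the separation.
* Integer-sample lag compensation; a global (not per-beat) gain track.
* The role-labeling rate bands assume non-overlapping maternal and fetal
  rates; fetal bradycardia into the maternal band (or maternal tachycardia
  into the fetal band) defeats the heuristic, as it does any rate-based
  rule.
* EDF support is read-only; WFDB support covers the plain format-16
  single-.dat layout, not the full header grammar.
* No event-level ST-analysis (episodic/baseline T/QRS rise alerts) — only
  the T/QRS determination itself.
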