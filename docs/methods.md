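# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic benchmark does and does not show
about real intracranial data.

## Signal model and conditioning

Recordings are multichannel voltage time series (microvolts) at 400–512 Hz.
The conditioning chain is fixed: zero-phase order-6 Butterworth high-pass at
0.5 Hz (DC correction), zero-phase order-6 band-stop filters at the mains
fundamental and harmonics (58–62/118–122/178–182 Hz for 60 Hz mains;
48–52/98–102/148–152/198–202 Hz for 50 Hz), common average reference (CAR),
then FIR-antialiased polyphase downsampling.  All IIR filters are designed
in zero-pole-gain form, converted to second-order sections, and applied
forward–backward, so the effective magnitude is the squared one-pass
response and there is no net group delay.  Channels flagged `excluded` are
dropped *before* the CAR (a stand-in for visual rejection of bad contacts);
an optional automatic trial rejection drops epochs whose peak amplitude
exceeds 8 robust SDs (1.4826 × MAD).

Epoch windows are half-open `[start, end)` in seconds; the
`production_window` rule pads the expected production interval by 250 ms on
both ends.  This reading (padding both ends) was chosen because it yields
window lengths compatible with word durations; an alternative
onset-anchored reading is supported through the event table's expected
onset/offset columns.

The acoustic-contamination screen reduces audio and neural signals to
spectrogram magnitudes (250 ms windows, 50% overlap) on a common time grid;
a channel's score is the maximum over frequency bins of the correlation
across time frames with the audio spectrogram, flagged against the 99th
percentile of a null built by circularly shifting the audio frames.  The
spectrogram parameters are config values, not signal-derived.

## Band power

Features come from the analytic Morlet transform with 7 cycles, sampled at
1 Hz steps in-band (2 Hz within 80–150 Hz).  Band power is the mean over
in-band frequencies and window samples of |W| — magnitude, not squared
power, and with no per-band normalization.  Bands: θ 4–8, low-β 12–18,
low-γ 25–35, BHA 80–150 Hz.

Two implementations exist with one contract:

- `wavelet_band_power(epochs)` transforms pre-cut epochs, reflection-padding
  epochs shorter than the longest wavelet.
- `wavelet_band_power_windows(recording, events)` transforms the continuous
  recording and averages |W| inside each event window.  This is the path the
  pipeline uses for task-vs-baseline contrasts: per-epoch transforms of
  windows with different lengths (0.5 s baselines vs ~1 s task windows)
  carry length-dependent edge attenuation at low frequencies that biases
  Cohen's d by roughly +0.1 even when nothing was injected; the
  continuous-transform path has no such artifact (measured null bias
  ≤ 0.03 across bands).

Effect sizes are Cohen's d with the pooled SD; positive d means the task
mean exceeds baseline.  p-values come from two-tailed two-sample t-tests
and are corrected by Benjamini–Hochberg FDR over the family of all
(channel × band) cells at α = 0.05 (the family choice is a package
decision; cells with zero pooled variance are excluded and logged).

## Phase–amplitude coupling

The modulating phase must be well defined, so coupling is anchored on
spectral peaks: the Welch log-spectrum (2 s segments) is fit by a straight
line in log-log coordinates (one outlier-trimmed refit), and an in-band
local maximum counts as a peak only if it exceeds the trend by 3 SDs of the
fit residuals.  The 3-SD threshold was calibrated on the generator: pure
1/f noise then yields a spurious peak in ~3% of cases while oscillatory
peaks at the signal-to-noise ratios of interest are always found (at 1 SD,
noise local maxima pass almost always, which would make "peak absent" an
empty notion).  Among peaks the maximal-amplitude one is selected; absence
is a value, not an error, and coupling for that channel/pair is marked
missing.

The phase band-pass is centered on the peak with a bandwidth of half the
band width (2/3/5 Hz for θ/low-β/low-γ).  The carrier bands are β 12–25,
γ 25–50, BHA 80–150 Hz; a carrier modulated at f_p carries sidebands at
±f_p, so when a carrier band is narrower than 2·f_p it is widened
symmetrically about its center (clipped below Nyquist) and the pair is
flagged `bandwidth_limited` — under the nominal bands this flags θ→β and
low-β→γ.  Phase and amplitude are the Hilbert angle/magnitude of the
centered filtered signals.

The modulation index uses an 18-bin phase histogram on [−π, π), bin 0
starting at −π: the mean amplitude per bin, averaged across trials,
normalized to sum 1, gives MI = (log 18 + Σ p log p)/log 18 ∈ [0, 1].
Empty bins contribute exactly 0 (the p log p limit; an ε-floor of 1e−12
guards the logarithm).  MI is invariant to amplitude scaling and to
rotations of the bin labels.

The condition contrast x_d = MI_task − MI_baseline is referenced to a
surrogate distribution built by permuting the epoch-to-condition assignment
between the pooled task and baseline epochs (200 surrogates by default;
per-epoch histograms are precomputed, so surrogates only re-average).
z = (x_d − x̄_ds)/s_ds; the one-tailed p comes from the normal survival
function; BH-FDR runs across channels × pairs.  Baseline epochs are pooled
(not matched per trial).  Under the null the empirical type-I rate is
0.050 ± 0.009 (600 replicates during development; the acceptance suite
checks 0.05 ± 0.02 at 200 replicates).

## Representation spaces

Phonemes map to groups along three dimensions: articulatory place (labial,
coronal, dorsal), phonetic manner (plosive, fricative, nasal, approximant)
and vowel position (low-back, low-front, high-back, high-front, central).
The shipped `group_table.tsv` is a curated long-format table covering the
six English study-1 words, twelve French study-2 words and the three
study-3 syllables, validated against the worked example
"python" [paɪθən] → labial+coronal / plosive+fricative+nasal /
low-front+high-front+central.  Debatable entries are explicit choices:
[w] is labial *and* dorsal (labio-velar), [ʁ] is a dorsal fricative, mid
vowels are folded into the nearest height class ([ɛ æ a]→low-front,
[o ʊ u]→high-back, [e i ɪ y]→high-front, [ə œ ø]→central, nasal vowels map
by their oral height/backness).  Users can override the table with their
own TSV.

A word's representation is the union of its phonemes' groups (sets, so
repetition is irrelevant).  The discriminant groups of a pair are the
symmetric difference of the two sets, and the representation distance is
its cardinality.  The distance is symmetric with a zero diagonal; the
triangle inequality is *not* guaranteed and not asserted.  An optional
semantic dimension uses the 0/1 category-indicator distance.

## Discriminability statistics

*Pairwise label correlation.*  For every item pair, trials get labels
+1/−1 and the Pearson correlation with the scalar feature (per channel and
band epoch mean) is computed; the signed correlations are averaged across
pairs.  The permutation null shuffles the whole item-label vector across
trials and repeats the averaging.  Permuting each pair's labels
independently — a literal per-pair scheme — under-disperses the null
because pairs share trials, inflating the type-I rate to ~0.10; the global
shuffle restores exchangeability (measured 0.05 ± 0.02).  The reported p
is two-sided on the signed mean and deliberately uncorrected across
electrodes.  Degenerate (zero-variance) features score r = 0 by policy.

*Fisher distances.*  Per region of interest (sensorimotor, superior
temporal, middle/inferior temporal, inferior frontal) and hemisphere, the
channel-feature matrix of one band is reduced by PCA fitted on all trials,
keeping the smallest component count reaching 95% explained variance (the
retention fraction is a package default; configurable).  For an item pair,
each component contributes (μ_i − μ_j)²/(σ_i² + σ_j²) (sample variances);
the pair's distance D is the **maximum** over components.  A
sum-over-components variant sits behind `fisher_mode="sum"` because the
printed definition is ambiguous between the two readings; max is the
default.  Components with zero total variance are skipped; if all are
skipped D is undefined.  Each pair's D is attributed to every discriminant
group of the pair; the group value is the mean over contributing pairs.
The permutation null shuffles item labels across trials (1000 by default)
and repeats the group averaging — PCA is label-free, so refitting it per
permutation would reproduce the same component space and is skipped.
BH-FDR runs across (ROI × hemisphere × band × representation × group).

## Decoding

Binary classes come from complete-linkage hierarchical clustering of the
representation distance matrix: every partition that separates one
dendrogram cluster from the rest is evaluated; minimal class imbalance
wins, ties broken by the larger maximum between-class distance, then
lexicographically (deterministic).  An all-zero distance matrix is a
degenerate representation and an error.

The decoder is a linear-kernel SVM (C = 1, no grid search, to keep the
nested budget honest) inside stratified 10-fold outer cross-validation.
Within each training fold, features are z-scored (train-fold statistics
only) and recursive feature elimination removes 10% of the starting
feature count per iteration, choosing the retained count by nested
stratified 5-fold cross-validation on balanced accuracy; the selected
model is refit on the full training fold and scored on the held-out fold.
Balanced accuracy (mean of per-class recalls) makes the score insensitive
to class imbalance.  Classes smaller than the fold count reduce the fold
count with a warning.

Chance thresholds use the exact inverse binomial rule: the smallest k/n
with P(Binomial(n, ½) ≥ k) < α.  For very small n (n ≤ 5 at α = 0.05) no
accuracy reaches significance and the threshold is reported as 1.0.  The
threshold decreases with n up to the discreteness of the k/n grid (±1/n
wiggles are inherent, e.g. 7/8 = 0.875 vs 8/9 ≈ 0.889).

Task discrimination (listen vs overt vs imagined) uses linear discriminant
analysis with stratified 5-fold cross-validation on concatenated band-power
time series or the <20 Hz zero-phase order-8 low-passed amplitude;
Ledoit–Wolf shrinkage replaces the sample covariance whenever features
outnumber trials.

## Synthetic data: what it emulates, and what it does not

The generator concatenates, per trial, a 0.5 s baseline segment and a ~1 s
task segment separated by 0.25 s gaps, over a 1/f background
(spectral-shaping of white noise, exponent 1, RMS 5 µV) plus a 60 Hz line
component (2 µV).  Each (channel, band) hosts a continuous-phase oscillator
at the band center whose amplitude envelope is piecewise constant per
segment (smoothed over 50 ms): baseline amplitudes are N(20, 4²) µV; task
amplitudes are shifted by d·4 µV for a target Cohen's d, plus per-item
offsets (in units of the 4 µV SD) for item discriminability.  Coupling is
injected by multiplying a carrier's envelope by (1 + m cos φ) with φ the
channel's own slow-band phase, gated to task segments.  The continuous
oscillator design matters: switching oscillations on and off per segment
leaves ramp and edge artifacts that masquerade as condition effects at low
frequencies.

The base amplitude and SD were chosen once so that the oscillatory
component dominates the in-band background: injected effect sizes are then
identifiable at the studies' trial counts, which is the property the test
suite needs.  Realized per-trial amplitudes and injected depths are
returned as ground truth.

What the generator does **not** emulate: spatially correlated neural
sources and volume conduction, non-sinusoidal waveform shape (a known
source of spurious coupling), epileptic discharges and movement artifacts,
trial-to-trial latency jitter, and electrode-dependent noise floors.
Passing tests therefore certify the *statistical machinery* — calibration,
unbiasedness, chance levels, oracle agreement — not decoding performance on
real patients.

## Problem sizes and numerical choices

The acceptance study runs the full null-decoding pipeline on 50 datasets of
2 items × 40 trials × 8 channels (mean balanced accuracy 50.05% at the
default seed), calibrates the coupling test on 200 replicates of 20+20
one-second epochs with 100 surrogates, and measures effect-size recovery on
50 replicates of 100+100 trials; these sizes give Monte-Carlo standard
errors comfortably inside the asserted tolerances while the whole suite
stays desk-scale.  Effect-size recovery is assessed on the generator →
spectral chain without the CAR step, because re-referencing deliberately
mixes same-frequency oscillators across channels and attenuates per-channel
injected d (by design of the montage, not a bias of the estimator); the
tolerance is max(0.1·d, 2.58·SEM), the first term being the band-bias
allowance adopted for the spectral stage.  All stochastic stages draw from
named substreams (seed + CRC32 of the stage name) of one global seed, so
stages are independently reproducible; TSV outputs use a fixed float format
and HDF5 datasets disable modification times, making artifacts byte-stable.

## Known limitations

- EDF files are read (via the MNE reader) but artifacts are written as
  delimited matrices with JSON sidecars; EDF export is out of scope.
- The epoch-based band-power path retains mild low-frequency edge bias for
  epochs much shorter than the 7-cycle wavelet; use the windowed path for
  contrasts between windows of different lengths.
- The wavelet precondition admits epochs holding ≥ 3 cycles of the slowest
  band's *center* frequency (0.5 s at 6 Hz), so standard 0.5 s baselines
  are analyzable; the 4 Hz edge of θ is then covered by ~2 cycles.
- The CFC contrast compares pools of epochs that may differ in duration;
  shorter epochs have noisier phase histograms, which makes the one-tailed
  test conservative (never anticonservative) in that configuration.
- Fisher-distance permutation p-values share one component space across
  permutations; if a supervised dimensionality reduction ever replaced PCA,
  the null would need refitting per permutation.
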