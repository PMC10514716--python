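# Methods

`synaptune` quantifies two kinds of recordings used to study synaptic
neuromodulation in auditory cortex — optogenetically evoked EPSC trains in
voltage clamp, and sound-evoked calcium responses of cortical neurons —
together with synthetic-data generators that emulate both recording types
with exact ground truth. This note documents the models, the defaults and
why they were chosen, and what the synthetic data does and does not show
about real recordings.

## EPSC train quantification

Sweeps are 10 kHz current traces held at a negative holding current with
inward (negative) AMPAR-mediated EPSCs at each light-pulse onset. Per the
standard workflow, 3–7 same-condition trials are averaged pointwise and all
amplitude metrics are computed on the average.

**Amplitude.** For pulse *n*, amplitude = |baseline − trough|, where the
baseline is the mean of the 1 ms window ending at the pulse onset (a single
onset sample by option) and the trough is the most negative sample between
the onset and min(inter-pulse interval, 100 ms). The 1 ms baseline window
and 100 ms search cap are robustness choices; both are configurable.
Amplitudes are reported as positive magnitudes and clipped at zero so a
flat trace yields exactly 0.

**Decay tau.** Nonlinear least squares of `c + a·exp(−t/τ)` from the peak
sample to the end of the decay window, initialized at the 1/e crossing
time. Flat or non-decaying segments (trough less than 1 pA below the
window end) and diverging fits return a flagged missing value rather than
a number.

**Normalization schemes.** Five schemes relate a test train to its control
train: `first_vs_first` (EPSC₁/Control₁), `train_vs_first_control`
(EPSCₙ/Control₁), `pointwise_vs_control` (EPSCₙ/Controlₙ), `mean_vs_mean`
(EPSC_avg/Control_avg) and `within_train` (EPSCₙ/EPSC₁). Zero divisors are
flagged per element.

**Derived ratios.** Paired-pulse ratio is A₂/A₁ (flagged when A₁ = 0); the
steady-state ratio is the mean of the last `n_last` amplitudes over A₁,
with `n_last = 3` by default (the number of pulses entering the
steady-state average is not standardized; 3 is stable for 10-pulse trains).

**Quality control.** A recording is excluded when any series-resistance
check exceeds 30 MΩ or deviates more than 15 % from the first check; the
returned reason names the rule that fired. Both limits are inclusive
(exactly 30 MΩ or exactly 15 % passes).

## Synthetic EPSC trains

The generator superimposes peak-normalized difference-of-exponentials
kernels (τ_rise 1 ms, τ_decay 15 ms by default; a slow-decay preset stands
in for NMDAR-like or cyclothiazide-slowed currents) on the holding current,
plus white Gaussian noise. Short-term depression follows a single-pool
vesicle-depletion recursion with release fraction *U* and recovery time
constant τ_rec:

    R₁ = 1,  R_{n+1} = R_n (1 − U) e^{−Δt/τ_rec} + 1 − e^{−Δt/τ_rec},

whose closed-form fixed point `R_ss = (1 − e)/(1 − (1 − U) e)` with
`e = e^{−Δt/τ_rec}` is used as an independent oracle in the tests. This
model was chosen because it reproduces the qualitative rate dependence of
cortical short-term depression (more depression at 10 Hz than 5 Hz) with
an analytically checkable steady state. Defaults: U = 0.5, τ_rec = 200 ms,
first-pulse amplitude 100 pA, noise SD = amplitude/20 (first-pulse
SNR ≈ 20).

A condition label applies a multiplicative gain to the postsynaptic
amplitude only — e.g. control → 1.0, chelator → 0.75 for the ~25 %
reduction seen when synaptic zinc is chelated — leaving *U* and τ_rec
untouched, so paired-pulse ratios and steady-state depression are
condition-invariant by construction, consistent with a purely postsynaptic
modulation.

## ROI tuning analysis

ROI traces are sampled at 5 Hz during repeated pseudorandom tone blocks
(5–40 kHz in 1/8-octave steps × 40–80 dB SPL; 125 tones per block; 3 s
inter-stimulus intervals; 5–7 block repetitions with the order re-drawn
per repetition).

Per tone: repeat-aligned segments spanning [onset − 1 s, onset + 2 s) are
converted to ΔF/F against the mean fluorescence of the 1 s preceding the
onset, averaged over repeats, and converted to a Z score by subtracting
the mean and dividing by the standard deviation of the entire averaged
trace (population convention by default; sample convention by flag). A
tone counts as a response when the Z trace exceeds 0.6 for at least two
consecutive frames within the half-open 1-s window after onset (5 frames
at 5 Hz, both criterion frames in-window). Response magnitude is the peak
ΔF/F in that window.

Two conventions deserve note:

* **Z-scoring scope.** Standardizing each 15-frame segment by itself is
  scale-invariant, so the 0.6-Z criterion would pass pure noise at a fixed
  ~23 % rate regardless of SNR. Standardizing by the whole trace keeps
  response amplitude information in the statistic: false positives vanish
  as noise decreases. The whole-trace scope is the default;
  `zscore_scope="segment"` is available for comparison.
* **Response magnitude.** BF ranking uses the peak ΔF/F, not the peak Z:
  with per-neuron Z normalization, all noise-free responses would have
  identical Z peaks and BF would be undefined. The surface stores both.

**Metrics.** BF is the frequency of the largest response at any level
(exact ties break toward the lower frequency, then the lower level).
Threshold is the lowest level with any response. Q20 is log₂ of the ratio
of the highest to the lowest responsive frequency in the single level row
20 dB above threshold (0 for a single responsive frequency; undefined, and
the neuron excluded from bandwidth analyses, when that level was not
tested or carries no response; responsive frequencies need not be
contiguous). d′ compares per-repeat evoked window peaks against
matched-duration pre-onset baseline peaks at the BF stimulus:
`d′ = (mean_evoked − mean_baseline)/√((var_e + var_b)/2)` with sample
variances; the top 20 % of sound-responsive neurons by d′ (ceil(0.2 n),
minimum 1, stable ranking) are retained for bandwidth analyses.

## Synthetic ROI traces

Ground-truth receptive fields are rectangular bands in log-frequency per
level row: tone (f, l) is responsive iff l ≥ threshold and
|log₂(f/BF)| ≤ bandwidth(l)·gain(condition)/2, with bandwidth(l) a
V-shape (0.5 octaves at threshold, +0.25 octave per 10 dB). Rectangular
fields make the true BF, threshold and Q20 exact closed forms on the tone
grid. The condition gain scales the bandwidth multiplicatively (>1 widens,
<1 sharpens), emulating chelator effects on tuning. Within the band the
transient amplitude tapers linearly with octave distance from BF
(0.15/octave) and grows mildly with level (0.05/10 dB), making the
(BF, 80 dB) cell the unique response maximum.

Responsive tones inject a peak-normalized difference-of-exponentials
calcium transient (τ_rise 0.1 s, τ_decay 0.4 s) scaled by the ground-truth
amplitude, with lognormal repeat-to-repeat amplitude jitter (sd 0.2) and
additive white frame noise on a flat baseline. The 0.4 s decay is a
deliberate choice at the fast end of the GCaMP family: it clears
completely within the 2.5 s between a tone onset and the next trial's
baseline window, so baselines are uncontaminated and the noise-free
simulate → analyze round trip recovers BF, threshold and Q20 exactly — a
property a 1 s decay cannot satisfy at a 3.5 s stimulus period, where the
residual tail (up to ~3 % ΔF/F in the next baseline) exceeds the amplitude
difference between adjacent grid tones. The peak still falls ~0.19 s after
onset, well inside the 1-s quantification window.

**Noise calibration.** The default frame-noise SD (0.12 ΔF/F) was
calibrated once so that a truly responsive tone is detected from a single
presentation with probability ≈ 0.9, averaged over a cohort with
heterogeneous response amplitudes (per-neuron peak ΔF/F lognormal, sd 0.6,
around 0.5). After 5-repeat averaging the pipeline detects ≈ 99 % of
responsive tones with ≈ 2 % false positives. Cohort amplitude
heterogeneity is essential realism: it is what makes d′ ranking meaningful
and gives every cohort a core of high-SNR neurons whose paired Q20 change
is uncontaminated.

## Wide-field mapping

Movies are 150 × 200-pixel frames at 20 Hz. Per mapping-tone onset: each
pixel is converted to ΔF/F against its 1-s pre-onset mean, every frame is
low-pass filtered with a 2-D Butterworth filter (order 2, cutoff ratio 0.1
— the order and cutoff are not standardized; both are configurable), and
the 10 consecutive frames (0.5 s) beginning at the tone offset are
averaged; maps over onsets are averaged. Sound-responsive regions are
8-connected components above mean + 2 SD of the map with a minimum area,
sorted by area. The synthetic movie generator places Gaussian blobs
(emulating the low-frequency regions of A1 and the anterior auditory
field) whose time course follows the tone onsets.

## Statistics

Paired comparisons are gated by the Lilliefors normality test applied to
the paired differences (the quantity entering the paired test): pass →
Student paired t; fail → Wilcoxon signed-rank (exact distribution for
n ≤ 25 without zeros or ties, normal approximation with continuity
correction otherwise). With fewer than 4 pairs the Lilliefors test is
unavailable and the t branch is used. All-zero differences are degenerate
and flagged with statistic 0 and p = 1. Family-wise error over multiple
comparisons is controlled with the Holm-Bonferroni step-down rule (sort p
ascending; reject p₍ᵢ₎ while p₍ᵢ₎ ≤ α/(m − i + 1); stop at the first
failure). Balanced within-subject two-factor designs (treatment × pulse
position over cells) use a two-way repeated-measures ANOVA with the
treatment main effect as the headline value.

## End-to-end experiments

A master seed spawns per-stage child seeds (`numpy.random.SeedSequence`),
so any bundle is byte-reproducible from its manifest (config + seed +
version + config hash). The ephys track simulates 6 cells (12 for
recovery studies) × 2 conditions × 4 trials with lognormal cell-to-cell
amplitude variation (sd 0.2), applies QC, quantifies trains, normalizes
under every scheme, and runs the paired first-EPSC test plus
Holm-corrected per-pulse comparisons. The imaging track simulates a
40-neuron cohort before and after a bandwidth-gain "infusion", extracts
tuning metrics, and tests the paired Q20 change with the signed-rank test
across all paired neurons; it also reports the top-20 %-by-d′ subset.

Problem sizes used by the test suite and the acceptance script — 40-neuron
cohorts, 100 cohort replicates per condition, 200 ephys replicates, 1000
null replicates for family-wise error — are desk-scale choices that keep
a full run under a minute while leaving Monte-Carlo margins well inside
the asserted bounds.

## What the synthetic data does not show

The generators omit neuropil contamination, motion, temporally correlated
(shot/indicator) noise, spike-to-calcium nonlinearity, dendritic
filtering, series-resistance dynamics during a sweep, and any real
receptive-field shape beyond rectangular bands — so passing tests
demonstrate correctness of the measurement pipeline under its stated
model, not robustness to every artifact of real recordings. Per-neuron
ΔQ20 in a noisy cohort has heavy tails (false-positive tones inflate the
frequency span in either condition); cohort medians are robust to this,
but single-cohort signed-rank significance is underpowered at these
effect sizes because the contaminated, sign-balanced deltas dominate the
ranks. Direction claims should therefore rest on replicate medians, as
the acceptance suite does.
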