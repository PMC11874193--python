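# Methods

This note documents the models and procedures implemented in
`isochron`, the choices made where the design was genuinely open, and
what the synthetic-data validation does and does not establish.

## The paradigm and its arithmetic

Subjects listen to 96 sequences of 13–16 pure tones with a fixed
650 ms inter-onset interval (IOI), so the stimulation frequency is
Sf = 1/IOI ≈ 1.5385 Hz and sequences last 8.45–10.4 s. Each sequence
contains one or two softer (−4 dB) deviant tones; the first falls on
position 8–11 and the second, when present, on position 12. Analyses
use only standard tones at positions 3–7, which always precede the
first possible deviant; deviants exist in the schedule (they define the
task) but receive no distinct neural response in the generator, since
no analysis window touches them.

## Synthetic EEG generator

Each subject's recording is built at 500 Hz on 24 channels (the 16
fronto-central cluster labels plus 8 posterior labels) as a sum of:

1. **Tone-locked evoked activity.** A biphasic kernel — a negative
   Gaussian lobe (50 ms SD) whose extremum is placed exactly
   `evoked_latency` (default 100 ms) after each tone onset, and an
   opposite-sign lobe of 0.4 relative amplitude 100 ms later (75 ms
   SD) — is added at every tone with per-tone Gaussian latency jitter
   (`latency_jitter_sd`). The lobes are evaluated over their full ±4 SD
   support so the kernel starts and ends smoothly; its rise therefore
   begins slightly before the onset. This width was chosen
   deliberately: 3-cycle Morlet wavelets have spectral SD f/3, so a
   sharp kernel would leak tone-locked phase into the alpha/beta bands
   and contaminate the coherence analyses there; the wide kernel keeps
   the evoked energy essentially below ~8 Hz.
2. **Entrained oscillations.** A sinusoid at Sf (amplitude
   `entrain_amp`) and a weaker companion at the 4th harmonic
   (~6.15 Hz, `entrain_amp_theta`, representing theta-range
   entrainment). Each sequence draws a starting phase from a von Mises
   distribution with concentration `phase_kappa` (κ → ∞ is perfect
   locking, κ = 0 uniform), *referenced to the evoked train's phase at
   the same frequency* — entrainment is modelled as anticipatory
   alignment with stimulus-driven activity, so a concentrated phase
   adds constructively to the tone-locked response. Within a sequence,
   a piecewise-linear phase-offset track is drawn with one Gaussian
   sample per tone whose SD shrinks linearly in time:
   `sd(t) = max(0, phase_jitter_sd − buildup_rate·t)` (radians,
   rad/s). This linear tightening of phase is what produces a positive
   time-resolved coherence slope downstream, and `buildup_rate` is the
   generative knob the slope statistic must rank-recover.
3. **1/f background.** Independent per channel, spectrally shaped so
   the one-sided PSD is `10^offset · f^(−exponent)` (offset = log10
   PSD at 1 Hz in units²/Hz).
4. **Endogenous alpha rhythm.** A narrow-band Gaussian process centred
   at 10 Hz (1 Hz spectral SD, RMS `alpha_amp`), independent per
   channel and not phase-locked to the stimulus. Real EEG carries such
   a rhythm at every age; here it also serves a methodological role:
   it dominates the alpha/beta bands, flooring their trial-to-trial
   coherence at the null level so that residual evoked leakage through
   the wide 3-cycle wavelets cannot manufacture spurious alpha/beta
   group effects.

Evoked and entrained components are scaled by a fronto-central gain
profile (1.0 on cluster channels, 0.4 posterior); noise components have
unit gain everywhere. Sequences are separated by 2.5 s of background
only, with 4 s of padding at both ends, and sequence start times are
snapped to the 250 Hz grid so downsampling preserves alignment. All
randomness flows from one master `SeedSequence` through named
substreams (paradigm, evoked, phase, per-channel noise), so every
component is independently reproducible.

### Aging-like defaults

The default cohort templates encode the group differences the pipeline
is meant to detect: the older group has a deeper evoked kernel (−4.5
vs −3.0), slightly larger latency jitter (10 vs 8 ms), a 1/f background
that is both steeper (χ 1.2 vs 1.0) and higher at the 1 Hz pivot
(offset −0.25 vs −0.75) — the offset difference dominates, so the older
fractal component is larger across the whole 0.5–40 Hz fit range — a
much less concentrated entrained phase (κ 1.5 vs 8) and a slower
build-up (0.04 vs 0.20 rad/s). The evoked-amplitude/jitter/noise
combination was chosen so that the evoked train's signal-to-background
ratio at the frequencies the 3-cycle wavelets actually see is matched
between groups: group differences in N100 amplitude then do not leak
into the alpha/beta coherence slopes, which the study design treats as
negative controls. Between-subject scatter (SDs per field) is modest so
that desk-scale cohorts (8 per group) retain power.

## Preprocessing

Order: 0.1–50 Hz band-pass (4th-order Butterworth) → ICA hook → ASR
hook → automatic channel rejection → windowed artifact suppression →
40 Hz low-pass + downsampling to 250 Hz → sequence segmentation
(−4 s to +4 s around each sequence). All filters are zero-phase
(forward–backward second-order sections), preserving evoked latencies;
each pass applies |H|² in amplitude. ICA-based ocular correction and
artifact-subspace reconstruction are identity hook points: the
generator produces no ocular or burst artifacts, and real-data users
can substitute their own callables.

* **Channel rejection** flags channels whose variance exceeds 2.5× the
  median channel variance and replaces them with the mean of the good
  channels (the synthetic montage has no geometry; a spherical-spline
  backend can be substituted for real caps). Note an intrinsic
  property: with a multiplier ≥ 1, at most half the channels can ever
  be flagged, so the >50 % abort guard can only trip with aggressive
  settings.
* **Artifact suppression** computes one threshold per channel,
  mean(|x|) + 4·SD(x) over the whole recording, tests non-overlapping
  200 ms windows against it, merges adjacent flagged windows, and
  linearly interpolates each merged span between its edge samples. On
  clean data it is a no-op and it is idempotent.
* **Stability.** Repeating the *data-dependent* steps on their own
  output flags nothing new and changes <1 % of samples. The filters
  themselves are not idempotent on broadband input — a second
  band-pass pass re-attenuates energy near the 0.1 Hz edge of a 1/f
  signal by a few percent RMS — which is why stability is defined over
  the adaptive steps.

## N100 peak metrics

ERP epochs are re-cut to [−1, 8] s (2251 samples at 250 Hz), 20 Hz
low-pass filtered (on the padded parent epoch, so edge transients fall
outside), and centred by a single per-channel scalar mean over all
trials and the full window. For each sequence and each position 3–7
the FC-cluster-averaged waveform is searched in a 60 ms window centred
100 ms after the tone onset; the sample of largest absolute deviation
(ties: earliest) yields the signed amplitude and latency. The
most-negative-sample rule is available behind `peak_mode="negative"`;
on N100-like data the two agree. Intra-individual variability is the
unbiased variance of amplitude and latency across all
sequence × position observations of a subject.

Two measurement properties worth knowing: the global-mean correction
subtracts a window mean that, at high SNR, is dominated by the evoked
response itself, shifting amplitudes toward zero by that mean; and
single-trial extremum search adds noise-driven variance on top of the
generative latency jitter. Both are properties of the procedure, not
bugs, and both are common to all subjects.

## Spectral decomposition

Spectra of the [0, 8] s sequence segments are computed by direct
projection of the Hann-tapered signal onto complex sinusoids on the
grid {0.2, 0.4, …, 40} ∪ {Sf} Hz (a unit-amplitude sinusoid at a grid
frequency yields |coefficient| ≈ 1). An 8 s window has native 0.125 Hz
resolution, so no FFT bin falls on Sf = 1.5385 Hz; explicit projection
guarantees an Sf-anchored bin without zero-padding ambiguity and keeps
per-trial complex coefficients for the coherence analysis. A single
Hann taper is used: no smoothing bandwidth was available to
parameterize a true multitaper, and phase coherence requires one phase
estimate per trial.

The aperiodic ("fractal") component is fitted to the trial-averaged
log10 power over 0.5–40 Hz as a no-knee line, with two pruning
iterations that drop points whose positive residual exceeds the 97.5 %
envelope (narrow peaks poking above the background). Subtracting the
fitted model leaves the oscillatory residual; its value at the Sf bin
(FC-cluster averaged, power units) is the entrainment endpoint, and
the mean log10 of the fitted fractal curve over the fit range is the
scalar used for the group comparison of the fractal component (a
pointwise curve is also exportable).

Because the 40 Hz anti-alias and 50 Hz band-pass edges attenuate the
top of the fit range — enough to bias the exponent by ~0.24 — the
exactly known power response of the zero-phase filter chain
(`chain_power_response`, |H|⁴ per filter) is divided out of the
averaged power before fitting. Recovery of injected exponents is then
unbiased to <0.01 on noise-only input.

**Limitation:** the two-pass percentile pruning removes narrow peaks
(the Sf line and its harmonics) but cannot excise a broad spectral
bump; with the endogenous alpha rhythm at its default RMS the fitted
exponent is inflated by roughly +0.07. The bias is common to both
groups (equal `alpha_amp`), so group contrasts are unaffected; absolute
exponent values under strong rhythms should be read with this in mind.
Full multi-Gaussian peak parameterization is out of scope.

## Phase coherence

ITPC at a frequency is the resultant length of unit-normalized per-trial
complex coefficients: `|mean(c/|c|)|`, 1 for identical phases,
E[R] = √π/(2√N) under uniform phases. Exactly zero coefficients carry
no phase and are dropped with a warning; an all-zero cell is reported
missing (NaN).

The time-resolved variant applies the same statistic per time point to
single-trial complex Morlet coefficients (3 cycles — the one stated
parameterization, used for all bands — on a 0.2 Hz grid). Band series
are formed by computing coherence per (channel, frequency) first and
averaging afterwards, keeping the statistic a mean of well-defined
[0, 1] quantities. Band edges: delta 0.54–2.54 Hz (centred on Sf),
theta 4–8, alpha 8–12, beta 13–25 Hz; all configurable. The transform
is a batched FFT convolution streamed one frequency at a time (peak
memory one trials × channels × times block); it matches
`mne.time_frequency.tfr_array_morlet` to ~2×10⁻⁵ rad, which the test
suite asserts. Epochs enter the transform with their full ±4 s padding
so wavelet edge effects (support ≈ 5.6 s at 0.54 Hz) fall outside the
analysed interval.

The build-up statistic is the least-squares line through the band
t-ITPC from the 3rd tone onset (1.3 s) to the 8th (4.55 s), both
boundary samples included; slope p1 in coherence/s, intercept p2.
Half-open window alternatives change p1 by less than a grid step. Two
intrinsic properties of this statistic, visible in the synthetic data
and relevant to interpretation on real data: a periodic tone-locked
coherence waveform fitted over five IOI cycles yields a small nonzero
pseudo-slope proportional to the waveform's within-cycle asymmetry
(an O(1/n²) finite-window effect), and the wide 3-cycle wavelets mix
neighbouring bands' locked content into each band's series. Both
motivated the generator-design choices above.

## Group inference

Permutation tests exchange group labels (1000 label draws by default)
and report two-sided p with the add-one rule
`p = (1 + #{|null| ≥ |obs|})/(1 + n_perm)`, never exactly zero. The
pooled sample is sorted before permuting so the Monte-Carlo null is
invariant to relabeling and input order under a fixed seed. The
statistic is the group mean difference (variance difference for
variability endpoints); mean and variance statistics are vectorized.
The Group × Time (tone position) interaction is tested by permuting a
per-subject linear position-trend — a distribution-free analogue of
the repeated-measures ANOVA interaction term that avoids sphericity
machinery. No multiple-testing correction is applied across endpoints,
mirroring the study design.

The mixed-model analogue `y ~ 1 + Group + (1 | participant)` is
estimated in closed form for balanced designs only: group effect =
difference of group means; residual variance = pooled within-subject
variance; intercept variance = method of moments,
`max(0, S² − σ²_e/m)` with S² the pooled within-group variance of
subject means and m the observations per subject. Unbalanced input is
rejected with a pointer to REML tooling (statsmodels MixedLM, lme4);
inferential statistics (t, DF, CI) are intentionally not reproduced —
only the point estimates that the recovery benchmark needs.

## Validation scale and what it shows

The test suite validates each stage against independent oracles (Welch
periodograms, closed-form complex arithmetic, exhaustive permutation
enumeration, Bessel-ratio limits, MNE's wavelet transform) and the
whole pipeline against the generator's ground truth. Problem sizes are
chosen for desk-scale runs: the end-to-end group study uses the fast
profile (8 subjects per group, 24 sequences — the reference
configuration is 18/96); calibration and power properties run at the
statistic level with hundreds of replicates; build-up rank recovery
uses 4 rates × 10 replicate subjects of 48 sequences. Passing these
shows the estimators recover what this generator injects, at these
SNRs, under this paradigm; it does not certify behaviour on real EEG
with ocular artifacts, nonstationary rhythms, unbalanced trial counts
after cleaning, or montage geometry — for those, the ICA/ASR hooks,
the spline-interpolation backend and REML tooling are the intended
extension points.
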