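# Methods

This note documents the models, estimators and design choices behind each
pipeline stage, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing its
output.

## Stimulus synthesis

The noise movie is the inverse FFT of a band-limited random spectrum.  We
generate a real Gaussian white-noise field (time × y × x), transform it,
zero every coefficient whose radial spatial frequency exceeds the 0.05
cycles/° cutoff or whose |temporal frequency| exceeds 4 Hz, and invert.
Starting from a real field keeps the spectrum Hermitian, so the inverse
transform is real to machine precision and the out-of-band power is
exactly zero.  The pass band is flat; a shaped (e.g. mouse
contrast-sensitivity-matched) spectrum can be emulated by filtering the
returned stack, but flat-within-band is the default because only the
cutoffs are specified.

Normalization is linear: the stack is divided by its global maximum
|value| so frames lie in [−1, 1].  A percentile-based normalization with
clipping was considered and rejected — clipping is nonlinear and re-leaks
a few parts in 10⁵ of power outside the cutoffs, breaking the band-limit
invariant the movie exists to satisfy.

The contrast envelope is the raised cosine e(t) = (1 − cos 2πt/P)/2 with
P = 10 s: zero (gray screen) at the start of each cycle, one (full
contrast) at mid-cycle, zero again at the end.  A plain sinusoid would go
negative and cannot describe a gray→full→gray transition; the absolute
sine |sin(πt/P)| satisfies the same endpoints and is available via
`envelope_form="abs_sine"`.  The movie object retains the pre-envelope
stack (`base_frames`) so the intrinsic spatiotemporal spectrum can be
measured without the envelope's modulation sidebands.

Grating protocols cross 12 equally spaced drift directions with six
spatial frequencies plus an SF = 0 blank/flicker condition at each
direction, 1.5 s per trial.  Trials are uniformly shuffled within each
repeat block, so blanks are interspersed throughout (they supply the
spontaneous-rate estimate).  Pixel (0, 0) is top-left; x increases
rightward (azimuth), y downward (elevation).

## Synthetic populations

Each simulated neuron carries ground-truth parameters: per-eye grating
gains and preferred orientations, a shared tuning width, a direction
ratio (secondary lobe amplitude), log-Gaussian SF tuning (octave width),
a Hill contrast–response (c₅₀, exponent n), a spontaneous rate, and
per-eye noise-movie gains.  Cell class is broad-spiking with probability
0.8.  Base distributions were chosen once to resemble mouse V1: gains
log-normal with ~10 sp/s median (gratings) and ~8 sp/s (noise), ipsi/
contra ratio log-normal around 0.6 (contralateral bias), tuning widths
uniform on 15–35°, c₅₀ uniform on 0.2–0.5, spontaneous rates gamma with
mean 2 sp/s (broad) and 5 sp/s (narrow, fast-spiking cells fire more).

Treatment groups act through multiplier profiles.  The experiments
report no per-unit effect sizes, so the defaults are placeholders that
encode only the qualitative contrasts: LTMD suppresses deprived-eye
(contra) gains to ×0.25 and broadens tuning; open-eye gains potentiate
(×1.3, broad cells only); broad-cell spontaneous rates rise (×1.5) while
narrow-cell rates fall (×0.4); home-cage binocular vision recovers
partially (×0.4); noise+run restores contra noise gain to ×0.9 of normal
but grating gain only to ×0.5, grating+run the mirror image; binocular
orientation mismatch (circular spread of θ_pref differences) is 15° in
controls, ~35° after LTMD, and renormalizes only under grating+run.

Recovery of the experienced stimulus is activity-dependent at the unit
level, not a uniform population multiplier: for broad-spiking cells the
contra-gain multiplier of the experienced stimulus is graded by the
unit's relative preference for that stimulus, from the LTMD floor (×0.25)
at zero preference up to twice the configured mean at full preference, so
the population mean stays at the configured multiplier.  This implements
the reported selectivity — neurons initially more responsive to the
experienced stimulus recover more — and is what makes the fictive EMD
flow fields condition-specific.  Narrow-spiking cells recover partially
(×0.6) and non-specifically in both recovery groups.  A uniform
multiplier was tried first and discarded: multiplicative scaling alone
produces proportionally identical flow patterns in both recovery
conditions, contradicting the selectivity it is meant to emulate.

Trial noise is Poisson (counts ~ Poisson(rate × 1.5 s) for gratings; an
inhomogeneous Poisson process discretized at the frame rate for the noise
movie).  No over-dispersion is modeled by default.  The generator's SF
tuning is log-Gaussian while the analysis fits a difference of Gaussians;
the mismatch is deliberate, so SF-recovery tests measure robustness to
model error rather than self-consistency.  The study conditions are 6
grating repeats per eye and 10 minutes of noise viewing per eye (the
5-minute movie played twice); F1 estimates from much shorter records are
noisy enough to obscure the population-level flow asymmetries.

What the generator does **not** emulate: locomotion-gain dynamics within
a session, eye movements, slow drift in responsiveness, spike-sorting
contamination, correlated trial-to-trial variability, and any biophysics.
Passing recovery tests therefore demonstrate estimator correctness under
idealized Poisson conditions, not performance on real recordings.

## Per-unit metrics

Spontaneous rate is the mean rate over blank trials; evoked responses are
condition means minus spontaneous, preserved when negative (suppression)
in output tables but clipped to zero inside ODI/OSI ratios, which are
unstable for signed values.

Preferred orientation is half the complex phase of Σ F(θ)e^{2iθ} over the
baseline-subtracted responses averaged across spatial frequencies.  The
sum is used unnormalized: dividing by Σ F(θ) cannot change the phase when
the total is positive but flips it (a spurious 90° shift) when
baseline-subtracted totals go negative.  A vanishing resultant raises an
undefined-preference error and excludes the unit from orientation
analyses.  With θ_pref fixed, the tuning curve over the full 360°
direction domain is fitted with B + A₁g(θ; θ_pref, σ) + A₂g(θ;
θ_pref + 180°, σ), circularly wrapped Gaussians (±360° images, adequate
for σ ≤ 90°), bounds A₁, A₂ ≥ 0 and σ ∈ [3°, 90°], multi-started over
σ₀ ∈ {10°, 20°, 40°} with the lowest-residual solution kept.  If the
secondary lobe fits larger (A₂ > A₁) the preferred *direction* is
relabeled θ_pref + 180°; the orientation is unchanged.  R_pref and
R_ortho are read off the fitted curve (not raw data) at θ_pref and the
mean of θ_pref ± 90° — fitted values are less noise-sensitive, and the
OSI follows.  Tuning width is the half-width at half-maximum of the fit
above baseline, found by a 0.01° grid scan with linear interpolation; for
an isolated Gaussian it equals σ√(2 ln 2).

The binocular mismatch is (θ_contra − θ_ipsi) wrapped into (−90°, 90°],
with the boundary mapped to +90°; analyses use |ΔO|.  SF tuning is a
difference of Gaussians on the linear SF axis with nonnegative
amplitudes, fitted at the tested directions nearest the preferred
orientation; the preferred SF is the argmax of the fitted curve on a fine
grid up to twice the highest tested SF, falling back (flagged) to the raw
argmax when the fit fails.

The F1 response folds the binned counts into one 10-s contrast cycle
(integer bins per period enforced, ≥2 full cycles) and reads the first
Fourier harmonic of the cycle-averaged rate, 2|Σ r_k e^{−2πik/m}|/m, in
spikes/s.  The contrast–response curve bins rates by instantaneous
contrast (20 equal-width bins on [0, 1]); C½ is the lowest contrast at
which the linearly interpolated curve crosses (max + baseline)/2, with
the baseline taken from the lowest-contrast bin; a curve that never
crosses leaves C½ undefined (NaN).

Units are responsive to gratings at ≥2.0 sp/s peak evoked response
through either eye, and to the noise at F1 > 0.2 through either eye.
Broad/narrow classification is a two-criterion rule — narrow iff
trough-to-peak < 0.5 ms *and* waveform slope 0.5 ms after the trough ≤ 0
— with thresholds calibrated against the generator's feature
distributions (the literature rule names the features but no numeric
boundary).

## Imaging analysis

Movies are trimmed to an integer number of stimulus cycles (≥2) and each
pixel regressed on [constant, linear drift, cos 2πft, sin 2πft] jointly.
Joint estimation matters: a linear ramp correlates with a sinusoid even
over whole cycles, so detrending first biases the amplitude low by a few
percent.  Amplitude is the single-sided equivalent 2|X_f|/N (= the
regression amplitude); phase follows the Σ x e^{−iωt} convention.  No
hemodynamic deconvolution and no spatial smoothing are applied.  ROI
masks are caller-supplied; ROI amplitude is the mask mean, and reported
response amplitudes average ≥4 independent measurements.  The imaging
ODI is (R − L)/(R + L) from peak amplitudes through right and left eyes.

## Fictive-longitudinal EMD

Populations recorded before and after treatment contain different
neurons, so correspondence is reconstructed by optimal transport in the
2-D response plane (peak grating response, noise F1), restricted to the
500 most responsive units per population (ranking score
max(g/s_g, f1/s_n)).  Axes are scaled by the pooled 95th percentile of
each response before transport so both span ~[0, 1] — the two responses
live on different spikes/s scales and would otherwise weight the ground
distance unequally.  Masses are uniform (1/|A|, 1/|B|); equal-size
problems are solved exactly as an assignment (`linear_sum_assignment`),
unequal sizes by the exact transport LP (HiGHS), where mass may split.
Total cost is the mass-weighted mean transport distance in scaled units.
Flow heat maps bin each flow at its source on a 25 × 25 grid over the
scaled plane and accumulate mass × displacement along one axis, reported
in original spikes/s.

The chi-square contrast between two recovery conditions builds the 2 × 2
table {above, below diagonal} × {condition} of positive-flow magnitudes,
rescaled by each flow field's source-cloud size so entries are per-neuron
displacement sums (a count-like scale), and tests homogeneity against
equal flow in the two conditions: expected values are half of each
diagonal-side total, df = 2.  This makes the statistic sensitive both to
a difference in total positive flow along the axis (the magnitude of
stimulus-specific recovery) and to a shift of flow across the diagonal
(which units recover).  A plain independence test on the same table was
evaluated and rejected: it compares only above/below proportions, which
are nearly invariant under the multiplicative components of recovery and
carry little power here.  The exact contingency construction behind the
original analysis is not recoverable; this one is our declared choice.

## Group statistics

Medians are reported with a bootstrap standard error (standard deviation
of the median over 1000 with-replacement resamples, seeded).  Cumulative
distributions are compared by the two-sample Kolmogorov–Smirnov test
(exact p for n ≤ 25 per sample, asymptotic otherwise), Bonferroni
corrected with family size = the number of group pairs per metric (the
alternative, one global family across the whole table, is available by
passing `m`), and bucketed into {<0.00001, <0.0001, <0.001, <0.01,
<0.05, n.s.}.  ANOVA and Kruskal–Wallis omnibus tests are thin
pass-throughs to scipy.

## Problem sizes and determinism

Default test and validation sizes: 200 units for tuning recovery, ~640
broad-spiking units per treatment group (top 500 most responsive
analyzed) for the population-level pattern, 10-minute noise records,
100 random instances (≤8 points) for the EMD permutation oracle.  Every
stochastic step takes an explicit seed; identical seeds reproduce every
table bit-exactly, and the streamed population-F1 path draws the same
variates as the table-based path for the same seed.

## Known limitations

Generator effect sizes are qualitative placeholders; absolute medians and
distances are not comparable to any real dataset.  The F1 has a positive
noise floor (|complex estimate| of a noisy zero is Rayleigh), so weak
units' noise responses are biased upward; group contrasts are affected
equally and orderings are preserved.  C½ is undefined for non-monotone
noisy curves that never cross half-maximum.  The imaging module assumes a
stationary sinusoidal response; it does not model hemodynamic delay
(which appears as a phase offset) or nonstationary amplitude.
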