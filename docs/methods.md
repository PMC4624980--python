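# Methods

`cacor` reconstructs the note-onset structure of continuous sound from
multichannel EEG and quantifies how strongly, and where, a listener's
brain tracks it.  This note documents the model, the numerical choices,
and what the synthetic benchmarks do and do not establish.

## The regression target: the audio power slope

Note onsets are rapid increases in sound intensity.  The waveform is cut
into 50 ms frames with 50 % overlap and the mean squared amplitude per
frame gives a 40 Hz short-time power series (this series doubles as the
*sound intensity* feature).  The power series is smoothed with a
three-tap Gaussian kernel (sigma = one sample, unit sum — the only
reading of a "three-sample" Gaussian consistent with its width), forward
differenced (scaled by the frame rate; the scale is immaterial because
every downstream use is a correlation), and linearly interpolated onto
the 100 Hz EEG grid.  The signed slope is kept: falling intensity
carries information too.  Before the first difference the series is
edge-padded so a constant input yields an identically zero slope rather
than boundary artifacts.

## Stimulus reconstruction: temporally embedded shrinkage ridge

EEG preprocessing is a Chebyshev-I lowpass (42 Hz passband edge, 49 Hz
stopband, 0.3 dB per-pass ripple, 40 dB stopband), decimation to 100 Hz,
then a second-order 1 Hz Butterworth highpass — all applied
forward-backward (zero phase), so no filter latency has to be absorbed
by the embedding.  The analysis band is therefore 1–42 Hz broadband.

The design matrix augments the n-channel EEG with lagged copies,
L = 30 lags at 100 Hz spanning response latencies of 0–300 ms.  Lag
convention: **column (c, l) at row t holds channel c at time t + l**.
The cortical response *follows* the stimulus by up to ~300 ms, so
reconstructing the slope at time t needs the EEG just after t; with
this convention the reconstruction is sample-aligned with the stimulus.
The last L rows of each recording are zero-padded and excluded from
training; embedding never crosses a concatenation boundary.  For 61
channels this yields 61 x 31 = 1891 regressors.

The fit is covariance-form ridge regression:

    w = ((1 - lambda) S + lambda nu I)^(-1) Cov(X, y),

with S the empirical covariance of the (mean-centred) design, nu the
mean of its diagonal, and lambda the analytic Ledoit–Wolf shrinkage
toward nu I (clipped to [0, 1]; designs with fewer than four usable rows
or zero variance get lambda = 1).  At lambda = 0 this is exactly
ordinary least squares, which the test suite verifies against a
normal-equations oracle.  Note that for isotropic data the shrinkage
target *is* the true covariance, so the analytic lambda is close to 1
there by design; it vanishes only for well-sampled anisotropic data.
X and y are centred per training set and the intercept is stored.

Filters are trained on two concatenated presentations of a stimulus and
applied to the held-out third (leave-one-recording-out), so a
significant held-out correlation reflects stimulus-driven structure
that generalises across presentations.

## Patterns, SVD, MUSIC

A backward-model filter is not interpretable as a topography; the
activation-pattern transform A = Cov(X) w / Var(Xw) is applied
(computed as X'(Xw) so the 1891 x 1891 covariance is never formed).
The channels x lags pattern is truncated by SVD at 98 % of the squared
singular mass and the retained spatial subspace is decomposed by a
recursive MUSIC scan: at each round the grid dipole whose best-oriented
field maximises the subspace correlation (a 3x3 generalised eigenvalue
problem per grid point) is emitted as a unit-norm component and
projected out of both subspace and gains.  The scan stops at four
components or when the correlation drops below 0.8; the first component
is always emitted.  Components need not be orthogonal.  Component time
courses are least-squares weights of the component map over the
retained pattern (weights over lags 0–300 ms); they are FIR-filter-like
descriptions of how evidence is integrated over latency, *not* ERP
waveforms.

The head model is a homogeneous unit sphere.  Electrode positions come
from the standard 10-20/10-10 montage, re-centred by a least-squares
sphere fit and normalised to unit radius (head frame: x toward the
right ear, y toward the nasion, z up).  Dipole potentials use the
classical Legendre series for a current dipole in a conducting sphere,
truncated at 80 terms (the outermost shell at radius 0.85 converges to
~1e-5); the grid places quasi-uniform Fibonacci points on concentric
shells at radii 0.30–0.85, and gain rows are average-referenced.
Mastoid channels A1/A2 lie outside the model and are dropped on read.
This model is generic by intent: the decomposition only requires a
self-consistent forward model, and the benchmarks (localization within
one grid spacing, spatial cosine >= 0.99 at SNR 10) are self-consistency
checks, not claims about real anatomy.

Per-subject component selection uses a reference topography: the
average onset-ERP topography (peak |amplitude| at Fz within
0.13–0.28 s, averaged over +-10 ms and across subjects, unit-normalised)
and the absolute cosine as similarity (scale- and sign-invariant; ties
break toward larger explained variance).

## Significance under autocorrelation

Both the projection and the slope are strongly autocorrelated, so two
corrected tests are computed for every correlation:

* **Surrogate test** — the slope is Fourier phase-randomised (amplitude
  spectrum preserved); p = (1 + #{r_surr >= r_obs}) / (n_surr + 1) with
  999 surrogates by default, one-sided positive by default (two-sided
  available).  Randomising the stimulus side leaves all EEG properties
  untouched.  The p floor is 1/(n_surr + 1); with Bonferroni correction
  over 27 presentations (alpha 0.05) the 999-surrogate floor of 0.001
  still clears the 0.00185 threshold.
* **Effective degrees of freedom** — 1/N* = 1/N + (2/N) sum_j
  ((N-j)/N) rho_xx(j) rho_yy(j) over lags up to 2 s (10 s for partial
  correlations), biased autocorrelation estimates, N* clipped to
  [2, N], and a t-test on N* - 2 df.  For matched AR(1) series this
  reproduces the closed form N (1-phi^2)/(1+phi^2).

Presentation-level p-values are Bonferroni-corrected within each
stimulus; the **CACor score** counts significant presentations.  The
grand-average CACor correlates the element-wise mean projection with
the slope (single test, uncorrected alpha).  Time-resolved CACor uses
3 s windows with 90 % overlap (0.3 s step, 3.33 Hz series); windows with
fewer than 10 finite pairs are NaN.

Profile comparisons use Spearman correlation with mid-ranked ties and,
for nine or fewer stimuli, an exact two-sided permutation p over all
rank permutations (the t approximation deviates from the exact value by
up to ~0.02 at n = 9, so the exact form is used where feasible).
Feature relationships use partial correlations: target and feature are
residualised on the remaining eight features (minimum-norm least
squares; collinear controls are tolerated with a warning), the residual
correlation is tested with the 10 s effective-df correction, two-sided,
and tables are FDR-controlled (Benjamini–Hochberg, q = 0.05).  When the
listwise-complete series is too short to support the full 10 s horizon
(short stimuli, NaN frames) the horizon is clipped to half the series
length with a warning.

## Ratings: lag, activity, coordination

Continuous tension ratings (nonnegative joystick deflection, 50 Hz) are
compared pairwise (Pearson, two-sided surrogate significance) and
lag-corrected: the z-scored mean rating is cross-correlated with sound
intensity on a 0–3 s grid in 10 ms steps; if the best nonzero lag does
not beat the zero-lag correlation by 0.01 (no clear peak — typical for
unstructured sounds) the lag falls back to exactly 1.0 s.

Activity analysis counts, per 1 s window with 50 % overlap, the
percentage of raters whose rating rises / falls (net change over the
window; zero change counts as neither, so rise + fall <= 100).  The
null circularly shifts each rater by an independent uniform offset,
preserving individual dynamics while destroying alignment; a window is
significant when its observed max(rise, fall) strictly exceeds the 95th
percentile of its own null.  With 14 raters the statistic is discrete;
this quantile rule calibrates at an empirical window rate of ~0.02–0.04
under the null (a p-value formulation with the +1 convention is
noticeably more conservative).  The **Coordination Score** is the
fraction of significant windows (a count would not compare stimuli of
different durations; the count is reported alongside).

## The synthetic generator

The generator defines the study conditions end to end:

* **Stimulus** — an isochronous major-triad chord sequence: 350 ms
  chords with 17.5 ms linear rise/fall ramps, 420 ms interonset
  interval, root change after 7–11 repetitions; onsets only for
  complete IOI cycles (floor(duration/IOI) onsets); optional uniform
  onset jitter as a fraction of the IOI.
* **EEG forward model** — the signed power slope convolved with a
  biphasic kernel (Gaussian lobes: negative at 100 ms, positive at
  180 ms, 30 ms width — the canonical N1–P2 timing), radiating through
  the field of a fronto-central radial dipole of the spherical model.
  Per-channel pink (1/f) noise at unit RMS plus a common 10 Hz alpha
  component from a posterior dipole.  ``snr`` is the average per-channel
  signal-to-noise amplitude ratio at coupling 1; ``coupling`` in [0, 1]
  scales the planted response (0 = EEG independent of the stimulus).
  A rectified-drive variant exists to probe model mismatch.
* **Ratings** — each rater mixes a lagged shared latent course with an
  individual smooth random course (Gaussian-filtered noise, ~0.3 s
  scale: smooth like joystick movement but with enough effective
  degrees of freedom that independent raters are genuinely
  uncorrelated), plus sensor noise, shifted to a positive baseline and
  clipped at zero.

What the generator does *not* emulate: eye/muscle artifacts (inputs are
assumed pre-cleaned), volume conduction beyond the single sphere,
non-stationary attention or arousal, and real music's spectral
complexity.  Passing benchmarks therefore demonstrate the statistical
machinery is calibrated and powerful under the stated forward model —
not that real EEG will reach any particular effect size.

## Benchmark problem sizes

The benchmark study is scaled down from the full design to desk scale:
nine stimuli of 40 s at a 19-channel standard 10-20 montage, three
subjects x three presentations each (nine presentations per stimulus),
with couplings (0.10 … 0.010, 0) spanning the detection transition of
the regression at unit SNR — the synthetic analogue of a stimulus set
running from an isochronous chord sequence down to unstructured
soundscapes.  Calibration runs use 216 null presentations on an
8-channel montage with 20 s stimuli.  These sizes are the package's
benchmark definition; `scripts/acceptance.py` re-runs them from scratch.

## Known limitations

* Pulse clarity and key clarity are simplified composites
  (autocorrelation peak ratio; Krumhansl–Kessler profile correlation)
  intended to order stimuli, not to reproduce any toolbox numerically.
* The spherical head model has no skull/scalp conductivity layers; only
  relative topographies are meaningful.
* Audio/EEG alignment is assumed exact (in acquisition the stimulus is
  recorded as an extra EEG channel); no resynchronisation is attempted.
* The sharpness feature is computed from the 40 Hz frame-power series;
  spectral flux uses normalised spectra.  Fluctuation analysis is fixed
  to the 0–10 Hz envelope band with the DC bin excluded.
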