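# Methods

This note documents the models and numerical choices behind `moveson`,
what the synthetic-data generators do and do not emulate, and the design
decisions taken where the underlying procedure left room.

## Sonification mapping

The training frame is a 51 × 51 cm board (nine equal fields, 3 × 3) with
51 cm vertical bars divided into six equal intervals labelled c′–a′.
Conventions fixed here (the physical setup does not pin them down
numerically):

* Axes: x runs left→right (timbre), y vertical (pitch), z
  proximal→distal (loudness); origin at the patient-side left board
  corner. Fields are numbered row-major from the patient's near-left
  corner.
* Pitch intervals are half-open `[low, high)` with the very top of the
  bar closed into interval 6, so every in-frame position maps to exactly
  one (field, pitch, timbre) triple.
* Default tuning table: the endpoints are kept exactly as the training
  software used them — c′ = 226.6 Hz and a′ = 440 Hz. Note that
  226.6 Hz is *not* equal-tempered c′ (261.63 Hz when a′ = 440): the
  endpoint is reproduced deliberately rather than "corrected", and the
  interior notes (293.66, 329.63, 349.23, 392.00 Hz) are equal
  temperament anchored at a′ = 440. The table is fully configurable.
* Loudness is a linear dB ramp along z spanning 20 dB (0 dB at the
  proximal edge); only monotonicity is inherent to the setup.
* Event discretisation uses a hysteresis dead band of 5 % of one
  interval height: a pitch change registers only once the hand is past
  the boundary by that margin, which debounces sensor jitter at interval
  boundaries (verified by a brute-force event-count oracle).

## Movement smoothness

Strokes are segmented automatically (the original workflow was manual):
trajectories are linearly resampled to a uniform 60 Hz grid, dropout
gaps > 250 ms are excluded, vertical velocity is smoothed with a
5-sample moving average, and strokes are delimited by its sign changes,
kept when the vertical excursion is ≥ 30 % of the bar height and the
duration ≥ 0.3 s.

Per sample, squared curvature is computed from central finite
differences (one-sided at stroke edges):

    κ² = (|v|² |a|² − (v·a)²) / |v|^(2p)

The default exponent is **p = 3**, the standard squared geometric
curvature of a space curve (`|v×a|²/|v|⁶`, units cm⁻²). A variant of
this formula circulates with the denominator `|v|²`; that form is
dimensionally inconsistent with curvature — the analytic circle oracle
(κ² = 1/r², independent of traversal speed) passes only with p = 3 — and
is presumed a typesetting loss of the cube. It remains available via
`exponent=1` rather than being silently corrected.

Numerical guards: samples slower than 0.5 cm/s are clamped (curvature is
meaningless at near-zero speed) and κ² is floored at 1e−12 before the
logarithm; the clamped fraction is always reported so analyses can
detect degenerate strokes. The per-stroke statistic is
`MedianLC = median(−ln κ²)`; under p = 3 it shifts by exactly +2·ln s
when the trajectory is spatially scaled by s, and is invariant to
traversal speed — both are tested.

Optical tracking data are Savitzky–Golay smoothed (window 9, cubic)
during resampling before differentiation; optical marker noise is white
in position and would otherwise dominate the second derivatives.
Inertial positions are already model-integrated and smooth, so they are
not smoothed. MedianLC is computed per stroke; pooling across a
patient's strokes happens in the multilevel model, not by pre-averaging.

## Record table

`build_records` emits one row per stroke with the modelling covariates:
`Group.c` and `MoCap.c` centred at ∓0.5, `Session.c` centred at the
per-patient median session, and `pre.z` = each patient's mean smoothness
over the pre-intervention session (session 0), standardised across the
cohort. The outcome is z-scored across all training-session records by
default; the raw MedianLC column is kept alongside, and
parameter-recovery analyses fit the raw outcome so coefficients stay in
the generator's units.

## Bayesian models

*Pre-intervention clinical differences.* For each scale, the z-scored
pre score is regressed on the treatment indicator (0/1) with
Student-t(3, 0, 1) priors on intercept and slope and half-t(3, 0, 1) on
the residual SD. Reported: posterior median, 50 % and 90 % central
intervals, and the posterior mass further than 0.9 SD from zero.

*Smoothness model ladder.* Gaussian linear mixed models of increasing
complexity (ladder #1–#7), e.g.

    MedianLC ~ Group.c × Session.c + pre.z + MoCap.c + (Session.c + pre.z | IDanon)

with Student-t(3, 0, 3) priors on population coefficients, half-t(3, 0, 3)
on all SDs and LKJ(η = 2) on the correlation matrix of the varying
coefficients. Models #6 and #7 extend #5 with the Group×MoCap and
pre×MoCap interactions respectively (their original description is
prose-only; the additive extension is this package's interpretation).

*Sampling.* Because likelihood and random effects are both Gaussian,
the per-patient varying coefficients are integrated out analytically and
MCMC runs on the low-dimensional marginal posterior
(β, log σ, log τ, partial correlations) with the affine-invariant
ensemble sampler (emcee), using per-group sufficient statistics so one
likelihood evaluation is O(#patients) regardless of record count.
Correlation matrices are parameterised by canonical partial correlations
(tanh-transformed); under LKJ(η) these are independent shifted
Beta(a, a) with a = η + (q − 1 − ℓ)/2 for layer ℓ, which the prior
sampler reproduces and the tests verify (q = 2, η = 2 ⇒ Var(r) = 1/5).
Defaults: 32 walkers × 1500 steps, first half discarded; walkers are
regrouped into 4 pseudo-chains for split-R̂ and ESS (arviz). The
convergence gate is R̂ < 1.01, reported as a flag rather than an
exception so pipelines can log and continue. Per-patient coefficients
are recovered from their exact Gaussian conditional given each posterior
draw — partial pooling is therefore exact, and the shrinkage contract
(sparser patients pulled harder toward the population mean) is tested
directly.

*PSIS-LOO.* The pointwise log-likelihood matrix is built by drawing the
varying coefficients from their Gaussian conditional per retained draw
(this samples the joint posterior exactly) and evaluating the
*conditional* per-observation density, matching common multilevel
practice. Consequence worth knowing: a covariate that is constant
within patients (like `pre.z`) is absorbed by a varying intercept and
contributes nothing to conditional LOO — model-comparison power for such
covariates exists only relative to models without that varying term.
Pareto-smoothing and the k diagnostics are delegated to arviz
(observations with k > 0.7 are flagged); pairwise comparison uses the
paired pointwise contributions with SE = √(n·Var(dᵢ)). The estimator is
validated against brute-force refit LOO (n = 8) within 0.3 elpd.

## Neurophysiology

*Preprocessing.* Linear detrend, then three zero-phase stages in the
stated order: 2–80 Hz band-pass, 1–80 Hz 3rd-order Butterworth
band-pass, 49–51 Hz band-stop (both band-passes are applied
sequentially rather than treating the first as preliminary). At 200 Hz
the 80 Hz corner leaves headroom to Nyquist; lower rates are rejected.

*EMG onsets.* Rectified, 5 Hz low-pass envelope; a detection fires when
the envelope crosses an individually adjusted threshold (accepted range
30–110 µV, default 50 µV) and is then back-tracked to where the envelope
last exceeded 20 % of the threshold, which removes the ramp-induced
latency (verified to ±50 ms against generator ground truth). A 3 s
refractory lockout suits movements paced ~5 s apart.

*Epoching.* Default window −1 to +2 s around EMG onset. Visual trial
inspection is replaced by an automated criterion: any EEG channel
exceeding 150 µV peak-to-peak rejects the trial, with reasons logged;
EMG is exempt (bursts are high-amplitude by design).

*WPLI.* Per epoch a single taper and FFT give the imaginary
cross-spectrum Im S_xy between each EEG channel and the EMG; the band
estimate pools trials *and* the 14–20 Hz bins into one ratio
`|Σ Im| / Σ |Im|`, keeping the null bias at ~1.13/√(n_trials·n_bins)
(≈ 0.04 at 100 trials). Two deliberate choices: the default taper is
**rectangular**, because for broadband signals it leaves the DFT bins
uncorrelated and the pooled estimator attains that nominal null level
(a Hann taper's inter-bin correlation roughly halves the effective bin
count and inflates the null to ~0.1); and the per-bin
averaged-across-band estimator remains available via
`band_average=True`. Purely real (zero-lag, volume-conducted)
cross-spectra are defined as WPLI 0. Significance is a jackknife z-test
on the *signed* ratio u = Σ Im/Σ|Im| — u is symmetric about 0 under the
null, whereas the folded |u| is positively biased and a naive z-test on
it would be anticonservative; the two-sided 5 % flag is calibrated in
the tests.

*Cluster permutation.* The trial-level coherence contribution is the
leave-one-trial-out jackknife pseudovalue of the band WPLI,
`n·W − (n−1)·W₋ᵢ`. Channels are compared pre vs. post by two-sample t on
pseudovalues; |t| above the two-sided α = 0.05 quantile forms
candidates, a candidate survives only with ≥ 2 suprathreshold
same-sign neighbours, connected components are summed, and the null is
the permutation distribution (trial labels shuffled) of the maximal
absolute cluster statistic; signed clusters are reported separately.
Adjacency comes from a packaged schematic 2D layout of the 20-channel
10–20 montage with a distance threshold of 0.50 head-radii, giving a
mean neighbour count of 3.5 (C3's neighbours: F3, P3, T3, Cz). Type-I
error is verified ≤ 0.075 at nominal 0.05 over 200 null subjects.

## Synthetic data: what it emulates, what it does not

*Trajectories* are piecewise minimum-jerk (quintic) vertical strokes
between note-interval centres; one full ascent or descent takes 2 s by
default (the stroke-duration distribution of real patients is not
documented; it is a configuration parameter, not an assertion).
Impairment is modelled by the `corruption` knob: a Poisson(corruption)
number of Gaussian position bumps per stroke (amplitude
0.6·corruption cm, width ≈ 0.12 s, random 3D direction — endpoints
unchanged) plus a 4 Hz horizontal tremor with amplitude
0.06·corruption cm, so roughness grows smoothly and strictly with the
knob. Sensor dialects: *inertial* = uniform 60 Hz, 0.002 cm noise;
*optical* = jittered sample times, 0.012 cm noise, occasional 1–3-sample
dropouts that are flagged, never silently deleted. Not emulated:
hemiparetic biomechanics, fatigue, learning within a session, or
marker-swap artifacts — so passing recovery tests demonstrate the
statistical machinery, not clinical realism.

*Cohorts* place each patient-session's latent smoothness on the MedianLC
scale (baseline 5.0; defaults: 14+14 patients, 15 training sessions plus
a pre session, group effect 0.5, patient SD 0.25, session slope 0.01,
device effect −0.3, devices alternating within arms) and realise it
through the corruption knob via a monotone inverse map calibrated by
simulation (≈ 3,000 strokes per dialect; shipped as a versioned JSON
fixture, rebuilt by `scripts/build_calibration.py`). Latents outside
the calibrated range clip to it. Under these defaults the total record
SD is close to 1, so design effects read as approximate SD units; the
recovery analyses fit the raw outcome so the Group coefficient estimates
the design's group effect directly.

*Clinical tables* are independent Gaussians per scale with plausible
subacute-stroke means/SDs and optional group offsets in SD units — they
are opaque numbers by construction, matching how the pipeline treats
them.

*EEG/EMG*: 20-channel 10–20 EEG (1/f background) plus a deltoid EMG of
envelope-gated broadband bursts every ~5 s. Coupling injects a
band-limited Gaussian beta process (centre 17 Hz, 6 Hz bandwidth) into
the chosen EEG channels and, delayed by 15 ms, into the EMG;
`coupling_strength` c mixes the shared and an independent beta component
as c and √(1−c²), so the EMG beta variance is constant and WPLI grows
monotonically with c (c = 0 ⇒ independence; c = 1 with zero noise ⇒
WPLI = 1). No volume conduction or source geometry is modelled — the
montage matters only through cluster adjacency.

## Problem sizes in the test suite

The suite's simulation scales were chosen as the smallest that make the
statistical contracts sharp: 200 null subjects × 500 permutations for
the cluster type-I bound, 20 replicate cohorts (14+14 × 15 sessions) for
group-effect recovery, 100 replicate null tables for interval coverage,
and n = 8 with eight refits for the exact-LOO oracle. The full suite
runs in a few minutes on one core.

## Known limitations

* The ensemble sampler mixes slowly for variance components near zero
  (the usual funnel); the R̂ gate flags such fits. A reparameterised
  HMC would mix better but is not required for the estimand-level
  contracts tested here.
* Conditional-likelihood LOO cannot rank patient-constant covariates
  against models that already carry a varying intercept (see above).
* The EDF ingest path maps channels by name and reads no annotation
  events; onsets must be re-detected from the EMG.
* Cluster p-values are resolution-limited by the permutation count
  (minimum p = 1/(n_perm + 1)).
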