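# Methods

This note documents the models, conventions, and numerical choices behind
each analysis stage, what the synthetic-session generators do and do not
emulate, and the known limitations.

## Time and binning conventions

All stored times are seconds relative to the drug injection (t = 0); the
baseline period occupies negative time and spans 30 minutes.  Binned series
use half-open 1-minute bins [k, k+1): an event exactly at the injection
belongs to bin 0.  Windowed areas (AUC) over binned series integrate the
piecewise-constant series exactly (bin value × overlap), which preserves
additivity over window partitions; AUC over irregularly sampled AIM
observations uses the trapezoid rule with linear interpolation at window
edges.  The dyskinesia onset window is 0–20 min post-injection and the
offset window 30–90 min.

## Photometry

**Motion correction.** The isosbestic (405 nm) channel is mapped onto the
signal (465 nm) channel with a first-degree polynomial fit over the whole
session and the fitted artifact is subtracted.  The isosbestic channel
carries no calcium/dopamine signal, so its fitted projection estimates the
shared non-biological component (fiber bending, autofluorescence drift).

**ΔF/F.** For calcium-indicator sessions a single decaying exponential plus
offset is fit (least squares) to the raw 465 nm channel to model gradual
photobleaching; ΔF/F% = 100 × (f465 − fitted405) / F0(t) with F0 the bleach
fit.  This form is exactly 0 % for a flat artifact-free trace and is
invariant to rescaling both raw channels by a common positive factor.  A
non-convergent exponential fit falls back to a linear trend (flagged in the
processing record); dopamine-sensor (GRAB-DA) sessions skip bleach
correction and normalize by the pre-injection mean instead, since the
quantity of interest there is a slow sustained elevation, not fast
transients.  Degenerate inputs (constant isosbestic channel, zero residual
signal) fall back to intercept-only fits or a defined ΔF/F ≡ 0, always
flagged.  The trace is then smoothed with a centered moving average
(default 0.5 s).

**Transient detection.** The upper envelope of the smoothed ΔF/F is built
by linear interpolation across its local maxima (a sliding-window maximum
is available as an alternative backend).  Envelope valleys are paired with
the immediately following envelope peak, in time order, each peak used at
most once; a pair whose rise *strictly* exceeds the threshold (default
2 % ΔF/F) yields one transient stamped at the peak with the rise as its
amplitude.  The strict inequality makes detection of a single clean
excursion a step function exactly at the threshold, which the test suite
verifies by bisection to 0.01 %.

Whether a published envelope is upper-only or upper-minus-lower, and
whether the 2 % criterion applies to envelope or raw extrema, are not
settled conventions; this package applies the criterion to upper-envelope
extrema and exposes the envelope backend in configuration.

**Session metrics.** Baseline rate is the mean per-minute transient count
over [−30, 0) min; the baseline-subtracted series Δr feeds the onset/offset
AUCs.  Time-to-baseline is the first 1-minute bin after the absolute peak
of |Δr| at which the series returns to within a tolerance band of zero
(default: crosses zero) and stays there for 5 consecutive bins; sessions
that never satisfy this are censored at session end and flagged, never
silently imputed.  Both the band and the run length are configurable.
Dopamine-sensor sessions are quantified on 1-minute binned ΔF/F (peak and
windowed AUC) without event detection.

## Behavior

AIM observations carry integer scores 0–4 per body segment (axial, limb,
orolingual); the total is their sum, at most 12.  Two scoring schedules are
supported: dense (every minute for 20 minutes post-injection, then every
5 minutes to 120) and sparse (every 20 minutes over 2 hours).  Time to AIM
resolution is the earliest scored time after the session's peak total at
which the total is 0 and remains 0 for every later observation; sessions
never reaching sustained zero are censored at the last timepoint.  Window
edges outside the scored span extend the nearest observation's value by
default (a zero-anchor policy is available); this makes a constant
timecourse integrate as a rectangle.  Velocity is averaged in half-open
1-minute bins with the partial trailing bin dropped.

## Single units

Units are screened on a refractory criterion — the fraction of inter-spike
intervals shorter than 2 ms must be below 1 % — and split into putative
MSNs versus putative interneurons by waveform peak-to-valley duration
(default boundary 0.3 ms, a convention from prior striatal recording work;
configurable and logged on use).  Only putative MSNs are classified.

Response classification compares firing rates in 1-minute bins over the
baseline ([−30, 0) min) and post-injection ([10, 40) min) windows with a
two-sided, tie-corrected asymptotic Mann-Whitney test; p < 0.01 assigns
increase/decrease by the sign of the mean rate change, otherwise no-change.
Degenerate all-tie inputs are assigned p = 1.  On discrete count data the
asymptotic test is mildly conservative: simulated stationary Poisson units
are classified responsive at a rate of ≈0.0085–0.009 rather than exactly
0.01, within the binomial 3σ band at 10,000 units.  The onset-window rate
change (mean rate over [0, 20) min minus baseline) is reported separately
from the classification window, since response magnitude during dyskinesia
onset and response significance are distinct questions.

## Ex vivo features

**Excitability.** Spikes are detected as upward crossings of −10 mV
confirmed by dV/dt ≥ 20 mV/ms within ±1 ms.  Rheobase is the smallest
tested step current evoking ≥ 1 spike (censored-above when none does).  AP
threshold is the voltage where dV/dt first reaches the slope criterion
before the first spike peak of the rheobase sweep; half-width is the
interpolated width at the level midway between threshold and peak; AHP is
threshold minus the post-peak minimum in a 2–50 ms window (positive =
trough below threshold); RMP is the pre-step mean; subthreshold deflection
is steady-state (last 25 % of the step) minus pre-step voltage for
non-spiking steps.  Both mean rate (count/step) and instantaneous rate
(1/first ISI) are emitted per step.  The slope criterion, detection level,
and AHP window are package conventions, exposed in configuration.

**mEPSCs.** Events are detected on the lightly smoothed (1 ms) current
trace by negative crossings of the first derivative at 5 MAD-scaled robust
standard deviations of the derivative noise, with a 5 ms minimum
separation; amplitude is the local pre-event baseline minus the event
trough, measured on the smoothed trace (raw minima ride the noise floor and
bias amplitudes upward).  Cells are included only with ≥ 500 detected
events, and cumulative inter-event-interval and amplitude distributions are
built from the first 500 events.  At the default simulation conditions
(18 ± 5 pA events, 1.5 pA noise) the detector reaches ≥ 0.9 sensitivity at
≤ 0.05 false discovery with ±2 ms matching.

**GIRK ratio.** Dopamine-evoked GIRK current amplitudes are plateau means
minus the pre-drug baseline mean; the sensitivity index is the ratio of the
1 μM response to the saturating 100 μM response, undefined (flagged) when
the saturating response is not positive.

## Session statistics

Pearson correlation of paired session metrics with listwise deletion of
incomplete rows (counted and reported); zero-variance inputs leave r
undefined rather than raising.  Group comparisons are contract-level
wrappers: repeated-measures one-way ANOVA (pingouin) with Tukey post-hoc,
Kruskal-Wallis (scipy) with Dunn's post-hoc (tie-corrected rank z
contrasts, Bonferroni-adjusted, implemented here), and two-way
repeated-measures ANOVA with Greenhouse-Geisser correction.
Repeated-measures designs drop subjects with incomplete timepoint coverage
and report the dropped ids.  No correction is layered on top of the named
post-hoc families.  Correlations pool sessions; a within-subject variant is
a caller-side grouping, not asserted as equivalent.

## Synthetic sessions

The generators define the test conditions and are deterministic:
identical configuration and seed give bit-identical output.

* **Photometry**: transients are an inhomogeneous Poisson process (baseline
  rate default 4/min plus a signed drug-response profile, default peaking
  near 6/min with a 40-min decay) convolved with a fast-rise (0.2 s) /
  slow-decay (1.5 s) difference-of-exponentials kernel, GCaMP6s-like;
  amplitudes ~5 ± 1.5 % ΔF/F.  Both channels bleach exponentially (465:
  400 min, 405: 600 min — gradual loss over a 2.5 h session) and share a
  multiplicative Ornstein-Uhlenbeck motion artifact (0.5 % fractional sd,
  0.3 s correlation time): coupling fluctuations scale all collected light,
  which is what an isosbestic channel can correct.  An additive-motion mode
  exists for stress-testing.  Sampling defaults to 20 Hz.
* **Spike trains**: inhomogeneous Poisson with an absolute refractory
  period enforced greedily (dead-time deletion lowers the realized rate by
  ≈λ·r, which rate-calibration tests account for by setting r = 0 when an
  exact Poisson oracle is needed).  Response classes are drawn per unit and
  realized as a signed additive rate modulation; waveform features come
  from MSN-like or interneuron-like normal distributions.
* **AIM**: a rise-and-decay severity curve rescaled to the configured peak,
  sampled on the declared schedule, and quantized so the three segment
  scores sum to the rounded curve, remainder points assigned axial > limb >
  orolingual.
* **Current clamp**: leaky-RC subthreshold responses (Ohmic steady state,
  τm 15 ms) plus piecewise-linear AP templates realizing the configured
  threshold, peak, half-width, and AHP *exactly* (linear rise over one
  half-width; fall slope set so the width at half amplitude equals the
  configured value; 5 ms trough hold so the AHP minimum lies inside the
  analysis window), inserted whenever the step reaches the programmed
  rheobase.
* **mEPSCs**: Poisson-timed biexponential inward events on Gaussian noise;
  **GIRK**: two first-order plateaus with programmed amplitudes.

What the generators do **not** emulate: sensor biophysics and kinetics
beyond a fixed kernel, hemodynamic or spectral artifacts, bursty or
history-dependent firing, correlated noise across units, rater variability
in AIM scoring, series-resistance and junction-potential errors, and
overlapping-event pileup beyond what Poisson timing produces.  Passing
tests therefore demonstrate correctness of the quantification rules under
the assumed statistical structure, not robustness to every pathology of
real recordings.

## Problem sizes and tolerances

Statistical tests in the suite use 3σ Monte-Carlo bands with explicitly
propagated error: Poisson event-count calibration over 100 seeds,
classifier power over a few hundred simulated units, null calibration over
10,000 units, and rate recovery over 50 sessions at event rates chosen so
detector merge losses (two transients closer than ~1 s envelope-merge into
one detection) stay well inside the band.  Detector quality (sensitivity
≥ 0.95, FDR ≤ 0.05 at ±1 s matching) is assessed in the isolated-event
regime (1 transient/min, 5 % amplitude, 0.3 % noise) because closely
spaced transients are not separable events under a valley-to-peak
criterion — a limitation of the detection rule itself, shared with any
envelope method.

## Known limitations

* The valley-to-peak detector undercounts during high-rate plateaus
  (merged events), so absolute rates during strong responses are
  conservative; baseline-subtracted comparisons across sessions remain
  valid since the bias is rate-dependent but session-symmetric.
* The exponential bleach model is single-component; traces with
  multi-component bleaching fall back to a linear trend only when the fit
  fails outright.
* The Mann-Whitney classifier inherits the mild conservatism of the
  asymptotic test on tied count data (see above).
* Time-to-baseline requires 5 consecutive sub-threshold bins; responses
  recovering within the last 4 minutes of a session are censored.
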