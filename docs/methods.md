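# Methods

## The scientific problem

Activity in the posterior medial frontal cortex (pMFC) is reliably greater
on incongruent than congruent trials of response-interference tasks (the
*congruency effect*). Two accounts compete:

* **Conflict monitoring** — the pMFC detects competition between response
  alternatives. Conflict tracks trial-specific reaction time (RT) in an
  interference task, but a one-choice simple-RT task involves no response
  selection and therefore no conflict.
* **Time on task** — the pMFC houses a process (sustained attention,
  effort, arousal) recruited for as long as the trial takes, in *any* task.

Both accounts predict a positive trial-by-trial RT-BOLD slope in the
interference task; only time on task predicts one in the simple-RT task,
and only time on task predicts that the simple-task slope can fully absorb
the congruency effect. This package implements (i) a generative simulator
for both worlds and (ii) the analysis that discriminates them.

## Generative model

Each simulated subject performs 4 runs of a multi-source interference task
(MSIT; 48 congruent + 48 incongruent trials per run, randomized order) and
2 runs of a simple-RT task (96 single-response trials per run). Stimuli
last 500 ms; SOAs are drawn from a pseudo-exponential distribution over
{2500, 3750, 5000, 6250} ms with halving weights 8:4:2:1 (short intervals
favoured, the usual event-related jitter convention; the exact weights are
a package choice and are configurable). Runs are 297 volumes at TR 1.25 s;
the first 5 volumes are discarded and contain no trials. SOA sequences
whose cumulative sum would overflow the run are redrawn.

**Behaviour.** RTs are ex-Gaussian per condition (Normal(mu, sigma) +
Exp(tau), ms), calibrated so condition means are 661 (congruent: mu 551,
sigma 60, tau 110), 858 (incongruent: 688/80/170) and 376 ms (simple:
316/40/60). Accuracies are 99.8 / 98.1 / 98.9 %. An incorrect simple-RT
trial is a *miss* (no response, RT missing); incorrect MSIT trials are
committed errors and keep their RT. Between-subject variation is a shared
mean-RT shift (SD 60 ms) plus independent per-condition shifts (SD 50 ms);
the latter reproduces a per-subject congruency-difference SD near the ~73
ms implied by published behavioural t-values. RTs are floored at 100 ms.

**Neural amplitudes** (arbitrary signal units, RT in seconds):

* time on task: `A_i = a_c + b * RT_i` for every trial of both tasks, with
  one shared slope `b` (default 1 unit/s, between-subject SD 0.25) and
  equal baselines `a_c = 1`.
* conflict monitoring: `A_i = a_c + c * (RT_i - mean RT of condition)` for
  MSIT trials (gain `c` default 1 unit/s, SD 0.25; centering is
  subject-level, pooled over runs), `A_i = a_simple` for simple-RT trials.
  Baselines default to 1.0 / 1.2 / 1.0 (congruent / incongruent / simple):
  under this account the congruency effect *is* a condition-mean
  difference, sized to match the time-on-task effect `b * dRT ~ 0.2`.
* misses get amplitude 0 (no response process engaged).

**BOLD.** Amplitude-scaled delta functions at trial onsets on a microtime
grid (TR/16), convolved with the canonical HRF, sampled at the TR. The HRF
is a double gamma with unit peak: positive lobe mode at 6 s, undershoot
mode at 16 s, dispersions 1 s, peak:undershoot 6:1, support [0, 32) s. We
parameterize the gamma shape as delay/dispersion + 1 so the lobe modes sit
exactly at the stated delays (the common shape = delay/dispersion variant
peaks ~1 s earlier); with dispersion 1 the difference is a uniform 1 s
shift and has no effect on any slope logic. Noise is stationary AR(1)
(rho 0.3, marginal SD 1.0 — roughly the single-trial response peak, a
realistic ROI-average CNR) plus two slow cosines (periods 1-4 run lengths,
half-amplitude 0.25 each) standing in for scanner drift. Signal is shared
across the 5 simulated units ("pMFC", bilateral IFG/IPL labels); noise is
independent per unit. Motion traces are smooth bounded random walks that
carry no signal — they exist to exercise the nuisance code path.

**What the generator does not emulate:** spatial structure and smoothing,
motion-correlated signal, physiological noise, slice timing, nonlinear
BOLD saturation, post-error slowing or any sequential trial dependence.
A green discrimination test therefore establishes that the *analysis*
separates the two amplitude models under realistic timing, behaviour and
noise — not that it would survive every artifact of real data.

## First-level model

Trials are screened per subject: misses, then errors, then RT outliers
(|RT - conditional mean| > 3 conditional SDs, computed once over correct
responded trials pooled across runs). Each run's design matrix contains:

* one condition-mean regressor per condition (unit onsets of included
  trials, convolved with the canonical HRF, zero duration);
* one parametric RT regressor per condition: the same onsets weighted by
  within-condition mean-centered RT in *seconds*, convolved. Weights are
  centered per run by default (regressors are built per run; a config
  switch centers on session-wide means instead). Mean-centering makes the
  modulator exactly orthogonal to its condition regressor before
  convolution — this is a tested contract;
* one pooled regressor for all excluded trials (omitted when empty);
* a 24-column motion expansion: linear, squared, lag-1 shifted, and
  squared-of-shifted transforms of the 6 realignment parameters;
* a discrete-cosine high-pass block (cutoff 128 s: floor(2*N*TR/128)
  columns, 5 at full scale) and an intercept.

All-zero columns (e.g. a modulator whose RTs are all equal) are dropped
with a warning; rank deficiency raises an error naming the collinear
columns. Fitting is two-pass: OLS residuals pooled across runs *and* units
give a single global lag-1 autocorrelation per subject (Yule-Walker); data
and design are then exactly AR(1)-whitened (first sample scaled by
sqrt(1 - rho^2)) and refit. Condition-mean and RT-slope betas are averaged
unweighted across a task's runs (runs are equal length). Slope betas are
in signal units per second of RT.

## RT equating and group inference

With per-subject estimates (Congruent, Incongruent, beta_RT-Congruent,
beta_RT-Simple, condition mean RTs), congruent activity is extrapolated to
the incongruent mean RT:

    CongruentEQ_Congruent = Congruent + beta_RT-Congruent * dRT
    CongruentEQ_Simple    = Congruent + beta_RT-Simple    * dRT

with dRT = (Incongruent RT - Congruent RT), the subject's own means over
included trials, converted ms -> s at the single multiplication point.
Corrected effects are Incongruent - CongruentEQ. Slopes enter as point
estimates; their estimation variance is not propagated into the group test
(mirroring the usual subject-then-group procedure) — a documented
limitation. The "MSIT average" slope is the unweighted mean of the
congruent and incongruent slopes. Group inference is random-effects:
one-sample t-tests across subjects (df = n - 1), two-tailed p, alpha 0.05
at the ROI level; whole-brain-style maps use Benjamini-Hochberg FDR at
q <= 0.05 with a k >= 20 voxel extent filter (face connectivity by
default) and conjunctions are intersections of the separately thresholded
masks. Sphere ROIs (6 mm radius; pMFC (2,16,46), L/R IFG, L/R IPL) use the
voxel-center distance rule.

## Numerical and design choices

* Microtime oversampling 16; onsets binned to the nearest microtime sample.
* One master seed; per-subject/per-run streams are spawned deterministically
  (numpy SeedSequence), so the pipeline is bit-reproducible end to end and
  subject k does not depend on how many subjects are generated.
* Zero across-subject variance in a group test yields t = +-inf (p = 0,
  with a warning), except the all-zero case which is t = 0, p = 1.
* A condition with fewer than two usable trials has an undefined outlier
  SD: nothing is flagged, with a warning.
* Degenerate ex-Gaussian (sigma = tau = 0) returns mu exactly, supporting
  deterministic tests.
* ROI mode (a handful of simulated units) is the default experiment;
  volumetric operations (cluster extent, sphere extraction, NIfTI I/O) are
  exercised on synthetic grids.

## Known limitations

* The simple-task RT-BOLD slope is intrinsically noisy (2 runs, ~70 ms RT
  spread), so per-subject estimates scatter widely (SD ~0.9 units/s at
  default CNR); only group-level inferences are meaningful at this scale.
* The corrected-simple test under a time-on-task world is a null test at
  alpha = 0.05: ~5% of replicates will flag it significant by design.
* Error trials keep their generative RT-linked amplitude but are modeled by
  a single unit-weight nuisance regressor — deliberate, mild model
  mismatch, negligible at the default ~1-2% exclusion rates.
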