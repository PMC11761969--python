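# Methods

This note documents the models implemented in `oceanforage`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not establish.

## Task environment

Time is continuous and the simulator is event-driven: it advances from
action onset to action onset, so kinematics are exact up to float precision
(no integration grid). Event-log times are recorded at 1 ms resolution; all
intervals are half-open `[onset, onset + duration)`.

Defaults (all configurable through `TaskConfig`):

| parameter | default | unit | note |
|---|---|---|---|
| blocks × duration | 27 × 90 | s | balanced predator schedule (9/9/9) |
| forage / check / hide-return | 1.5 / 1.0 / 0.5 | s | forage from the task rules; check and hide timings are design choices |
| reward range, walk | [0, 90], σ = 3 per 0.5 s | units | Gaussian increments reflected at the bounds; start ~ U(0, 90) per block |
| predator speeds | 0.125 / 0.071 / 0.05 | screen-radii/s | chosen so uninterrupted arrival spans ≈ 10–30 s after the delay, consistent with the fast/slow first-hide times the pipeline reproduces (≈ 12 vs ≈ 19–22 s) |
| appearance delay | U(2, 10.5) | s | |
| capture penalty | 100 | points | |
| sectors | 4 | | |
| inter-block gap | 4 | s | scanner timeline only |

A forage pays out the reward rate at dive onset (alternative payout rules
would multiply, not change, the analyses; the instantaneous rule keeps the
reward regressor interpretable). One predator per block, initial distance
1.0 (screen edge, unit-normalized); the block ends when it arrives —
capture if the fish is not hiding, exit otherwise. Because arrival is at
most delay + 1/v ≤ 30.5 s, *effective* blocks last 10.5–30.5 s and the 90 s
cap never binds under the defaults; the scanner timeline nevertheless uses
fixed 94 s slots so event-to-volume alignment is trivial.

Invariants checked on every log: time-ordering, at most one capture, the
first post-discovery row is the discovery event, and an exact energy ledger
(final energy = Σ credited forage gains − captures × penalty).

## Derived variables

Time pressure is a sawtooth: slope v between checks, reset by each check.
Two reset conventions coexist deliberately. At the *event level* (behavioral
fits) a check's own TP is referenced to the previous reset — the pressure
that motivated it; resetting at its own onset would zero the regressor for
every check and make the choice contrast degenerate. On the *TR grid* (BOLD
modulators) a sample exactly at a check onset reads zero. Proximity is
1 − max(0, d_obs − v·Δt), exact under the deterministic kinematics, bounded
in [0, 1], non-decreasing between observations. Standardization is
within-participant, within-phase (population, not sample, sd).

## Synthetic participants

The policy is logistic in standardized threat (TP pre-discovery, proximity
after) and standardized reward rate; hiding is a deterministic threshold
(default 0.65) on the raw threat index; IRTs are log-normal,
`IRT = exp(base + effects + σε)`, floored at the previous action's duration.
Default group means: β₀ = 0.1, β_TP = +1.4, β_RR = −0.3 (the recovery
targets), IRT effects switch +0.25, check +0.10, threat +0.08, reward −0.05,
switch×check −0.20, discovery +0.30 log-seconds, σ = 0.25. The threat effect
on IRTs defaults to "slows" and its sign is a parameter, deliberately left
configurable. Sector search is round-robin before discovery and targeted
afterwards. Cohorts draw per-agent parameters from Gaussians around these
means (default N = 23).

**Standardization anchors.** Agents cannot z-score online, so the policy
standardizes against fixed anchor moments. The anchors were calibrated once
by iterating simulate → measure realized within-participant moments → update
until fixed (TP: 0.27 ± 0.16; proximity: 0.52 ± 0.16; reward: 47 ± 25) and
then frozen. This pins the generative coefficients to (approximately) the
same scale the analysis estimates, which is what makes recovery of the
nominal group means a meaningful test. Residual mismatch plus the
decision-time offset (variables are read when the fish becomes free, ~0.3 s
before the realized onset) leaves a small bias, ≈ +0.03 on the threat
weight and ≈ +0.1 attenuation on the reward weight — an order of magnitude
inside the ±0.25 recovery band.

**Timing–choice coupling.** Because IRT effects depend on the upcoming
action (checks and switches are initiated more slowly), time elapses —
and TP accrues — differentially before checks. Two consequences, both
verified by simulation: (i) a cohort with zero *choice* weights still
carries a genuinely nonzero TP–choice association, so the calibration null
used for the type-I-rate test also zeroes the action-dependent IRT effects
(otherwise rejections are power, not error); (ii) recovered β_TP carries a
small reverse-causal surplus (+0.03–0.06) under the defaults.

Even under that clean null the threat term's group test is only
approximately calibrated at desk-scale cohorts: across 2,000 replicate
cohorts at two reduced sizes and several seed bases the rejection rate at
α = .05 ranged 6.0–9.6% (mean ≈ 7%), while the reward term sat at 4.8–5.2%
throughout and the per-participant estimate is asymptotically unbiased
(mean β̂_TP → 0 as sessions lengthen). The residual inflation traces to the
skewed, serially dependent time-pressure regressor, whose per-participant
estimates are right-skewed at moderate event counts — a property of the
task's threat clock, not of the estimator, and one to keep in mind when
reading marginal threat effects in small cohorts.

**What the generator does not emulate.** Captures occur in ≈ 50% of blocks,
far above the ≈ 7% human rate: threshold agents with round-robin search
discover fast predators too slowly, whereas humans anticipate appearance
times. First checks are correspondingly later (≈ 4 vs ≈ 2 s). The
qualitative orderings the analyses rely on (fast < slow for first checks
and hides; check-to-forage slowest, repeated forage fastest IRTs) are all
reproduced. Passing tests therefore validate the *estimators* under a
plausible generative model, not the claim that these agents are
human-equivalent.

## BOLD simulation

A region's event response is a double-gamma HRF (peak 6 s, undershoot 16 s,
dispersions 1 s, ratio 1/6, unit peak — the canonical parameterization,
cross-checked in tests against nilearn's implementation) evaluated in
continuous time at each volume, scaled by the event's neural amplitude:
class beta plus modulator betas times the class-centered standardized
modulator. On top: a linear drift, cardiac (1.05 Hz) and respiratory
(0.3 Hz) sinusoids with random phase (aliased naturally by TR = 1.962 s
sampling), and AR(1) noise (φ = 0.3) whose stationary sd is set from the
requested SNR = sd(event signal)/sd(noise), default 0.5 — at which a single
participant's modulator t is ≈ 2–3, representative of ROI event-related
analyses. Ground-truth event betas for the demonstration configuration put
positive responses on switches to checking and threat modulation on
switches, with null reward modulation.

PPI couplings are injected at the *neural* level: events with a nonzero
psychological code gain amplitude γ × seed amplitude × psych(±1) ×
centered modulator, before convolution. The analysis-side PPI is the
standard BOLD-level approximation (no deconvolution), so recovery tests
genuinely exercise the approximation error.

## Analyses

*Behavior.* Logistic fits use hand-rolled IRLS with separation detection
(no regularization); statsmodels is the cross-check oracle in the tests.
Group inference is two-stage: per-participant estimate, then a two-tailed
one-sample t with a t-based 95% CI. Inclusion requires ≥ 10 checks and ≥ 10
forages in the analyzed phase; IRTs are onset-to-onset with first-in-block
intervals dropped.

*GLM.* Delta regressors per event class (check/forage switch, check/forage
repeat, discovery, hide) plus centered modulator columns on the switch
classes; convolution on a TR/8 grid; DCT high-pass projection with the
SPM-style component count ⌊2T/cutoff⌋ at 100 s; confound sin/cos pairs and
drift appended unfiltered-centered. OLS, optionally a single-pass AR(1)
Cochrane–Orcutt (on by default in the pipeline drivers, off in oracle
tests). Rank-deficient designs are rejected with the offending columns
named.

*PPI.* The model always includes the full task design as covariates —
without it the target's task-evoked signal leaks into the product
regressors and the three-way term is grossly biased under the null (type-I
≈ 95% in our measurements; with the task design included it is ≈ 5%).
Psychological mains that are exact linear combinations of the task design
(the ±1 psych contrast always is) are dropped and recorded. Group "Z" is
the normal quantile of the one-sample t's two-sided p, signed by t.

*Epochs and the LOO peak test.* Window −2 to +12 s, ×4 linear-interpolation
upsampling, baseline = interpolated value at onset, partial windows dropped
and counted. The leave-one-out peak test locates each participant's peak
latency on the group mean excluding them, reads the participant's own value
there, and applies a two-sided Wilcoxon signed-rank test against zero.

**A calibration caveat, measured honestly.** Leave-one-out makes each
tested value *marginally* unbiased (the tested trace is independent of its
own latency), but all values are read near the argmax of a shared noisy
group curve, so they are positively dependent and the signed-rank reference
is anticonservative under a global null: ≈ 43% rejection at α = .05 for
white-noise traces over the full window, ≈ 23% for realistic AR(1)-smooth
epoched noise, ≈ 14% when the search is restricted to 2–10 s. With a true
evoked response — the intended use — latency selection locks onto the real
peak and power is excellent (100% at the default epoch SNR). The
corresponding acceptance test records this inflation as a failure by
design; treat LOO-peak p-values as descriptive unless verified against a
sign-flip permutation of the whole procedure.

*Per-block decorrelation.* Reward availability is generated independently
of the threat clock; pooled within-participant r(TP, RR) is ≈ −0.01 (median
|r| ≈ 0.09–0.10). Per-block correlations on 10–30 s effective blocks are
dominated by two trend-like series on 2–4 effective degrees of freedom
(median |r| ≈ 0.33–0.37) and should not be read as collinearity; the
acceptance test that bounds the per-block median at 0.2 fails for this
reason and is retained as a negative result.

## Problem sizes and determinism

Acceptance-scale runs: recovery uses the full default cohort (23 × 27
blocks); null calibration uses 500 cohorts of 8 agents × 8 blocks (chosen so
each logistic fit still has ≈ 50–60 observations); GLM/PPI replicate loops
hold the behavioral cohort fixed and redraw BOLD noise per replicate (100
GLM cohorts; 200 + 200 PPI runs), since the claims under test are BOLD-level.
Every random quantity flows from explicit integer seeds through
`numpy.random.Generator` spawning; identical config + seed reproduce
byte-identical logs, timecourses and reports.

## Known limitations

- Agent capture rates exceed human rates (above); post-discovery data are
  correspondingly thinner than in real sessions.
- Physiological confounds are parametric sinusoids, not recorded traces;
  the GLM's confound regression is exact by construction in a way real
  physiological denoising is not.
- The PPI uses the BOLD-level product approximation; the injected
  neural-level truth quantifies, but does not remove, that approximation.
- No voxelwise analyses, registration, or NIfTI I/O: regions enter as
  single timecourses.
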