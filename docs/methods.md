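# Methods

## Task and schedule model

A session consists of `n` rewarded (correct) trials; each delivers 1, 2,
or 3 drops of juice.  Fixing the probability of the 2-drop outcome at
`p2` and the mean at `m` determines the outcome distribution:
`p3 = (m − 1 − p2)/2`, `p1 = 1 − p2 − p3`.  This gives 45/10/45 for the
stable schedule (m = 2, p2 = 0.1), 70/10/20 and 20/10/70 for the lean
and rich halves of the changing schedules (m = 1.5 / 2.5), and 1/3 each
for the equiprobable schedule (p2 = 1/3).

**Count-enforced allocation.**  Outcome counts are fixed per half
session rather than drawn i.i.d.: the session's 2-drop count is
`round(p2·n)` (split across halves by largest remainder, random tie),
and the 1- vs 3-drop split in each half is chosen so the realized half
total of drops is as close to `m·n_half` as integer parity allows, with
the residual carried into the other half.  Consequences: a 150-trial
stable session has exactly 15 rare-reward events, and each half mean is
within one rounding unit (1 drop over the half) of its target.  When the
2-drop count of a 75-trial half is 8, parity makes the half's drop total
odd, so a deviation of exactly one unit is unavoidable — the construction
is optimal, not sloppy.  An i.i.d. mode (`count_enforced=False`) exists
for sensitivity checks.

**Sides.**  Stimulus sides come in runs whose lengths are uniform on
{11…19} (mean 15, matching the stated range and mean with the simplest
distribution); after each run the side reverses and a fresh length is
drawn.  Within a run each trial is independently displaced to the
opposite side with probability `p_offside = 0.1`.  The off-side rate is
not documented for the original task beyond "occasional"; 0.1 matches
the rarity of the other surprise events and is configurable.  Off-side
trials do not reset the run.

**Timing.**  Blank 2–4 s (uniform), stimulus onset (decision phase),
manual response, reward 200 ms after the response, 1.5 s juice delivery,
2–4 s inter-trial interval.  Schedule-only sessions place outcomes a
nominal 0.5 s response latency after stimulus onset; behavioral
simulation replaces this with sampled reaction times.  Rewards, sides,
and timing use independent child streams of the session seed, so reward
magnitude and stimulus side are independent by construction.

## Generative agent

The agent's reward expectation is the Rescorla–Wagner trace
`V_{t+1} = V_t + α(r_t − V_t)` with `α = 0.257` and prior `V_1 = 2`
drops (animals trained extensively under a 2-drop mean carry that prior
into every session); the trace updates only on rewarded outcomes, and
repeated attempts inherit the trial's pre-outcome value.

Per attempt, lapse probability is `logistic(β₀ + βᵀx)` with z-scored
predictors x = (VS, sRE, RRE₋₁, position, trial number).  Defaults:
intercept `logit(0.11)` (mid-range of the observed per-animal lapse
rates of roughly 7–16%), `β_VS = +0.3`, `β_sRE = −0.3`, `β_RRE = 0`,
`β_pos = +0.1`, `β_trial = +0.2`.  A realized lapse becomes an error
(wrong side, trial repeated with the stimulus unchanged) with
probability 0.5, otherwise an outlier response with RT uniform on
4–6 s; the behavioral models pool both outcomes, so the split is free.
Correct-attempt RTs are gamma with shape 10 and mean
`exp(γ₀ + γᵀx)` (γ₀ = 5.99 log-ms ≈ 400 ms; `γ_VS = +0.05` so spatial
surprise slows responding; `γ_trial = +0.02`).

Standardization of the generative predictors uses per-session moments
computed from the schedule's error-free realization, so the generative
model is deterministic given the schedule and seed; the fitting side
z-scores the realized attempt-level predictors.  The mismatch is
negligible at the default lapse rates.

**Outlier rule.**  RTs > 4000 ms or < 50 ms are flagged absolutely;
then RTs more than 2.5 SD from the session mean are flagged, with the
moments computed over the not-already-flagged trials.  The ordering
(absolute first) is a choice the source description leaves open;
computing moments after removing gross outliers is the numerically
stable option.

## Behavioral estimation

The design matrix is attempt-level: VS (side change, zeroed on
post-error repeats, which cannot be spatially surprising), either the
sRE column implied by a given learning rate or the previous five rewards
as separate columns, RRE (2-drop event on the previous rewarded trial,
zeroed after errors; the lag-0 variant is exposed as an option but the
outcome of the current trial arrives only after the response, so lag 1
is the default), position, and trial number.  Attempts lacking five
preceding rewarded trials are dropped; all columns are z-scored within
session, making position and trial number comparable across sessions.
Zero-variance columns are excluded with a warning.

**Fitting.**  No frequentist random-slope logistic mixed model is
available in the scientific Python stack, and such fits are fragile on
small cohorts anyway, so the population fit is a two-stage
summary-statistics scheme: per-subject maximum-likelihood GLMs
(binomial/logit for lapses, gamma/log for RTs) aggregated by
inverse-variance weighting.  The inferential targets are population
coefficient signs, for which this scheme is well suited.  Quasi-separated
subject-level coefficients are flagged with a floored SE rather than
failed.  For likelihood-ratio tests a pooled single-GLM mode is used:
its log-likelihood moves by exactly one parameter per dropped regressor,
matching the 1-df convention (the sRE term is charged 2 df for its
upstream learning rate and scale).  The pooled LR p-values are uniform
under the null (tested).

**Two-stage learning rate.**  Stage 1 fits the lapse model with five
lagged-reward regressors; stage 2 minimizes
`‖b − c·w(α)‖₂` with `w_k(α) = α(1−α)^{k−1}` over α ∈ [0, 1] and the
free scale c (the inverse-temperature analogue, solved per α by
least-squares projection), on a 1001-point grid with bounded local
refinement.  Noiseless inversion is exact to grid resolution; on
default-size cohorts the median recovery error is well under 0.1.  The
reward-history slope test fits an OLS line through each subject's five
lag weights and tests the slopes against zero (df = n_subjects − 1).

## fMRI model

Events are modelled as impulses (durations are not documented; impulse +
HRF is the conservative default) convolved with a single-gamma HRF with
distribution mean 4.5 s and SD 2 s — shape 5.0625, scale 0.889 s, mode
3.61 s.  We adopt distribution-mean semantics; a reported peak of
"3.5 s" would imply a slightly different parameterization, a 0.1-s
discrepancy without practical consequence here.  The kernel is unit-sum
at any sampling step.

Thirteen named regressors are built per session — decision phase:
VS-left, VS-right (zeroed on post-error repeats), decision-RRE, decision
constant, hand movement at each response; outcome phase: current reward
magnitude (drops), five lagged reward magnitudes (all placed at the
current outcome onset), outcome-RRE, outcome constant.  A config hook
accepts extra nuisance columns rather than inventing identities for
them.  Outcome onset is response time + 200 ms.  Columns are sampled at
TR = 2.28 s and z-scored.  Contrasts: `sRPE = current − Σ w_k·lag_k`
with `w_k = α(1−α)^{k−1}`; a variant excluding the most recent outcome
restarts the geometric weights at lag 2; `VS = VS_left + VS_right`;
`RRE` is the outcome-phase regressor alone.

**Synthetic ROI BOLD** is the design times an injected effect vector
plus stationary AR(1) noise (coefficient 0.3, marginal SD 1 by default;
SNR chosen so a single session yields a clear but not degenerate
contrast z for the default amplitudes 0.15–0.2).  Session GLMs are OLS;
contrast variance comes from the residual variance and design
covariance; z is the t statistic under a normal approximation (sessions
have hundreds of volumes; an exact-t mode exists).  Under white-noise
nulls the z calibration is nominal (tested); under AR(1) noise
session-level z values are mildly miscalibrated, which the group level
absorbs — group inference is a one-sample random-effects t across the
subjects' precision-weighted fixed-effects means, a two-level
summary-statistics stand-in for a full Bayesian mixed-effects variance
model, declared in the result metadata.

**Detection rule.**  The dissociation table marks a contrast detected in
an ROI when its group p survives Bonferroni correction over the
ROI × contrast family (0.05/9 with the default three ROIs) — a stringent
threshold in the spirit of cluster-corrected mapping, applied uniformly
to the session-type-restricted analyses as well.

**Epoch analysis.**  ROI series are cubic-spline interpolated, upsampled
×10, cut at onsets, baselined at the onset sample, averaged over
0–10 s, split by outcome, and tested against baseline with subject as
the random effect (session means → subject means → one-sample t).

## Design diagnostics and what the simulations do not show

Pooled over simulated cohorts, the trial-level shared variance
(100·r²) between the α-weighted sRPE regressor and the RRE indicator is
of order 0.005% in both stable and changing cohorts — the schedules
decorrelate frequency surprise from scalar prediction error essentially
completely, because count enforcement removes even the sampling
covariance between the current reward and its 2-drop indicator.  The
HRF-convolved, TR-sampled versions of the same regressors share more
(~0.2%), through the low-frequency event-density component that
convolution introduces.  Either number is far below anything that could
confuse the GLM's effect attribution, and the pipeline reports both.
Realized single sequences from any one experiment will scatter around
these levels; matching any particular realized value is not a goal of
the generator.

The synthetic cohort emulates the study layout (6 subjects; 6 stable,
2 + 2 changing, 2 equiprobable sessions of 150 rewarded trials), lapse
statistics, RT distributions, and ROI-level BOLD with injected effects.
It does not emulate: within-trial motor kinematics or satiety drift;
spatially extended activation (no volumes, smoothing, or
cluster-forming thresholds); scanner artefacts beyond AR(1) noise and an
optional 100-s high-pass; or physiological HRF variability.  Passing
tests therefore validate the estimation machinery and the design's
decorrelation logic, not claims about real neural data.

## Problem sizes

Default test and acceptance runs use the full 6-subject study layout for
single-cohort checks, 5–10 replicate cohorts for recovery and
dissociation properties, and 150–400 seeds for calibration checks —
sizes at which the Monte-Carlo assertions are stable across reruns at
fixed seeds.

## Known limitations

* Session-level z statistics ignore temporal autocorrelation (no
  prewhitening); group-level inference is the intended readout.
* The pooled-GLM likelihood-ratio path assumes coefficient homogeneity
  across subjects; heterogeneous cohorts should rely on the two-stage
  coefficient signs and the slope test.
* The truncated Rescorla–Wagner inversion identifies α only up to the
  five-lag horizon; learning rates below ~0.05 are poorly constrained
  by five lags.
* `reward_history_slope_test` treats the per-subject lag weights as
  fixed quantities, ignoring their estimation error (as does the
  original procedure).
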