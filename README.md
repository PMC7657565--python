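# rewardsurprise

Simulation and analysis of **three dissociable kinds of surprise** in a
macaque operant reward task:

* **sRPE** — the scalar reward prediction error, `r_t − V_t`, where the
  expectation `V_t` follows a Rescorla–Wagner update
  `V_{t+1} = V_t + α (r_t − V_t)`;
* **RRE** — the rare reward event: delivery of the 2-drop outcome, which
  matches the mean expectation (so carries ≈ no sRPE) but is rare under
  the schedule — a purely frequency-based surprise;
* **VS** — visuospatial surprise: the stimulus appearing on the side
  opposite the recently established common side.

The task's reward schedules are engineered to decorrelate the three.
In stable/unlearnable sessions the mean reward is 2 drops but 2 drops
are delivered on only 10% of trials (1 and 3 drops on 45% each); in
changing/learnable sessions the half-session means are 1.5 and 2.5
drops (solved distribution 70/10/20); equiprobable sessions deliver each
amount with probability 1/3, removing frequency surprise altogether.

The package provides, as tested library code:

* `schedules` — count-enforced reward sequences for the four session
  types, reversing stimulus-side runs (11–19 trials, mean 15) with rare
  off-side stimuli, and trial timing;
* `behavior` — a generative agent producing lapses (errors and outlier
  reaction times) from a logistic model of VS, scalar reward
  expectation, RRE, position, and trial number, plus gamma-distributed
  reaction times with a log-linear mean;
* `analysis` — the trial-level lapse/RT models, likelihood-ratio tests,
  the two-stage learning-rate estimation (lagged-reward logistic weights
  inverted through a truncated Rescorla–Wagner model
  `w_k = c·α(1−α)^{k−1}`), and the reward-history slope test;
* `fmri` — gamma-HRF event regressors (mean lag 4.5 s, SD 2 s,
  TR 2.28 s), contrast-level sRPE/VS/RRE definitions, synthetic ROI BOLD
  with AR(1) noise, session GLMs, two-level group combination, and
  epoch time-course analysis;
* `pipeline` — cohort orchestration with a reproducible seed tree and a
  JSON/TSV report.

## Worked example

```python
from rewardsurprise import CohortConfig, run_pipeline

manifest, report = run_pipeline(CohortConfig(seed=5))
```

With the default study layout (6 subjects; 6 stable, 2 changing-up,
2 changing-down, 2 equiprobable sessions of 150 rewarded trials each;
generative learning rate α = 0.257) this prints, via the report:

```
learning rate alpha_hat = 0.269
reward-history slope: t(5) = 4.20, p = 0.0085
LR test sRE: chi2(2) = 128.26, p = 1.41e-28
LR test VS:  chi2(1) = 179.86, p = 5.21e-41
LR test RRE: chi2(1) = 2.27,   p = 0.132
```

The two-stage procedure recovers the generative learning rate (0.269 vs
0.257); higher reward expectation and unsurprising stimulus locations
both protect against performance lapses, while the rare-reward event has
no behavioral effect — the same qualitative pattern the task was built
to produce.  The group-level fMRI table (one-sample t across the six
subjects' precision-weighted session effects) shows the three-way
dissociation of the injected ROI effects:

```
contrast             RRE     VS   sRPE
roi
lpfc_like          -2.13  37.43  -0.42
plofc_like         12.95  -0.73  -1.72
vta_striatum_like  -0.78   1.04  23.40
```

and the RRE effect in the plOFC-like ROI exists only when the analysis
is restricted to changing/learnable sessions (t = 27.30 there, t = 1.14
in stable and t = 0.94 in equiprobable sessions) — rare-reward surprise
is only expressed where the reward statistics can actually be learned.

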