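"""Headline design quantities recomputed from scratch.

These are the quantities a reader would check first: the analytically
solved outcome distribution of the changing-schedule halves, the exact
rare-reward rate of a generated stable session, and the pooled shared
variance between the learning-rate-weighted scalar-reward-prediction-
error (sRPE) regressor and the rare-reward-event (RRE) regressor for
stable and changing cohorts.
"""

from __future__ import annotations

import numpy as np

from .pipeline import session_seed, trial_level_regressors
from .schedules import ScheduleSpec, generate_session, solve_outcome_probs
from .fmri import shared_variance

ALPHA = 0.257
N_SUBJECTS = 6


def _cohort_shared_variance(master_seed: int, session_types: list[str],
                            n_trials: int = 150,
                            alpha: float = ALPHA) -> tuple[float, int]:
    """Pooled 100*r^2 between trial-level sRPE and RRE for one cohort."""
    sessions = {}
    for s in range(N_SUBJECTS):
        for j, stype in enumerate(session_types):
            spec = ScheduleSpec.for_type(stype, n_rewarded_trials=n_trials)
            sessions[(s, j)] = generate_session(
                spec, session_seed(master_seed, s, j, 0))
    df = trial_level_regressors(sessions, alpha)
    return shared_variance(df["srpe"], df["rre"]), len(df)


def mean_shared_variance(seed: int, session_types: list[str],
                         n_seeds: int = 20) -> tuple[float, int]:
    """Shared variance averaged over ``n_seeds`` master seeds."""
    masters = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    vals, n = [], 0
    for m in masters:
        v, n = _cohort_shared_variance(int(m), session_types)
        vals.append(v)
    return float(np.mean(vals)), n


def compute_targets(seed: int) -> dict:
    """Recompute every reported target quantity from scratch."""
    out = {}

    # pooled sRPE/RRE shared variance, stable cohort (6 subjects x 6 sessions)
    v, n = mean_shared_variance(seed, ["stable"] * 6)
    out["t2"] = {"value": v, "n": n}

    # same for the changing/learnable cohort (2 up + 2 down per subject)
    v, n = mean_shared_variance(
        seed, ["changing_up", "changing_up", "changing_down", "changing_down"])
    out["t3"] = {"value": v, "n": n}

    # modal outcome probability of a half with mean 2.5 drops, P(2)=0.1
    probs = solve_outcome_probs(2.5, 0.1)
    out["t4"] = {"value": 100.0 * max(probs), "n": len(probs)}

    # 2-drop fraction of one generated stable session of 150 trials
    spec = ScheduleSpec.for_type("stable")
    session = generate_session(spec, seed)
    out["t7"] = {"value": float(np.mean(session.drops == 2)),
                 "n": len(session)}
    return out
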