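"""Generative behavioral agent: lapses, reaction times, and value learning.

The agent holds a scalar reward expectation (sRE) updated by a
Rescorla-Wagner rule, ``V(t+1) = V(t) + alpha * (r(t) - V(t))``, and on
every attempt produces

* a *lapse* (an error response to the wrong side, or an outlier-length
  reaction time) with probability given by a logistic model of
  visuospatial surprise (VS), sRE, the previous trial's rare-reward
  event (RRE), stimulus position, and trial number; and
* otherwise a correct response whose reaction time is gamma-distributed
  with a log-linear mean in the same predictors.

Error attempts repeat the trial (with the stimulus unchanged) until the
correct side is touched; reward is delivered only on the correct
attempt.  This matches the statistical structure the trial-level lapse
and reaction-time mixed models assume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .schedules import Session

__all__ = ["AgentParams", "compute_sre", "simulate_behavior", "label_outliers"]

PREDICTORS = ("VS", "sRE", "RRE", "Position", "TrialNumber")

RT_ABS_LOW_MS = 50.0     # below: impulsive responding
RT_ABS_HIGH_MS = 4000.0  # above: task disengagement
RT_REL_SD = 2.5          # relative outlier threshold in session SDs


def _default_lapse_coefs() -> dict[str, float]:
    # Intercept logit(0.11) puts the baseline lapse rate mid-range of the
    # observed per-animal rates (7-16%).  VS raises and sRE lowers lapse
    # odds; RRE is null; a small position bias and a time-on-task drift.
    return {
        "Intercept": -2.09,
        "VS": 0.30,
        "sRE": -0.30,
        "RRE": 0.0,
        "Position": 0.10,
        "TrialNumber": 0.20,
    }


def _default_rt_coefs() -> dict[str, float]:
    # log-ms scale: exp(5.99) ~ 400 ms median touch latency; VS slows
    # responding, consistent with the behavioral effect of surprise.
    return {
        "Intercept": 5.99,
        "VS": 0.05,
        "sRE": 0.0,
        "RRE": 0.0,
        "Position": 0.0,
        "TrialNumber": 0.02,
    }


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of the behavioral agent.

    ``lapse_coefs`` act on the logit scale and ``rt_coefs`` on the
    log-RT(ms) scale, both over per-session z-scored predictors.
    ``alpha`` is the Rescorla-Wagner learning rate and ``v0`` the prior
    reward expectation in drops (2 drops: the long-run training mean the
    animals carry into every session).  A realized lapse becomes an
    error with probability ``lapse_error_frac``, otherwise an
    outlier-length reaction time drawn uniformly from
    ``outlier_rt_range_ms``.
    """

    alpha: float = 0.257
    v0: float = 2.0
    lapse_coefs: dict[str, float] = field(default_factory=_default_lapse_coefs)
    rt_coefs: dict[str, float] = field(default_factory=_default_rt_coefs)
    rt_shape: float = 10.0
    lapse_error_frac: float = 0.5
    outlier_rt_range_ms: tuple[float, float] = (4000.0, 6000.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.rt_shape <= 0:
            raise ValueError("rt_shape must be positive")
        if not 0.0 <= self.lapse_error_frac <= 1.0:
            raise ValueError("lapse_error_frac must lie in [0, 1]")

    def with_(self, **kwargs) -> "AgentParams":
        return replace(self, **kwargs)

    def to_json(self) -> str:
        d = {
            "alpha": self.alpha,
            "v0": self.v0,
            "lapse_coefs": self.lapse_coefs,
            "rt_coefs": self.rt_coefs,
            "rt_shape": self.rt_shape,
            "lapse_error_frac": self.lapse_error_frac,
            "outlier_rt_range_ms": list(self.outlier_rt_range_ms),
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AgentParams":
        d = json.loads(text)
        if "outlier_rt_range_ms" in d:
            d["outlier_rt_range_ms"] = tuple(d["outlier_rt_range_ms"])
        return cls(**d)


def compute_sre(drops, alpha: float, v0: float = 2.0) -> np.ndarray:
    """Rescorla-Wagner value trace (scalar reward expectation, sRE).

    Returns an array of length ``len(drops) + 1`` whose entry ``t``
    (0-based) is the expectation held *before* the outcome of trial
    ``t + 1``; the final entry is the expectation carried beyond the
    last outcome.  ``trace[0] == v0`` and

        trace[t + 1] = trace[t] + alpha * (drops[t] - trace[t]).

    With ``alpha = 0`` the trace is constant at ``v0``; with
    ``alpha = 1`` it tracks the most recent reward.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    drops = np.asarray(drops, dtype=float)
    trace = np.empty(len(drops) + 1)
    trace[0] = v0
    for t, r in enumerate(drops):
        trace[t + 1] = trace[t] + alpha * (r - trace[t])
    return trace


def label_outliers(rts) -> np.ndarray:
    """Flag outlier reaction times (ms).

    Absolute rule first: RTs above 4,000 ms (disengagement) or below
    50 ms (impulsive responding).  Then RTs more than 2.5 SDs from the
    session mean, with mean and SD computed over the not-already-flagged
    trials; if those have zero variance only the absolute rule applies.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("rts must be nonempty")
    flags = (rts > RT_ABS_HIGH_MS) | (rts < RT_ABS_LOW_MS)
    clean = rts[~flags]
    if clean.size >= 2:
        sd = clean.std(ddof=0)
        if sd > 0:
            mean = clean.mean()
            flags |= np.abs(rts - mean) > RT_REL_SD * sd
    return flags


def _session_standardizer(session: Session, agent: AgentParams):
    """Per-session means/SDs of the generative predictors.

    Computed from the schedule's rewarded-trial sequence (the
    error-free realization), so standardization is deterministic given
    the schedule and does not depend on the lapses being generated.
    """
    n = len(session)
    sides = (session.side == "right").astype(float)
    vs = np.zeros(n)
    vs[1:] = (session.side[1:] != session.side[:-1]).astype(float)
    sre = compute_sre(session.drops, agent.alpha, agent.v0)[:n]
    rre_prev = np.zeros(n)
    rre_prev[1:] = (session.drops[:-1] == 2).astype(float)
    trialno = session.trial.astype(float)
    cols = {"VS": vs, "sRE": sre, "RRE": rre_prev,
            "Position": sides, "TrialNumber": trialno}
    mean = {k: v.mean() for k, v in cols.items()}
    sd = {k: (v.std(ddof=0) if v.std(ddof=0) > 0 else 1.0) for k, v in cols.items()}
    return mean, sd


def simulate_behavior(session: Session, agent: AgentParams, seed) -> pd.DataFrame:
    """Simulate attempt-level behavior for one session.

    Returns a table with one row per *attempt*.  Error attempts repeat
    the trial; the reward (``drops``) is recorded only on the final,
    correct attempt, and the value update happens only then.  ``vs_raw``
    marks a side change relative to the previous attempt; ``vs_zeroed``
    is the analysis version, zeroed on any attempt following an error
    (repeated trials cannot be spatially surprising).  ``rre_prev``
    flags that the previous *rewarded* trial delivered 2 drops (also
    zeroed after errors).  ``is_outlier`` applies the session-level
    outlier rule to the realized reaction times.
    """
    rng = np.random.default_rng(seed)
    t = session.spec.timing
    mean, sd = _session_standardizer(session, agent)

    def z(name, value):
        return (value - mean[name]) / sd[name]

    rows: list[dict] = []
    v = agent.v0
    prev_side: str | None = None
    prev_was_error = False
    prev_rre = 0.0
    clock = 0.0
    lc, rc = agent.lapse_coefs, agent.rt_coefs

    for i in range(len(session)):
        side = session.side[i]
        drops = int(session.drops[i])
        position = 1.0 if side == "right" else 0.0
        sre_t = v
        attempt = 0
        done = False
        while not done:
            attempt += 1
            vs_raw = 0.0 if prev_side is None else float(side != prev_side)
            vs_zeroed = 0.0 if prev_was_error else vs_raw
            rre = 0.0 if prev_was_error else prev_rre
            zvals = {
                "VS": z("VS", vs_zeroed),
                "sRE": z("sRE", sre_t),
                "RRE": z("RRE", rre),
                "Position": z("Position", position),
                "TrialNumber": z("TrialNumber", float(session.trial[i])),
            }
            lp_lapse = lc["Intercept"] + sum(lc[k] * zvals[k] for k in PREDICTORS)
            lapse = rng.random() < expit(lp_lapse)
            is_error = bool(lapse and rng.random() < agent.lapse_error_frac)

            if lapse and not is_error:
                rt = rng.uniform(*agent.outlier_rt_range_ms)
            else:
                lp_rt = rc["Intercept"] + sum(rc[k] * zvals[k] for k in PREDICTORS)
                rt = rng.gamma(agent.rt_shape, np.exp(lp_rt) / agent.rt_shape)

            t_decision = clock + rng.uniform(*t.pre_stim_blank)
            t_response = t_decision + rt / 1000.0
            done = not is_error
            if done:
                t_outcome = t_response + t.reward_delay
                clock = t_outcome + t.juice_duration + rng.uniform(*t.iti)
            else:
                t_outcome = np.nan
                clock = t_response + rng.uniform(*t.iti)

            rows.append({
                "trial": int(session.trial[i]),
                "attempt": attempt,
                "side": side,
                "responded_side": side if done else ("left" if side == "right" else "right"),
                "is_error": is_error,
                "rt_ms": rt,
                "drops": drops if done else np.nan,
                "vs_raw": vs_raw,
                "vs_zeroed": vs_zeroed,
                "rre_prev": rre,
                "sre": sre_t,
                "half": session.half[i],
                "t_decision": t_decision,
                "t_outcome": t_outcome,
            })
            prev_side = side
            prev_was_error = is_error

        # value update on the rewarded outcome only
        v = v + agent.alpha * (drops - v)
        prev_rre = float(drops == 2)

    df = pd.DataFrame(rows)
    df["is_outlier"] = label_outliers(df["rt_ms"].to_numpy())
    df["is_lapse"] = df["is_error"] | df["is_outlier"]
    return df
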