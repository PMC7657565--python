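"""Cohort orchestration: simulate -> behavioral fits -> fMRI fits -> report.

The default cohort mirrors the study conditions: 6 subjects, each with
6 stable/unlearnable, 2 changing-up, 2 changing-down, and 2 equiprobable
sessions of 150 rewarded trials.  Three synthetic ROIs carry injected
effects — a scalar-reward-prediction-error (sRPE) pattern
("vta_striatum_like"), a rare-reward-event (RRE) effect present only in
changing/learnable sessions ("plofc_like"), and a visuospatial-surprise
(VS) effect ("lpfc_like") — so the end-to-end pipeline can demonstrate
the three-way dissociation of surprise signals.

Randomness is organized as a seed tree: master seed -> subject ->
session -> stage (schedule, behavior, one stream per ROI), so altering
one stage's settings does not perturb the draws of any other stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (build_behavior_design, estimate_learning_rate,
                       fit_lapse_model, fit_rt_model, lr_test,
                       reward_history_slope_test)
from .behavior import AgentParams, simulate_behavior
from .fmri import (build_fmri_design, combine_levels, fit_session_glm,
                   shared_variance, simulate_roi_bold)
from .schedules import ScheduleSpec, SessionType, generate_session

__all__ = ["CohortConfig", "RunManifest", "simulate_cohort", "run_pipeline",
           "make_fixtures", "DEFAULT_ROI_EFFECTS", "trial_level_regressors"]

# stage ids for the per-session seed tree
_STAGE_SCHEDULE, _STAGE_BEHAVIOR, _STAGE_BOLD = 0, 1, 2

DEFAULT_SESSION_COUNTS = {
    "stable": 6, "changing_up": 2, "changing_down": 2, "equiprobable": 2,
}

#: ROI -> (target pattern, amplitude, session types carrying the effect).
#: Patterns are contrast names expanded through the design's contrast
#: weights ("sRPE", "RRE", "VS") or "unsigned_sRPE" (|reward - expectation|,
#: the orofacial/lPFC-style magnitude-independent response).
DEFAULT_ROI_EFFECTS = {
    "vta_striatum_like": {"pattern": "sRPE", "amplitude": 0.15, "session_types": "all"},
    "plofc_like": {"pattern": "RRE", "amplitude": 0.20,
                   "session_types": ["changing_up", "changing_down"]},
    "lpfc_like": {"pattern": "VS", "amplitude": 0.15, "session_types": "all"},
}


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 6
    session_counts: dict = field(default_factory=lambda: dict(DEFAULT_SESSION_COUNTS))
    n_rewarded_trials: int = 150
    seed: int = 0
    agent: AgentParams = field(default_factory=AgentParams)
    roi_effects: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_ROI_EFFECTS.items()})
    noise_sd: float = 1.0
    ar1_coef: float = 0.3
    tr: float = 2.28

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if any(v < 0 for v in self.session_counts.values()):
            raise ValueError("session counts must be >= 0")

    def config_hash(self) -> str:
        payload = json.dumps({
            "n_subjects": self.n_subjects,
            "session_counts": self.session_counts,
            "n_rewarded_trials": self.n_rewarded_trials,
            "seed": self.seed,
            "agent": json.loads(self.agent.to_json()),
            "roi_effects": self.roi_effects,
            "noise_sd": self.noise_sd,
            "ar1_coef": self.ar1_coef,
            "tr": self.tr,
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def session_seed(master: int, subject: int, session: int, stage: int) -> np.random.SeedSequence:
    """Labelled substream of the master seed for one session stage."""
    return np.random.SeedSequence(entropy=master,
                                  spawn_key=(subject, session, stage))


def _session_plan(config: CohortConfig):
    plan = []
    j = 0
    for stype, count in config.session_counts.items():
        for _ in range(count):
            plan.append((j, SessionType(stype)))
            j += 1
    return plan


def simulate_cohort(config: CohortConfig):
    """Simulate every subject/session: schedules plus behavior.

    Returns ``(sessions, trials)`` where ``sessions`` maps
    ``(subject, session_index)`` to the realized :class:`Session` and
    ``trials`` is the pooled attempt-level table with ``subject``,
    ``session``, and ``session_type`` columns.
    """
    sessions = {}
    tables = []
    plan = _session_plan(config)
    for s in range(config.n_subjects):
        for j, stype in plan:
            spec = ScheduleSpec.for_type(
                stype, n_rewarded_trials=config.n_rewarded_trials)
            sess = generate_session(
                spec, session_seed(config.seed, s, j, _STAGE_SCHEDULE))
            df = simulate_behavior(
                sess, config.agent,
                session_seed(config.seed, s, j, _STAGE_BEHAVIOR))
            df.insert(0, "subject", s)
            df.insert(1, "session", j)
            df.insert(2, "session_type", stype.value)
            sessions[(s, j)] = sess
            tables.append(df)
    return sessions, pd.concat(tables, ignore_index=True)


def trial_level_regressors(sessions, alpha: float = 0.257,
                           n_lags: int = 5) -> pd.DataFrame:
    """Per-rewarded-trial sRPE and RRE regressors, pooled over sessions.

    sRPE(t) = r(t) - sum_k alpha*(1-alpha)**(k-1) * r(t-k) over the
    previous ``n_lags`` rewards; RRE(t) = 1 if r(t) == 2.  Trials
    without a full lag history are dropped (mirroring the design rule).
    """
    from .analysis import rw_lag_weights
    w = rw_lag_weights(alpha, n_lags)
    rows = []
    for (s, j), sess in sessions.items():
        r = sess.drops.astype(float)
        side_change = np.zeros(len(r))
        side_change[1:] = (sess.side[1:] != sess.side[:-1]).astype(float)
        for t in range(n_lags, len(r)):
            expectation = float(w @ r[t - n_lags:t][::-1])
            rows.append({
                "subject": s, "session": j,
                "session_type": sess.spec.session_type.value,
                "srpe": r[t] - expectation,
                "rre": float(r[t] == 2.0),
                "vs": side_change[t],
            })
    return pd.DataFrame(rows)


def _design_diagnostics(sessions, alpha: float) -> pd.DataFrame:
    df = trial_level_regressors(sessions, alpha)
    group_of = {"stable": "stable", "changing_up": "changing",
                "changing_down": "changing", "equiprobable": "equiprobable"}
    df["group"] = df["session_type"].map(group_of)
    rows = []
    for grp, g in df.groupby("group"):
        rows.append({"session_group": grp,
                     "shared_variance_srpe_rre_pct":
                         shared_variance(g["srpe"], g["rre"]),
                     "shared_variance_vs_srpe_pct":
                         shared_variance(g["vs"], g["srpe"]),
                     "shared_variance_vs_rre_pct":
                         shared_variance(g["vs"], g["rre"]),
                     "n_trials": len(g)})
    return pd.DataFrame(rows).set_index("session_group")


def dissociation_summary(group_table: pd.DataFrame,
                         family_alpha: float = 0.05) -> tuple[dict, float]:
    """Detection table over ROI x contrast in the all-sessions analysis.

    A contrast counts as detected in an ROI when its group p-value
    survives Bonferroni correction over the ROI x contrast family — a
    deliberately stringent detection rule, in the spirit of
    cluster-corrected mapping thresholds.  Returns the detection dict
    keyed by (roi, contrast) and the corrected threshold, which callers
    reuse for the session-type-restricted tests.
    """
    sub = group_table[group_table["restriction"] == "all"]
    thr = family_alpha / len(sub)
    detections = {(r["roi"], r["contrast"]): bool(r["p"] < thr)
                  for _, r in sub.iterrows()}
    return detections, thr


def _roi_effect_map(roi_cfg: dict, session_type: str) -> dict:
    kinds = roi_cfg.get("session_types", "all")
    if kinds != "all" and session_type not in kinds:
        return {}
    amp = roi_cfg["amplitude"]
    pattern = roi_cfg["pattern"]
    if pattern == "unsigned_sRPE":
        return {"__unsigned_srpe__": amp}
    return {pattern: amp}


def _simulate_roi(design, roi_cfg, session_type, seed, config, label):
    effects = _roi_effect_map(roi_cfg, session_type)
    if "__unsigned_srpe__" in effects:
        # magnitude-of-surprise response: |sRPE| time course injected
        # directly rather than through a linear effect map
        amp = effects["__unsigned_srpe__"]
        srpe_tc = design.contrast_timecourse("sRPE")
        base = simulate_roi_bold(design, {}, config.noise_sd,
                                 config.ar1_coef, seed, roi_label=label)
        base.values = base.values + amp * np.abs(srpe_tc)
        return base
    return simulate_roi_bold(design, effects, config.noise_sd,
                             config.ar1_coef, seed, roi_label=label)


def analyze_fmri(config: CohortConfig, sessions, trials: pd.DataFrame,
                 alpha: float = 0.257):
    """Per-session designs and ROI GLMs, then group tests per contrast.

    Returns ``(session_table, group_table)``: session-level contrast z
    statistics per ROI, and group-level random-effects tests per ROI x
    contrast x session-type restriction (all / stable / changing /
    equiprobable).
    """
    results = []   # rows: subject, session, session_type, roi, SessionGLMResult
    for (s, j), sess in sessions.items():
        t = trials[(trials["subject"] == s) & (trials["session"] == j)]
        stype = t["session_type"].iloc[0]
        design = build_fmri_design(sess, t, alpha=alpha, tr=config.tr)
        ss = session_seed(config.seed, s, j, _STAGE_BOLD)
        roi_seeds = ss.spawn(len(config.roi_effects))
        for (roi, roi_cfg), rs in zip(config.roi_effects.items(), roi_seeds):
            ts = _simulate_roi(design, roi_cfg, stype, rs, config, roi)
            glm = fit_session_glm(ts, design)
            results.append({"subject": s, "session": j, "session_type": stype,
                            "roi": roi, "glm": glm})
    res = pd.DataFrame(results)

    sess_rows = []
    for _, r in res.iterrows():
        for cname, row in r["glm"].contrast_table.iterrows():
            sess_rows.append({"subject": r["subject"], "session": r["session"],
                              "session_type": r["session_type"], "roi": r["roi"],
                              "contrast": cname, "effect": row["effect"],
                              "z": row["z"]})
    session_table = pd.DataFrame(sess_rows)

    restrictions = {
        "all": None,
        "stable": ["stable"],
        "changing": ["changing_up", "changing_down"],
        "equiprobable": ["equiprobable"],
    }
    contrasts = ["sRPE", "RRE", "VS"]
    group_rows = []
    for roi, g in res.groupby("roi"):
        for rname, types in restrictions.items():
            sel = g if types is None else g[g["session_type"].isin(types)]
            if sel.empty or sel["subject"].nunique() < 2:
                continue
            for cname in contrasts:
                gr = combine_levels(list(sel["glm"]), list(sel["subject"]), cname)
                group_rows.append({
                    "roi": roi, "restriction": rname, "contrast": cname,
                    "group_mean": gr.group_mean, "t": gr.t, "df": gr.df,
                    "p": gr.p, "flagged": gr.flagged})
    return session_table, pd.DataFrame(group_rows)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    outputs: dict

    def to_json(self) -> str:
        return json.dumps({
            "config_hash": self.config_hash, "seed": self.seed,
            "version": self.version, "outputs": self.outputs,
        }, indent=2, sort_keys=True)


def run_pipeline(config: CohortConfig, outdir=None):
    """Run the full pipeline; returns ``(manifest, report)``.

    Stages: cohort simulation; behavioral estimation (two-stage learning
    rate, likelihood-ratio tests for the sRE and VS terms, reward-history
    slope test, RT model); trial-level design diagnostics; fMRI ROI
    simulation, session GLMs, and group tests.  When ``outdir`` is given
    the report tables are written as TSV/JSON alongside the manifest.
    """
    report: dict = {}

    sessions, trials = simulate_cohort(config)
    report["n_sessions"] = len(sessions)
    report["n_attempts"] = len(trials)
    report["lapse_rate"] = float(trials["is_lapse"].mean())

    # --- behavioral stack ---------------------------------------------
    rw, lag_fit, lag_design = estimate_learning_rate(trials)
    alpha_hat = rw.alpha_hat if rw.ok and np.isfinite(rw.alpha_hat) else config.agent.alpha
    lag_betas = lag_fit.per_subject[
        [f"coef_RewardLag{k}" for k in range(1, 6)]].to_numpy()
    t_slope, df_slope, p_slope = reward_history_slope_test(lag_betas)

    design1 = build_behavior_design(trials, alpha=alpha_hat)
    full = fit_lapse_model(design1)
    # likelihood-ratio tests on pooled fits, whose log-likelihood moves
    # by one parameter per dropped regressor (the 1-df convention; the
    # sRE term costs 2 df for its upstream learning rate and scale)
    full_pooled = fit_lapse_model(design1, method="pooled")
    tests = {}
    for term, dfree in (("sRE", 2), ("VS", 1), ("RRE", 1)):
        if term not in full.params.index:
            continue
        reduced = fit_lapse_model(
            design1, predictors=[c for c in design1.predictors if c != term],
            method="pooled")
        chi2, p = lr_test(full_pooled, reduced, dfree)
        tests[term] = {"chi2": chi2, "df": dfree, "p": p}
    rt_fit = fit_rt_model(design1, exclude="outliers")

    report["behavior"] = {
        "alpha_hat": alpha_hat,
        "rw_scale": rw.scale_hat,
        "reward_history_slope": {"t": t_slope, "df": df_slope, "p": p_slope},
        "lapse_coefficients": full.summary_frame().to_dict(orient="index"),
        "lr_tests": tests,
        "rt_coefficients": rt_fit.summary_frame().to_dict(orient="index"),
        "fit_method": full.method,
    }

    # --- design diagnostics -------------------------------------------
    diag = _design_diagnostics(sessions, alpha=alpha_hat)
    report["design_diagnostics"] = diag.reset_index().to_dict(orient="records")

    # --- fMRI ----------------------------------------------------------
    session_table, group_table = analyze_fmri(config, sessions, trials,
                                              alpha=alpha_hat)
    report["fmri_group"] = group_table.to_dict(orient="records")

    outputs = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        trials.to_csv(outdir / "trials.tsv", sep="\t", index=False)
        diag.to_csv(outdir / "design_diagnostics.tsv", sep="\t")
        session_table.to_csv(outdir / "fmri_sessions.tsv", sep="\t", index=False)
        group_table.to_csv(outdir / "fmri_group.tsv", sep="\t", index=False)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
        outputs = {p.name: str(p) for p in sorted(outdir.iterdir())}

    manifest = RunManifest(config_hash=config.config_hash(), seed=config.seed,
                           version=__version__, outputs=outputs)
    if outdir is not None:
        (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest, report


def make_fixtures(seed: int = 0):
    """Small deterministic datasets for unit tests and worked examples.

    Returns a dict with a 20-trial stable session, a 2-subject
    mini-cohort attempt table, and a noiseless single-ROI series with a
    known injected sRPE effect.
    """
    spec = ScheduleSpec.for_type("stable", n_rewarded_trials=20)
    session = generate_session(spec, np.random.SeedSequence(entropy=seed,
                                                            spawn_key=(0,)))
    mini = CohortConfig(n_subjects=2,
                        session_counts={"stable": 1, "changing_up": 1},
                        n_rewarded_trials=40, seed=seed)
    sessions, trials = simulate_cohort(mini)
    design = build_fmri_design(session, alpha=0.257)
    ts = simulate_roi_bold(design, {"sRPE": 0.5}, noise_sd=0.0, ar1_coef=0.0,
                           seed=seed, roi_label="noiseless_srpe")
    return {"session": session, "mini_cohort": (sessions, trials),
            "design": design, "roi_series": ts}
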