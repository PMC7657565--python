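"""ROI-level fMRI design, simulation, and effect recovery.

Event regressors are built from the task's decision and outcome onsets,
convolved with a single-gamma hemodynamic response function (mean lag
4.5 s, SD 2 s — the faster macaque HRF), sampled at the scanner TR
(2.28 s), and z-scored.  Scalar reward prediction error (sRPE) is formed
at the *contrast* level as the current reward minus the learning-rate-
weighted previous five rewards; visuospatial surprise (VS) combines the
left- and right-side regressors; the rare-reward event (RRE) is the
2-drop indicator at outcome.

Synthetic ROI time series are the design times injected effects plus
AR(1) Gaussian noise; session GLMs are ordinary least squares, sessions
are combined within subject by precision-weighted fixed effects, and
subjects by a one-sample random-effects t test — a two-level
summary-statistics scheme (declared in the result metadata).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, signal, stats

from .analysis import rw_lag_weights
from .schedules import Session

__all__ = [
    "HRFSpec",
    "FMRIDesign",
    "ROITimeseries",
    "GroupResult",
    "hrf_kernel",
    "build_fmri_design",
    "define_contrasts",
    "shared_variance",
    "simulate_roi_bold",
    "fit_session_glm",
    "combine_levels",
    "extract_timecourse",
]

TR_DEFAULT = 2.28
N_LAGS = 5

#: Regressors of interest named by the design (decision- and
#: outcome-phase events).  Config hooks can append extra nuisance
#: columns to honor a larger design without inventing their identity.
DESIGN_COLUMNS = (
    "VS_left", "VS_right", "RRE_decision", "const_decision", "hand_movement",
    "reward_current", "reward_lag1", "reward_lag2", "reward_lag3",
    "reward_lag4", "reward_lag5", "RRE_outcome", "const_outcome",
)


@dataclass(frozen=True)
class HRFSpec:
    """Single-gamma HRF: distribution mean ``mean_lag`` s, SD ``sd`` s."""

    mean_lag: float = 4.5
    sd: float = 2.0
    dt: float = 0.114  # kernel / event-train sampling step (TR / 20)
    duration: float = 30.0

    @property
    def shape(self) -> float:
        return (self.mean_lag / self.sd) ** 2

    @property
    def scale(self) -> float:
        return self.sd**2 / self.mean_lag

    @property
    def mode(self) -> float:
        """Time-to-peak, (shape - 1) * scale."""
        return (self.shape - 1.0) * self.scale


def hrf_kernel(spec: HRFSpec) -> np.ndarray:
    """Sampled gamma HRF kernel, normalized to unit sum.

    Moment matching gives shape ``(mean/sd)**2`` and scale
    ``sd**2/mean``; a shape <= 1 has no interior mode and is rejected.
    """
    if spec.shape <= 1.0:
        raise ValueError("gamma shape must exceed 1 for a peaked HRF")
    t = np.arange(0.0, spec.duration, spec.dt)
    k = stats.gamma.pdf(t, a=spec.shape, scale=spec.scale)
    return k / k.sum()


def _impulse_train(onsets, amplitudes, n_fine: int, dt: float) -> np.ndarray:
    x = np.zeros(n_fine)
    idx = np.round(np.asarray(onsets, float) / dt).astype(int)
    ok = (idx >= 0) & (idx < n_fine)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} event(s) beyond the scan window truncated")
    np.add.at(x, idx[ok], np.asarray(amplitudes, float)[ok])
    return x


def _zscore(col: np.ndarray) -> np.ndarray:
    sd = col.std(ddof=0)
    if sd == 0:
        return np.zeros_like(col)
    return (col - col.mean()) / sd


@dataclass
class FMRIDesign:
    """TR-sampled, HRF-convolved, z-scored regressor matrix."""

    X: pd.DataFrame
    tr: float
    frame_times: np.ndarray
    contrasts: dict = field(default_factory=dict)
    zero_columns: list = field(default_factory=list)

    @property
    def n_volumes(self) -> int:
        return len(self.X)

    def contrast_vector(self, name: str) -> np.ndarray:
        w = self.contrasts[name]
        v = np.zeros(self.X.shape[1])
        for col, weight in w.items():
            v[self.X.columns.get_loc(col)] = weight
        return v

    def contrast_timecourse(self, name: str) -> np.ndarray:
        return self.X.to_numpy() @ self.contrast_vector(name)


def define_contrasts(alpha: float, excl_recent_lags: int = 4) -> dict:
    """Contrast weight maps over the named design columns.

    ``sRPE`` subtracts the learning-rate-weighted previous five rewards
    from the current reward (weights ``alpha * (1-alpha)**(k-1)``);
    ``sRPE_excl_recent`` leaves out the most recent outcome, restarting
    the geometric weighting at lag 2 (a control for orofacial/gustatory
    carry-over from the last juice delivery); ``VS`` sums the left and
    right visuospatial-surprise regressors; ``RRE`` is the outcome-phase
    rare-reward regressor alone.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    w = rw_lag_weights(alpha, N_LAGS)
    srpe = {"reward_current": 1.0}
    srpe.update({f"reward_lag{k}": -w[k - 1] for k in range(1, N_LAGS + 1)})
    w4 = rw_lag_weights(alpha, excl_recent_lags)
    srpe_x = {"reward_current": 1.0}
    srpe_x.update({f"reward_lag{k + 1}": -w4[k - 1] for k in range(1, excl_recent_lags + 1)})
    return {
        "sRPE": srpe,
        "sRPE_excl_recent": srpe_x,
        "VS": {"VS_left": 1.0, "VS_right": 1.0},
        "RRE": {"RRE_outcome": 1.0},
    }


def build_fmri_design(session: Session, trials: pd.DataFrame | None = None,
                      alpha: float = 0.257, tr: float = TR_DEFAULT,
                      n_volumes: int | None = None,
                      hrf: HRFSpec = HRFSpec(),
                      extra_columns: dict | None = None) -> FMRIDesign:
    """Build the session design matrix.

    Decision-phase impulse events: VS on the left/right (zeroed on
    post-error repeats), the decision-phase RRE (previous reward was 2
    drops), a decision constant, and a hand-movement regressor at every
    manual response.  Outcome-phase events at reward onset: the current
    reward magnitude in drops, the previous five reward magnitudes, the
    outcome-phase RRE (current reward is 2 drops), and an outcome
    constant.  Events are impulses convolved with the gamma HRF, sampled
    at the TR, and z-scored.

    When an attempt-level ``trials`` table is given, onsets, errors, and
    response times come from it (outcome onset = response + reward
    delay); otherwise the session's nominal timing is used and no lapses
    occur.  ``extra_columns`` maps names to (onsets, amplitudes) pairs
    for additional nuisance regressors.
    """
    drops = session.drops.astype(float)
    lag_amp = {k: np.concatenate([np.zeros(k), drops[:-k]])
               for k in range(1, N_LAGS + 1)}
    rre_out = (session.drops == 2).astype(float)
    rre_dec = np.concatenate([[0.0], rre_out[:-1]])

    if trials is not None:
        t = trials.sort_values(["trial", "attempt"])
        dec_on = t["t_decision"].to_numpy(float)
        resp_on = dec_on + t["rt_ms"].to_numpy(float) / 1000.0
        vs = t["vs_zeroed"].to_numpy(float)
        is_right = (t["side"] == "right").to_numpy()
        out_rows = t["drops"].notna().to_numpy()
        out_on = t.loc[out_rows, "t_outcome"].to_numpy(float)
        out_trial = t.loc[out_rows, "trial"].to_numpy(int) - 1
        rre_dec_amp = t["rre_prev"].to_numpy(float)
    else:
        dec_on = session.t_decision
        resp_on = session.t_outcome - session.spec.timing.reward_delay
        vs = np.zeros(len(session))
        vs[1:] = (session.side[1:] != session.side[:-1]).astype(float)
        is_right = session.side == "right"
        out_on = session.t_outcome
        out_trial = np.arange(len(session))
        rre_dec_amp = rre_dec

    if n_volumes is None:
        n_volumes = int(np.ceil((out_on.max() + 20.0) / tr))

    dt = hrf.dt
    n_fine = int(np.ceil(n_volumes * tr / dt))
    kernel = hrf_kernel(hrf)

    events: dict[str, tuple[np.ndarray, np.ndarray]] = {
        "VS_left": (dec_on, vs * (~is_right)),
        "VS_right": (dec_on, vs * is_right),
        "RRE_decision": (dec_on, rre_dec_amp),
        "const_decision": (dec_on, np.ones_like(dec_on)),
        "hand_movement": (resp_on, np.ones_like(resp_on)),
        "reward_current": (out_on, drops[out_trial]),
        "RRE_outcome": (out_on, rre_out[out_trial]),
        "const_outcome": (out_on, np.ones_like(out_on)),
    }
    for k in range(1, N_LAGS + 1):
        events[f"reward_lag{k}"] = (out_on, lag_amp[k][out_trial])
    if extra_columns:
        events.update(extra_columns)

    frame_times = np.arange(n_volumes) * tr
    fine_idx = np.round(frame_times / dt).astype(int)
    cols, zero_cols = {}, []
    for name, (onsets, amps) in events.items():
        train = _impulse_train(onsets, amps, n_fine, dt)
        conv = signal.fftconvolve(train, kernel)[:n_fine]
        col = conv[fine_idx]
        if col.std(ddof=0) == 0:
            zero_cols.append(name)
        cols[name] = _zscore(col)
    if zero_cols:
        warnings.warn(f"all-zero regressor(s): {zero_cols}")

    order = [c for c in DESIGN_COLUMNS if c in cols]
    order += [c for c in cols if c not in order]
    X = pd.DataFrame({c: cols[c] for c in order})
    return FMRIDesign(X=X, tr=tr, frame_times=frame_times,
                      contrasts=define_contrasts(alpha),
                      zero_columns=zero_cols)


def shared_variance(x, y) -> float:
    """Percent shared variance, ``100 * r**2`` for Pearson ``r``."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        raise ValueError("shared variance undefined for a constant input")
    r = np.corrcoef(x, y)[0, 1]
    return 100.0 * r**2


@dataclass
class ROITimeseries:
    values: np.ndarray
    tr: float
    roi_label: str = "roi"
    subject: object = None
    session: object = None

    def __len__(self) -> int:
        return len(self.values)


def simulate_roi_bold(design: FMRIDesign, true_effects: dict, noise_sd: float,
                      ar1_coef: float, seed, roi_label: str = "roi",
                      highpass_s: float | None = None) -> ROITimeseries:
    """Synthetic ROI BOLD: design-driven signal plus AR(1) Gaussian noise.

    ``true_effects`` maps regressor names (or contrast names, expanded
    through the design's contrast weights) to amplitudes in units of the
    z-scored regressors.  Noise is stationary AR(1) with marginal SD
    ``noise_sd``.  ``highpass_s`` applies the acquisition-style temporal
    high-pass (first-order Butterworth, cutoff ``1/highpass_s`` Hz).
    """
    rng = np.random.default_rng(seed)
    betas = np.zeros(design.X.shape[1])
    for name, amp in true_effects.items():
        if name in design.X.columns:
            betas[design.X.columns.get_loc(name)] += amp
        elif name in design.contrasts:
            betas += amp * design.contrast_vector(name)
        else:
            raise KeyError(f"unknown regressor or contrast: {name!r}")
    y = design.X.to_numpy() @ betas
    n = len(y)
    if noise_sd > 0:
        innov_sd = noise_sd * np.sqrt(1.0 - ar1_coef**2)
        eps = rng.normal(0.0, innov_sd, size=n)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, noise_sd)
        for i in range(1, n):
            noise[i] = ar1_coef * noise[i - 1] + eps[i]
        y = y + noise
    if highpass_s is not None:
        b, a = signal.butter(1, (1.0 / highpass_s) / (0.5 / design.tr), "highpass")
        y = signal.filtfilt(b, a, y)
    return ROITimeseries(values=y, tr=design.tr, roi_label=roi_label)


@dataclass
class SessionGLMResult:
    betas: pd.Series
    bse: pd.Series
    contrast_table: pd.DataFrame  # effect, se, t, z per contrast
    df_resid: int
    rank: int
    dropped: list


def fit_session_glm(ts: ROITimeseries, design: FMRIDesign,
                    exact_t: bool = False) -> SessionGLMResult:
    """Ordinary least squares of one ROI series on the session design.

    Contrast variance comes from the residual variance and the design
    covariance; ``z`` is the t statistic under a normal approximation
    (sessions have hundreds of volumes), or an exact t-to-z conversion
    with ``exact_t=True``.  All-zero columns are dropped with a warning;
    any remaining rank deficiency is rejected.
    """
    keep = [c for c in design.X.columns if c not in design.zero_columns]
    if design.zero_columns:
        warnings.warn(f"dropping all-zero column(s): {design.zero_columns}")
    X = np.column_stack([design.X[keep].to_numpy(),
                         np.ones(design.n_volumes)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("design is rank deficient after z-scoring")
    y = np.asarray(ts.values, float)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = len(y) - X.shape[1]
    s2 = resid @ resid / df_resid
    cov = s2 * np.linalg.inv(X.T @ X)
    bse = np.sqrt(np.diag(cov))

    names = keep + ["const"]
    rows = []
    for cname, wmap in design.contrasts.items():
        c = np.zeros(len(names))
        usable = True
        for col, wgt in wmap.items():
            if col in design.zero_columns:
                usable = False
                continue
            c[names.index(col)] = wgt
        eff = c @ beta
        se = float(np.sqrt(c @ cov @ c))
        t = eff / se if se > 0 else np.nan
        if exact_t and np.isfinite(t):
            z = stats.norm.isf(stats.t.sf(t, df_resid)) if t >= 0 else \
                -stats.norm.isf(stats.t.sf(-t, df_resid))
        else:
            z = t
        rows.append({"contrast": cname, "effect": eff, "se": se,
                     "t": t, "z": z, "complete": usable})
    table = pd.DataFrame(rows).set_index("contrast")
    return SessionGLMResult(
        betas=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        contrast_table=table,
        df_resid=df_resid,
        rank=rank,
        dropped=list(design.zero_columns),
    )


@dataclass
class GroupResult:
    """Two-level combination: fixed effects within subject, random across.

    ``subject_effects`` holds the precision-weighted per-subject means;
    the group statistic is a one-sample t across subjects (a
    summary-statistics stand-in for a full Bayesian mixed-effects
    variance model, declared here).
    """

    contrast: str
    subject_effects: pd.Series
    group_mean: float
    t: float
    df: int
    p: float
    flagged: bool = False
    method: str = "two-level summary statistics (FE within, RE across subjects)"


def combine_levels(session_results, subject_ids, contrast: str) -> GroupResult:
    """Combine session-level contrast estimates into a group test.

    Level 2: per subject, precision-weighted fixed-effects mean of that
    subject's session effects (a single session passes through as the
    subject mean).  Level 3: one-sample t across subject means.  A
    degenerate zero-variance case is flagged rather than failed.
    """
    subject_ids = list(subject_ids)
    if len(session_results) != len(subject_ids):
        raise ValueError("one subject id per session result required")
    eff = np.array([r.contrast_table.loc[contrast, "effect"] for r in session_results])
    var = np.array([r.contrast_table.loc[contrast, "se"] for r in session_results])**2
    by_subject: dict = {}
    for e, v, s in zip(eff, var, subject_ids):
        by_subject.setdefault(s, []).append((e, v))
    if len(by_subject) < 2:
        raise ValueError("need >= 2 subjects for a group test")
    means = {}
    for s, pairs in by_subject.items():
        es = np.array([p[0] for p in pairs])
        ws = 1.0 / np.array([p[1] for p in pairs])
        means[s] = float((es * ws).sum() / ws.sum())
    m = pd.Series(means)
    sd = m.std(ddof=1)
    dfree = len(m) - 1
    if sd == 0:
        gm = float(m.mean())
        return GroupResult(contrast, m, gm, np.inf if gm != 0 else 0.0,
                           dfree, 0.0 if gm != 0 else 1.0, flagged=True)
    t, p = stats.ttest_1samp(m.to_numpy(), 0.0)
    return GroupResult(contrast, m, float(m.mean()), float(t), dfree, float(p))


@dataclass
class EpochResult:
    time: np.ndarray                 # s relative to onset, upsampled
    mean_courses: dict               # level -> mean upsampled course
    session_means: pd.DataFrame      # columns: subject, session, level, mean_0_10
    n_excluded: int
    group_tests: pd.DataFrame | None = None


def extract_timecourse(ts: ROITimeseries, onsets, window_s: float = 10.0,
                       split_by=None, upsample: int = 10) -> EpochResult:
    """Epoch, upsample, baseline, and average an ROI time course.

    Epochs are cut at each onset, spline-interpolated to ``upsample``
    times the volume rate, baselined at the onset sample, averaged over
    ``0..window_s`` s, and optionally split by a per-onset condition
    (e.g. drops).  Epochs overrunning the scan are excluded and counted.
    """
    y = np.asarray(ts.values, float)
    vol_t = np.arange(len(y)) * ts.tr
    if window_s < ts.tr:
        raise ValueError("window must cover at least one TR")
    spline = interpolate.CubicSpline(vol_t, y)
    dt = ts.tr / upsample
    rel_t = np.arange(0.0, window_s + dt / 2, dt)
    onsets = np.asarray(onsets, float)
    levels = np.asarray(split_by) if split_by is not None else np.zeros(len(onsets))
    ok = onsets + window_s <= vol_t[-1]
    n_excluded = int((~ok).sum())

    courses: dict = {}
    rows = []
    for onset, lev in zip(onsets[ok], levels[ok]):
        course = spline(onset + rel_t)
        course = course - course[0]
        courses.setdefault(lev, []).append(course)
        rows.append({"subject": ts.subject, "session": ts.session,
                     "level": lev, "mean_0_10": float(course.mean())})
    mean_courses = {lev: np.mean(cs, axis=0) for lev, cs in courses.items()}
    return EpochResult(time=rel_t, mean_courses=mean_courses,
                       session_means=pd.DataFrame(rows), n_excluded=n_excluded)


def epoch_group_test(session_means: pd.DataFrame) -> pd.DataFrame:
    """Test epoch averages against baseline with subject as random effect.

    Per condition level: average within session, then within subject,
    then a one-sample t across subjects against zero.
    """
    rows = []
    for lev, g in session_means.groupby("level"):
        per_sess = g.groupby(["subject", "session"])["mean_0_10"].mean()
        per_subj = per_sess.groupby(level=0).mean()
        if len(per_subj) >= 2 and per_subj.std(ddof=1) > 0:
            t, p = stats.ttest_1samp(per_subj.to_numpy(), 0.0)
        else:
            t, p = np.nan, np.nan
        rows.append({"level": lev, "mean": float(per_subj.mean()),
                     "t": float(t), "df": len(per_subj) - 1, "p": float(p)})
    return pd.DataFrame(rows).set_index("level")
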