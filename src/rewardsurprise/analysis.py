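"""Behavioral estimation stack.

Implements the trial-level lapse and reaction-time models and the
two-stage learning-rate estimation:

1.  A logistic model of performance lapses with the previous five
    rewards as separate regressors yields lagged-reward weights.
2.  A truncated Rescorla-Wagner model ``w_k = c * alpha * (1-alpha)**(k-1)``
    is fitted to those weights by minimizing the Euclidean norm over the
    learning rate ``alpha`` and a free multiplicative scale ``c`` (the
    inverse-temperature analogue), giving the learning rate used to build
    the scalar-reward-expectation (sRE) regressor of the main lapse model.

Hierarchical fitting note: the population-level fit is a two-stage
summary-statistics scheme — maximum-likelihood fits per subject followed
by inverse-variance-weighted aggregation of the coefficients.  The
inferential targets here are population coefficient signs and
likelihood-ratio tests of nested predictor sets, for which this scheme
is well suited and numerically robust on small cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .behavior import compute_sre

__all__ = [
    "BehaviorDesign",
    "FitResult",
    "RWFit",
    "build_behavior_design",
    "fit_lapse_model",
    "fit_rt_model",
    "lr_test",
    "fit_truncated_rw",
    "reward_history_slope_test",
    "rw_lag_weights",
    "estimate_learning_rate",
]

N_LAGS = 5


@dataclass
class BehaviorDesign:
    """Trial-level regressor matrix for the lapse / RT models.

    ``X`` holds per-session z-scored predictor columns, ``y`` the binary
    lapse indicator, ``rt_ms`` the raw reaction times, and ``groups``
    the subject/session labels.  ``n_dropped`` counts rows removed for
    lacking five preceding rewarded trials; ``dropped_columns`` lists
    zero-variance predictors excluded from fitting.
    """

    X: pd.DataFrame
    y: pd.Series
    rt_ms: pd.Series
    groups: pd.DataFrame
    is_error: pd.Series
    is_outlier: pd.Series
    is_repeat: pd.Series
    n_dropped: int = 0
    dropped_columns: list = field(default_factory=list)

    @property
    def predictors(self) -> list:
        return [c for c in self.X.columns if c not in self.dropped_columns]


def _zscore_by_session(df: pd.DataFrame, cols, session_key) -> tuple[pd.DataFrame, list]:
    out = df.copy()
    degenerate = set()
    for _, idx in df.groupby(session_key, sort=False).groups.items():
        block = df.loc[idx, cols]
        mean = block.mean()
        sd = block.std(ddof=0)
        zero = sd == 0
        sd = sd.where(~zero, 1.0)
        out.loc[idx, cols] = (block - mean) / sd
    # a column constant in every session carries no information at all
    for c in cols:
        if np.allclose(out[c].to_numpy(float), 0.0):
            degenerate.add(c)
    return out, sorted(degenerate)


def build_behavior_design(trials: pd.DataFrame, alpha: float | None = None,
                          rre_lag: int = 1) -> BehaviorDesign:
    """Build the z-scored trial-level design from an attempt table.

    ``trials`` is the attempt-level output of the behavioral simulator
    (or a concatenation over sessions/subjects with ``subject`` and
    ``session`` columns).  Per attempt the predictors are: VS (side
    change, zeroed after errors), either the sRE column implied by
    ``alpha`` or the previous five rewards as separate ``RewardLag1`` …
    ``RewardLag5`` columns when ``alpha`` is None, RRE (2-drop event on
    the previous rewarded trial by default, ``rre_lag=0`` for the
    current trial's outcome), Position, and TrialNumber.  Attempts with
    fewer than five preceding rewarded trials are dropped; all columns
    are z-scored within session.
    """
    df = trials.copy()
    if "subject" not in df.columns:
        df["subject"] = 0
    if "session" not in df.columns:
        df["session"] = 0
    skey = ["subject", "session"]

    parts = []
    n_dropped = 0
    for _, g in df.groupby(skey, sort=False):
        g = g.sort_values(["trial", "attempt"]).copy()
        rewarded = g.loc[g["drops"].notna()]
        r_hist = rewarded["drops"].to_numpy(float)
        # map each attempt to the number of completed rewarded trials before it
        trial_order = rewarded["trial"].to_numpy()
        n_before = np.searchsorted(trial_order, g["trial"].to_numpy())
        for k in range(1, N_LAGS + 1):
            lagged = np.full(len(g), np.nan)
            ok = n_before >= k
            lagged[ok] = r_hist[n_before[ok] - k]
            g[f"RewardLag{k}"] = lagged
        if rre_lag == 0:
            # the current trial's outcome, zeroed on repeats (post-error)
            g["RRE"] = ((g["drops"] == 2) & (g["attempt"] == 1)).astype(float)
        else:
            g["RRE"] = g["rre_prev"].astype(float)
        if alpha is not None:
            # value trace over the full reward history, before any rows
            # are dropped, so early outcomes still shape later expectations
            trace = compute_sre(r_hist, alpha)
            g["sRE"] = trace[n_before]
        keep = n_before >= N_LAGS
        n_dropped += int((~keep).sum())
        parts.append(g.loc[keep])
    df = pd.concat(parts, ignore_index=True)

    df["VS"] = df["vs_zeroed"].astype(float)
    df["Position"] = (df["side"] == "right").astype(float)
    df["TrialNumber"] = df["trial"].astype(float)
    if alpha is not None:
        cols = ["VS", "sRE", "RRE", "Position", "TrialNumber"]
    else:
        cols = (["VS"] + [f"RewardLag{k}" for k in range(1, N_LAGS + 1)]
                + ["RRE", "Position", "TrialNumber"])

    df["_sess"] = df["subject"].astype(str) + "/" + df["session"].astype(str)
    df, degenerate = _zscore_by_session(df, cols, "_sess")
    if degenerate:
        warnings.warn(
            f"zero-variance predictor(s) excluded from fitting: {degenerate}")

    # trials only complete on a correct attempt, so the attempts that
    # follow an error are exactly the within-trial repeats
    is_repeat = df["attempt"] > 1

    return BehaviorDesign(
        X=df[cols].astype(float),
        y=df["is_lapse"].astype(int),
        rt_ms=df["rt_ms"].astype(float),
        groups=df[skey],
        is_error=df["is_error"].astype(bool),
        is_outlier=df["is_outlier"].astype(bool),
        is_repeat=is_repeat.astype(bool),
        n_dropped=n_dropped,
        dropped_columns=degenerate,
    )


@dataclass
class FitResult:
    """Population-level fit: coefficients, their SEs, and log-likelihood."""

    params: pd.Series
    bse: pd.Series
    llf: float
    per_subject: pd.DataFrame
    converged: bool
    method: str
    family: str

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    def summary_frame(self) -> pd.DataFrame:
        z = self.zvalues
        return pd.DataFrame({
            "coef": self.params, "se": self.bse, "z": z,
            "p": 2 * stats.norm.sf(np.abs(z)),
        })


_SEPARATION_SE = 1e3  # SE floor signalling quasi-separated coefficients


def _fit_glm_population(X: pd.DataFrame, y: np.ndarray, groups: pd.DataFrame,
                        family, family_name: str, predictors=None) -> FitResult:
    predictors = list(predictors) if predictors is not None else list(X.columns)
    Xd = sm.add_constant(X[predictors], has_constant="add")
    subjects = groups["subject"].to_numpy()
    uniq = pd.unique(subjects)

    per_rows, llf_total, converged = [], 0.0, True
    for s in uniq:
        m = subjects == s
        model = sm.GLM(y[m], Xd[m], family=family)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(maxiter=200)
            except Exception:
                converged = False
                continue
        llf_total += res.llf
        bse = res.bse.copy()
        degenerate = ~np.isfinite(bse) | (bse > _SEPARATION_SE)
        if degenerate.any():
            bse[degenerate] = _SEPARATION_SE
        row = {"subject": s}
        row.update({f"coef_{k}": res.params[k] for k in Xd.columns})
        row.update({f"se_{k}": bse[k] for k in Xd.columns})
        per_rows.append(row)
    if not per_rows:
        raise RuntimeError("no subject-level fit converged")
    per = pd.DataFrame(per_rows).set_index("subject")

    names = list(Xd.columns)
    coefs = per[[f"coef_{k}" for k in names]].to_numpy()
    ses = per[[f"se_{k}" for k in names]].to_numpy()
    w = 1.0 / ses**2
    pooled = (coefs * w).sum(axis=0) / w.sum(axis=0)
    pooled_se = np.sqrt(1.0 / w.sum(axis=0))
    return FitResult(
        params=pd.Series(pooled, index=names),
        bse=pd.Series(pooled_se, index=names),
        llf=llf_total,
        per_subject=per,
        converged=converged,
        method="per-subject ML + inverse-variance aggregation",
        family=family_name,
    )


def _fit_glm_pooled(X: pd.DataFrame, y: np.ndarray, family, family_name: str,
                    predictors) -> FitResult:
    Xd = sm.add_constant(X[list(predictors)], has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, Xd, family=family).fit(maxiter=200)
    bse = res.bse.copy()
    degenerate = ~np.isfinite(bse) | (bse > _SEPARATION_SE)
    if degenerate.any():
        bse[degenerate] = _SEPARATION_SE
    return FitResult(params=res.params, bse=bse, llf=float(res.llf),
                     per_subject=pd.DataFrame(), converged=res.converged,
                     method="pooled ML", family=family_name)


def fit_lapse_model(design: BehaviorDesign, predictors=None,
                    method: str = "two-stage") -> FitResult:
    """Fit the logistic lapse model at the population level.

    ``method='two-stage'`` (default) fits each subject by maximum
    likelihood and aggregates coefficients by inverse-variance
    weighting — the robust route to population coefficient signs.
    ``method='pooled'`` fits one GLM over all rows with shared
    coefficients; its log-likelihood changes by exactly one parameter
    per dropped regressor, which is what paper-style 1-df
    likelihood-ratio tests assume.  ``predictors`` defaults to every
    non-degenerate design column; a subset gives a reduced (nested)
    model.  Subject-level quasi-separation is flagged by an inflated SE
    rather than a failure.
    """
    if predictors is None:
        predictors = design.predictors
    if method == "pooled":
        return _fit_glm_pooled(design.X, design.y.to_numpy(),
                               sm.families.Binomial(), "binomial-logit",
                               predictors)
    if method != "two-stage":
        raise ValueError(f"unknown method: {method!r}")
    return _fit_glm_population(
        design.X, design.y.to_numpy(), design.groups,
        sm.families.Binomial(), "binomial-logit", predictors)


def fit_rt_model(design: BehaviorDesign, predictors=None,
                 exclude: str = "outliers",
                 method: str = "two-stage") -> FitResult:
    """Gamma / log-link model of reaction times.

    ``exclude='outliers'`` drops outlier-RT attempts only;
    ``exclude='outliers_errors_repeats'`` additionally drops error
    attempts and the repeated attempts that follow them.  ``method`` as
    in :func:`fit_lapse_model`.
    """
    if exclude == "outliers":
        keep = ~design.is_outlier
    elif exclude == "outliers_errors_repeats":
        keep = ~(design.is_outlier | design.is_error | design.is_repeat)
    else:
        raise ValueError(f"unknown exclusion rule: {exclude!r}")
    keep = keep.to_numpy()
    rts = design.rt_ms.to_numpy()[keep]
    if np.any(rts <= 0):
        raise ValueError("reaction times must be positive")
    if predictors is None:
        predictors = design.predictors
    family = sm.families.Gamma(link=sm.families.links.Log())
    if method == "pooled":
        return _fit_glm_pooled(design.X[keep], rts, family, "gamma-log",
                               predictors)
    if method != "two-stage":
        raise ValueError(f"unknown method: {method!r}")
    return _fit_glm_population(
        design.X[keep], rts, design.groups[keep], family, "gamma-log",
        predictors)


def lr_test(full: FitResult, reduced: FitResult, df: int) -> tuple[float, float]:
    """Likelihood-ratio test of a reduced (nested) model against the full one.

    ``df`` is the number of constrained parameters; the learning-rate
    term costs 2 (learning rate and scale).  The statistic is clipped at
    zero.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    full_terms = set(full.params.index)
    red_terms = set(reduced.params.index)
    if not red_terms <= full_terms:
        raise ValueError("reduced model is not nested in the full model")
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    return chi2, float(stats.chi2.sf(chi2, df))


def rw_lag_weights(alpha: float, n_lags: int = N_LAGS, start_lag: int = 1) -> np.ndarray:
    """Geometric Rescorla-Wagner weights ``alpha * (1-alpha)**(k-1)``.

    ``start_lag`` shifts the geometric sequence, so
    ``rw_lag_weights(a, 4, start_lag=2)`` gives the weights used when the
    most recent outcome is excluded.
    """
    k = np.arange(n_lags)
    return alpha * (1.0 - alpha) ** k


@dataclass
class RWFit:
    alpha_hat: float
    scale_hat: float
    residual_norm: float
    ok: bool = True


def fit_truncated_rw(lag_betas, grid_size: int = 1001) -> RWFit:
    """Invert lagged-reward weights into a learning rate and scale.

    Minimizes ``||b - c * w(alpha)||_2`` with
    ``w_k(alpha) = alpha * (1-alpha)**(k-1)`` over ``alpha`` in [0, 1]
    and the free scale ``c`` (solved in closed form per ``alpha`` as the
    least-squares projection), on a 1001-point grid followed by bounded
    local refinement.  All-zero betas leave the learning rate undefined.
    """
    b = np.asarray(lag_betas, dtype=float)
    if b.shape != (N_LAGS,):
        raise ValueError(f"expected exactly {N_LAGS} lag weights")
    if np.allclose(b, 0.0):
        return RWFit(np.nan, 0.0, 0.0, ok=False)

    def residual(alpha: float) -> tuple[float, float]:
        w = rw_lag_weights(alpha)
        denom = w @ w
        if denom == 0.0:
            return float(np.linalg.norm(b)), 0.0
        c = (w @ b) / denom
        return float(np.linalg.norm(b - c * w)), c

    grid = np.linspace(0.0, 1.0, grid_size)
    res = np.array([residual(a)[0] for a in grid])
    i = int(np.argmin(res))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, grid_size - 1)]
    opt = optimize.minimize_scalar(lambda a: residual(a)[0],
                                   bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    alpha_hat = float(opt.x) if opt.fun <= res[i] else float(grid[i])
    rnorm, c = residual(alpha_hat)
    return RWFit(alpha_hat, c, rnorm)


def reward_history_slope_test(per_subject_lag_betas) -> tuple[float, int, float]:
    """Test whether lagged-reward weights decay over lags 1..5.

    Fits an ordinary least-squares line through each subject's five lag
    weights and runs a one-sample t test of the slopes against zero
    (df = n_subjects - 1).  Subjects with missing weights are excluded
    with a warning; zero slope variance is flagged as undefined.
    """
    B = np.asarray(per_subject_lag_betas, dtype=float)
    if B.ndim != 2 or B.shape[1] != N_LAGS:
        raise ValueError(f"expected an (n_subjects, {N_LAGS}) array")
    ok = np.isfinite(B).all(axis=1)
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} subject(s) with missing betas")
        B = B[ok]
    if B.shape[0] < 2:
        raise ValueError("need at least 2 subjects with complete betas")
    lags = np.arange(1, N_LAGS + 1, dtype=float)
    slopes = np.polyfit(lags, B.T, 1)[0]
    dfree = len(slopes) - 1
    if np.std(slopes, ddof=1) == 0.0:
        t = 0.0 if np.allclose(slopes, 0.0) else np.inf
        warnings.warn("zero variance across subject slopes; t undefined")
        return t, dfree, 0.0 if np.isinf(t) else 1.0
    t, p = stats.ttest_1samp(slopes, 0.0)
    return float(t), dfree, float(p)


def estimate_learning_rate(trials: pd.DataFrame) -> tuple[RWFit, FitResult, BehaviorDesign]:
    """Two-stage learning-rate estimation from an attempt-level cohort table.

    Stage 1 fits the lapse model with the previous five rewards as
    separate regressors; stage 2 inverts the population lag weights into
    a truncated Rescorla-Wagner learning rate.
    """
    design = build_behavior_design(trials, alpha=None)
    fit = fit_lapse_model(design)
    betas = np.array([fit.params[f"RewardLag{k}"] for k in range(1, N_LAGS + 1)])
    return fit_truncated_rw(betas), fit, design
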