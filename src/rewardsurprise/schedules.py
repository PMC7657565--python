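"""Reward and stimulus-side schedule generation for the operant reward task.

The task delivers 1, 2, or 3 drops of juice on every rewarded (correct)
trial.  Four schedule types manipulate the outcome distribution:

``stable``
    Mean reward 2 drops throughout; 2 drops delivered on only 10% of
    trials (1 and 3 drops on 45% each), so the mean outcome is a *rare
    reward event* (RRE) despite carrying no scalar prediction error.
``changing_up`` / ``changing_down``
    Mean reward 1.5 drops in one half of the session and 2.5 in the
    other; 2 drops still delivered on 10% of trials.
``equiprobable``
    Each outcome delivered with probability 1/3; 2 drops is no longer
    rare, removing frequency-based surprise while keeping scalar
    prediction errors.

The visual stimulus appears on one side of the screen for runs of 11-19
trials (mean 15) before reversing, with occasional single-trial
appearances on the opposite side (*visuospatial surprise*, VS).  Reward
magnitude and stimulus side are generated from independent random
streams, so the two are decorrelated by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SessionType",
    "TimingSpec",
    "ScheduleSpec",
    "Session",
    "solve_outcome_probs",
    "generate_reward_sequence",
    "generate_side_sequence",
    "generate_session",
]

DROP_LEVELS = (1, 2, 3)

#: Nominal response latency (s) used for schedule-only outcome onsets;
#: behavioral simulation replaces it with sampled reaction times.
NOMINAL_RT_S = 0.5


class SessionType(str, Enum):
    STABLE = "stable"
    CHANGING_UP = "changing_up"
    CHANGING_DOWN = "changing_down"
    EQUIPROBABLE = "equiprobable"


_HALF_MEANS = {
    SessionType.STABLE: (2.0, 2.0),
    SessionType.CHANGING_UP: (1.5, 2.5),
    SessionType.CHANGING_DOWN: (2.5, 1.5),
    SessionType.EQUIPROBABLE: (2.0, 2.0),
}


@dataclass(frozen=True)
class TimingSpec:
    """Trial timing, all in seconds from the animal's point of view.

    A trial is: blank screen (uniform ``pre_stim_blank``), stimulus
    onset (= decision phase), manual response, reward after
    ``reward_delay``, juice delivery of ``juice_duration``, then an
    inter-trial interval drawn uniformly from ``iti``.
    """

    pre_stim_blank: tuple[float, float] = (2.0, 4.0)
    reward_delay: float = 0.2
    juice_duration: float = 1.5
    iti: tuple[float, float] = (2.0, 4.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.pre_stim_blank, self.iti):
            if lo < 0 or hi < lo:
                raise ValueError("interval bounds must satisfy 0 <= lo <= hi")
        if self.reward_delay < 0 or self.juice_duration < 0:
            raise ValueError("durations must be non-negative")


@dataclass(frozen=True)
class ScheduleSpec:
    """Full parameterization of one session's schedule."""

    session_type: SessionType = SessionType.STABLE
    n_rewarded_trials: int = 150
    p_rre: float = 0.1
    half_means: tuple[float, float] = (2.0, 2.0)
    run_length_range: tuple[int, int] = (11, 19)
    p_offside: float = 0.1
    timing: TimingSpec = field(default_factory=TimingSpec)
    count_enforced: bool = True

    def __post_init__(self) -> None:
        if self.n_rewarded_trials <= 5:
            raise ValueError("n_rewarded_trials must exceed 5")
        if not 0.0 <= self.p_rre <= 1.0:
            raise ValueError("p_rre must lie in [0, 1]")
        if not 0.0 <= self.p_offside <= 1.0:
            raise ValueError("p_offside must lie in [0, 1]")
        for m in self.half_means:
            if not 1.0 <= m <= 3.0:
                raise ValueError("half means must lie in [1, 3] drops")
        lo, hi = self.run_length_range
        if not (1 <= lo <= hi):
            raise ValueError("run_length_range must satisfy 1 <= lo <= hi")
        # validate feasibility of each half's outcome distribution
        for m in self.half_means:
            solve_outcome_probs(m, self.p_rre)

    @classmethod
    def for_type(cls, session_type: SessionType | str, **kwargs) -> "ScheduleSpec":
        """Spec with the canonical defaults for a named session type."""
        st = SessionType(session_type)
        defaults: dict = {"half_means": _HALF_MEANS[st]}
        if st is SessionType.EQUIPROBABLE:
            defaults["p_rre"] = 1.0 / 3.0
        defaults.update(kwargs)
        return cls(session_type=st, **defaults)

    def with_(self, **kwargs) -> "ScheduleSpec":
        return replace(self, **kwargs)

    def to_json(self) -> str:
        d = {
            "session_type": self.session_type.value,
            "n_rewarded_trials": self.n_rewarded_trials,
            "p_rre": self.p_rre,
            "half_means": list(self.half_means),
            "run_length_range": list(self.run_length_range),
            "p_offside": self.p_offside,
            "timing": {
                "pre_stim_blank": list(self.timing.pre_stim_blank),
                "reward_delay": self.timing.reward_delay,
                "juice_duration": self.timing.juice_duration,
                "iti": list(self.timing.iti),
            },
            "count_enforced": self.count_enforced,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScheduleSpec":
        d = json.loads(text)
        t = d.pop("timing", None)
        timing = TimingSpec(
            pre_stim_blank=tuple(t["pre_stim_blank"]),
            reward_delay=t["reward_delay"],
            juice_duration=t["juice_duration"],
            iti=tuple(t["iti"]),
        ) if t else TimingSpec()
        return cls(
            session_type=SessionType(d["session_type"]),
            n_rewarded_trials=d["n_rewarded_trials"],
            p_rre=d["p_rre"],
            half_means=tuple(d["half_means"]),
            run_length_range=tuple(d["run_length_range"]),
            p_offside=d["p_offside"],
            timing=timing,
            count_enforced=d.get("count_enforced", True),
        )


def solve_outcome_probs(mean_drops: float, p2: float) -> tuple[float, float, float]:
    """Solve for the (1, 2, 3)-drop probabilities given the mean and P(2 drops).

    With outcomes in drops ``r ∈ {1, 2, 3}``, fixing ``P(r = 2) = p2`` and
    requiring ``E[r] = mean_drops`` determines the distribution:

        p3 = (mean_drops - 1 - p2) / 2,   p1 = 1 - p2 - p3.

    Raises ``ValueError`` when no valid distribution exists (a probability
    would fall outside ``[0, 1]``).

    >>> solve_outcome_probs(2.0, 0.1)
    (0.45, 0.1, 0.45)
    """
    if not 0.0 <= p2 <= 1.0:
        raise ValueError("p2 must lie in [0, 1]")
    p3 = (mean_drops - 1.0 - p2) / 2.0
    p1 = 1.0 - p2 - p3
    eps = 1e-12
    if p1 < -eps or p3 < -eps:
        raise ValueError(
            f"mean of {mean_drops} drops is infeasible with P(2 drops) = {p2}: "
            f"solved p1 = {p1:.4f}, p3 = {p3:.4f}"
        )
    p1, p3 = max(p1, 0.0), max(p3, 0.0)
    return (p1, p2, p3)


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total`` by the largest-remainder rule."""
    floors = np.floor(targets).astype(int)
    short = total - int(floors.sum())
    if short < 0:
        raise ValueError("targets exceed total")
    remainders = targets - floors
    order = np.argsort(-remainders, kind="stable")
    counts = floors.copy()
    counts[order[:short]] += 1
    return counts


def _half_outcome_counts(mean_drops: float, n_half: int, n2: int,
                         carry: float = 0.0) -> np.ndarray:
    """Counts of (1, 2, 3)-drop trials in one half with the 2-drop count fixed.

    Chooses the 1- vs 3-drop split whose realized total of drops is
    closest to ``mean_drops * n_half`` (at most one rounding unit away).
    ``carry`` propagates the previous half's rounding residual so the
    session total stays as close to its target as parity allows.
    """
    n13 = n_half - n2
    if n13 < 0:
        raise ValueError("more 2-drop trials than trials in the half")
    own_target = mean_drops * n_half
    # n1 + 3*n3 = total - 2*n2 with n1 + n3 = n13  =>  n3 = (...) / 2
    x = (own_target - 2 * n2 - n13) / 2.0
    cands = {int(np.clip(np.floor(x), 0, n13)), int(np.clip(np.ceil(x), 0, n13))}

    def total(n3: int) -> int:
        return (n13 - n3) + 2 * n2 + 3 * n3

    # closest to this half's own mean first, then whichever best cancels
    # the session-level rounding carry; final tie toward more 3-drops
    n3 = min(cands, key=lambda c: (abs(total(c) - own_target),
                                   abs(carry + own_target - total(c)),
                                   -c))
    return np.array([n13 - n3, n2, n3], dtype=int)


def generate_reward_sequence(spec: ScheduleSpec, seed) -> np.ndarray:
    """Sequence of juice drops (1, 2, or 3) per rewarded trial.

    In the default count-enforced mode the number of 2-drop trials in the
    session is exactly ``round(p_rre * n)`` and per-half outcome counts are
    the largest-remainder rounding of the solved distribution; trial order
    within each half is a seeded uniform shuffle.  With
    ``count_enforced=False`` outcomes are drawn i.i.d. from the per-half
    distributions instead.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_rewarded_trials
    n_first = n // 2
    halves = (n_first, n - n_first)

    drops = np.empty(n, dtype=int)
    if not spec.count_enforced:
        start = 0
        for n_half, m in zip(halves, spec.half_means):
            probs = solve_outcome_probs(m, spec.p_rre)
            drops[start:start + n_half] = rng.choice(
                DROP_LEVELS, size=n_half, p=probs)
            start += n_half
        return drops

    # 2-drop count enforced at the session level, split across halves by
    # largest remainder; ties between halves broken at random.
    n2_total = int(np.floor(spec.p_rre * n + 0.5))
    targets = np.array([spec.p_rre * h for h in halves])
    if rng.random() < 0.5:
        n2_halves = _largest_remainder(targets, n2_total)
    else:
        n2_halves = _largest_remainder(targets[::-1], n2_total)[::-1]

    start = 0
    carry = 0.0
    for n_half, m, n2 in zip(halves, spec.half_means, n2_halves):
        counts = _half_outcome_counts(m, n_half, int(n2), carry)
        carry += m * n_half - float(counts @ np.array(DROP_LEVELS))
        block = np.repeat(DROP_LEVELS, counts)
        rng.shuffle(block)
        drops[start:start + n_half] = block
        start += n_half
    return drops


def generate_side_sequence(spec: ScheduleSpec, seed) -> np.ndarray:
    """Stimulus sides ('left'/'right') organized in reversing runs.

    Run lengths are drawn uniformly from ``run_length_range`` (inclusive);
    after each run the prevailing side reverses.  Within a run, each trial
    is independently displaced to the opposite side with probability
    ``p_offside`` (a visuospatially surprising trial); such trials do not
    reset the run.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_rewarded_trials
    lo, hi = spec.run_length_range
    base = np.empty(n, dtype=bool)  # True = right
    current = bool(rng.integers(2))
    pos = 0
    while pos < n:
        length = int(rng.integers(lo, hi + 1))
        base[pos:pos + length] = current
        pos += length
        current = not current
    offside = rng.random(n) < spec.p_offside
    sides = base ^ offside
    return np.where(sides, "right", "left")


@dataclass
class Session:
    """Realized per-rewarded-trial record of one session.

    ``t_decision`` is stimulus onset; ``t_outcome`` is reward onset,
    placed a nominal response latency plus the reward delay after the
    stimulus (behavioral simulation substitutes sampled reaction times).
    """

    spec: ScheduleSpec
    trial: np.ndarray       # 1-based index
    drops: np.ndarray       # 1, 2, or 3
    side: np.ndarray        # 'left' / 'right'
    half: np.ndarray        # 'first' / 'second'
    t_decision: np.ndarray  # s from session start
    t_outcome: np.ndarray

    def __len__(self) -> int:
        return len(self.trial)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trial": self.trial,
            "drops": self.drops,
            "side": self.side,
            "half": self.half,
            "t_decision": self.t_decision,
            "t_outcome": self.t_outcome,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, spec: ScheduleSpec | None = None) -> "Session":
        if spec is None:
            spec = ScheduleSpec(n_rewarded_trials=len(df))
        return cls(
            spec=spec,
            trial=df["trial"].to_numpy(int),
            drops=df["drops"].to_numpy(int),
            side=df["side"].to_numpy(str),
            half=df["half"].to_numpy(str),
            t_decision=df["t_decision"].to_numpy(float),
            t_outcome=df["t_outcome"].to_numpy(float),
        )


def generate_session(spec: ScheduleSpec, seed) -> Session:
    """Compose reward, side, and timing generation into one session.

    Rewards, sides, and timing each consume an independent child stream
    of ``seed``, so the reward and side sequences are independent by
    construction and a change to one generator cannot perturb the others.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_reward, s_side, s_time = ss.spawn(3)
    drops = generate_reward_sequence(spec, s_reward)
    sides = generate_side_sequence(spec, s_side)

    rng = np.random.default_rng(s_time)
    n = spec.n_rewarded_trials
    t = spec.timing
    blanks = rng.uniform(*t.pre_stim_blank, size=n)
    itis = rng.uniform(*t.iti, size=n)
    t_decision = np.empty(n)
    t_outcome = np.empty(n)
    clock = 0.0
    for i in range(n):
        t_decision[i] = clock + blanks[i]
        t_outcome[i] = t_decision[i] + NOMINAL_RT_S + t.reward_delay
        clock = t_outcome[i] + t.juice_duration + itis[i]

    n_first = n // 2
    half = np.where(np.arange(1, n + 1) <= n_first, "first", "second")
    return Session(
        spec=spec,
        trial=np.arange(1, n + 1),
        drops=drops,
        side=sides,
        half=half,
        t_decision=t_decision,
        t_outcome=t_outcome,
    )
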