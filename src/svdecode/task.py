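"""Risky decision-making task: choice set and event timing.

Every trial offers a certain $5 against a two-outcome lottery ($0 or ``v``).
Half of the lotteries carry an explicitly stated win probability (known
risk, p in {25, 50, 75}%); the other half carry a partially occluded
probability (ambiguity, occlusion A in {24, 50, 74}%, objective p fixed at
50%). Each of the 20 non-catch amounts is paired with each of the 6
uncertainty levels exactly once (120 unique trials over four runs), and a
dominated $4 catch lottery opens every run, giving 124 trials in the
default design.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Context",
    "Trial",
    "TrialSchedule",
    "amount_list",
    "build_choice_set",
    "SAFE_VALUE",
    "RISK_LEVELS",
    "AMBIGUITY_LEVELS",
]

#: The 21 lottery amounts, dollars, ascending (non-uniform steps).
_AMOUNTS = (4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18,
            20, 23, 26, 30, 34, 39, 44, 50, 57, 66)

SAFE_VALUE = 5.0
CATCH_VALUE = 4.0
RISK_LEVELS = (0.25, 0.50, 0.75)
AMBIGUITY_LEVELS = (0.24, 0.50, 0.74)

# Event timing (seconds): lottery display, response window, choice
# confirmation, then a jittered fixation.  The inter-trial fixation is
# 5 +/- 0.75 s plus a (2 s - RT) compensation, which exactly cancels the
# response time, so per-trial duration is response-independent.
DISPLAY_S = 4.0
RESPONSE_S = 2.0
CONFIRM_S = 0.5
ITI_MEAN_S = 5.0
ITI_JITTER_S = 0.75
DECISION_DURATION_S = 4.0
#: Length of one run (6 min 4 s).
RUN_DURATION_S = 364.0

_TRIALS_PER_RUN = 30  # non-catch


class Context(str, enum.Enum):
    RISK = "risk"
    AMBIGUITY = "ambiguity"


def amount_list() -> list[float]:
    """The 21 lottery amounts in dollars, ascending ($4 ... $66)."""
    return [float(v) for v in _AMOUNTS]


@dataclass(frozen=True)
class Trial:
    """One choice between the safe $5 and a lottery.

    ``win_prob`` is the objective win probability (always 0.5 on ambiguity
    trials); ``ambiguity`` is the occluded fraction A (0 on risk trials).
    """

    run_id: int
    position: int
    context: Context
    win_prob: float
    ambiguity: float
    lottery_value: float
    safe_value: float = SAFE_VALUE
    is_catch: bool = False
    onset_s: float = 0.0
    decision_duration_s: float = DECISION_DURATION_S

    def __post_init__(self):
        if self.lottery_value <= 0:
            raise ValueError("lottery_value must be positive")
        if self.context is Context.RISK and self.ambiguity != 0.0:
            raise ValueError("risk trials carry no ambiguity")
        if self.context is Context.AMBIGUITY and self.win_prob != 0.5:
            raise ValueError("ambiguous lotteries have objective p = 0.5")


@dataclass
class TrialSchedule:
    """Ordered trials with run structure and onsets."""

    trials: list[Trial]
    n_runs: int
    run_duration_s: float = RUN_DURATION_S
    rng_seed: int = 0

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def run(self, run_id: int) -> list[Trial]:
        return [t for t in self.trials if t.run_id == run_id]

    def to_frame(self) -> pd.DataFrame:
        """One row per trial, columns as Trial fields."""
        rows = [dataclasses.asdict(t) for t in self.trials]
        df = pd.DataFrame(rows)
        df["context"] = df["context"].map(lambda c: c.value)
        return df

    def events_frame(self) -> pd.DataFrame:
        """BIDS-events-style table (onset, duration, trial_id)."""
        df = self.to_frame()
        out = pd.DataFrame({
            "onset": df["onset_s"],
            "duration": df["decision_duration_s"],
            "trial_id": np.arange(len(df)),
            "run": df["run_id"],
        })
        return out

    # convenience vectors used throughout the pipeline
    @property
    def win_probs(self) -> np.ndarray:
        return np.array([t.win_prob for t in self.trials])

    @property
    def ambiguities(self) -> np.ndarray:
        return np.array([t.ambiguity for t in self.trials])

    @property
    def lottery_values(self) -> np.ndarray:
        return np.array([t.lottery_value for t in self.trials])

    @property
    def run_ids(self) -> np.ndarray:
        return np.array([t.run_id for t in self.trials])

    @property
    def contexts(self) -> np.ndarray:
        return np.array([t.context.value for t in self.trials])

    @property
    def is_catch_mask(self) -> np.ndarray:
        return np.array([t.is_catch for t in self.trials])


def _uncertainty_levels() -> list[tuple[Context, float, float]]:
    """The 6 (context, p, A) levels: 3 risk probabilities, 3 occlusions."""
    levels = [(Context.RISK, p, 0.0) for p in RISK_LEVELS]
    levels += [(Context.AMBIGUITY, 0.5, a) for a in AMBIGUITY_LEVELS]
    return levels


def build_choice_set(n_runs: int = 4, seed: int = 0) -> TrialSchedule:
    """Build the full task schedule.

    The 20 non-catch amounts ($5-$66) are crossed with the 6 uncertainty
    levels (120 unique pairs), dealt 30 per run in a seeded random order,
    and a $4 catch lottery (p = 0.5, no ambiguity) opens each run.  With
    the default four runs every pair appears exactly once.  For other run
    counts the shuffled 120-pair pool is (re)drawn in blocks of four runs.

    Onsets accumulate display (4 s) + response window (2 s) + confirmation
    (0.5 s) + jittered fixation (uniform on [4.25, 5.75] s); response-time
    compensation makes this sum response-independent.
    """
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    rng = np.random.default_rng(seed)

    pairs: list[tuple[float, Context, float, float]] = []
    n_blocks = -(-n_runs // 4)  # each block of 4 runs exhausts the pool once
    for _ in range(n_blocks):
        pool = [(float(v), ctx, p, a)
                for v in _AMOUNTS if v != CATCH_VALUE
                for (ctx, p, a) in _uncertainty_levels()]
        order = rng.permutation(len(pool))
        pairs.extend(pool[i] for i in order)

    trials: list[Trial] = []
    for run in range(1, n_runs + 1):
        onset = 0.0
        run_pairs = pairs[(run - 1) * _TRIALS_PER_RUN: run * _TRIALS_PER_RUN]
        catch = Trial(run_id=run, position=1, context=Context.RISK,
                      win_prob=0.5, ambiguity=0.0,
                      lottery_value=CATCH_VALUE, is_catch=True,
                      onset_s=onset)
        trials.append(catch)
        onset += _trial_duration(rng)
        for pos, (v, ctx, p, a) in enumerate(run_pairs, start=2):
            trials.append(Trial(run_id=run, position=pos, context=ctx,
                                win_prob=p, ambiguity=a, lottery_value=v,
                                onset_s=onset))
            onset += _trial_duration(rng)

    return TrialSchedule(trials=trials, n_runs=n_runs, rng_seed=seed)


def _trial_duration(rng: np.random.Generator) -> float:
    jitter = rng.uniform(ITI_MEAN_S - ITI_JITTER_S, ITI_MEAN_S + ITI_JITTER_S)
    return DISPLAY_S + RESPONSE_S + CONFIRM_S + jitter
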