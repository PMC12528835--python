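"""Expected-utility model of choice under risk and ambiguity.

Subjective value of a two-outcome lottery ($0 or v):

    SV = [p - beta * (A / 2)] * v ** alpha

with alpha the risk-tolerance exponent (alpha = 1 risk-neutral, < 1
averse), beta the ambiguity-attitude coefficient (beta = 0 neutral,
> 0 averse; ambiguity tolerance is reported as -beta), and the safe
option evaluated at p = 1, A = 0.  The probability that the lottery is
chosen follows a logistic rule in the value difference,

    Pr(lottery) = 1 / (1 + exp(gamma * (SV_lottery - SV_safe))),

written exactly in this sign convention: value-consistent choice
corresponds to gamma < 0, and gamma is left unbounded.  Preferences are
estimated per participant by bound-constrained maximum likelihood
(0 <= alpha <= 10, -5 <= beta <= 5) with seeded multistart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .task import SAFE_VALUE, TrialSchedule

__all__ = [
    "PreferenceParams",
    "ChoiceDataset",
    "FitResult",
    "ALPHA_BOUNDS",
    "BETA_BOUNDS",
    "subjective_value",
    "choice_probability",
    "negative_log_likelihood",
    "fit_preferences",
    "model_free_summary",
    "classify_preferences",
]

ALPHA_BOUNDS = (0.0, 10.0)
BETA_BOUNDS = (-5.0, 5.0)
_P_CLIP = 1e-12  # probability clipping before log

#: response coding in ChoiceDataset.responses
LOTTERY, SAFE, MISSING = 1, 0, -1


@dataclass(frozen=True)
class PreferenceParams:
    """Participant-specific (alpha, beta, gamma)."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        if not (ALPHA_BOUNDS[0] <= self.alpha <= ALPHA_BOUNDS[1]):
            raise ValueError(f"alpha {self.alpha} outside {ALPHA_BOUNDS}")
        if not (BETA_BOUNDS[0] <= self.beta <= BETA_BOUNDS[1]):
            raise ValueError(f"beta {self.beta} outside {BETA_BOUNDS}")
        if not np.isfinite(self.gamma):
            raise ValueError("gamma must be finite")

    @property
    def ambiguity_tolerance(self) -> float:
        """Reported ambiguity tolerance, -beta (higher = more tolerant)."""
        return -self.beta

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)


@dataclass
class ChoiceDataset:
    """A schedule plus one response per trial (lottery / safe / missing)."""

    schedule: TrialSchedule
    responses: np.ndarray  # int array, values in {LOTTERY, SAFE, MISSING}
    participant_id: str = "sub-00"

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=int)
        if self.responses.shape != (self.schedule.n_trials,):
            raise ValueError("one response per trial required")
        bad = ~np.isin(self.responses, (LOTTERY, SAFE, MISSING))
        if bad.any():
            raise ValueError("responses must be 1 (lottery), 0 (safe) or -1 (missing)")

    @property
    def non_missing(self) -> np.ndarray:
        return self.responses != MISSING

    @property
    def n_non_missing(self) -> int:
        return int(self.non_missing.sum())


@dataclass
class FitResult:
    params: PreferenceParams
    nll: float
    pseudo_r2: float
    n_trials_used: int
    converged: bool
    n_starts: int
    best_start: tuple[float, float, float]

    def to_dict(self) -> dict:
        return {
            "alpha": self.params.alpha,
            "beta": self.params.beta,
            "gamma": self.params.gamma,
            "ambiguity_tolerance": self.params.ambiguity_tolerance,
            "nll": self.nll,
            "pseudo_r2": self.pseudo_r2,
            "n_trials_used": self.n_trials_used,
            "converged": self.converged,
            "n_starts": self.n_starts,
        }


def subjective_value(p, A, v, alpha: float, beta: float):
    """SV = [p - beta*(A/2)] * v**alpha.  Scalar or array inputs.

    The safe option is evaluated as ``subjective_value(1, 0, 5, ...)``.
    """
    p = np.asarray(p, dtype=float)
    A = np.asarray(A, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("lottery values must be positive")
    out = (p - beta * (A / 2.0)) * v ** alpha
    return out if out.ndim else float(out)


def choice_probability(sv_lottery, sv_safe, gamma: float):
    """Pr(lottery) = 1 / (1 + exp(gamma * (SV_lottery - SV_safe)))."""
    diff = np.asarray(sv_lottery, dtype=float) - np.asarray(sv_safe, dtype=float)
    out = expit(-gamma * diff)  # numerically safe logistic
    return out if out.ndim else float(out)


def _trial_svs(schedule: TrialSchedule, alpha: float, beta: float):
    sv_lot = subjective_value(schedule.win_probs, schedule.ambiguities,
                              schedule.lottery_values, alpha, beta)
    sv_safe = subjective_value(1.0, 0.0, SAFE_VALUE, alpha, beta)
    return np.atleast_1d(sv_lot), float(sv_safe)


def negative_log_likelihood(data: ChoiceDataset, params: PreferenceParams) -> float:
    """-sum log Pr(observed response) over non-missing trials."""
    mask = data.non_missing
    if not mask.any():
        raise ValueError("all trials missing; nothing to fit")
    sv_lot, sv_safe = _trial_svs(data.schedule, params.alpha, params.beta)
    p_lot = np.atleast_1d(choice_probability(sv_lot, sv_safe, params.gamma))[mask]
    chose_lottery = data.responses[mask] == LOTTERY
    p_obs = np.where(chose_lottery, p_lot, 1.0 - p_lot)
    p_obs = np.clip(p_obs, _P_CLIP, 1.0 - _P_CLIP)
    return float(-np.sum(np.log(p_obs)))


def fit_preferences(data: ChoiceDataset, n_starts: int = 20,
                    seed: int = 0) -> FitResult:
    """Constrained maximum-likelihood estimate of (alpha, beta, gamma).

    Minimizes the negative log-likelihood with L-BFGS-B under the bounds
    0 <= alpha <= 10 and -5 <= beta <= 5 (gamma unbounded), from
    ``n_starts`` seeded uniform starts over the box (gamma starting in
    [-5, 5]).  Pseudo-R^2 is McFadden's 1 - LL/LL0 against the chance
    model (log 0.5 per trial).
    """
    if data.n_non_missing < 1:
        raise ValueError("all trials missing; nothing to fit")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    mask = data.non_missing
    chose_lottery = data.responses[mask] == LOTTERY
    p_arr = data.schedule.win_probs[mask]
    a_arr = data.schedule.ambiguities[mask]
    v_arr = data.schedule.lottery_values[mask]

    def nll_vec(theta: np.ndarray) -> float:
        alpha, beta, gamma = theta
        sv_lot = (p_arr - beta * (a_arr / 2.0)) * v_arr ** alpha
        sv_safe = SAFE_VALUE ** alpha
        p_lot = expit(-gamma * (sv_lot - sv_safe))
        p_obs = np.where(chose_lottery, p_lot, 1.0 - p_lot)
        p_obs = np.clip(p_obs, _P_CLIP, 1.0 - _P_CLIP)
        return -np.sum(np.log(p_obs))

    bounds = [ALPHA_BOUNDS, BETA_BOUNDS, (None, None)]
    # canonical starts (neutral and mildly averse choosers, both noise
    # signs) guard against plateaus far from the interpretable range;
    # the remainder are uniform over the bounded box
    canonical = np.array([
        [1.0, 0.0, -0.5],
        [0.6, 0.5, -1.0],
        [1.0, 0.0, 0.5],
        [0.8, -0.5, -0.2],
    ])[:n_starts]
    n_random = n_starts - len(canonical)
    starts = np.vstack([canonical, np.column_stack([
        rng.uniform(*ALPHA_BOUNDS, size=n_random),
        rng.uniform(*BETA_BOUNDS, size=n_random),
        rng.uniform(-5.0, 5.0, size=n_random),
    ])])
    best = None
    best_start = None
    any_converged = False
    for x0 in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = minimize(nll_vec, x0, method="L-BFGS-B", bounds=bounds)
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best, best_start = res, tuple(x0)

    alpha, beta, gamma = best.x
    alpha = float(np.clip(alpha, *ALPHA_BOUNDS))
    beta = float(np.clip(beta, *BETA_BOUNDS))
    n_used = data.n_non_missing
    ll0 = -n_used * np.log(2.0)
    pseudo_r2 = 1.0 - (-best.fun) / ll0
    return FitResult(
        params=PreferenceParams(alpha, beta, float(gamma)),
        nll=float(best.fun),
        pseudo_r2=float(pseudo_r2),
        n_trials_used=n_used,
        converged=any_converged,
        n_starts=n_starts,
        best_start=best_start,
    )


def model_free_summary(data: ChoiceDataset) -> dict:
    """Proportion of lottery choices overall and per (context, level),
    plus the count of dominated-lottery 'error' trials (v < $5 chosen)."""
    sched = data.schedule
    mask = data.non_missing
    chose = data.responses == LOTTERY

    def _prop(sel: np.ndarray) -> float:
        sel = sel & mask
        return float(chose[sel].mean()) if sel.any() else np.nan

    rows = []
    levels = np.where(sched.contexts == "risk", sched.win_probs,
                      sched.ambiguities)
    for ctx in ("risk", "ambiguity"):
        for level in sorted(set(levels[sched.contexts == ctx])):
            sel = (sched.contexts == ctx) & (levels == level)
            rows.append({"context": ctx, "level": level,
                         "prop_lottery": _prop(sel),
                         "n": int((sel & mask).sum())})
    per_cell = pd.DataFrame(rows)
    dominated = sched.lottery_values < SAFE_VALUE
    n_errors = int((dominated & chose & mask).sum())
    return {
        "prop_lottery_overall": _prop(np.ones(sched.n_trials, dtype=bool)),
        "per_cell": per_cell,
        "n_dominated_errors": n_errors,
        "n_missing": int((~mask).sum()),
    }


def classify_preferences(params: PreferenceParams) -> dict:
    """Label attitudes: alpha vs 1 for risk, -beta vs 0 for ambiguity."""
    if params.alpha < 1:
        risk = "averse"
    elif params.alpha > 1:
        risk = "seeking"
    else:
        risk = "neutral"
    tol = params.ambiguity_tolerance
    if tol < 0:
        amb = "averse"
    elif tol > 0:
        amb = "seeking"
    else:
        amb = "neutral"
    return {"risk": risk, "ambiguity": amb}
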