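"""Synthetic cohorts: preferences, choices, beta patterns, BOLD runs.

The generator emulates the statistical structure the analysis stages
assume: agents drawn from group-level preference distributions choose
according to the logistic rule applied to their subjective values; each
ROI carries a multivoxel pattern that encodes standardized lottery SV
linearly along a fixed (seeded) voxel-weight direction, with tunable
amplitude per ROI, tunable sharing of the direction across uncertainty
contexts, and additive white noise.  Group differences are expressed by
giving the groups different amplitude maps (e.g., zero amplitude in a
subset of networks), which propagates monotonically to decoding accuracy
and network widespreadness downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import ROIAtlas
from .choice import (LOTTERY, MISSING, SAFE, ChoiceDataset, PreferenceParams,
                     choice_probability, subjective_value)
from .decoding import BetaSeries
from .task import SAFE_VALUE, TrialSchedule, build_choice_set

__all__ = [
    "CohortSpec",
    "SignalSpec",
    "ConfoundSpec",
    "Participant",
    "default_preference_distributions",
    "simulate_agent",
    "simulate_choices",
    "simulate_beta_series",
    "simulate_bold_run",
    "simulate_cohort",
]

_CONFOUND_NAMES = (["framewise_displacement"]
                   + [f"trans_{a}" for a in "xyz"]
                   + [f"rot_{a}" for a in "xyz"]
                   + [f"a_comp_cor_{i:02d}" for i in range(6)])

_ALPHA_BOUNDS = (0.0, 10.0)
_BETA_BOUNDS = (-5.0, 5.0)


def default_preference_distributions() -> dict[str, dict[str, tuple]]:
    """Group-level (alpha, beta, gamma) distributions.

    Centered on the observed group medians for risk tolerance (controls
    0.599, patients 0.628) and ambiguity attitude (beta 0.524 / 0.352),
    with spreads on the order of the reported interquartile ranges.
    Choice stochasticity gamma is negative (value-consistent choice) with
    a lognormal magnitude whose median (1.5) was calibrated so simulated
    cohorts reproduce the reported moderate-to-good fit quality
    (mean pseudo-R^2 near 0.52-0.58) on the 124-trial design.
    """
    gamma = ("neg_lognormal", float(np.log(1.5)), 0.5)
    return {
        "control": {"alpha": ("normal", 0.599, 0.40),
                    "beta": ("normal", 0.524, 0.70),
                    "gamma": gamma},
        "oud": {"alpha": ("normal", 0.628, 0.40),
                "beta": ("normal", 0.352, 0.80),
                "gamma": gamma},
    }


@dataclass
class CohortSpec:
    n_per_group: int
    group_labels: tuple[str, str] = ("control", "oud")
    preference_distributions: dict | None = None
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.missing_rate <= 0.2):
            raise ValueError("missing_rate must lie in [0, 0.2]")
        if self.preference_distributions is None:
            dists = default_preference_distributions()
            self.preference_distributions = {
                g: dists.get(g, dists["control"]) for g in self.group_labels}

    @property
    def n_total(self) -> int:
        return 2 * self.n_per_group

    def group_of(self, index: int) -> str:
        if not (0 <= index < self.n_total):
            raise IndexError(f"index {index} outside cohort of {self.n_total}")
        return self.group_labels[index // self.n_per_group]


@dataclass
class SignalSpec:
    """How much SV information each ROI's pattern carries.

    ``amplitude_per_roi`` maps roi_id -> signal scale (a scalar applies
    to every ROI).  ``shared_across_contexts`` in [0, 1] is the variance
    fraction of the encoding direction common to risk and ambiguity
    trials (1 = identical direction, 0 = independent directions).
    """

    atlas: ROIAtlas
    amplitude_per_roi: dict[int, float] | float = 1.0
    shared_across_contexts: float = 1.0
    noise_sd: float = 1.0
    voxel_weight_seed: int = 0

    def __post_init__(self):
        if isinstance(self.shared_across_contexts, bool):
            self.shared_across_contexts = float(self.shared_across_contexts)
        if not (0.0 <= self.shared_across_contexts <= 1.0):
            raise ValueError("shared_across_contexts must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def amplitude(self, roi_id: int) -> float:
        if isinstance(self.amplitude_per_roi, dict):
            amp = float(self.amplitude_per_roi.get(roi_id, 0.0))
        else:
            amp = float(self.amplitude_per_roi)
        if amp < 0 or not np.isfinite(amp):
            raise ValueError("amplitudes must be finite and >= 0")
        return amp


@dataclass
class ConfoundSpec:
    """Nuisance structure for simulated BOLD: 13 confound series
    (FD-like, 6 motion-like random walks, 6 component-like), optional
    leakage of those series into the data, and slow drift."""

    leakage: float = 0.0
    drift_amplitude: float = 0.0
    noise_sd: float = 0.0


def _draw(dist: tuple, rng: np.random.Generator) -> float:
    kind = dist[0]
    if kind == "constant":
        return float(dist[1])
    if kind == "normal":
        return float(rng.normal(dist[1], dist[2]))
    if kind == "uniform":
        return float(rng.uniform(dist[1], dist[2]))
    if kind == "lognormal":
        return float(rng.lognormal(dist[1], dist[2]))
    if kind == "neg_lognormal":
        return float(-rng.lognormal(dist[1], dist[2]))
    raise ValueError(f"unknown distribution kind {kind!r}")


def simulate_agent(spec: CohortSpec, index: int) -> PreferenceParams:
    """Seeded draw of one agent's preferences, truncated to the
    estimation bounds (0 <= alpha <= 10, -5 <= beta <= 5)."""
    group = spec.group_of(index)
    dists = spec.preference_distributions[group]
    rng = np.random.default_rng([spec.seed, index])

    def _trunc(dist, bounds):
        for _ in range(100):
            x = _draw(dist, rng)
            if bounds[0] <= x <= bounds[1]:
                return x
        return float(np.clip(x, *bounds))

    alpha = _trunc(dists["alpha"], _ALPHA_BOUNDS)
    beta = _trunc(dists["beta"], _BETA_BOUNDS)
    gamma = _draw(dists["gamma"], rng)
    return PreferenceParams(alpha, beta, gamma)


def simulate_choices(schedule: TrialSchedule, params: PreferenceParams,
                     missing_rate: float = 0.0, seed: int = 0,
                     participant_id: str = "sub-00") -> ChoiceDataset:
    """Bernoulli choices from the logistic rule, plus uniform missingness."""
    rng = np.random.default_rng(seed)
    sv_lot = subjective_value(schedule.win_probs, schedule.ambiguities,
                              schedule.lottery_values, params.alpha, params.beta)
    sv_safe = subjective_value(1.0, 0.0, SAFE_VALUE, params.alpha, params.beta)
    p_lot = np.atleast_1d(choice_probability(sv_lot, sv_safe, params.gamma))
    responses = np.where(rng.random(len(p_lot)) < p_lot, LOTTERY, SAFE)
    if missing_rate > 0:
        responses[rng.random(len(p_lot)) < missing_rate] = MISSING
    return ChoiceDataset(schedule=schedule, responses=responses,
                         participant_id=participant_id)


def _context_weights(n_vox: int, mix: float,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Unit-norm encoding direction per context with shared fraction ``mix``."""
    def unit(v):
        return v / np.linalg.norm(v)
    w_shared = unit(rng.standard_normal(n_vox))
    out = {}
    for ctx in ("risk", "ambiguity"):
        w_own = unit(rng.standard_normal(n_vox))
        w = np.sqrt(mix) * w_shared + np.sqrt(1.0 - mix) * w_own
        out[ctx] = unit(w)
    return out


def simulate_beta_series(schedule: TrialSchedule, params: PreferenceParams,
                         signal: SignalSpec, seed: int = 0,
                         responses: np.ndarray | None = None,
                         participant_id: str = "sub-00"
                         ) -> dict[int, BetaSeries]:
    """Trial x voxel beta patterns per ROI.

    beta_t = amplitude_roi * z(SV_lottery,t) * w(context_t) + noise, with
    z the within-participant standardization over included trials and w
    the ROI's unit-norm encoding direction (seeded by the signal spec, so
    it is a property of the cohort, not of the participant).  Rows cover
    non-missing trials only, in schedule order.
    """
    noise_rng = np.random.default_rng(seed)
    include = np.ones(schedule.n_trials, dtype=bool)
    if responses is not None:
        include = np.asarray(responses) != MISSING
    sv_lot = subjective_value(schedule.win_probs, schedule.ambiguities,
                              schedule.lottery_values, params.alpha, params.beta)
    z = np.atleast_1d(sv_lot)[include]
    z = (z - z.mean()) / z.std() if z.std() > 0 else np.zeros_like(z)
    contexts = schedule.contexts[include]
    run_ids = schedule.run_ids[include]
    trial_ids = np.flatnonzero(include)

    out: dict[int, BetaSeries] = {}
    for roi in signal.atlas:
        w_rng = np.random.default_rng([signal.voxel_weight_seed, roi.roi_id])
        if roi.n_voxels < 2:
            raise ValueError(f"ROI {roi.roi_id} has fewer than 2 voxels")
        weights = _context_weights(roi.n_voxels, signal.shared_across_contexts,
                                   w_rng)
        amp = signal.amplitude(roi.roi_id)
        W = np.stack([weights[c] for c in contexts])  # (n_trials, n_vox)
        mat = amp * z[:, None] * W
        mat = mat + signal.noise_sd * noise_rng.standard_normal(mat.shape)
        out[roi.roi_id] = BetaSeries(roi_id=roi.roi_id, matrix=mat,
                                     run_ids=run_ids, trial_ids=trial_ids,
                                     participant_id=participant_id)
    return out


def simulate_confounds(n_scans: int, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    walk = np.cumsum(rng.normal(0, 0.02, size=(n_scans, 6)), axis=0)
    fd = np.abs(np.diff(walk, axis=0, prepend=walk[:1])).sum(axis=1)
    cols["framewise_displacement"] = fd
    for i, name in enumerate(_CONFOUND_NAMES[1:7]):
        cols[name] = walk[:, i]
    for name in _CONFOUND_NAMES[7:]:
        cols[name] = rng.standard_normal(n_scans) * 0.5
    return pd.DataFrame(cols)


def simulate_bold_run(schedule: TrialSchedule, params: PreferenceParams,
                      signal: SignalSpec, confound_spec: ConfoundSpec,
                      seed: int = 0, run_id: int = 1, tr: float = 1.0,
                      responses: np.ndarray | None = None):
    """One BOLD run (time x voxels, TR 1 s) plus its 13-column confound
    table and the ground-truth betas.

    The series is built from the same convolved regressors the GLM uses
    (decision epoch + run-max-scaled SV modulator), so with zero noise and
    drift the GLM recovers the true betas to numerical precision.
    """
    from .glm import build_design

    rng = np.random.default_rng([seed, run_id])
    n_scans = int(np.ceil(schedule.run_duration_s / tr))
    design = build_design(schedule, run_id, modulator_kind="sv_lottery",
                          params=params, responses=responses, tr=tr,
                          n_scans=n_scans)
    confounds = simulate_confounds(n_scans, rng)

    n_vox = signal.atlas.n_voxels
    epoch_betas = rng.normal(1.0, 0.2, size=n_vox)
    sv_betas = np.zeros(n_vox)
    for roi in signal.atlas:
        w_rng = np.random.default_rng([signal.voxel_weight_seed, roi.roi_id])
        weights = _context_weights(roi.n_voxels, signal.shared_across_contexts,
                                   w_rng)
        sv_betas[roi.voxel_ids] = signal.amplitude(roi.roi_id) * weights["risk"]

    truth = {"decision": epoch_betas, "mod_sv_lottery": sv_betas,
             "constant": np.full(n_vox, 100.0)}
    bold = (np.outer(design.column("decision"), epoch_betas)
            + np.outer(design.column("mod_sv_lottery"), sv_betas)
            + truth["constant"])
    if "missing" in design.names:
        truth["missing"] = rng.normal(1.0, 0.2, size=n_vox)
        bold = bold + np.outer(design.column("missing"), truth["missing"])
    if confound_spec.leakage:
        leak = confound_spec.leakage * rng.standard_normal((13, n_vox))
        bold = bold + confounds.to_numpy() @ leak
        truth["confound_leakage"] = leak
    if confound_spec.drift_amplitude:
        t = np.arange(n_scans) * tr
        drift = (np.cos(2 * np.pi * t / 300.0)[:, None]
                 * confound_spec.drift_amplitude)
        bold = bold + drift
    if confound_spec.noise_sd:
        bold = bold + confound_spec.noise_sd * rng.standard_normal(bold.shape)
    return bold, confounds, truth


@dataclass
class Participant:
    participant_id: str
    group: str
    params: PreferenceParams
    choices: ChoiceDataset
    beta: dict[int, BetaSeries]


def simulate_cohort(spec: CohortSpec, signal_by_group: dict[str, SignalSpec],
                    schedule: TrialSchedule | None = None,
                    n_runs: int = 4) -> list[Participant]:
    """Full cohort: agents, choices, and per-ROI beta series.

    Every participant sees the same schedule (seeded from the cohort
    seed) — the trial set is a fixed design, only its order is random.
    """
    if schedule is None:
        schedule = build_choice_set(n_runs=n_runs, seed=spec.seed)
    out = []
    for i in range(spec.n_total):
        group = spec.group_of(i)
        pid = f"sub-{i:02d}"
        params = simulate_agent(spec, i)
        choices = simulate_choices(
            schedule, params, missing_rate=spec.missing_rate,
            seed=np.random.SeedSequence([spec.seed, 1, i]).generate_state(1)[0],
            participant_id=pid)
        beta = simulate_beta_series(
            schedule, params, signal_by_group[group],
            seed=np.random.SeedSequence([spec.seed, 2, i]).generate_state(1)[0],
            responses=choices.responses, participant_id=pid)
        out.append(Participant(pid, group, params, choices, beta))
    return out
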