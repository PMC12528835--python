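"""First-level GLM machinery for model-based fMRI.

Implements the two designs the pipeline relies on: a parametric-modulator
model (a 4 s decision-epoch regressor whose height is modulated by the
trial's subjective value, run-max scaled to [0, 1] and mean-centered
within run before HRF convolution) and a beta-series model (one regressor
per trial) whose single-trial estimates feed the decoder.  Both share a
canonical double-gamma HRF, 13 nuisance regressors, and a discrete-cosine
high-pass filter with a 128 s cutoff, and are solved by ordinary least
squares per voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .task import DECISION_DURATION_S, SAFE_VALUE, TrialSchedule

__all__ = [
    "DesignMatrix",
    "SphereROI",
    "canonical_hrf",
    "scale_modulator",
    "dct_highpass_basis",
    "build_design",
    "fit_glm",
    "sphere_extract",
    "default_value_spheres",
    "group_tests",
]

HIGHPASS_CUTOFF_S = 128.0
MODULATOR_KINDS = ("sv_lottery", "sv_chosen", "sv_difficulty", "none", "per_trial")

# Double-gamma HRF: response gamma (peak ~5 s), undershoot gamma (peak
# ~15 s) scaled by 1/6 — the canonical shape used by common fMRI software.
_HRF_PEAK_SHAPE = 6.0
_HRF_UNDER_SHAPE = 16.0
_HRF_UNDER_RATIO = 1.0 / 6.0
_HRF_LENGTH_S = 32.0


@dataclass
class DesignMatrix:
    matrix: np.ndarray          # (n_scans, n_regressors)
    names: list[str]
    tr: float
    highpass_s: float = HIGHPASS_CUTOFF_S

    def __post_init__(self):
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("one name per column required")

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)


def _hrf_continuous(t: np.ndarray) -> np.ndarray:
    h = stats.gamma.pdf(t, _HRF_PEAK_SHAPE)
    h = h - _HRF_UNDER_RATIO * stats.gamma.pdf(t, _HRF_UNDER_SHAPE)
    return h


# peak of the continuous-time kernel, located by dense evaluation once
_DENSE_T = np.arange(0.0, _HRF_LENGTH_S, 1e-3)
_HRF_PEAK_VALUE = float(_hrf_continuous(_DENSE_T).max())


def canonical_hrf(tr: float) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``tr`` seconds over 32 s,
    normalized to unit peak of the underlying continuous kernel (so
    kernels at different TRs sample the same function)."""
    if tr <= 0:
        raise ValueError("TR must be positive")
    t = np.arange(0.0, _HRF_LENGTH_S, tr)
    return _hrf_continuous(t) / _HRF_PEAK_VALUE


def scale_modulator(sv_per_trial: np.ndarray, run_ids: np.ndarray) -> np.ndarray:
    """Run-max scaling of per-trial SVs to [0, 1].

    Negative SVs (possible under extreme ambiguity aversion) are floored
    at 0, then each run is divided by its maximum SV.
    """
    sv = np.asarray(sv_per_trial, dtype=float)
    run_ids = np.asarray(run_ids)
    if sv.shape != run_ids.shape:
        raise ValueError("sv_per_trial and run_ids must align")
    sv = np.maximum(sv, 0.0)
    out = np.empty_like(sv)
    for r in np.unique(run_ids):
        sel = run_ids == r
        mx = sv[sel].max()
        if mx <= 0:
            raise ValueError(f"run {r}: maximum SV <= 0, cannot scale")
        out[sel] = sv[sel] / mx
    return out


def dct_highpass_basis(n_scans: int, tr: float,
                       cutoff_s: float = HIGHPASS_CUTOFF_S) -> np.ndarray:
    """Discrete cosine drift regressors for periods longer than ``cutoff_s``.

    Returns the k = 1..K cosines (no constant term), K = floor(2*T/cutoff).
    """
    T = n_scans * tr
    K = int(np.floor(2.0 * T / cutoff_s))
    t = np.arange(n_scans)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2 * n_scans)) for k in range(1, K + 1)]
    if not cols:
        return np.empty((n_scans, 0))
    return np.column_stack(cols)


def _convolved_regressor(onsets: np.ndarray, durations: np.ndarray,
                         heights: np.ndarray, n_scans: int, tr: float,
                         oversample: int = 16) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at scan times."""
    dt = tr / oversample
    n_fine = n_scans * oversample
    x = np.zeros(n_fine)
    for on, dur, h in zip(onsets, durations, heights):
        i0 = int(round(on / dt))
        i1 = int(round((on + dur) / dt))
        x[i0:min(i1, n_fine)] += h
    hrf = _hrf_continuous(np.arange(0.0, _HRF_LENGTH_S, dt)) / _HRF_PEAK_VALUE
    conv = np.convolve(x, hrf)[:n_fine] * dt
    return conv[::oversample][:n_scans]


def build_design(schedule: TrialSchedule, run_id: int,
                 modulator_kind: str = "sv_lottery",
                 params=None,
                 confounds: pd.DataFrame | None = None,
                 responses: np.ndarray | None = None,
                 tr: float = 1.0,
                 n_scans: int | None = None) -> DesignMatrix:
    """Build the design matrix for one run.

    ``modulator_kind``:
      * ``sv_lottery``   — SV of the lottery option (the primary model)
      * ``sv_chosen``    — SV of whichever option was chosen (needs responses)
      * ``sv_difficulty``— |SV(safe) - SV(lottery)|
      * ``none``         — condition regressors only
      * ``per_trial``    — one regressor per (non-missing) trial (beta series)

    Modulators are run-max scaled to [0, 1], mean-centered within the run,
    and applied as heights on the 4 s decision boxcars before convolution.
    ``params`` supplies the preference parameters used to compute SVs (the
    caller decides between individual and group-median parameters).
    Columns: decision epoch, [modulator | trial regressors], missing-trial
    regressor (when any), confounds, constant.
    """
    from .choice import MISSING, LOTTERY, subjective_value

    if modulator_kind not in MODULATOR_KINDS:
        raise ValueError(f"unknown modulator_kind {modulator_kind!r}; "
                         f"one of {MODULATOR_KINDS}")
    trials = schedule.run(run_id)
    if not trials:
        raise ValueError(f"no trials in run {run_id}")
    if n_scans is None:
        n_scans = int(np.ceil(schedule.run_duration_s / tr))

    onsets = np.array([t.onset_s for t in trials])
    durations = np.array([t.decision_duration_s for t in trials])
    run_mask = schedule.run_ids == run_id
    trial_ids = np.flatnonzero(run_mask)
    if responses is not None:
        responses = np.asarray(responses)
        miss = responses[run_mask] == MISSING
    else:
        miss = np.zeros(len(trials), dtype=bool)

    cols, names = [], []
    # decision epoch (non-missing trials)
    cols.append(_convolved_regressor(onsets[~miss], durations[~miss],
                                     np.ones((~miss).sum()), n_scans, tr))
    names.append("decision")

    if modulator_kind == "per_trial":
        for tid, on, dur in zip(trial_ids[~miss], onsets[~miss], durations[~miss]):
            cols.append(_convolved_regressor([on], [dur], [1.0], n_scans, tr))
            names.append(f"trial_{tid:04d}")
    elif modulator_kind != "none":
        if params is None:
            raise ValueError("preference params required for SV modulators")
        sv_lot = np.array([
            subjective_value(t.win_prob, t.ambiguity, t.lottery_value,
                             params.alpha, params.beta) for t in trials])
        sv_safe = subjective_value(1.0, 0.0, SAFE_VALUE, params.alpha, params.beta)
        if modulator_kind == "sv_lottery":
            vals = sv_lot
        elif modulator_kind == "sv_chosen":
            if responses is None:
                raise ValueError("sv_chosen modulator requires responses")
            chose_lot = responses[run_mask] == LOTTERY
            vals = np.where(chose_lot, sv_lot, sv_safe)
        else:  # sv_difficulty
            vals = np.abs(sv_safe - sv_lot)
        scaled = scale_modulator(vals[~miss],
                                 np.zeros((~miss).sum(), dtype=int))
        heights = scaled - scaled.mean()
        cols.append(_convolved_regressor(onsets[~miss], durations[~miss],
                                         heights, n_scans, tr))
        names.append(f"mod_{modulator_kind}")

    if miss.any():
        cols.append(_convolved_regressor(onsets[miss], durations[miss],
                                         np.ones(miss.sum()), n_scans, tr))
        names.append("missing")

    if confounds is not None:
        if len(confounds) != n_scans:
            raise ValueError("confound table must align with scan length")
        for c in confounds.columns:
            cols.append(np.asarray(confounds[c], dtype=float))
            names.append(str(c))

    cols.append(np.ones(n_scans))
    names.append("constant")
    return DesignMatrix(np.column_stack(cols), names, tr)


def fit_glm(bold: np.ndarray, design: DesignMatrix) -> dict[str, np.ndarray]:
    """High-pass filter (DCT, 128 s cutoff) data and design, then OLS.

    Returns a mapping regressor name -> beta vector over voxels.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.shape[0] != design.n_scans:
        raise ValueError("BOLD and design row counts differ")
    K = dct_highpass_basis(design.n_scans, design.tr, design.highpass_s)
    X = design.matrix
    if K.shape[1]:
        # project out drift from both sides (cosines are zero-mean, so the
        # constant column is untouched)
        P = K @ np.linalg.pinv(K)
        X = X - P @ X
        bold = bold - P @ bold

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [design.names[piv[i]] for i in range(len(diag)) if diag[i] < tol]
        raise ValueError(f"design is rank deficient after filtering; "
                         f"offending columns: {bad}")
    betas, *_ = np.linalg.lstsq(X, bold, rcond=None)
    return {name: betas[i] for i, name in enumerate(design.names)}


@dataclass(frozen=True)
class SphereROI:
    """A sphere in MNI millimeter space."""

    name: str
    center_mni: tuple[float, float, float]
    radius_mm: float = 5.0


def default_value_spheres() -> list[SphereROI]:
    """5 mm spheres at meta-analytic valuation-system coordinates."""
    return [
        SphereROI("vmPFC", (-1.0, 46.0, -7.0)),
        SphereROI("vStr_L", (-10.0, 10.0, -4.0)),
        SphereROI("vStr_R", (10.0, 10.0, -4.0)),
        SphereROI("PCC", (-4.0, -30.0, 36.0)),
    ]


def sphere_extract(beta_map, rois: list[SphereROI],
                   affine: np.ndarray | None = None) -> dict[str, float]:
    """Mean beta within each sphere.

    ``beta_map`` may be a nibabel spatial image or a 3-D array with an
    explicit voxel-to-mm ``affine``.  A voxel belongs to a sphere when its
    center lies within the radius of the sphere's MNI coordinate.
    """
    if affine is None:
        data = np.asarray(beta_map.get_fdata())
        affine = beta_map.affine
    else:
        data = np.asarray(beta_map, dtype=float)
    ijk = np.array(np.meshgrid(*[np.arange(s) for s in data.shape],
                               indexing="ij")).reshape(3, -1)
    xyz = (affine[:3, :3] @ ijk + affine[:3, 3:4]).T
    flat = data.reshape(-1)
    out = {}
    for roi in rois:
        d = np.linalg.norm(xyz - np.asarray(roi.center_mni), axis=1)
        sel = d <= roi.radius_mm
        if not sel.any():
            raise ValueError(f"sphere {roi.name} contains no voxels")
        out[roi.name] = float(flat[sel].mean())
    return out


def group_tests(betas_by_participant: np.ndarray,
                group_labels: np.ndarray | None = None) -> dict:
    """One-sample t (task effect vs 0) and, when two groups are given,
    a pooled two-sample t (df = n1 + n2 - 2), two-tailed."""
    x = np.asarray(betas_by_participant, dtype=float)
    if x.std(ddof=1) == 0:
        if not np.allclose(x, 0):
            raise ValueError("zero variance across participants")
        t1, p1 = 0.0, 1.0  # identically zero betas: no effect, by convention
    else:
        t1, p1 = stats.ttest_1samp(x, popmean=0.0)
    out = {"one_sample_t": float(t1), "one_sample_p": float(p1)}
    if group_labels is not None:
        group_labels = np.asarray(group_labels)
        groups = np.unique(group_labels)
        if len(groups) != 2:
            raise ValueError("exactly two groups required")
        a = x[group_labels == groups[0]]
        b = x[group_labels == groups[1]]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need >= 2 participants per group")
        t2, p2 = stats.ttest_ind(a, b, equal_var=True)
        out.update(two_sample_t=float(t2), two_sample_p=float(p2),
                   groups=(str(groups[0]), str(groups[1])))
    return out
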