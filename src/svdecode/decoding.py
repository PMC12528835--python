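"""Trial-wise multivoxel decoding of subjective-value level.

Trials are labeled low/high by a median split on the participant's
run-normalized lottery SVs (individual preference parameters), extreme
trials are dropped by a 3-SD rule on each ROI's spatial mean, and a
linear support-vector classifier (C = 1) is evaluated by leave-one-run-out
cross-validation.  Because a median split on discrete values leaves the
classes slightly imbalanced, every training fold is balanced by bootstrap
subsampling of the majority class before fitting; fold accuracy is the
mean held-out accuracy over bootstraps.  Cross-context decoding trains on
one uncertainty context (risk or ambiguity) and tests on the other in the
held-out run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .glm import scale_modulator

__all__ = [
    "BetaSeries",
    "LabeledTrials",
    "DecodingResult",
    "label_by_median_split",
    "remove_outlier_trials",
    "loro_cv_decode",
    "cross_context_decode",
]

LOW, HIGH = 0, 1


@dataclass
class BetaSeries:
    """Per-ROI trials x voxels single-trial estimates.

    Rows align with the non-missing trials of the schedule, in schedule
    order; ``trial_ids`` index into the full schedule.
    """

    roi_id: int
    matrix: np.ndarray          # (n_trials_included, n_voxels)
    run_ids: np.ndarray         # (n_trials_included,)
    trial_ids: np.ndarray       # (n_trials_included,)
    participant_id: str = "sub-00"
    dropped_trial_ids: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.run_ids = np.asarray(self.run_ids, dtype=int)
        self.trial_ids = np.asarray(self.trial_ids, dtype=int)
        n = self.matrix.shape[0]
        if not (len(self.run_ids) == len(self.trial_ids) == n):
            raise ValueError("run_ids/trial_ids must match matrix rows")

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[1]


@dataclass
class LabeledTrials:
    """Low/high SV labels per trial (by trial_id)."""

    trial_ids: np.ndarray
    labels: np.ndarray          # LOW / HIGH
    contexts: np.ndarray        # "risk" / "ambiguity" per trial
    split_kind: str             # "overall" | "within_context"

    def label_of(self, trial_ids: np.ndarray) -> np.ndarray:
        idx = {t: i for i, t in enumerate(self.trial_ids)}
        return np.array([self.labels[idx[t]] for t in trial_ids])

    def context_of(self, trial_ids: np.ndarray) -> np.ndarray:
        idx = {t: i for i, t in enumerate(self.trial_ids)}
        return np.array([self.contexts[idx[t]] for t in trial_ids])


@dataclass
class DecodingResult:
    roi_id: int
    scheme: str                 # "within" | "cross_context"
    fold_accuracies: np.ndarray
    mean_accuracy: float
    n_boot: int
    seed: int


def _balanced_split(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Median split with tie balancing.

    Strictly below the median -> LOW, strictly above -> HIGH; values equal
    to the median are assigned one by one (seeded order) to whichever
    class is currently smaller, breaking exact ties at random.
    """
    med = np.median(values)
    labels = np.full(len(values), -1, dtype=int)
    labels[values < med] = LOW
    labels[values > med] = HIGH
    tied = np.flatnonzero(labels == -1)
    rng.shuffle(tied)
    n_low = int((labels == LOW).sum())
    n_high = int((labels == HIGH).sum())
    for t in tied:
        if n_low < n_high:
            labels[t] = LOW
            n_low += 1
        elif n_high < n_low:
            labels[t] = HIGH
            n_high += 1
        else:
            labels[t] = int(rng.integers(2))
            if labels[t] == LOW:
                n_low += 1
            else:
                n_high += 1
    return labels


def label_by_median_split(sv_per_trial: np.ndarray,
                          run_ids: np.ndarray,
                          contexts: np.ndarray,
                          split_kind: str = "overall",
                          seed: int = 0,
                          trial_ids: np.ndarray | None = None) -> LabeledTrials:
    """Label trials low/high SV by a (tie-balanced) median split.

    SVs are first normalized to [0, 1] within run by the same run-max
    scaling used for the univariate parametric modulator.  With
    ``split_kind='within_context'`` separate medians are taken for risk
    and ambiguity trials (the labeling used for cross-context decoding).
    """
    sv_per_trial = np.asarray(sv_per_trial, dtype=float)
    run_ids = np.asarray(run_ids)
    contexts = np.asarray(contexts)
    if len(sv_per_trial) < 2:
        raise ValueError("need at least two trials to split")
    if np.ptp(sv_per_trial) == 0:
        raise ValueError("all SVs identical; median split is degenerate")
    if split_kind not in ("overall", "within_context"):
        raise ValueError(f"unknown split_kind {split_kind!r}")
    if trial_ids is None:
        trial_ids = np.arange(len(sv_per_trial))
    rng = np.random.default_rng(seed)

    norm = scale_modulator(sv_per_trial, run_ids)
    labels = np.empty(len(norm), dtype=int)
    if split_kind == "overall":
        labels[:] = _balanced_split(norm, rng)
    else:
        for ctx in ("risk", "ambiguity"):
            sel = contexts == ctx
            if sel.any():
                labels[sel] = _balanced_split(norm[sel], rng)
    return LabeledTrials(trial_ids=np.asarray(trial_ids), labels=labels,
                         contexts=contexts, split_kind=split_kind)


def remove_outlier_trials(series: BetaSeries, n_sd: float = 3.0) -> BetaSeries:
    """Drop trials whose spatial mean lies outside ``n_sd`` standard
    deviations of the across-trial mean of those means."""
    if series.n_trials < 10:
        raise ValueError("need at least 10 trials for outlier screening")
    m = series.matrix.mean(axis=1)
    sd = m.std(ddof=1)
    keep = np.ones(series.n_trials, dtype=bool)
    if sd > 0:
        keep = np.abs(m - m.mean()) <= n_sd * sd
    dropped = series.trial_ids[~keep]
    return BetaSeries(
        roi_id=series.roi_id,
        matrix=series.matrix[keep],
        run_ids=series.run_ids[keep],
        trial_ids=series.trial_ids[keep],
        participant_id=series.participant_id,
        dropped_trial_ids=np.concatenate([series.dropped_trial_ids, dropped]),
    )


def _fit_predict(X_train, y_train, X_test, C) -> np.ndarray:
    clf = SVC(kernel="linear", C=C)
    clf.fit(X_train, y_train)
    return clf.predict(X_test)


def _boot_fold_accuracy(X_train, y_train, X_test, y_test,
                        n_boot: int, C: float,
                        rng: np.random.Generator) -> float:
    """Mean held-out accuracy over bootstrap-balanced training sets.

    Balancing randomly removes samples of the majority class (globally
    across the training runs) so both classes have equal counts.
    """
    n_low = int((y_train == LOW).sum())
    n_high = int((y_train == HIGH).sum())
    n_keep = min(n_low, n_high)
    accs = np.empty(n_boot)
    for b in range(n_boot):
        if n_low == n_high:
            idx = np.arange(len(y_train))
        else:
            low_idx = np.flatnonzero(y_train == LOW)
            high_idx = np.flatnonzero(y_train == HIGH)
            low_keep = rng.choice(low_idx, size=n_keep, replace=False)
            high_keep = rng.choice(high_idx, size=n_keep, replace=False)
            idx = np.sort(np.concatenate([low_keep, high_keep]))
        pred = _fit_predict(X_train[idx], y_train[idx], X_test, C)
        accs[b] = np.mean(pred == y_test)
    return float(accs.mean())


def _cv_folds(run_ids: np.ndarray) -> list[tuple[int, np.ndarray, np.ndarray]]:
    runs = np.unique(run_ids)
    if len(runs) < 2:
        raise ValueError("leave-one-run-out needs at least two runs")
    return [(int(r), run_ids != r, run_ids == r) for r in runs]


def loro_cv_decode(series: BetaSeries, labels: LabeledTrials,
                   n_boot: int = 100, C: float = 1.0, seed: int = 0,
                   train_labels: np.ndarray | None = None,
                   rng: np.random.Generator | None = None) -> DecodingResult:
    """Leave-one-run-out cross-validated decoding of low vs high SV.

    Each fold trains a linear SVC (regularization C) on the other runs
    after bootstrap label balancing and scores the held-out run.
    ``train_labels`` (aligned with the series rows) substitutes for the
    true labels in every training fold while testing stays against the
    true labels — the primitive used to build empirical null
    distributions from permuted training labels.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    y = labels.label_of(series.trial_ids)
    y_fit = y if train_labels is None else np.asarray(train_labels)
    if len(y_fit) != len(y):
        raise ValueError("train_labels must align with the series rows")
    X = series.matrix
    fold_accs = []
    for _run, train, test in _cv_folds(series.run_ids):
        y_train = y_fit[train]
        if len(np.unique(y_train)) < 2:
            warnings.warn(f"fold holding out run {_run}: single-label "
                          "training set, fold skipped")
            continue
        fold_accs.append(_boot_fold_accuracy(
            X[train], y_train, X[test], y[test], n_boot, C, rng))
    if not fold_accs:
        raise ValueError("all folds skipped (single-label training sets)")
    fold_accs = np.array(fold_accs)
    return DecodingResult(roi_id=series.roi_id, scheme="within",
                          fold_accuracies=fold_accs,
                          mean_accuracy=float(fold_accs.mean()),
                          n_boot=n_boot, seed=seed)


def cross_context_decode(series: BetaSeries, labels: LabeledTrials,
                         n_boot: int = 100, C: float = 1.0, seed: int = 0,
                         train_labels: np.ndarray | None = None,
                         rng: np.random.Generator | None = None) -> DecodingResult:
    """Cross-context decoding: train on one uncertainty context in the
    retained runs, test on the other context in the held-out run; both
    directions are run and averaged.  Labels should come from a
    ``within_context`` median split."""
    if rng is None:
        rng = np.random.default_rng(seed)
    y = labels.label_of(series.trial_ids)
    y_fit = y if train_labels is None else np.asarray(train_labels)
    ctx = labels.context_of(series.trial_ids)
    X = series.matrix
    fold_accs = []
    for train_ctx, test_ctx in (("risk", "ambiguity"), ("ambiguity", "risk")):
        for _run, train, test in _cv_folds(series.run_ids):
            tr = train & (ctx == train_ctx)
            te = test & (ctx == test_ctx)
            if not te.any():
                warnings.warn(f"run {_run}: no {test_ctx} trials to test on")
                continue
            y_train = y_fit[tr]
            if len(np.unique(y_train)) < 2:
                warnings.warn(f"run {_run}: single-label {train_ctx} "
                              "training set, fold skipped")
                continue
            fold_accs.append(_boot_fold_accuracy(
                X[tr], y_train, X[te], y[te], n_boot, C, rng))
    if not fold_accs:
        raise ValueError("all folds skipped")
    fold_accs = np.array(fold_accs)
    return DecodingResult(roi_id=series.roi_id, scheme="cross_context",
                          fold_accuracies=fold_accs,
                          mean_accuracy=float(fold_accs.mean()),
                          n_boot=n_boot, seed=seed)


def results_frame(results: list[DecodingResult], atlas=None) -> pd.DataFrame:
    """Tidy per-ROI results table."""
    rows = []
    for r in results:
        row = {"roi_id": r.roi_id, "scheme": r.scheme,
               "mean_accuracy": r.mean_accuracy,
               "n_folds": len(r.fold_accuracies),
               "n_boot": r.n_boot, "seed": r.seed}
        if atlas is not None:
            row["network"] = atlas.network_of(r.roi_id)
        rows.append(row)
    return pd.DataFrame(rows)
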