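"""Permutation inference for decoding accuracies and widespreadness.

Significance of decoding is assessed nonparametrically: for each
participant the training labels are permuted within each cross-validation
fold and the full CV rerun, building an empirical null distribution of
accuracies; the group null is the participant average per permutation and
the permuted p-value is the fraction of null values at or above the
observed group accuracy (ties count as exceedances; no +1 smoothing, so
the attainable floor is 1/n_perm and exact zeros can occur only when the
observed statistic strictly exceeds every null value).  Group contrasts
permute group membership of the per-participant CV scores.  The
"widespreadness" index is, per network and significance threshold, the
proportion of ROIs whose decoding survives that threshold; its group test
permutes group labels while reusing each participant's cached null
accuracies, so no re-decoding is required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import ROIAtlas
from .decoding import (BetaSeries, DecodingResult, LabeledTrials,
                       cross_context_decode, loro_cv_decode)

__all__ = [
    "DecodeConfig",
    "NullDistribution",
    "ParticipantNullCache",
    "permutation_null",
    "group_difference_permutation",
    "widespreadness",
    "widespreadness_group_test",
    "WidespreadnessTable",
]

DEFAULT_THRESHOLDS = (0.05, 0.01, 0.001)


@dataclass
class DecodeConfig:
    """Decoding settings shared between observed and null analyses."""

    n_boot: int = 100
    C: float = 1.0
    scheme: str = "within"  # or "cross_context"
    seed: int = 0

    def decode(self, series: BetaSeries, labels: LabeledTrials,
               rng=None, train_labels=None) -> DecodingResult:
        fn = loro_cv_decode if self.scheme == "within" else cross_context_decode
        return fn(series, labels, n_boot=self.n_boot, C=self.C,
                  seed=self.seed, rng=rng, train_labels=train_labels)


@dataclass
class NullDistribution:
    roi_id: int
    observed_per_participant: np.ndarray   # (P,)
    per_participant_null: np.ndarray       # (P, n_perm)
    observed: float                        # group mean accuracy
    group_null: np.ndarray                 # (n_perm,)
    p_perm: float

    @property
    def n_perm(self) -> int:
        return self.per_participant_null.shape[1]


def _p_greater(null: np.ndarray, observed: float) -> float:
    """Permuted p: fraction of null values at or above the observed one.

    Ties count as exceedances.  Counting only strict exceedances would
    anti-conservatively shrink p whenever the statistic is discrete
    (tied null values are common for accuracies and proportions at desk
    scale), inflating the type-I error well past the nominal level; the
    tie-inclusive count is valid (P(p <= a) <= a) under exchangeability.
    """
    return float(np.mean(np.asarray(null) >= observed))


def permutation_null(series_by_participant: list[BetaSeries],
                     labels_by_participant: list[LabeledTrials],
                     n_perm: int = 1000,
                     decode_config: DecodeConfig | None = None,
                     seed: int = 0) -> NullDistribution:
    """Empirical null for one ROI across participants.

    Uses the same decoding configuration as the observed analysis.  For
    each permutation one shuffle of the participant's trial labels is
    drawn and substituted for the training labels in every fold (test
    labels untouched), and the CV accuracy recomputed.  Drawing the
    shuffle once per permutation, rather than independently per fold,
    preserves the cross-fold correlation structure of the observed
    statistic and keeps the null exchangeable with it.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives an unstable p floor of "
                      f"{1.0 / max(n_perm, 1):.3g}")
    if decode_config is None:
        decode_config = DecodeConfig()
    P = len(series_by_participant)
    if P != len(labels_by_participant):
        raise ValueError("one label set per participant required")
    roi_id = series_by_participant[0].roi_id

    observed = np.empty(P)
    null = np.empty((P, n_perm))
    for i, (series, labels) in enumerate(
            zip(series_by_participant, labels_by_participant)):
        rng = np.random.default_rng([seed, i])
        observed[i] = decode_config.decode(series, labels, rng=rng).mean_accuracy
        y = labels.label_of(series.trial_ids)
        for k in range(n_perm):
            null[i, k] = decode_config.decode(
                series, labels, rng=rng,
                train_labels=rng.permutation(y)).mean_accuracy

    group_null = null.mean(axis=0)
    obs = float(observed.mean())
    return NullDistribution(roi_id=roi_id,
                            observed_per_participant=observed,
                            per_participant_null=null,
                            observed=obs,
                            group_null=group_null,
                            p_perm=_p_greater(group_null, obs))


def group_difference_permutation(scores_a: np.ndarray, scores_b: np.ndarray,
                                 n_perm: int = 1000, seed: int = 0) -> dict:
    """One-sided permutation test of mean(a) - mean(b) by reshuffling
    group membership of the pooled scores."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    na = len(a)
    observed = a.mean() - b.mean()
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(len(pooled))
        null[k] = pooled[perm[:na]].mean() - pooled[perm[na:]].mean()
    return {"observed_difference": float(observed),
            "null": null,
            "p_perm": _p_greater(null, observed)}


@dataclass
class ParticipantNullCache:
    """Observed and null accuracies per ROI x participant, retained so the
    widespreadness group test can re-pool participants without re-decoding."""

    participant_ids: list[str]
    observed: dict[int, np.ndarray]        # roi_id -> (P,)
    null: dict[int, np.ndarray]            # roi_id -> (P, n_perm)

    @classmethod
    def from_nulls(cls, participant_ids: list[str],
                   nulls: dict[int, NullDistribution]) -> "ParticipantNullCache":
        return cls(participant_ids=list(participant_ids),
                   observed={r: n.observed_per_participant for r, n in nulls.items()},
                   null={r: n.per_participant_null for r, n in nulls.items()})

    @property
    def roi_ids(self) -> list[int]:
        return sorted(self.observed)

    def pooled_p(self, roi_id: int, members: np.ndarray) -> float:
        """Permuted p for a (pseudo-)group given by a boolean member mask."""
        obs = self.observed[roi_id][members].mean()
        null = self.null[roi_id][members].mean(axis=0)
        return _p_greater(null, obs)


@dataclass
class WidespreadnessTable:
    table: pd.DataFrame            # group x network x threshold proportions
    overall: pd.DataFrame          # per group x threshold, all-ROI proportion
    overlap: pd.DataFrame          # per threshold, share of significant ROIs
                                   # significant in both groups

    def proportion(self, group: str, network: str, threshold: float) -> float:
        t = self.table
        sel = ((t["group"] == group) & (t["network"] == network)
               & (t["threshold"] == threshold))
        return float(t.loc[sel, "proportion"].iloc[0])


def widespreadness(p_by_group_roi: dict[str, dict[int, float]],
                   atlas: ROIAtlas,
                   thresholds=DEFAULT_THRESHOLDS) -> WidespreadnessTable:
    """Per group, network and threshold: the proportion of that network's
    ROIs whose permuted p falls below the threshold.  Also reports the
    all-ROI proportions and the cross-group overlap share."""
    for group, pvals in p_by_group_roi.items():
        for roi_id in pvals:
            if roi_id not in atlas.rois:
                raise ValueError(f"ROI {roi_id} has no atlas/network entry")
    rows, overall_rows = [], []
    for group, pvals in p_by_group_roi.items():
        for thr in thresholds:
            sig = {r: (p < thr) for r, p in pvals.items()}
            overall_rows.append({
                "group": group, "threshold": thr,
                "proportion": float(np.mean(list(sig.values())))})
            for network in atlas.networks:
                members = atlas.rois_in_network(network)
                members = [r for r in members if r in pvals]
                if not members:
                    continue
                prop = float(np.mean([sig[r] for r in members]))
                rows.append({"group": group, "network": network,
                             "threshold": thr, "proportion": prop,
                             "n_rois": len(members),
                             "n_significant": int(sum(sig[r] for r in members))})
    overlap_rows = []
    groups = list(p_by_group_roi)
    if len(groups) == 2:
        g1, g2 = groups
        for thr in thresholds:
            s1 = {r for r, p in p_by_group_roi[g1].items() if p < thr}
            s2 = {r for r, p in p_by_group_roi[g2].items() if p < thr}
            union = s1 | s2
            share = len(s1 & s2) / len(union) if union else np.nan
            overlap_rows.append({"threshold": thr, "overlap_share": share,
                                 "n_both": len(s1 & s2), "n_union": len(union)})
    return WidespreadnessTable(table=pd.DataFrame(rows),
                               overall=pd.DataFrame(overall_rows),
                               overlap=pd.DataFrame(overlap_rows))


def _network_proportions(cache: ParticipantNullCache, members: np.ndarray,
                         atlas: ROIAtlas, thresholds) -> dict:
    """Proportion significant per (network, threshold) for one member mask."""
    pvals = {r: cache.pooled_p(r, members) for r in cache.roi_ids}
    out = {}
    for network in atlas.networks:
        rois = [r for r in atlas.rois_in_network(network) if r in pvals]
        if not rois:
            continue
        for thr in thresholds:
            out[(network, thr)] = float(np.mean([pvals[r] < thr for r in rois]))
    return out


def widespreadness_group_test(cache: ParticipantNullCache,
                              group_labels: np.ndarray,
                              atlas: ROIAtlas,
                              thresholds=DEFAULT_THRESHOLDS,
                              n_perm: int = 1000,
                              seed: int = 0) -> pd.DataFrame:
    """Permutation test of the group difference in widespreadness.

    For the observed grouping and for each of ``n_perm`` random
    reshufflings of the participant group labels, per-pseudo-group ROI
    p-values are recomputed from the cached observed/null accuracies and
    summarized into network proportions; the reported p is the fraction
    of null proportion-differences strictly greater than the observed
    difference (first group minus second).
    """
    group_labels = np.asarray(group_labels)
    if len(group_labels) != len(cache.participant_ids):
        raise ValueError("one group label per cached participant required")
    groups = list(dict.fromkeys(group_labels))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    rng = np.random.default_rng(seed)
    mask_a = group_labels == groups[0]

    obs_a = _network_proportions(cache, mask_a, atlas, thresholds)
    obs_b = _network_proportions(cache, ~mask_a, atlas, thresholds)
    keys = list(obs_a)
    obs_diff = {k: obs_a[k] - obs_b[k] for k in keys}

    null_diff = {k: np.empty(n_perm) for k in keys}
    n_a = int(mask_a.sum())
    for p in range(n_perm):
        perm = rng.permutation(len(group_labels))
        pmask = np.zeros(len(group_labels), dtype=bool)
        pmask[perm[:n_a]] = True
        prop_a = _network_proportions(cache, pmask, atlas, thresholds)
        prop_b = _network_proportions(cache, ~pmask, atlas, thresholds)
        for k in keys:
            null_diff[k][p] = prop_a[k] - prop_b[k]

    rows = []
    for (network, thr) in keys:
        rows.append({
            "network": network, "threshold": thr,
            "proportion_a": obs_a[(network, thr)],
            "proportion_b": obs_b[(network, thr)],
            "observed_difference": obs_diff[(network, thr)],
            "p_perm_group": _p_greater(null_diff[(network, thr)],
                                       obs_diff[(network, thr)]),
            "group_a": str(groups[0]), "group_b": str(groups[1]),
        })
    return pd.DataFrame(rows)
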