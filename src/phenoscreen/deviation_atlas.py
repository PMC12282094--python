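"""Cross-condition deviation summaries and nutrient-independent outliers.

Three views of a scored screen:

* breadth — per strain, how many conditions and how many features show at
  least one deviation (|s| >= 3), plus a binned 2-D histogram;
* condition-subset partition — each deviating strain assigned to the exact
  subset of conditions in which it deviates (the four-way Venn counts);
* nutrient-independent outliers — (strain, feature) pairs whose score passes
  the primary threshold (> 3) in at least one condition and the secondary
  threshold (> 1.5) with the same sign in every other evaluated condition;
* cross-condition robustness — for each condition pair, the feature-averaged
  correlation of scores over strains that deviate for that feature.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import DeviationCalls, ScoreMatrix

log = logging.getLogger(__name__)

#: Default feature-count bins for the breadth histogram (inclusive ranges).
DEFAULT_FEATURE_BINS: tuple[tuple[int, int], ...] = (
    (1, 1), (2, 5), (6, 10), (11, 20), (21, 40), (41, 10_000),
)

#: Default strain-level outlier-count bins (frequency-distribution view).
DEFAULT_STRAIN_BINS: tuple[tuple[int, int], ...] = (
    (1, 1), (2, 5), (6, 10), (11, 20), (21, 40), (41, 10_000),
)


def _bin_label(lo: int, hi: int) -> str:
    if lo == hi:
        return str(lo)
    if hi >= 10_000:
        return f">{lo - 1}"
    return f"{lo}-{hi}"


@dataclass
class BreadthSummary:
    per_strain: pd.DataFrame  # columns: n_conditions, n_features
    histogram: pd.DataFrame   # index: n_conditions, columns: feature bins


@dataclass
class OutlierRecord:
    """One nutrient-independent outlying (strain, feature) pair."""

    strain: str
    feature: str
    sign: int
    scores_by_condition: dict[str, float]  # NaN for unevaluated conditions
    conditions_evaluated: int


@dataclass
class OutlierScan:
    records: list[OutlierRecord]
    n_skipped: int                 # (strain, feature) pairs with too few conditions
    primary: float
    secondary: float
    same_sign: bool
    min_conditions: int


@dataclass
class OutlierCounts:
    per_feature: pd.Series
    per_strain: pd.Series
    per_strain_histogram: pd.Series


@dataclass
class RobustnessMatrix:
    pair_means: pd.DataFrame       # conditions x conditions, diag 1.0
    per_feature: pd.DataFrame      # feature, condition_a, condition_b, corr, n_strains
    method: str = "spearman"


# ---------------------------------------------------------------------------

def summarize_breadth(
    calls: DeviationCalls,
    feature_bins: Sequence[tuple[int, int]] = DEFAULT_FEATURE_BINS,
) -> BreadthSummary:
    """Per-strain deviation breadth and its binned 2-D histogram.

    n_conditions counts conditions with >= 1 deviating feature; n_features
    counts features deviating in >= 1 condition.
    """
    dev = calls.deviating
    by_cond = dev.T.groupby(level="condition").any().T
    by_feat = dev.T.groupby(level="feature").any().T
    per_strain = pd.DataFrame(
        {"n_conditions": by_cond.sum(axis=1), "n_features": by_feat.sum(axis=1)}
    )
    labels = ["0"] + [_bin_label(lo, hi) for lo, hi in feature_bins]
    n_cond_levels = range(0, len(calls.condition_ids) + 1)
    hist = pd.DataFrame(0, index=list(n_cond_levels), columns=labels)
    for _, row in per_strain.iterrows():
        nf = int(row["n_features"])
        if nf == 0:
            label = "0"
        else:
            label = next(
                _bin_label(lo, hi) for lo, hi in feature_bins if lo <= nf <= hi
            )
        hist.loc[int(row["n_conditions"]), label] += 1
    hist.index.name = "n_conditions"
    return BreadthSummary(per_strain=per_strain, histogram=hist)


def venn_partition(calls: DeviationCalls) -> dict[tuple[str, ...], int]:
    """Assign each deviating strain to the subset of conditions where it deviates.

    Strains with zero deviations are excluded; subsets are disjoint by
    construction so counts sum to the number of deviating strains.  Keys are
    condition tuples in the table's canonical condition order.
    """
    dev = calls.deviating
    order = calls.condition_ids
    by_cond = dev.T.groupby(level="condition").any().T.reindex(columns=order)
    partition: dict[tuple[str, ...], int] = {}
    for _, row in by_cond.iterrows():
        subset = tuple(c for c in order if row[c])
        if not subset:
            continue
        partition[subset] = partition.get(subset, 0) + 1
    return partition


def detect_nutrient_independent_outliers(
    scores: ScoreMatrix,
    primary: float = 3.0,
    secondary: float = 1.5,
    same_sign: bool = True,
    min_conditions: int = 3,
) -> OutlierScan:
    """Find (strain, feature) pairs deviating consistently across conditions.

    A pair qualifies when sign*s > primary in at least one evaluated
    (non-missing) condition and sign*s > secondary in every other evaluated
    condition, for a single sign.  With ``same_sign=False`` the magnitude
    rule |s| is used instead and the record's sign is that of the strongest
    score.  Pairs evaluated in fewer than ``min_conditions`` conditions are
    skipped (counted, not recorded) — this guards features undefined in one
    condition against single-condition "nutrient-independent" calls.
    """
    if not (primary > secondary > 0):
        raise ValueError("need primary > secondary > 0")
    arr = scores.as_array()  # strains x conditions x features
    strains = scores.strain_ids
    conditions = scores.condition_ids
    features = scores.feature_ids
    valid = ~np.isnan(arr)
    n_eval = valid.sum(axis=1)  # strains x features
    enough = n_eval >= min_conditions
    n_skipped = int((~enough & (n_eval > 0)).sum())

    with np.errstate(invalid="ignore"):
        if same_sign:
            pos_min = np.where(valid, arr, np.inf).min(axis=1)
            pos_max = np.where(valid, arr, -np.inf).max(axis=1)
            neg_min = np.where(valid, -arr, np.inf).min(axis=1)
            neg_max = np.where(valid, -arr, -np.inf).max(axis=1)
            pos_hit = (pos_max > primary) & (pos_min > secondary)
            neg_hit = (neg_max > primary) & (neg_min > secondary)
        else:
            mag = np.abs(arr)
            mag_min = np.where(valid, mag, np.inf).min(axis=1)
            mag_max = np.where(valid, mag, -np.inf).max(axis=1)
            hit = (mag_max > primary) & (mag_min > secondary)
            strongest = np.nanargmax(np.where(valid, mag, -np.inf), axis=1)
            sign_of_max = np.sign(
                np.take_along_axis(arr, strongest[:, None, :], axis=1).squeeze(1)
            )
            pos_hit = hit & (sign_of_max > 0)
            neg_hit = hit & (sign_of_max < 0)

    records: list[OutlierRecord] = []
    for si, fi in zip(*np.nonzero(enough & (pos_hit | neg_hit))):
        sign = 1 if pos_hit[si, fi] else -1
        records.append(
            OutlierRecord(
                strain=strains[si],
                feature=features[fi],
                sign=sign,
                scores_by_condition={
                    conditions[ci]: float(arr[si, ci, fi]) for ci in range(len(conditions))
                },
                conditions_evaluated=int(n_eval[si, fi]),
            )
        )
    log.info(
        "nutrient-independent outliers: %d records, %d pairs skipped (<%d conditions)",
        len(records), n_skipped, min_conditions,
    )
    return OutlierScan(
        records=records, n_skipped=n_skipped, primary=primary,
        secondary=secondary, same_sign=same_sign, min_conditions=min_conditions,
    )


def verify_outlier(record: OutlierRecord, scan: OutlierScan) -> bool:
    """Replay one record's defining inequality against its stored scores."""
    s = np.array([v for v in record.scores_by_condition.values() if not np.isnan(v)])
    if len(s) < scan.min_conditions or len(s) != record.conditions_evaluated:
        return False
    signed = record.sign * s
    if scan.same_sign:
        return bool(signed.max() > scan.primary and signed.min() > scan.secondary)
    mag = np.abs(s)
    return bool(mag.max() > scan.primary and mag.min() > scan.secondary)


def outlier_counts(
    scan: OutlierScan,
    strain_bins: Sequence[tuple[int, int]] = DEFAULT_STRAIN_BINS,
) -> OutlierCounts:
    """Tally outliers per feature and per strain, with a binned strain histogram."""
    per_feature: dict[str, int] = {}
    per_strain: dict[str, int] = {}
    for rec in scan.records:
        per_feature[rec.feature] = per_feature.get(rec.feature, 0) + 1
        per_strain[rec.strain] = per_strain.get(rec.strain, 0) + 1
    feat_s = pd.Series(per_feature, dtype=int).sort_values(ascending=False)
    strain_s = pd.Series(per_strain, dtype=int).sort_values(ascending=False)
    labels = [_bin_label(lo, hi) for lo, hi in strain_bins]
    hist = pd.Series(0, index=labels)
    for n in per_strain.values():
        for (lo, hi), label in zip(strain_bins, labels):
            if lo <= n <= hi:
                hist[label] += 1
                break
    return OutlierCounts(per_feature=feat_s, per_strain=strain_s, per_strain_histogram=hist)


def cross_condition_robustness(
    scores: ScoreMatrix,
    calls: DeviationCalls,
    method: str = "spearman",
    min_strains: int = 3,
) -> RobustnessMatrix:
    """Feature-averaged score correlations between condition pairs.

    For each feature, only strains deviating for that feature in at least one
    condition enter the correlation; condition pairs with fewer than
    ``min_strains`` qualifying strains (after dropping missing scores) are
    excluded from the feature's contribution.  The per-pair average over
    contributing features forms a symmetric matrix with unit diagonal.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    arr = scores.as_array()
    dev = calls.deviating.to_numpy().reshape(arr.shape)
    conditions = scores.condition_ids
    features = scores.feature_ids
    rows = []
    for fi, feat in enumerate(features):
        qualifying = dev[:, :, fi].any(axis=1)
        if qualifying.sum() < min_strains:
            continue
        sub = arr[qualifying, :, fi]  # strains x conditions
        for a, b in itertools.combinations(range(len(conditions)), 2):
            pairwise = ~np.isnan(sub[:, a]) & ~np.isnan(sub[:, b])
            n = int(pairwise.sum())
            if n < min_strains:
                continue
            x, y = sub[pairwise, a], sub[pairwise, b]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            if method == "spearman":
                corr = stats.spearmanr(x, y).statistic
            else:
                corr = stats.pearsonr(x, y).statistic
            if np.isnan(corr):
                continue
            rows.append(
                {"feature": feat, "condition_a": conditions[a],
                 "condition_b": conditions[b], "corr": float(corr), "n_strains": n}
            )
    per_feature = pd.DataFrame(
        rows, columns=["feature", "condition_a", "condition_b", "corr", "n_strains"]
    )
    pair_means = pd.DataFrame(np.eye(len(conditions)), index=conditions, columns=conditions)
    if len(per_feature):
        means = per_feature.groupby(["condition_a", "condition_b"])["corr"].mean()
        for (a, b), v in means.items():
            pair_means.loc[a, b] = v
            pair_means.loc[b, a] = v
    return RobustnessMatrix(pair_means=pair_means, per_feature=per_feature, method=method)
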