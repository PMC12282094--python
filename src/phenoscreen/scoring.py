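"""Robust deviation scoring of mutant feature values against parent replicates.

A mutant's measurement for a feature in a condition is expressed as a
normalized score

    s = 1.35 * (value - median(parent)) / iqr(parent)

where the median and interquartile range come from the parent-strain replicate
distribution for the same (condition, feature).  Because the IQR of a normal
distribution is 1.35 times its standard deviation, s reads as "standard
deviations from the parent median" while staying robust to outlying parent
replicates.  Cells with |s| >= 3 are called deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .feature_table import FeatureTable, ParentReference

log = logging.getLogger(__name__)

#: Normal-distribution IQR/SD ratio used to put robust scores on an SD scale.
SCORE_SCALE = 1.35

#: Default quantile interpolation convention for the IQR (numpy method name).
DEFAULT_QUANTILE_RULE = "linear"

DEFAULT_THRESHOLD = 3.0


class DegenerateReferenceError(ValueError):
    """Parent replicate vector has zero interquartile range."""


@dataclass
class ScoreMatrix:
    """Normalized scores per (strain, condition, feature).

    ``scores`` mirrors the FeatureTable layout (strains x condition-major
    (condition, feature) columns); NaN marks cells where the input value or
    the parent reference is missing/undefined, including zero-IQR references.
    ``quantile_rule`` records the IQR convention for provenance.
    """

    scores: pd.DataFrame
    threshold_primary: float = DEFAULT_THRESHOLD
    quantile_rule: str = DEFAULT_QUANTILE_RULE

    @property
    def strain_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(pd.unique(self.scores.columns.get_level_values("condition")))

    @property
    def feature_ids(self) -> list[str]:
        return list(pd.unique(self.scores.columns.get_level_values("feature")))

    def as_array(self) -> np.ndarray:
        """Scores as (n_strains, n_conditions, n_features)."""
        return self.scores.to_numpy().reshape(
            len(self.scores), len(self.condition_ids), len(self.feature_ids)
        )


@dataclass
class DeviationCalls:
    """Boolean deviation mask: |s| >= threshold and s not missing."""

    deviating: pd.DataFrame
    threshold: float

    @property
    def condition_ids(self) -> list[str]:
        return list(pd.unique(self.deviating.columns.get_level_values("condition")))

    @property
    def feature_ids(self) -> list[str]:
        return list(pd.unique(self.deviating.columns.get_level_values("feature")))


def parent_location_scale(
    parent_values: np.ndarray, quantile_rule: str = DEFAULT_QUANTILE_RULE
) -> tuple[float, float]:
    """Median and IQR of a parent replicate vector under the given quantile rule."""
    pv = np.asarray(parent_values, dtype=float)
    q1, med, q3 = np.quantile(pv, [0.25, 0.5, 0.75], method=quantile_rule)
    return float(med), float(q3 - q1)


def compute_score(
    value: float,
    parent_values: np.ndarray,
    quantile_rule: str = DEFAULT_QUANTILE_RULE,
) -> float:
    """Score one value against a parent replicate vector.

    Raises
    ------
    DegenerateReferenceError
        If the parent IQR is zero (callers convert to MISSING + warning).
    """
    med, iqr = parent_location_scale(parent_values, quantile_rule)
    if iqr == 0:
        raise DegenerateReferenceError("parent replicate vector has zero IQR")
    return SCORE_SCALE * (float(value) - med) / iqr


def score_table(
    table: FeatureTable,
    ref: ParentReference,
    quantile_rule: str = DEFAULT_QUANTILE_RULE,
    threshold_primary: float = DEFAULT_THRESHOLD,
) -> ScoreMatrix:
    """Score every cell of a feature table against the parent reference.

    Missing propagation: undefined (condition, feature) pairs, absent parent
    references, and zero-IQR references all yield MISSING scores (the latter
    two with a logged warning), never infinities.
    """
    out = pd.DataFrame(
        np.nan, index=table.values.index, columns=table.values.columns
    )
    n_absent = n_zero_iqr = 0
    for cond, feat in table.values.columns:
        if not table.feature_defined.loc[cond, feat]:
            continue
        pv = ref.get(cond, feat)
        if pv is None:
            n_absent += 1
            continue
        med, iqr = parent_location_scale(pv, quantile_rule)
        if iqr == 0:
            n_zero_iqr += 1
            continue
        out[(cond, feat)] = SCORE_SCALE * (table.values[(cond, feat)] - med) / iqr
    if n_absent:
        log.warning("%d (condition, feature) pairs lacked a parent reference", n_absent)
    if n_zero_iqr:
        log.warning("%d parent references had zero IQR; scores set MISSING", n_zero_iqr)
    scores = ScoreMatrix(
        scores=out, threshold_primary=threshold_primary, quantile_rule=quantile_rule
    )
    summary = (
        (out.abs() >= threshold_primary).T.groupby(level="condition").sum().T.sum(axis=0)
    )
    log.info("deviating cells (|s| >= %g) per condition: %s", threshold_primary, summary.to_dict())
    return scores


def call_deviations(scores: ScoreMatrix, threshold: float = DEFAULT_THRESHOLD) -> DeviationCalls:
    """Inclusive threshold call: deviating iff |s| >= threshold; MISSING never deviates."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    mask = scores.scores.abs() >= threshold
    mask &= scores.scores.notna()
    return DeviationCalls(deviating=mask, threshold=threshold)
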