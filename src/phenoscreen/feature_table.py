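"""Data model and I/O for screen feature tables and parent references.

The screen measures population-averaged cellular features for a library of
deletion strains across several nutrient conditions.  The canonical on-disk
representation is a long-format delimited text file with columns
``strain, condition, feature, value``; in memory a table is a single wide
:class:`pandas.DataFrame` whose rows are strains and whose columns form a
condition-major ``(condition, feature)`` MultiIndex.  Missing measurements
(strain not sampled in a condition, feature not determined, unparseable cell)
are NaN.

The parent (wild-type) strain is measured many times per condition; its
replicate vectors per ``(condition, feature)`` are the normalisation baseline
for deviation scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Cell contents treated as MISSING on read (case-insensitive, whitespace-stripped).
#: "ND" mirrors the screen's not-determined marker for features that cannot be
#: measured in a condition (e.g. replication timing under overlapping rounds).
DEFAULT_MISSING_SENTINELS = ("", "na", "nan", "nd")

LONG_COLUMNS = ("strain", "condition", "feature", "value")

#: Separator for the wide (read-only) layout: columns named "<feature>@<condition>".
WIDE_SEP = "@"


class DuplicateRecordError(ValueError):
    """A (strain, condition, feature) triple occurs more than once in a file."""


class UnknownConditionError(ValueError):
    """A condition label is not in the configured whitelist."""


def _unique_in_order(values: Iterable[str]) -> list[str]:
    return list(pd.unique(pd.Series(list(values))))


@dataclass
class FeatureTable:
    """Per-(strain, condition, feature) population-average values.

    Parameters
    ----------
    values
        Wide frame: index = strain ids, columns = MultiIndex
        ``(condition, feature)`` in condition-major order, NaN = missing.
    feature_defined
        Boolean frame, index = conditions, columns = features; False marks
        features not determined in a condition (all values NaN there).
    """

    values: pd.DataFrame
    feature_defined: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        cols = self.values.columns
        if cols.nlevels != 2:
            raise ValueError("values must have (condition, feature) MultiIndex columns")
        cols = cols.set_names(["condition", "feature"])
        self.values = self.values.copy()
        self.values.columns = cols
        self.values.index.name = "strain"
        conditions = _unique_in_order(cols.get_level_values("condition"))
        features = _unique_in_order(cols.get_level_values("feature"))
        if len(set(conditions)) != len(conditions) or len(set(features)) != len(features):
            raise ValueError("duplicate condition or feature labels")
        # normalise to the full (condition x feature) grid, condition-major
        full = pd.MultiIndex.from_product([conditions, features], names=["condition", "feature"])
        self.values = self.values.reindex(columns=full)
        if self.feature_defined is None:
            defined = self.values.notna().any(axis=0).unstack("feature")
            self.feature_defined = defined.reindex(index=conditions, columns=features)
        else:
            self.feature_defined = self.feature_defined.reindex(
                index=conditions, columns=features, fill_value=False
            ).astype(bool)
        # enforce: undefined (condition, feature) pairs carry no values
        for cond in conditions:
            undef = [f for f in features if not self.feature_defined.loc[cond, f]]
            if undef:
                self.values.loc[:, [(cond, f) for f in undef]] = np.nan

    # -- accessors ---------------------------------------------------------

    @property
    def strain_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def condition_ids(self) -> list[str]:
        return _unique_in_order(self.values.columns.get_level_values("condition"))

    @property
    def feature_ids(self) -> list[str]:
        return _unique_in_order(self.values.columns.get_level_values("feature"))

    def value(self, strain: str, condition: str, feature: str) -> float:
        return float(self.values.at[strain, (condition, feature)])

    def n_missing_by_condition(self) -> pd.Series:
        return self.values.isna().T.groupby(level="condition").sum().T.sum(axis=0)

    def sampled_conditions(self, strain: str) -> list[str]:
        """Conditions in which the strain has at least one measurement."""
        row = self.values.loc[strain]
        present = row.notna().groupby(level="condition").any()
        return [c for c in self.condition_ids if present.get(c, False)]

    def to_long(self) -> pd.DataFrame:
        long = self.values.stack(["condition", "feature"], future_stack=True).rename("value")
        return long.reset_index()[list(LONG_COLUMNS)]


@dataclass
class ParentReference:
    """Parent-strain replicate values per (condition, feature).

    The study design calls for at least ``min_replicates`` (default 115)
    independent parent replicates in every condition; fewer is flagged by
    :func:`validate_parent_reference`, not rejected outright.
    """

    replicates: dict[tuple[str, str], np.ndarray]
    min_replicates: int = 115

    def __post_init__(self) -> None:
        clean: dict[tuple[str, str], np.ndarray] = {}
        for key, vec in self.replicates.items():
            arr = np.asarray(vec, dtype=float)
            if np.isnan(arr).any():
                raise ValueError(f"parent replicates for {key} contain missing values")
            clean[tuple(key)] = arr
        self.replicates = clean

    def get(self, condition: str, feature: str) -> np.ndarray | None:
        return self.replicates.get((condition, feature))

    def conditions(self) -> list[str]:
        return _unique_in_order(k[0] for k in self.replicates)

    def features(self) -> list[str]:
        return _unique_in_order(k[1] for k in self.replicates)


@dataclass
class CVSpec:
    """Coefficient-of-variation feature augmentation plan.

    Each triple ``(mean_feature, sd_feature, cv_feature)`` derives a new
    feature cv = sd/mean, the population-variability readout for one cellular
    property.
    """

    triples: Sequence[tuple[str, str, str]]

    def validate(self, feature_ids: Sequence[str]) -> None:
        have = set(feature_ids)
        for mean_id, sd_id, cv_id in self.triples:
            if mean_id not in have:
                raise ValueError(f"CV spec references unknown mean feature {mean_id!r}")
            if sd_id not in have:
                raise ValueError(f"CV spec references unknown sd feature {sd_id!r}")
            if cv_id in have:
                raise ValueError(f"CV feature {cv_id!r} already present in the table")
        cv_ids = [t[2] for t in self.triples]
        if len(set(cv_ids)) != len(cv_ids):
            raise ValueError("duplicate cv feature ids in CV spec")


@dataclass
class ParentValidationReport:
    """Report-only validation of a parent reference against a feature table."""

    low_replicates: list[tuple[str, str, int]] = field(default_factory=list)
    zero_iqr: list[tuple[str, str]] = field(default_factory=list)
    absent: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.low_replicates or self.zero_iqr or self.absent)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _coerce_values(raw: pd.Series, missing_sentinels: Sequence[str]) -> pd.Series:
    sentinels = {s.strip().lower() for s in missing_sentinels}
    txt = raw.astype("string").str.strip()
    is_sentinel = txt.isna() | txt.str.lower().isin(sentinels)
    def parse(x):
        try:
            return float(x)
        except (TypeError, ValueError):
            return np.nan

    out = txt.mask(is_sentinel).map(parse, na_action="ignore").astype("Float64")
    n_unparseable = int((out.isna() & ~is_sentinel).sum())
    if n_unparseable:
        log.warning("%d unparseable numeric cells coerced to MISSING", n_unparseable)
    return out.astype(float)


def _long_from_wide(df: pd.DataFrame) -> pd.DataFrame:
    strain_col = df.columns[0]
    records = df.melt(id_vars=[strain_col], var_name="_col", value_name="value")
    parts = records["_col"].str.split(WIDE_SEP, n=1, expand=True)
    if parts.shape[1] != 2 or parts.isna().any().any():
        raise ValueError(
            f"wide layout requires columns named '<feature>{WIDE_SEP}<condition>'"
        )
    records["feature"] = parts[0]
    records["condition"] = parts[1]
    records["strain"] = records[strain_col]
    return records[list(LONG_COLUMNS)]


def read_feature_table(
    path: str | Path,
    *,
    delimiter: str = "\t",
    layout: str = "long",
    missing_sentinels: Sequence[str] = DEFAULT_MISSING_SENTINELS,
    condition_whitelist: Sequence[str] | None = None,
    condition_order: Sequence[str] | None = None,
) -> FeatureTable:
    """Read a delimited feature table (long format canonical, wide read-only).

    Empty cells and the configured sentinels ("NA", "ND", ...) become MISSING;
    unparseable numeric cells are coerced to MISSING with a logged warning.
    Duplicate (strain, condition, feature) triples are a hard error.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if layout == "wide":
        df = _long_from_wide(df)
    missing_cols = [c for c in LONG_COLUMNS[:3] if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing required columns: {missing_cols}")
    dup = df.duplicated(subset=["strain", "condition", "feature"], keep=False)
    if dup.any():
        first = df.loc[dup, ["strain", "condition", "feature"]].iloc[0]
        raise DuplicateRecordError(
            f"duplicate record for (strain={first['strain']!r}, "
            f"condition={first['condition']!r}, feature={first['feature']!r})"
        )
    if condition_whitelist is not None:
        unknown = sorted(set(df["condition"]) - set(condition_whitelist))
        if unknown:
            raise UnknownConditionError(f"unknown condition labels: {unknown}")
    df = df.assign(value=_coerce_values(df["value"], missing_sentinels))

    conditions = list(condition_order) if condition_order else _unique_in_order(df["condition"])
    features = _unique_in_order(df["feature"])
    strains = _unique_in_order(df["strain"])
    wide = df.pivot(index="strain", columns=["condition", "feature"], values="value")
    wide = wide.reindex(
        index=strains,
        columns=pd.MultiIndex.from_product([conditions, features], names=["condition", "feature"]),
    )
    table = FeatureTable(values=wide)
    report = table.values.isna().T.groupby(level="condition").sum().T.sum(axis=0)
    log.info("read %d strains x %d conditions x %d features from %s; missing per condition: %s",
             len(strains), len(conditions), len(features), path, report.to_dict())
    return table


def write_feature_table(
    table: FeatureTable, path: str | Path, *, delimiter: str = "\t", missing: str = "NA"
) -> None:
    """Write long-format text; finite values round-trip bit-exactly."""
    long = table.to_long()
    long.to_csv(path, sep=delimiter, index=False, na_rep=missing)


def read_parent_reference(
    path: str | Path,
    *,
    delimiter: str = "\t",
    min_replicates: int = 115,
) -> ParentReference:
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    required = {"condition", "feature", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"parent reference file must have columns {sorted(required)}")
    replicates = {
        (cond, feat): grp["value"].to_numpy(dtype=float)
        for (cond, feat), grp in df.groupby(["condition", "feature"], sort=False)
    }
    return ParentReference(replicates=replicates, min_replicates=min_replicates)


def write_parent_reference(
    ref: ParentReference, path: str | Path, *, delimiter: str = "\t"
) -> None:
    rows = [
        {"condition": cond, "feature": feat, "replicate": i, "value": v}
        for (cond, feat), vec in ref.replicates.items()
        for i, v in enumerate(vec)
    ]
    pd.DataFrame(rows, columns=["condition", "feature", "replicate", "value"]).to_csv(
        path, sep=delimiter, index=False
    )


# ---------------------------------------------------------------------------
# CV augmentation
# ---------------------------------------------------------------------------

def augment_cv_features(
    table: FeatureTable, spec: CVSpec, *, epsilon: float = 1e-9
) -> FeatureTable:
    """Extend a table with coefficient-of-variation features (cv = sd / mean).

    The cv cell is MISSING when either input is MISSING or when
    ``|mean| < epsilon`` (degenerate denominator; warned, not fatal).
    Pre-existing cells are never modified.
    """
    spec.validate(table.feature_ids)
    conditions = table.condition_ids
    new_cols: dict[tuple[str, str], pd.Series] = {}
    defined = table.feature_defined.copy()
    n_degenerate = 0
    for mean_id, sd_id, cv_id in spec.triples:
        for cond in conditions:
            both_defined = bool(defined.loc[cond, mean_id] and defined.loc[cond, sd_id])
            if both_defined:
                mean = table.values[(cond, mean_id)]
                sd = table.values[(cond, sd_id)]
                small = mean.abs() < epsilon
                n_degenerate += int((small & sd.notna() & mean.notna()).sum())
                cv = sd / mean.mask(small)
            else:
                cv = pd.Series(np.nan, index=table.values.index)
            new_cols[(cond, cv_id)] = cv
            defined.loc[cond, cv_id] = both_defined
    if n_degenerate:
        log.warning("%d cv cells set MISSING: |mean| below epsilon=%g", n_degenerate, epsilon)
    extra = pd.DataFrame(new_cols, index=table.values.index)
    extra.columns = pd.MultiIndex.from_tuples(extra.columns, names=["condition", "feature"])
    values = pd.concat([table.values, extra], axis=1)
    features = table.feature_ids + [t[2] for t in spec.triples]
    values = values.reindex(
        columns=pd.MultiIndex.from_product([conditions, features], names=["condition", "feature"])
    )
    return FeatureTable(values=values, feature_defined=defined)


def augment_cv_reference(
    ref: ParentReference, spec: CVSpec, *, epsilon: float = 1e-9
) -> ParentReference:
    """Derive parent replicate vectors for CV features.

    Each parent replicate is itself a population average, so its CV replicate
    is the per-replicate quotient sd_rep / mean_rep; CV features are then
    scored against these replicate CVs like any other feature.
    """
    replicates = dict(ref.replicates)
    for mean_id, sd_id, cv_id in spec.triples:
        for cond in ref.conditions():
            mean = ref.get(cond, mean_id)
            sd = ref.get(cond, sd_id)
            if mean is None or sd is None:
                continue
            if np.any(np.abs(mean) < epsilon):
                log.warning("skipping cv reference (%s, %s): near-zero parent means", cond, cv_id)
                continue
            replicates[(cond, cv_id)] = sd / mean
    return ParentReference(replicates=replicates, min_replicates=ref.min_replicates)


def validate_parent_reference(
    ref: ParentReference, table: FeatureTable
) -> ParentValidationReport:
    """Report (never raise) deficiencies of a parent reference for a table."""
    report = ParentValidationReport()
    for cond in table.condition_ids:
        for feat in table.feature_ids:
            if not table.feature_defined.loc[cond, feat]:
                continue
            vec = ref.get(cond, feat)
            if vec is None:
                report.absent.append((cond, feat))
                continue
            if len(vec) < ref.min_replicates:
                report.low_replicates.append((cond, feat, len(vec)))
            q1, q3 = np.quantile(vec, [0.25, 0.75])
            if q3 - q1 == 0:
                report.zero_iqr.append((cond, feat))
    return report
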