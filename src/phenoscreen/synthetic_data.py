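"""Synthetic screen generator with planted ground truth.

Emulates the statistical structure the analysis assumes: a library of ~800
deletion strains measured across four nutrient conditions for 96 population-
average features (77 base features plus 19 derived coefficients of variation),
against a parent reference of >= 115 replicates per condition.  Per
(condition, feature) the parent is Normal(mu, sigma); null strains draw each
cell from the parent distribution, so their normalized scores are calibrated
to ~N(0, 1).  On top of that the generator plants, with a full manifest:

* same-sign multi-condition outliers (per-condition effect sizes in parent-SD
  units) — the recoverable nutrient-independent phenotypes;
* strain modules sharing a latent effect vector, scaled so that the expected
  phenoprint correlation hits a target rho (negative loadings give negative
  edges);
* pleiotropic strains with many features shifted consistently across
  conditions;
* missing conditions for a fraction of (null) strains and features not
  determined in one condition.

Features are conditionally independent given planted effects; the generator
does not attempt to emulate the unknown covariance structure of real image
features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_table import (
    CVSpec,
    FeatureTable,
    ParentReference,
    augment_cv_features,
    augment_cv_reference,
    read_feature_table,
    read_parent_reference,
    write_feature_table,
    write_parent_reference,
)

log = logging.getLogger(__name__)

#: The study's four M9-based nutrient conditions, poorest to richest.
DEFAULT_CONDITIONS = ("M9Lala", "M9gly", "M9glu", "M9LaraCAAT")

#: Cellular properties measured as population mean + SD, each contributing a
#: derived CV feature (19 properties -> 57 of the 96 features).
PROPERTIES = (
    "cell_length", "cell_width", "cell_area", "cell_volume", "surface_area",
    "aspect_ratio", "perimeter", "circularity", "nucleoid_length",
    "nucleoid_area", "nucleoid_cell_ratio", "nucleoid_number",
    "ftsz_intensity", "ftsz_ring_diameter", "seqa_focus_count",
    "constriction_degree", "septum_position", "dna_content", "elongation_rate",
)

#: Single-valued features (39, completing 77 base features).  The four
#: replication-timing features cannot be determined under overlapping
#: replication rounds and default to not-determined in the richest condition.
REPLICATION_TIMING_FEATURES = (
    "repC_timing", "repC_timing_abs", "repD_timing", "repD_timing_abs",
)
SINGLE_FEATURES = REPLICATION_TIMING_FEATURES + (
    "growth_rate", "doubling_time", "division_length", "birth_length",
    "initiation_length", "ftsz_ring_position", "ftsz_ring_count",
    "ftsz_assembly_timing", "ftsz_disassembly_timing", "ftsz_total_intensity",
    "seqa_focus_intensity", "seqa_focus_spacing", "seqa_total_intensity",
    "nucleoid_splitting_timing", "nucleoid_compaction", "nucleoid_offset",
    "constriction_onset", "constriction_duration", "septum_intensity",
    "pole_age_asymmetry", "width_taper", "cell_bending",
    "phase_contrast_intensity", "cell_density", "division_symmetry",
    "replication_origins", "terminus_position", "origin_position",
    "ori_ter_ratio", "growth_lag", "area_growth_rate", "volume_growth_rate",
    "surface_to_volume", "width_at_septum", "length_width_coupling",
)

BASE_FEATURES = tuple(
    [f"{p}_mean" for p in PROPERTIES]
    + [f"{p}_sd" for p in PROPERTIES]
    + list(SINGLE_FEATURES)
)  # 77

DEFAULT_ND_FEATURES = tuple((f, "M9LaraCAAT") for f in REPLICATION_TIMING_FEATURES)

#: Features eligible for default outlier plants: plain singles, defined in all
#: conditions, not inputs to a derived CV feature.
PLANTABLE_FEATURES = tuple(f for f in SINGLE_FEATURES if f not in REPLICATION_TIMING_FEATURES)


def default_cv_spec() -> CVSpec:
    """The 19 coefficient-of-variation triples that expand 77 -> 96 features."""
    return CVSpec(triples=[(f"{p}_mean", f"{p}_sd", f"{p}_cv") for p in PROPERTIES])


def _letters(i: int) -> str:
    s = ""
    for _ in range(3):
        s = chr(ord("a") + i % 26) + s
        i //= 26
    return s


def strain_names(n: int) -> list[str]:
    """Deterministic gene-like strain ids; every third strain is y-named
    (a gene of unknown function), the rest carry ordinary gene-like names."""
    return [("y" if i % 3 == 0 else "g") + _letters(i) for i in range(n)]


# ---------------------------------------------------------------------------
# plans and spec
# ---------------------------------------------------------------------------

@dataclass
class PlantedOutlier:
    strain: str
    feature: str
    effects: tuple[float, ...]  # per-condition effect magnitudes, parent-SD units
    sign: int                   # +1 or -1


@dataclass
class ModulePlan:
    strains: tuple[str, ...]
    rho: float                  # target pairwise phenoprint correlation
    loadings: tuple[int, ...]   # +/-1 per strain; opposite signs -> negative edge


@dataclass
class PleiotropyPlan:
    strain: str
    effects: dict[str, float]   # feature -> signed effect (SD units), constant across conditions


@dataclass
class ScreenSpec:
    """Study-scale defaults: 806 strains x 4 conditions x 96 features,
    115 parent replicates, ~6% of strains missing one condition."""

    n_strains: int = 806
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_parent_replicates: int = 115
    missing_condition_fraction: float = 0.06
    nd_features: tuple[tuple[str, str], ...] = DEFAULT_ND_FEATURES
    outlier_plan: tuple[PlantedOutlier, ...] = ()
    module_plan: tuple[ModulePlan, ...] = ()
    pleiotropy_plan: tuple[PleiotropyPlan, ...] = ()
    parent_mean_range: tuple[float, float] = (5.0, 50.0)
    parent_cv_range: tuple[float, float] = (0.05, 0.2)
    parent_sd_override: float | None = None  # constant parent SD (0 allowed, for degenerate tests)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_condition_fraction <= 1.0:
            raise ValueError("missing_condition_fraction must be in [0, 1]")
        for plan in self.outlier_plan:
            if len(plan.effects) != len(self.conditions):
                raise ValueError(f"outlier plan for {plan.strain}: wrong effect count")
            if not all(math.isfinite(e) for e in plan.effects):
                raise ValueError("effect sizes must be finite")

    @property
    def strains(self) -> list[str]:
        return strain_names(self.n_strains)


@dataclass
class GroundTruth:
    """Manifest of everything planted, for parameter-recovery testing."""

    planted_outliers: set[tuple[str, str, int]]
    planted_edges: set[tuple[str, str, int]]
    null_strains: set[str]
    pleiotropic: dict[str, set[tuple[str, int]]] = field(default_factory=dict)


def default_screen_spec(seed: int = 0, n_strains: int = 806) -> ScreenSpec:
    """The default synthetic study: 100 nutrient-independent outlier plants at
    effects (4.5, 2.5, 2.5, 2.5) sigma (primary condition randomized), ten
    two-strain modules at target rho 0.9 (five negative), and five pleiotropic
    strains with 45 consistently shifted features each.  For smaller
    libraries the plan counts scale down proportionally."""
    rng = np.random.default_rng([seed, 7])
    names = strain_names(n_strains)
    n_out = min(100, n_strains // 8)
    n_mod = min(10, n_strains // 40)
    n_pleio = min(5, max(n_strains // 160, 0))
    outlier_strains = names[:n_out]
    module_strains = names[n_out:n_out + 2 * n_mod]
    pleio_strains = names[n_out + 2 * n_mod:n_out + 2 * n_mod + n_pleio]

    outliers = []
    for i, strain in enumerate(outlier_strains):
        feature = PLANTABLE_FEATURES[int(rng.integers(len(PLANTABLE_FEATURES)))]
        effects = [2.5, 2.5, 2.5, 2.5]
        effects[int(rng.integers(4))] = 4.5
        outliers.append(
            PlantedOutlier(strain=strain, feature=feature,
                           effects=tuple(effects), sign=1 if i % 2 == 0 else -1)
        )

    modules = []
    for m in range(n_mod):
        pair = tuple(module_strains[2 * m: 2 * m + 2])
        loadings = (1, 1) if m < (n_mod + 1) // 2 else (1, -1)
        modules.append(ModulePlan(strains=pair, rho=0.9, loadings=loadings))

    pleiotropy = []
    for strain in pleio_strains:
        feats = rng.choice(len(BASE_FEATURES), size=45, replace=False)
        effects = {
            BASE_FEATURES[f]: float(rng.choice([-1, 1]) * rng.uniform(3.5, 6.0))
            for f in feats
        }
        pleiotropy.append(PleiotropyPlan(strain=strain, effects=effects))

    return ScreenSpec(
        n_strains=n_strains,
        outlier_plan=tuple(outliers),
        module_plan=tuple(modules),
        pleiotropy_plan=tuple(pleiotropy),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _parent_params(spec: ScreenSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per (condition, base feature) parent mean and SD, derived from the seed."""
    rng = np.random.default_rng([spec.seed, 1])
    n_feat = len(BASE_FEATURES)
    n_cond = len(spec.conditions)
    lo, hi = spec.parent_mean_range
    base_mu = rng.uniform(lo, hi, size=n_feat)
    cond_factor = rng.uniform(0.7, 1.3, size=(n_cond, n_feat))
    mu = base_mu[None, :] * cond_factor
    cv_lo, cv_hi = spec.parent_cv_range
    sigma = mu * rng.uniform(cv_lo, cv_hi, size=n_feat)[None, :]
    if spec.parent_sd_override is not None:
        sigma = np.full_like(sigma, float(spec.parent_sd_override))
    return mu, sigma


def _nd_mask(spec: ScreenSpec) -> np.ndarray:
    """(condition, base feature) boolean: True where not determined."""
    nd = np.zeros((len(spec.conditions), len(BASE_FEATURES)), dtype=bool)
    for feat, cond in spec.nd_features:
        if cond not in spec.conditions or feat not in BASE_FEATURES:
            raise ValueError(f"nd feature ({feat}, {cond}) not in the screen")
        nd[spec.conditions.index(cond), BASE_FEATURES.index(feat)] = True
    return nd


def generate_parent_reference(spec: ScreenSpec) -> ParentReference:
    """Draw parent replicates per (condition, feature) and derive CV replicates."""
    mu, sigma = _parent_params(spec)
    nd = _nd_mask(spec)
    rng = np.random.default_rng([spec.seed, 2])
    draws = mu[:, :, None] + sigma[:, :, None] * rng.standard_normal(
        (len(spec.conditions), len(BASE_FEATURES), spec.n_parent_replicates)
    )
    replicates = {
        (cond, feat): draws[ci, fi]
        for ci, cond in enumerate(spec.conditions)
        for fi, feat in enumerate(BASE_FEATURES)
        if not nd[ci, fi]
    }
    ref = ParentReference(replicates=replicates, min_replicates=spec.n_parent_replicates)
    return augment_cv_reference(ref, default_cv_spec())


def _effect_array(spec: ScreenSpec) -> tuple[np.ndarray, GroundTruth]:
    """Planted effects in parent-SD units, shape (strains, conditions, base features)."""
    strains = spec.strains
    index = {s: i for i, s in enumerate(strains)}
    feat_index = {f: i for i, f in enumerate(BASE_FEATURES)}
    eff = np.zeros((len(strains), len(spec.conditions), len(BASE_FEATURES)))
    planted: set[str] = set()

    planted_outliers = set()
    for plan in spec.outlier_plan:
        if plan.strain not in index:
            raise ValueError(f"outlier plan references unknown strain {plan.strain!r}")
        if plan.feature not in feat_index:
            raise ValueError(f"outlier plan references unknown feature {plan.feature!r}")
        si, fi = index[plan.strain], feat_index[plan.feature]
        eff[si, :, fi] += plan.sign * np.asarray(plan.effects)
        planted_outliers.add((plan.strain, plan.feature, plan.sign))
        planted.add(plan.strain)

    rng = np.random.default_rng([spec.seed, 4])
    planted_edges = set()
    for plan in spec.module_plan:
        if not 0.0 < plan.rho < 1.0:
            raise ValueError("module rho must be in (0, 1)")
        if len(plan.loadings) != len(plan.strains):
            raise ValueError("module loadings must match member count")
        amp = math.sqrt(plan.rho / (1.0 - plan.rho))
        latent = amp * rng.standard_normal((len(spec.conditions), len(BASE_FEATURES)))
        for strain, loading in zip(plan.strains, plan.loadings):
            if strain not in index:
                raise ValueError(f"module plan references unknown strain {strain!r}")
            eff[index[strain]] += loading * latent
            planted.add(strain)
        for a in range(len(plan.strains)):
            for b in range(a + 1, len(plan.strains)):
                sign = plan.loadings[a] * plan.loadings[b]
                planted_edges.add((plan.strains[a], plan.strains[b], sign))

    pleiotropic: dict[str, set[tuple[str, int]]] = {}
    for plan in spec.pleiotropy_plan:
        if plan.strain not in index:
            raise ValueError(f"pleiotropy plan references unknown strain {plan.strain!r}")
        entries = set()
        for feat, effect in plan.effects.items():
            if feat not in feat_index:
                raise ValueError(f"pleiotropy plan references unknown feature {feat!r}")
            eff[index[plan.strain], :, feat_index[feat]] += effect
            entries.add((feat, 1 if effect > 0 else -1))
        pleiotropic[plan.strain] = entries
        planted.add(plan.strain)

    truth = GroundTruth(
        planted_outliers=planted_outliers,
        planted_edges=planted_edges,
        null_strains=set(strains) - planted,
        pleiotropic=pleiotropic,
    )
    return eff, truth


def generate_mutant_library(spec: ScreenSpec) -> tuple[FeatureTable, GroundTruth]:
    """Generate the mutant feature table (96 features incl. CVs) + ground truth.

    Null strains draw every cell from the parent distribution; planted cells
    add effect x parent_SD on top of the draw.  Missing conditions are
    assigned among null strains (so planted structures remain evaluable);
    not-determined features are blanked for all strains.
    """
    mu, sigma = _parent_params(spec)
    nd = _nd_mask(spec)
    eff, truth = _effect_array(spec)
    strains = spec.strains
    rng = np.random.default_rng([spec.seed, 3])
    z = rng.standard_normal((len(strains), len(spec.conditions), len(BASE_FEATURES)))
    values = mu[None] + sigma[None] * (z + eff)
    values[:, nd] = np.nan

    rng_miss = np.random.default_rng([spec.seed, 5])
    null_list = [s for s in strains if s in truth.null_strains]
    drop = rng_miss.random(len(null_list)) < spec.missing_condition_fraction
    which = rng_miss.integers(len(spec.conditions), size=len(null_list))
    sindex = {s: i for i, s in enumerate(strains)}
    for s, d, ci in zip(null_list, drop, which):
        if d:
            values[sindex[s], ci, :] = np.nan

    flat = values.reshape(len(strains), -1)
    columns = pd.MultiIndex.from_product(
        [list(spec.conditions), list(BASE_FEATURES)], names=["condition", "feature"]
    )
    defined = pd.DataFrame(
        ~nd, index=list(spec.conditions), columns=list(BASE_FEATURES)
    )
    table = FeatureTable(
        values=pd.DataFrame(flat, index=strains, columns=columns),
        feature_defined=defined,
    )
    table = augment_cv_features(table, default_cv_spec())
    log.info(
        "generated %d strains x %d conditions x %d features (%d planted outliers, "
        "%d planted edges, %d pleiotropic, %d null strains)",
        len(strains), len(spec.conditions), len(table.feature_ids),
        len(truth.planted_outliers), len(truth.planted_edges),
        len(truth.pleiotropic), len(truth.null_strains),
    )
    return table, truth


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

GROUND_TRUTH_COLUMNS = ("record_type", "strain", "strain_b", "feature", "sign")


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    rows = []
    for strain, feature, sign in sorted(truth.planted_outliers):
        rows.append(("planted_outlier", strain, "", feature, sign))
    for a, b, sign in sorted(truth.planted_edges):
        rows.append(("planted_edge", a, b, "", sign))
    for strain, entries in sorted(truth.pleiotropic.items()):
        for feature, sign in sorted(entries):
            rows.append(("pleiotropic_feature", strain, "", feature, sign))
    for strain in sorted(truth.null_strains):
        rows.append(("null_strain", strain, "", "", 0))
    pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    outliers, edges, null_strains = set(), set(), set()
    pleiotropic: dict[str, set[tuple[str, int]]] = {}
    for row in df.itertuples(index=False):
        if row.record_type == "planted_outlier":
            outliers.add((row.strain, row.feature, int(row.sign)))
        elif row.record_type == "planted_edge":
            edges.add((row.strain, row.strain_b, int(row.sign)))
        elif row.record_type == "pleiotropic_feature":
            pleiotropic.setdefault(row.strain, set()).add((row.feature, int(row.sign)))
        elif row.record_type == "null_strain":
            null_strains.add(row.strain)
    return GroundTruth(
        planted_outliers=outliers, planted_edges=edges,
        null_strains=null_strains, pleiotropic=pleiotropic,
    )


def write_fixture_bundle(
    table: FeatureTable, ref: ParentReference, truth: GroundTruth, dir: str | Path
) -> dict[str, Path]:
    """Serialize a complete synthetic screen to a directory of TSV files."""
    dir = Path(dir)
    dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "feature_table": dir / "feature_table.tsv",
        "parent_reference": dir / "parent_reference.tsv",
        "ground_truth": dir / "ground_truth.tsv",
    }
    write_feature_table(table, paths["feature_table"])
    write_parent_reference(ref, paths["parent_reference"])
    write_ground_truth(truth, paths["ground_truth"])
    return paths


def read_fixture_bundle(
    dir: str | Path, min_replicates: int = 115
) -> tuple[FeatureTable, ParentReference, GroundTruth]:
    dir = Path(dir)
    table = read_feature_table(dir / "feature_table.tsv")
    ref = read_parent_reference(dir / "parent_reference.tsv", min_replicates=min_replicates)
    truth = read_ground_truth(dir / "ground_truth.tsv")
    return table, ref, truth
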