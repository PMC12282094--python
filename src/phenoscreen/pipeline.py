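"""End-to-end orchestration: simulate/read -> score -> atlas -> network.

A single YAML config (sections ``io``, ``simulate``, ``scoring``,
``outliers``, ``network``) plus one top-level seed drives the full analysis;
per-stage seeds are derived deterministically from the top-level seed, so a
rerun with the same config and seed reproduces every numeric output
byte-for-byte.  Each run directory carries a provenance record (config hash,
package and library versions, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deviation_atlas import (
    cross_condition_robustness,
    detect_nutrient_independent_outliers,
    outlier_counts,
    summarize_breadth,
    venn_partition,
)
from .feature_table import (
    CVSpec,
    augment_cv_features,
    augment_cv_reference,
    read_feature_table,
    read_parent_reference,
    validate_parent_reference,
)
from .phenoprint_network import (
    assemble_phenoprints,
    empirical_thresholds,
    export_network,
    pairwise_spearman,
    permutation_null,
    significant_connections,
)
from .scoring import call_deviations, score_table
from .synthetic_data import (
    default_screen_spec,
    generate_mutant_library,
    generate_parent_reference,
    write_fixture_bundle,
)

log = logging.getLogger(__name__)

DEFAULTS: dict[str, dict[str, Any]] = {
    "io": {
        "feature_table": None,
        "parent_reference": None,
        "delimiter": "\t",
        "missing_sentinels": ["", "NA", "NaN", "ND"],
        "condition_order": None,
        "cv_spec": None,          # list of [mean, sd, cv] triples, applied on read
        "min_replicates": 115,
    },
    "simulate": {"enabled": False},
    "scoring": {"threshold_primary": 3.0, "quantile_rule": "linear"},
    "outliers": {"primary": 3.0, "secondary": 1.5, "same_sign": True, "min_conditions": 3},
    "network": {
        "central_mass": 0.997,
        "min_overlap": None,
        "threshold_source": "empirical",
        "n_perm": 10000,
        "complete_only": True,
        "focus_strains": None,    # path to a file of strain ids (e.g. y-genes)
    },
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration with per-section parameter dicts."""

    io: dict[str, Any] = field(default_factory=dict)
    simulate: dict[str, Any] = field(default_factory=dict)
    scoring: dict[str, Any] = field(default_factory=dict)
    outliers: dict[str, Any] = field(default_factory=dict)
    network: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    run_id: str = "run"

    def __post_init__(self) -> None:
        for section in ("io", "simulate", "scoring", "outliers", "network"):
            merged = dict(DEFAULTS[section])
            merged.update(getattr(self, section) or {})
            setattr(self, section, merged)
        if not self.simulate["enabled"]:
            for key in ("feature_table", "parent_reference"):
                path = self.io[key]
                if path is None:
                    raise ConfigError(f"config missing io.{key} (and simulate is disabled)")
                if not Path(path).exists():
                    raise ConfigError(f"io.{key} does not exist: {path}")
        focus = self.network["focus_strains"]
        if focus is not None and not Path(focus).exists():
            raise ConfigError(f"network.focus_strains does not exist: {focus}")

    def canonical(self) -> str:
        return yaml.safe_dump(
            {
                "io": self.io, "simulate": self.simulate, "scoring": self.scoring,
                "outliers": self.outliers, "network": self.network,
                "seed": self.seed, "run_id": self.run_id,
            },
            sort_keys=True,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def load_config(path: str | Path, seed: int | None = None) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(
        io=raw.get("io", {}),
        simulate=raw.get("simulate", {}),
        scoring=raw.get("scoring", {}),
        outliers=raw.get("outliers", {}),
        network=raw.get("network", {}),
        seed=raw.get("seed", 0) if seed is None else seed,
        run_id=raw.get("run_id", "run"),
    )
    return cfg


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute read/simulate -> augment -> score -> call -> atlas ->
    phenoprints -> correlations -> thresholds -> network -> exports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    if config.simulate["enabled"]:
        spec = default_screen_spec(
            seed=_stage_seed(config.seed, "simulate"),
            n_strains=config.simulate.get("n_strains", 806),
        )
        overrides = {
            k: v for k, v in config.simulate.items() if k not in ("enabled", "n_strains")
        }
        if overrides:
            from dataclasses import replace
            spec = replace(spec, **overrides)
        ref = generate_parent_reference(spec)
        table, truth = generate_mutant_library(spec)
        write_fixture_bundle(table, ref, truth, out / "simulated")
    else:
        table = read_feature_table(
            config.io["feature_table"],
            delimiter=config.io["delimiter"],
            missing_sentinels=config.io["missing_sentinels"],
            condition_order=config.io["condition_order"],
        )
        ref = read_parent_reference(
            config.io["parent_reference"],
            delimiter=config.io["delimiter"],
            min_replicates=config.io["min_replicates"],
        )
        if config.io["cv_spec"]:
            cv = CVSpec(triples=[tuple(t) for t in config.io["cv_spec"]])
            table = augment_cv_features(table, cv)
            ref = augment_cv_reference(ref, cv)

    report = validate_parent_reference(ref, table)
    if not report.ok:
        log.warning(
            "parent reference deficiencies: %d low-replicate, %d zero-IQR, %d absent",
            len(report.low_replicates), len(report.zero_iqr), len(report.absent),
        )

    # --- scoring ----------------------------------------------------------
    scores = score_table(
        table, ref,
        quantile_rule=config.scoring["quantile_rule"],
        threshold_primary=config.scoring["threshold_primary"],
    )
    long_scores = scores.scores.stack(["condition", "feature"], future_stack=True)
    long_scores.rename("s").reset_index().rename(columns={"level_0": "strain"}).to_csv(
        out / "scores.tsv", sep="\t", index=False, na_rep="NA"
    )
    calls = call_deviations(scores, threshold=config.scoring["threshold_primary"])

    # --- deviation atlas --------------------------------------------------
    breadth = summarize_breadth(calls)
    breadth.per_strain.rename_axis("strain").to_csv(out / "breadth.tsv", sep="\t")
    breadth.histogram.to_csv(out / "breadth_histogram.tsv", sep="\t")
    partition = venn_partition(calls)
    pd.DataFrame(
        [{"conditions": "+".join(k), "n_strains": v} for k, v in sorted(partition.items())]
    ).to_csv(out / "venn_partition.tsv", sep="\t", index=False)

    scan = detect_nutrient_independent_outliers(
        scores,
        primary=config.outliers["primary"],
        secondary=config.outliers["secondary"],
        same_sign=config.outliers["same_sign"],
        min_conditions=config.outliers["min_conditions"],
    )
    rows = [
        {"strain": r.strain, "feature": r.feature, "sign": r.sign,
         "conditions_evaluated": r.conditions_evaluated,
         **{f"s_{c}": v for c, v in r.scores_by_condition.items()}}
        for r in scan.records
    ]
    pd.DataFrame(rows).to_csv(out / "outliers.tsv", sep="\t", index=False, na_rep="NA")
    counts = outlier_counts(scan)
    counts.per_feature.rename_axis("feature").rename("n_outliers").to_csv(
        out / "outliers_per_feature.tsv", sep="\t"
    )
    counts.per_strain_histogram.rename_axis("n_features_bin").rename("n_strains").to_csv(
        out / "outliers_per_strain_histogram.tsv", sep="\t"
    )

    robustness = cross_condition_robustness(scores, calls)
    robustness.pair_means.to_csv(out / "robustness.tsv", sep="\t")

    # --- phenoprint network -----------------------------------------------
    pheno = assemble_phenoprints(scores, complete_only=config.network["complete_only"])
    corr = pairwise_spearman(pheno, min_overlap=config.network["min_overlap"])
    corr.rho.to_csv(out / "correlations.tsv", sep="\t", na_rep="NA")
    if config.network["threshold_source"] == "permutation":
        thr = permutation_null(
            pheno, n_perm=config.network["n_perm"],
            seed=_stage_seed(config.seed, "permutation"),
            central_mass=config.network["central_mass"],
        )
    else:
        thr = empirical_thresholds(corr, central_mass=config.network["central_mass"])
    (out / "thresholds.json").write_text(
        json.dumps(
            {"lower": thr.lower, "upper": thr.upper,
             "central_mass": thr.central_mass, "source": thr.source},
            indent=2,
        )
    )
    focus = None
    if config.network["focus_strains"]:
        focus = [
            line.strip()
            for line in Path(config.network["focus_strains"]).read_text().splitlines()
            if line.strip()
        ]
    net = significant_connections(corr, thr, focus=focus)
    export_network(net, out / "edges.tsv", format="edgelist")
    export_network(net, out / "network.graphml", format="graphml")
    net.connection_counts.rename_axis("strain").rename("n_connections").to_csv(
        out / "connection_counts.tsv", sep="\t"
    )

    provenance = {
        "run_id": config.run_id,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "versions": {
            "phenoscreen": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_strains": len(table.strain_ids),
        "n_conditions": len(table.condition_ids),
        "n_features": len(table.feature_ids),
        "n_outlier_records": len(scan.records),
        "n_edges": net.graph.number_of_edges(),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    log.info("pipeline complete: %s", out)
    return out
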