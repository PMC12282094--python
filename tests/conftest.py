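"""Shared fixtures: synthetic screens at study scale and small hand fixtures."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phenoscreen.feature_table import FeatureTable, ParentReference
from phenoscreen.phenoprint_network import assemble_phenoprints, pairwise_spearman
from phenoscreen.scoring import ScoreMatrix, call_deviations, score_table
from phenoscreen.synthetic_data import (
    default_screen_spec,
    generate_mutant_library,
    generate_parent_reference,
)

BUNDLE_SEED = 20


@pytest.fixture(scope="session")
def default_bundle():
    """Full-scale synthetic screen (806 strains, planted ground truth)."""
    spec = default_screen_spec(seed=BUNDLE_SEED)
    ref = generate_parent_reference(spec)
    table, truth = generate_mutant_library(spec)
    return spec, ref, table, truth


@pytest.fixture(scope="session")
def default_scores(default_bundle):
    spec, ref, table, truth = default_bundle
    scores = score_table(table, ref)
    calls = call_deviations(scores)
    return scores, calls


@pytest.fixture(scope="session")
def default_network(default_scores):
    scores, _ = default_scores
    pheno = assemble_phenoprints(scores, complete_only=True)
    corr = pairwise_spearman(pheno)
    return pheno, corr


def make_score_matrix(
    scores_by_strain: dict[str, dict[tuple[str, str], float]],
    conditions: list[str],
    features: list[str],
) -> ScoreMatrix:
    """Build a ScoreMatrix from a sparse {strain: {(cond, feat): s}} dict."""
    columns = pd.MultiIndex.from_product(
        [conditions, features], names=["condition", "feature"]
    )
    frame = pd.DataFrame(np.nan, index=list(scores_by_strain), columns=columns)
    for strain, cells in scores_by_strain.items():
        for key, s in cells.items():
            frame.loc[strain, key] = s
    return ScoreMatrix(scores=frame)


@pytest.fixture
def tiny_table() -> FeatureTable:
    """3 strains x 2 conditions x 2 features, fully observed."""
    conditions, features = ["c1", "c2"], ["f1", "f2"]
    columns = pd.MultiIndex.from_product(
        [conditions, features], names=["condition", "feature"]
    )
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.normal(10, 1, size=(3, 4)), index=["s1", "s2", "s3"], columns=columns
    )
    return FeatureTable(values=values)


@pytest.fixture
def tiny_ref(tiny_table) -> ParentReference:
    rng = np.random.default_rng(7)
    replicates = {
        (cond, feat): rng.normal(10, 1, size=120)
        for cond in tiny_table.condition_ids
        for feat in tiny_table.feature_ids
    }
    return ParentReference(replicates=replicates, min_replicates=115)
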