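"""Phenoprint correlations, significance thresholds, connection networks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import networkx as nx

from phenoscreen.phenoprint_network import (
    CorrelationMatrix,
    PhenoprintSet,
    SignificanceThresholds,
    assemble_phenoprints,
    empirical_thresholds,
    export_network,
    pairwise_spearman,
    permutation_null,
    significant_connections,
)

from conftest import make_score_matrix


def _pheno_from_rows(rows: dict[str, np.ndarray]) -> PhenoprintSet:
    n = len(next(iter(rows.values())))
    columns = pd.MultiIndex.from_product(
        [["c1"], [f"f{i}" for i in range(n)]], names=["condition", "feature"]
    )
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = columns
    return PhenoprintSet(vectors=frame, complete_only=False, dropped_strains=[])


# -- assembly ----------------------------------------------------------------

def test_phenoprint_axis_is_conditions_times_features(default_scores):
    scores, _ = default_scores
    pheno = assemble_phenoprints(scores, complete_only=True)
    assert len(pheno.axis) == 96 * 4 == 384
    # condition-major layout
    conds = [c for c, _ in pheno.axis]
    assert conds == sorted(conds, key=scores.condition_ids.index)


def test_complete_only_drops_partially_sampled_strains():
    matrix = make_score_matrix(
        {
            "full": {(c, "f1"): 1.0 for c in ["c1", "c2"]},
            "partial": {("c1", "f1"): 1.0},
        },
        ["c1", "c2"], ["f1"],
    )
    pheno = assemble_phenoprints(matrix, complete_only=True)
    assert pheno.strains == ["full"]
    assert pheno.dropped_strains == ["partial"]
    pheno_all = assemble_phenoprints(matrix, complete_only=False)
    assert set(pheno_all.strains) == {"full", "partial"}


def test_assembly_is_deterministic(default_scores):
    scores, _ = default_scores
    a = assemble_phenoprints(scores, complete_only=True)
    b = assemble_phenoprints(scores, complete_only=True)
    assert a.axis == b.axis
    assert np.array_equal(a.vectors.to_numpy(), b.vectors.to_numpy(), equal_nan=True)


# -- pairwise Spearman -------------------------------------------------------

def test_identical_and_reversed_vectors():
    rng = np.random.default_rng(0)
    v = rng.normal(size=30)
    pheno = _pheno_from_rows({"a": v, "b": v.copy(), "c": np.exp(-v)})
    corr = pairwise_spearman(pheno, min_overlap=10)
    assert corr.rho.loc["a", "b"] == pytest.approx(1.0)
    assert corr.rho.loc["a", "c"] == pytest.approx(-1.0)  # strictly decreasing map


def test_rank_invariance_under_increasing_transform():
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=40), rng.normal(size=40)
    p1 = _pheno_from_rows({"a": x, "b": y})
    p2 = _pheno_from_rows({"a": np.expm1(x), "b": y**3})
    r1 = pairwise_spearman(p1, min_overlap=10).rho.loc["a", "b"]
    r2 = pairwise_spearman(p2, min_overlap=10).rho.loc["a", "b"]
    assert r1 == pytest.approx(r2, abs=1e-12)


def _rank_average_ties(v: np.ndarray) -> np.ndarray:
    """Brute-force average ranks, independent of scipy."""
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v), float)
    i = 0
    sorted_v = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def test_spearman_with_ties_matches_two_independent_oracles():
    rng = np.random.default_rng(5)
    x = rng.integers(0, 5, size=20).astype(float)  # heavy ties
    y = rng.integers(0, 5, size=20).astype(float)
    pheno = _pheno_from_rows({"a": x, "b": y})
    rho = pairwise_spearman(pheno, min_overlap=5).rho.loc["a", "b"]
    # oracle 1: rank-then-Pearson with hand-rolled average ranks
    rx, ry = _rank_average_ties(x), _rank_average_ties(y)
    oracle1 = np.corrcoef(rx, ry)[0, 1]
    # oracle 2: scipy
    oracle2 = stats.spearmanr(x, y).statistic
    assert rho == pytest.approx(oracle1, abs=1e-12)
    assert rho == pytest.approx(oracle2, abs=1e-12)


def test_pairwise_complete_missing_handling_matches_scipy():
    rng = np.random.default_rng(6)
    x, y = rng.normal(size=40), rng.normal(size=40)
    x[rng.choice(40, 8, replace=False)] = np.nan
    y[rng.choice(40, 8, replace=False)] = np.nan
    pheno = _pheno_from_rows({"a": x, "b": y, "c": rng.normal(size=40)})
    corr = pairwise_spearman(pheno, min_overlap=5)
    joint = ~np.isnan(x) & ~np.isnan(y)
    expected = stats.spearmanr(x[joint], y[joint]).statistic
    assert corr.rho.loc["a", "b"] == pytest.approx(expected, abs=1e-12)
    assert corr.n_overlap.loc["a", "b"] == joint.sum()


def test_min_overlap_gives_undefined():
    x = np.full(20, np.nan)
    x[:4] = [1.0, 2.0, 3.0, 4.0]
    y = np.arange(20.0)
    pheno = _pheno_from_rows({"a": x, "b": y})
    corr = pairwise_spearman(pheno, min_overlap=10)
    assert np.isnan(corr.rho.loc["a", "b"])
    assert corr.rho.loc["a", "a"] == 1.0


def test_constant_vector_is_undefined():
    pheno = _pheno_from_rows({"a": np.ones(20), "b": np.arange(20.0)})
    corr = pairwise_spearman(pheno, min_overlap=5)
    assert np.isnan(corr.rho.loc["a", "b"])


def test_matrix_symmetry_and_range(default_network):
    _, corr = default_network
    arr = corr.rho.to_numpy()
    assert np.allclose(arr, arr.T, equal_nan=True)
    assert np.allclose(np.diag(arr), 1.0)
    finite = arr[~np.isnan(arr)]
    assert ((finite >= -1 - 1e-12) & (finite <= 1 + 1e-12)).all()


# -- thresholds --------------------------------------------------------------

def _fake_corr(values: np.ndarray) -> CorrelationMatrix:
    """Pack a value vector into the upper triangle of a synthetic matrix."""
    m = int(np.ceil((1 + np.sqrt(1 + 8 * len(values))) / 2))
    arr = np.full((m, m), np.nan)
    iu = np.triu_indices(m, k=1)
    take = min(len(values), len(iu[0]))
    arr[iu[0][:take], iu[1][:take]] = values[:take]
    arr[iu[1][:take], iu[0][:take]] = values[:take]
    np.fill_diagonal(arr, 1.0)
    names = [f"s{i}" for i in range(m)]
    frame = pd.DataFrame(arr, index=names, columns=names)
    n = pd.DataFrame(100, index=names, columns=names)
    return CorrelationMatrix(rho=frame, n_overlap=n)


def test_thresholds_of_symmetric_distribution_are_symmetric():
    rng = np.random.default_rng(2)
    vals = np.clip(rng.normal(0, 0.2, size=20_000), -1, 1)
    thr = empirical_thresholds(_fake_corr(vals))
    assert thr.lower == pytest.approx(-thr.upper, abs=0.03)


def test_central_mass_machinery_recovers_normal_three_sigma():
    """Middle-99.7% quantiles of 100k standard-normal draws sit near +/-3."""
    rng = np.random.default_rng(3)
    vals = rng.standard_normal(100_000)
    thr = empirical_thresholds(_fake_corr(vals))
    assert thr.lower == pytest.approx(-3.0, abs=0.05)
    assert thr.upper == pytest.approx(3.0, abs=0.05)


def test_threshold_exclusion_mass_bound(default_network):
    _, corr = default_network
    thr = empirical_thresholds(corr)
    vals = corr.upper_triangle_values()
    frac = ((vals < thr.lower) | (vals > thr.upper)).mean()
    assert frac <= 0.003 + 2 / len(vals)


def test_no_defined_correlations_is_error():
    arr = np.full((3, 3), np.nan)
    frame = pd.DataFrame(arr, index=list("abc"), columns=list("abc"))
    corr = CorrelationMatrix(rho=frame, n_overlap=frame.notna().astype(int))
    with pytest.raises(ValueError):
        empirical_thresholds(corr)


def test_permutation_null_deterministic_under_seed(default_network):
    pheno, _ = default_network
    small = PhenoprintSet(
        vectors=pheno.vectors.iloc[:40], complete_only=True, dropped_strains=[]
    )
    t1 = permutation_null(small, n_perm=200, seed=9)
    t2 = permutation_null(small, n_perm=200, seed=9)
    assert (t1.lower, t1.upper) == (t2.lower, t2.upper)


def test_permutation_null_single_draw_degenerate():
    rng = np.random.default_rng(0)
    pheno = _pheno_from_rows({"a": rng.normal(size=30), "b": rng.normal(size=30)})
    thr = permutation_null(pheno, n_perm=1, seed=1)
    assert thr.upper == pytest.approx(thr.lower, abs=1e-12)


def test_permutation_null_less_stringent_than_empirical_on_structured_data(
    default_network,
):
    """With genuine positive structure, the empirical interval is wider than
    the permutation null — the reason the analysis uses empirical cutoffs."""
    pheno, corr = default_network
    emp = empirical_thresholds(corr)
    perm = permutation_null(pheno, n_perm=2000, seed=4)
    assert perm.upper < emp.upper
    assert perm.lower > emp.lower


# -- networks ----------------------------------------------------------------

THR = SignificanceThresholds(lower=-0.5154, upper=0.6476)


def test_edge_when_rho_beyond_printed_upper_threshold():
    corr = _fake_corr(np.array([0.7]))
    net = significant_connections(corr, THR)
    edges = net.edges
    assert len(edges) == 1
    assert edges.iloc[0]["sign"] == "+"
    assert edges.iloc[0]["weight"] == pytest.approx(0.7)


def test_no_edge_for_null_rho():
    corr = _fake_corr(np.array([0.0]))
    net = significant_connections(corr, THR)
    assert net.graph.number_of_edges() == 0


def test_planted_clique_recovered():
    """Five mutually correlated strains come back as a 5-clique."""
    rng = np.random.default_rng(12)
    shared = rng.normal(size=60)
    rows = {f"m{i}": shared + rng.normal(0, 0.3, 60) for i in range(5)}
    rows.update({f"n{i}": rng.normal(size=60) for i in range(30)})
    pheno = _pheno_from_rows(rows)
    corr = pairwise_spearman(pheno, min_overlap=10)
    thr = SignificanceThresholds(lower=-0.6, upper=0.6)
    net = significant_connections(corr, thr)
    module = [f"m{i}" for i in range(5)]
    sub = net.graph.subgraph(module)
    assert sub.number_of_edges() == 10  # complete K5


def test_focus_filtering_never_adds_edges(default_network):
    _, corr = default_network
    thr = empirical_thresholds(corr)
    full = significant_connections(corr, thr)
    focus = [s for s in corr.rho.index if s.startswith("y")][:50]
    focused = significant_connections(corr, thr, focus=focus)
    full_edges = {frozenset(e) for e in full.graph.edges}
    focused_edges = {frozenset(e) for e in focused.graph.edges}
    assert focused_edges <= full_edges
    assert all(u in focus or v in focus for u, v in focused.graph.edges)
    assert set(focused.connection_counts.index) == set(focus)


def test_edges_replay_against_thresholds(default_network):
    _, corr = default_network
    thr = empirical_thresholds(corr)
    net = significant_connections(corr, thr)
    assert net.graph.number_of_edges() > 0
    for _, row in net.edges.iterrows():
        assert thr.is_significant(row["rho"])
        assert row["rho"] == corr.rho.loc[row["source"], row["target"]]


def test_y_gene_flags_on_nodes():
    corr = _fake_corr(np.array([0.9]))
    corr.rho.index = corr.rho.columns = ["yabC", "gdfX"]
    corr.n_overlap.index = corr.n_overlap.columns = ["yabC", "gdfX"]
    net = significant_connections(corr, THR)
    assert net.graph.nodes["yabC"]["y_gene"] is True
    assert net.graph.nodes["gdfX"]["y_gene"] is False


# -- export ------------------------------------------------------------------

def test_export_empty_network(tmp_path):
    corr = _fake_corr(np.array([0.0]))
    net = significant_connections(corr, THR)
    path = export_network(net, tmp_path / "edges.tsv")
    assert path.read_text().splitlines() == ["source\ttarget\trho\tsign\tweight"]


def test_export_round_trip_and_sign_column(tmp_path):
    corr = _fake_corr(np.array([0.7, -0.8, 0.9]))
    net = significant_connections(corr, THR)
    path = export_network(net, tmp_path / "edges.tsv")
    back = pd.read_csv(path, sep="\t")
    assert len(back) == 3
    assert set(back["sign"]) <= {"+", "-"}
    merged = back.set_index(["source", "target"])["rho"]
    for (u, v), rho in merged.items():
        assert rho == corr.rho.loc[u, v]
    gml = export_network(net, tmp_path / "net.graphml", format="graphml")
    again = nx.read_graphml(gml)
    assert again.number_of_edges() == 3
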