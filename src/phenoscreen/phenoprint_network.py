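"""Phenoprint assembly, rank correlation, significance thresholds, networks.

A strain's phenoprint is its concatenated score vector over all
(feature, condition) cells — 384 entries at study defaults (96 features x 4
conditions), laid out condition-major.  Pairwise Spearman correlations
between phenoprints, thresholded by the empirical middle-99.7% interval of
all pairwise coefficients (the analogue of +/- 3 SD on a normal), define a
signed, weighted connection network: strongly positive connections suggest
shared function of the deleted genes, strongly negative ones opposing roles.

A permutation null (shuffling one member of a random strain pair per draw,
destroying alignment while preserving marginals) is provided as the
alternative threshold source; on data with genuine positive structure it is
less stringent than the empirical interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .scoring import ScoreMatrix

log = logging.getLogger(__name__)

DEFAULT_CENTRAL_MASS = 0.997


@dataclass
class PhenoprintSet:
    """Per-strain score vectors over a fixed condition-major axis."""

    vectors: pd.DataFrame  # strains x MultiIndex (condition, feature)
    complete_only: bool
    dropped_strains: list[str]

    @property
    def strains(self) -> list[str]:
        return list(self.vectors.index)

    @property
    def axis(self) -> list[tuple[str, str]]:
        return list(self.vectors.columns)


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise rank-correlation matrix; NaN marks undefined pairs."""

    rho: pd.DataFrame
    n_overlap: pd.DataFrame
    method: str = "spearman"
    min_overlap: int = 0

    def upper_triangle_values(self) -> np.ndarray:
        """Defined off-diagonal coefficients, each unordered pair counted once."""
        arr = self.rho.to_numpy()
        iu = np.triu_indices_from(arr, k=1)
        vals = arr[iu]
        return vals[~np.isnan(vals)]


@dataclass
class SignificanceThresholds:
    lower: float
    upper: float
    central_mass: float = DEFAULT_CENTRAL_MASS
    source: str = "empirical"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("lower threshold must be below upper threshold")

    def is_significant(self, rho: float) -> bool:
        return bool(rho < self.lower or rho > self.upper)


@dataclass
class ConnectionNetwork:
    """Significant phenoprint connections as a signed, weighted graph."""

    graph: nx.Graph
    thresholds: SignificanceThresholds
    connection_counts: pd.Series  # per focus strain (or all strains)

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "rho": d["rho"], "sign": d["sign"], "weight": d["weight"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "rho", "sign", "weight"])


# ---------------------------------------------------------------------------

def assemble_phenoprints(scores: ScoreMatrix, complete_only: bool = True) -> PhenoprintSet:
    """Lay out per-strain phenoprint vectors on the fixed condition-major axis.

    With ``complete_only`` (the default, matching the correlation analysis),
    strains lacking every measurement in some condition are dropped and
    reported; within retained strains, missing cells stay missing.
    """
    vectors = scores.scores.copy()
    dropped: list[str] = []
    if complete_only:
        present = vectors.notna().T.groupby(level="condition").any().T
        complete = present.all(axis=1)
        dropped = [s for s in vectors.index if not complete[s]]
        vectors = vectors.loc[complete]
        if dropped:
            log.info("dropped %d strains not sampled in all conditions", len(dropped))
    return PhenoprintSet(vectors=vectors, complete_only=complete_only, dropped_strains=dropped)


def pairwise_spearman(pheno: PhenoprintSet, min_overlap: int | None = None) -> CorrelationMatrix:
    """All-pairs Spearman rank correlation with pairwise-complete missing handling.

    Ranks use the average-rank convention for ties.  A pair's coefficient is
    undefined (NaN) when the jointly non-missing overlap is below
    ``min_overlap`` (default: half the axis length) or when either vector has
    zero variance over the overlap.
    """
    if len(pheno.strains) < 2:
        raise ValueError("need at least two strains")
    if min_overlap is None:
        min_overlap = len(pheno.axis) // 2
    X = pheno.vectors
    # axis entries missing in every strain (e.g. features not determined in a
    # condition) belong to no pairwise overlap; drop them up front
    X = X.loc[:, X.notna().any(axis=0)]
    mask = X.notna().to_numpy()
    n_overlap = mask.astype(np.int64) @ mask.T
    strains = list(X.index)
    if mask.all():
        ranked = stats.rankdata(X.to_numpy(), axis=1)
        sd = ranked.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.corrcoef(ranked)
        rho[sd == 0, :] = np.nan
        rho[:, sd == 0] = np.nan
        if (sd == 0).any():
            log.warning("%d constant phenoprints: correlations undefined", int((sd == 0).sum()))
        rho_df = pd.DataFrame(rho, index=strains, columns=strains)
    else:
        rho_df = X.T.corr(method="spearman", min_periods=max(min_overlap, 2))
    rho_df = rho_df.where(n_overlap >= min_overlap)
    np.fill_diagonal(rho_df.values, 1.0)
    return CorrelationMatrix(
        rho=rho_df,
        n_overlap=pd.DataFrame(n_overlap, index=strains, columns=strains),
        method="spearman",
        min_overlap=min_overlap,
    )


def empirical_thresholds(
    corr: CorrelationMatrix,
    central_mass: float = DEFAULT_CENTRAL_MASS,
    quantile_rule: str = "linear",
) -> SignificanceThresholds:
    """Quantile thresholds excluding the central mass of observed coefficients.

    Lower/upper are the (1-central_mass)/2 and 1-(1-central_mass)/2 empirical
    quantiles of all defined upper-triangle coefficients (each unordered pair
    once), under the same quantile convention as scoring.
    """
    vals = corr.upper_triangle_values()
    if len(vals) == 0:
        raise ValueError("no defined correlation coefficients")
    if len(vals) < 100:
        log.warning("only %d coefficients: thresholds will be coarse", len(vals))
    tail = (1.0 - central_mass) / 2.0
    lower, upper = np.quantile(vals, [tail, 1.0 - tail], method=quantile_rule)
    return SignificanceThresholds(
        lower=float(lower), upper=float(upper), central_mass=central_mass, source="empirical"
    )


def permutation_null(
    pheno: PhenoprintSet,
    n_perm: int = 10_000,
    seed: int = 0,
    central_mass: float = DEFAULT_CENTRAL_MASS,
    quantile_rule: str = "linear",
) -> SignificanceThresholds:
    """Threshold from a permutation null of phenoprint correlations.

    Each draw picks a random strain pair, shuffles the axis entries of one
    member (destroying alignment, preserving marginals), and records the
    Spearman coefficient over the jointly non-missing entries.  Thresholds
    are the tail quantiles of the pooled null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    X = pheno.vectors.to_numpy()
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two strains")
    null = np.empty(n_perm)
    k = 0
    for _ in range(n_perm):
        i, j = rng.choice(n, size=2, replace=False)
        y = X[j].copy()
        rng.shuffle(y)
        joint = ~np.isnan(X[i]) & ~np.isnan(y)
        if joint.sum() < 3:
            continue
        null[k] = stats.spearmanr(X[i][joint], y[joint]).statistic
        k += 1
    null = null[:k]
    null = null[~np.isnan(null)]
    if len(null) == 1:
        log.warning("single permutation: degenerate thresholds equal to that value")
        v = float(null[0])
        return SignificanceThresholds(
            lower=float(np.nextafter(v, -np.inf)), upper=v,
            central_mass=central_mass, source="permutation",
        )
    tail = (1.0 - central_mass) / 2.0
    lower, upper = np.quantile(null, [tail, 1.0 - tail], method=quantile_rule)
    return SignificanceThresholds(
        lower=float(lower), upper=float(upper), central_mass=central_mass, source="permutation"
    )


def significant_connections(
    corr: CorrelationMatrix,
    thr: SignificanceThresholds,
    focus: list[str] | None = None,
    y_gene_prefix: str = "y",
) -> ConnectionNetwork:
    """Extract the network of strain pairs whose rho falls outside the thresholds.

    With ``focus`` (e.g. the y-gene deletion strains), only edges incident to
    a focus strain are kept, and per-focus-strain connection counts (including
    zeros) are reported — the frequency-distribution view of how connected
    each gene of unknown function is.
    """
    strains = list(corr.rho.index)
    focus_set = set(focus) if focus is not None else None
    graph = nx.Graph()
    for s in strains:
        graph.add_node(s, gene=s, y_gene=s.startswith(y_gene_prefix))
    arr = corr.rho.to_numpy()
    iu, ju = np.triu_indices(len(strains), k=1)
    vals = arr[iu, ju]
    hit = ~np.isnan(vals) & ((vals < thr.lower) | (vals > thr.upper))
    for a, b, rho in zip(iu[hit], ju[hit], vals[hit]):
        u, v = strains[a], strains[b]
        if focus_set is not None and u not in focus_set and v not in focus_set:
            continue
        graph.add_edge(u, v, rho=float(rho), sign="+" if rho > 0 else "-", weight=abs(float(rho)))
    count_over = sorted(focus_set & set(strains)) if focus_set is not None else strains
    counts = pd.Series({s: graph.degree(s) for s in count_over}, dtype=int)
    return ConnectionNetwork(graph=graph, thresholds=thr, connection_counts=counts)


def export_network(net: ConnectionNetwork, path: str | Path, format: str = "edgelist") -> Path:
    """Write the network as an edge-list TSV or GraphML file."""
    path = Path(path)
    if format == "edgelist":
        net.edges.to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        nx.write_graphml(net.graph, path)
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path
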