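"""FDR-screened Spearman co-occurrence networks and network complexity.

The workflow mirrors standard amplicon network practice: Spearman rank
correlations between all taxon pairs, Benjamini-Hochberg adjustment across
the pair family, a hard screen (|r| > 0.70, adjusted p < 0.01 by default)
to form an undirected signed network, per-treatment induced subnetworks,
topological parameters per subnetwork, and a single "network complexity"
score per subnetwork taken as axis 1 of a principal-coordinate ordination
of the z-scored topology table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import FeatureTable, SampleMetadata

__all__ = [
    "SpearmanMatrix",
    "TopologySummary",
    "spearman_matrix",
    "adjust_fdr",
    "build_network",
    "treatment_subnetwork",
    "topology_summary",
    "topology_table",
    "complexity_scores",
]


@dataclass
class SpearmanMatrix:
    """All-pairs Spearman correlations with raw and BH-adjusted p-values.

    Symmetric DataFrames indexed by taxon; ``p_adj`` is adjusted across the
    upper-triangle family of this matrix only, so independently built
    networks (e.g. bacteria vs fungi) carry independent FDR families.
    """

    r: pd.DataFrame
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame

    @property
    def taxa(self) -> list:
        return list(self.r.index)


def spearman_matrix(t: FeatureTable) -> SpearmanMatrix:
    """Spearman rank correlation for every unordered taxon pair.

    Average ranks for ties; p-values from the t approximation with n-2
    degrees of freedom. Zero-variance taxa are excluded with a warning
    (their rank correlation is undefined).
    """
    if len(t.sample_ids) < 4:
        raise ValueError("need at least 4 samples for correlation screening")
    data = t.data
    variances = data.var(axis=0)
    dropped = list(variances.index[variances == 0])
    if dropped:
        warnings.warn(f"excluding zero-variance taxa: {dropped}")
        data = data.drop(columns=dropped)
    if data.shape[1] < 2:
        raise ValueError("fewer than 2 variable taxa")
    rho, pval = stats.spearmanr(data.to_numpy())
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly 2 columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        pval = np.array([[0.0, float(pval)], [float(pval), 0.0]])
    np.fill_diagonal(pval, 0.0)
    taxa = list(data.columns)
    r = pd.DataFrame(rho, index=taxa, columns=taxa)
    p_raw = pd.DataFrame(pval, index=taxa, columns=taxa)

    iu = np.triu_indices(len(taxa), k=1)
    adj_flat = adjust_fdr(pval[iu])
    p_adj_mat = np.zeros_like(pval)
    p_adj_mat[iu] = adj_flat
    p_adj_mat = p_adj_mat + p_adj_mat.T
    p_adj = pd.DataFrame(p_adj_mat, index=taxa, columns=taxa)
    return SpearmanMatrix(r=r, p_raw=p_raw, p_adj=p_adj)


def adjust_fdr(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_network(corr: SpearmanMatrix, r_min: float = 0.70,
                  p_max: float = 0.01) -> nx.Graph:
    """Screen edges by |r| > r_min (strict) and adjusted p < p_max (strict).

    Isolated taxa are dropped; each edge carries r, p_raw, p_adj and a
    sign label ('+' / '-').
    """
    if not (0 < r_min <= 1) or not (0 < p_max <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    g = nx.Graph()
    taxa = corr.taxa
    rv = corr.r.to_numpy()
    pr = corr.p_raw.to_numpy()
    pa = corr.p_adj.to_numpy()
    n = len(taxa)
    for i in range(n):
        for j in range(i + 1, n):
            r = rv[i, j]
            if abs(r) > r_min and pa[i, j] < p_max:
                g.add_edge(taxa[i], taxa[j], r=float(r),
                           p_raw=float(pr[i, j]), p_adj=float(pa[i, j]),
                           sign="+" if r > 0 else "-")
    return g


def treatment_subnetwork(g: nx.Graph, t: FeatureTable, meta: SampleMetadata,
                         group: str) -> nx.Graph:
    """Induced subgraph on taxa present (nonzero mean abundance) in *group*.

    Edge attributes are inherited unchanged from the parent network.
    """
    samples = meta.samples_for(group)
    sub_means = t.data.loc[samples].mean(axis=0)
    present = {taxon for taxon in g.nodes if sub_means.get(taxon, 0.0) > 0}
    return g.subgraph(present).copy()


@dataclass
class TopologySummary:
    """Topological parameters of one (sub)network."""

    n_nodes: int
    n_edges: int
    average_degree: float
    density: float
    positive_edge_proportion: float
    average_path_length: float
    mean_betweenness_centrality: float
    modularity: float
    clustering_coefficient: float

    def as_series(self, name=None) -> pd.Series:
        return pd.Series(vars(self), name=name, dtype=float)


def _average_path_length(g: nx.Graph) -> float:
    """Mean shortest-path length over connected pairs (within components)."""
    total, pairs = 0.0, 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.shortest_path_length(sub):
            total += sum(dists.values())
            pairs += len(dists) - 1  # exclude self
    return total / pairs if pairs else 0.0


def topology_summary(g: nx.Graph) -> TopologySummary:
    """Compute the standard topology panel for one network.

    Betweenness is normalised by (n-1)(n-2)/2 and averaged over nodes;
    path length is averaged within components. Graphs with fewer than 3
    nodes report 0 for the path/centrality metrics with a warning.
    """
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        return TopologySummary(0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    if n < 3:
        warnings.warn("fewer than 3 nodes: path-based metrics reported as 0")
        avg_path = float(m > 0) if n == 2 else 0.0
        pos = _positive_fraction(g)
        return TopologySummary(n, m, 2 * m / n, nx.density(g), pos,
                               avg_path, 0.0, 0.0, 0.0)
    from .community import detect_modules

    part = detect_modules(g)
    bc = nx.betweenness_centrality(g, normalized=True)
    return TopologySummary(
        n_nodes=n,
        n_edges=m,
        average_degree=2 * m / n,
        density=nx.density(g),
        positive_edge_proportion=_positive_fraction(g),
        average_path_length=_average_path_length(g),
        mean_betweenness_centrality=float(np.mean(list(bc.values()))),
        modularity=part.modularity,
        clustering_coefficient=nx.average_clustering(g),
    )


def _positive_fraction(g: nx.Graph) -> float:
    if g.number_of_edges() == 0:
        return 0.0
    pos = sum(1 for _, _, d in g.edges(data=True) if d.get("r", 1.0) > 0)
    return pos / g.number_of_edges()


def topology_table(subnetworks: dict) -> pd.DataFrame:
    """Label -> TopologySummary table (one row per subnetwork)."""
    rows = {label: topology_summary(g).as_series() for label, g in subnetworks.items()}
    return pd.DataFrame(rows).T


def complexity_scores(summaries: pd.DataFrame) -> pd.DataFrame:
    """Network-complexity scores from a PCoA of the z-scored topology table.

    Metrics are standardised across subnetworks (constant columns dropped
    with a warning); principal coordinates of the Euclidean distance matrix
    are computed (equivalent to principal components here); axis 1 is
    oriented so that average_degree loads positively and is designated the
    network-complexity score.

    Returns a DataFrame (subnetwork x axes) whose first column is
    ``complexity``.
    """
    if summaries.shape[0] < 2:
        raise ValueError("need at least 2 subnetworks")
    sds = summaries.std(axis=0, ddof=1)
    constant = list(sds.index[(sds == 0) | sds.isna()])
    if constant:
        warnings.warn(f"dropping constant metric columns: {constant}")
    kept = summaries.drop(columns=constant)
    if kept.shape[1] == 0:
        # identical subnetworks: zero variance everywhere, all scores 0
        return pd.DataFrame(0.0, index=summaries.index, columns=["complexity"])
    z = (kept - kept.mean(axis=0)) / kept.std(axis=0, ddof=1)

    from .multivariate import pcoa
    from scipy.spatial.distance import pdist, squareform

    dist = squareform(pdist(z.to_numpy()))
    coords, _, _ = pcoa(pd.DataFrame(dist, index=z.index, columns=z.index))
    if coords.shape[1] == 0:  # all summaries identical after z-scoring
        coords = pd.DataFrame(0.0, index=z.index, columns=["PCo1"])
    axis1 = coords.iloc[:, 0]
    if "average_degree" in z.columns:
        orient = np.corrcoef(axis1.to_numpy(), z["average_degree"].to_numpy())[0, 1]
        if np.isfinite(orient) and orient < 0:
            coords.iloc[:, 0] = -axis1
    coords = coords.rename(columns={coords.columns[0]: "complexity"})
    return coords
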