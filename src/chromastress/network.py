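"""Mutant-correlation networks: Pearson matrix, UPGMA tree, QQ significance.

Each mutant's difference profile (all probes, all time points concatenated)
is correlated against every other mutant's.  The correlation matrix is
clustered with UPGMA on Euclidean distances between its rows; significant
partners of a query mutant are those whose Fisher-z-transformed
correlation deviates from the query's own null distribution by more than
``z_threshold`` robust SDs (the quantile-quantile criterion made
quantitative); and an undirected network keeps edges with r at or above a
threshold (0.45 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import median_abs_deviation, norm

from .errors import ConfigError, EstimationError
from .responsiveness import DifferenceMap

MIN_OVERLAP = 50
NETWORK_THRESHOLD = 0.45


@dataclass
class MutantCorrelation:
    """Pairwise mutant correlations plus clustering products.

    r : symmetric Pearson matrix (unit diagonal); pairs with fewer than
        ``min_overlap`` shared observations are NaN
    n_overlap : pairwise complete-observation counts
    tree : scipy linkage matrix (UPGMA), set by :func:`cluster_mutants`
    leaf_order : mutant ids in dendrogram order
    """

    r: pd.DataFrame
    n_overlap: pd.DataFrame
    tree: np.ndarray | None = None
    leaf_order: list | None = None

    @property
    def mutants(self):
        return list(self.r.index)


def correlation_matrix(dm: DifferenceMap,
                       min_overlap: int = MIN_OVERLAP) -> MutantCorrelation:
    """Pairwise-complete Pearson correlations between concatenated profiles.

    Mutants with fewer than ``min_overlap`` unmasked values overall are
    excluded with a warning; pairs overlapping in fewer than
    ``min_overlap`` values are masked (NaN).
    """
    vectors = dm.mutant_vectors()  # mutants x features, NaN = masked
    if vectors.shape[0] < 3:
        raise EstimationError("correlation matrix requires >= 3 mutants")
    counts = vectors.notna().sum(axis=1)
    bad = counts.index[counts < min_overlap]
    if len(bad):
        warnings.warn(f"excluding mutants with < {min_overlap} observed values: "
                      f"{list(bad)}")
        vectors = vectors.drop(index=bad)
    # mutants are sorted lexicographically for deterministic downstream order
    vectors = vectors.sort_index()
    feats = vectors.T  # features x mutants
    r = feats.corr(method="pearson", min_periods=min_overlap)
    present = feats.notna().astype(float)
    n_overlap = present.T @ present
    return MutantCorrelation(r=r, n_overlap=n_overlap.astype(int))


def cluster_mutants(mc: MutantCorrelation) -> tuple[np.ndarray, list]:
    """UPGMA on Euclidean distances between correlation-matrix rows.

    Masked correlations are treated as 0 for the distance computation.
    Leaf order is deterministic: mutants enter in lexicographic order and
    scipy's linkage tie-handling is stable.  Results are stored on ``mc``
    and returned.
    """
    filled = mc.r.fillna(0.0).to_numpy()
    d = pdist(filled, metric="euclidean")
    tree = hierarchy.linkage(d, method="average")
    order = hierarchy.leaves_list(tree)
    mc.tree = tree
    mc.leaf_order = [mc.r.index[i] for i in order]
    return tree, mc.leaf_order


def to_newick(mc: MutantCorrelation) -> str:
    """Serialize the UPGMA tree as Newick (clusters run first if needed)."""
    if mc.tree is None:
        cluster_mutants(mc)
    from skbio.tree import TreeNode
    tree = TreeNode.from_linkage_matrix(mc.tree, list(mc.r.index))
    return str(tree)


def significant_partners(mc: MutantCorrelation, query_mutant,
                         z_threshold: float = 3.0) -> pd.DataFrame:
    """Partners whose correlation with the query stands out of its null.

    The query's correlation vector (self excluded) is Fisher
    z-transformed, centered on its median and scaled by its MAD; partners
    with |standardized deviation| > ``z_threshold`` are flagged.  The
    returned frame carries (partner, r, z, qq_theoretical) sorted by
    descending |z|, with ``significant`` flags; the qq column gives the
    normal theoretical quantile matched to each observation's rank, for
    QQ-plot parity.
    """
    if query_mutant not in mc.r.index:
        raise ConfigError(f"query mutant {query_mutant!r} not in matrix")
    vec = mc.r.loc[query_mutant].drop(index=query_mutant).dropna()
    z = np.arctanh(np.clip(vec.to_numpy(), -0.999999, 0.999999))
    med = float(np.median(z))
    mad = float(median_abs_deviation(z, scale="normal"))
    if mad == 0:
        mad = float(np.std(z)) or 1.0
    score = (z - med) / mad
    ranks = pd.Series(score).rank(method="average").to_numpy()
    qq = norm.ppf((ranks - 0.5) / len(score))
    out = pd.DataFrame({"partner": vec.index, "r": vec.to_numpy(), "z": score,
                        "qq_theoretical": qq})
    out["significant"] = np.abs(out["z"]) > z_threshold
    return out.sort_values("z", key=np.abs, ascending=False,
                           ignore_index=True)


def build_network(mc: MutantCorrelation,
                  threshold: float = NETWORK_THRESHOLD) -> pd.DataFrame:
    """Undirected edges with r >= threshold, one row each, with components.

    Returns a frame (mutant_a, mutant_b, r, component); component ids are
    0-based over the subgraph induced by the edges.
    """
    ids = list(mc.r.index)
    rows = []
    rv = mc.r.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rij = rv[i, j]
            if np.isfinite(rij) and rij >= threshold:
                rows.append((ids[i], ids[j], float(rij)))
    edges = pd.DataFrame(rows, columns=["mutant_a", "mutant_b", "r"])
    g = nx.Graph()
    g.add_edges_from(edges[["mutant_a", "mutant_b"]].itertuples(index=False))
    comp_of = {}
    for ci, comp in enumerate(sorted(nx.connected_components(g),
                                     key=lambda c: sorted(c)[0])):
        for node in comp:
            comp_of[node] = ci
    edges["component"] = edges["mutant_a"].map(comp_of)
    return edges
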