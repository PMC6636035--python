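"""From many species' landscapes to a distance matrix, dendrogram and tree
comparison.

Each species contributes a window-smoothed landscape vector over the genes
shared by every included species (complete mode, the default — Euclidean
distance needs commensurate vectors). Pairwise Pearson correlations are
always reported; the dendrogram clusters either the Euclidean distance
between smoothed vectors (default) or the 1 − r correlation distance,
under average linkage (UPGMA) unless another linkage is requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy import stats

from .landscape import DEFAULT_HALF_WIDTH, ReferenceOrder, order_genes, sliding_window

LINKAGES = ("average", "single", "complete", "ward")


def build_landscape_matrix(
    metrics: dict[str, pd.Series],
    order: ReferenceOrder,
    w: int = DEFAULT_HALF_WIDTH,
) -> pd.DataFrame:
    """Species × gene matrix of smoothed values on the shared gene set.

    ``metrics`` maps species name → per-gene metric series. Genes must be
    present (non-NaN) in every species; each species' vector is smoothed
    after restriction to that common set, so all vectors cover identical
    window supports.
    """
    if len(metrics) < 2:
        raise ValueError("need at least 2 species")
    common = None
    for s in metrics.values():
        idx = s.dropna().index
        common = idx if common is None else common.intersection(idx)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} genes shared by all species")
    first = order_genes(next(iter(metrics.values())).loc[common], order)
    symbols = first["gene_symbol"].tolist()
    rows = {}
    for sp, series in metrics.items():
        raw = series.loc[symbols].to_numpy(dtype=float)
        rows[sp] = sliding_window(raw, w=w)
    return pd.DataFrame.from_dict(rows, orient="index", columns=symbols)


def correlation_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r between species landscape vectors (unit diagonal)."""
    if m.shape[0] < 2 or m.shape[1] < 3:
        raise ValueError("need ≥ 2 species and ≥ 3 shared genes")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(m.to_numpy())
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=m.index, columns=m.index)


def distance_matrix(m: pd.DataFrame, mode: str = "euclidean") -> pd.DataFrame:
    """Species × species distances.

    ``euclidean``: d(i,j) = sqrt(Σ_g (m[i,g] − m[j,g])²) on the smoothed
    vectors. ``one-minus-r``: 1 − Pearson correlation.
    """
    if mode == "euclidean":
        d = squareform(pdist(m.to_numpy(), metric="euclidean"))
    elif mode == "one-minus-r":
        d = 1.0 - correlation_matrix(m).to_numpy()
        np.fill_diagonal(d, 0.0)
    else:
        raise ValueError(f"unknown distance mode {mode!r}")
    return pd.DataFrame(d, index=m.index, columns=m.index)


@dataclass
class ClusterResult:
    """Hierarchical clustering of a species distance matrix."""

    linkage_matrix: np.ndarray
    labels: list[str]
    method: str
    newick: str

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage_matrix)]


def hierarchical_cluster(d: pd.DataFrame, linkage: str = "average") -> ClusterResult:
    """Agglomerative clustering of a symmetric distance matrix.

    Returns the scipy linkage matrix plus a Newick tree whose branch
    lengths derive from merge heights (each node sits at half the merge
    distance under UPGMA-style linkages, so leaf-to-root path lengths are
    the cophenetic half-distances).
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    a = d.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(a), 0.0, atol=1e-8):
        raise ValueError("distance matrix diagonal must be zero")
    condensed = squareform(a, checks=False)
    z = hierarchy.linkage(condensed, method=linkage)
    labels = list(d.index)
    newick = linkage_to_newick(z, labels)
    return ClusterResult(linkage_matrix=z, labels=labels, method=linkage, newick=newick)


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string.

    Node heights are half the merge distances (ultrametric convention);
    branch lengths are height differences between parent and child.
    """
    tree = hierarchy.to_tree(z)

    def recurse(node, parent_height: float) -> str:
        height = node.dist / 2.0
        bl = parent_height - height
        if node.is_leaf():
            return f"{labels[node.id]}:{bl:.10g}"
        left = recurse(node.left, height)
        right = recurse(node.right, height)
        return f"({left},{right}):{bl:.10g}"

    root_height = tree.dist / 2.0
    left = recurse(tree.left, root_height)
    right = recurse(tree.right, root_height)
    return f"({left},{right});"


def compare_trees(newick_a: str, newick_b: str) -> dict:
    """Unrooted Robinson–Foulds distance and cophenetic correlation.

    Both trees must carry the same leaf set; a mismatch raises with the
    symmetric difference. The cophenetic correlation is the Pearson r
    between the two trees' leaf-to-leaf path-length matrices over all
    unordered leaf pairs.
    """
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    leaves1 = {x.taxon.label for x in t1.leaf_node_iter()}
    leaves2 = {x.taxon.label for x in t2.leaf_node_iter()}
    if leaves1 != leaves2:
        raise ValueError(
            f"leaf sets differ; symmetric difference: {sorted(leaves1 ^ leaves2)}"
        )
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
    labels = sorted(leaves1)
    pdm1 = t1.phylogenetic_distance_matrix()
    pdm2 = t2.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tns}
    d1, d2 = [], []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            d1.append(pdm1.patristic_distance(taxa[labels[i]], taxa[labels[j]]))
            d2.append(pdm2.patristic_distance(taxa[labels[i]], taxa[labels[j]]))
    if np.ptp(d1) == 0 or np.ptp(d2) == 0:
        coph = float("nan")
    else:
        coph, _ = stats.pearsonr(d1, d2)
    return {"robinson_foulds": int(rf), "cophenetic_r": float(coph)}


def heatmap_matrix(m: pd.DataFrame, species_order: list[str]) -> pd.DataFrame:
    """Rows permuted to dendrogram leaf order; columns stay in gene order."""
    missing = set(species_order) ^ set(m.index)
    if missing:
        raise ValueError(f"species order does not match matrix rows: {sorted(missing)}")
    return m.loc[species_order]
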