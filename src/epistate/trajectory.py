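"""Pseudotemporal ordering along a cluster chain and SOM co-expression modules.

Cells on a dedifferentiation trajectory (an ordered chain of clusters, e.g.
1-2-3-4) are projected onto the segments between consecutive cluster
medoids, concatenated into a pseudotemporal order, and each gene's z-scored
pseudotime profile is mapped onto a one-dimensional self-organizing map.
Neighbouring SOM nodes with highly correlated average profiles are merged
into modules of co-expressed genes; only modules with more than five member
profiles are retained.

Cells are embedded by their vector of distances to the cluster medoids, so
everything here is defined purely from the precomputed distance matrix.
Link significance uses a permutation stand-in (a simplification of the full
lineage-tree scoring of trajectory-inference tools): the number of
member-cluster cells whose nearest inter-medoid segment is the link,
compared against cluster-label shuffles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sc_expression import ClusterAssignment

logger = logging.getLogger("epistate")


@dataclass
class PseudotimeOrdering:
    """Cells in pseudotemporal order along a cluster chain.

    ``table`` has one row per ordered cell: cell index, cluster, assigned
    link (as "a-b"), and a projection coordinate in [0, 1] along that link
    (monotone within each link).  ``link_pvalues`` holds the permutation
    significance per link; links failing the threshold are flagged.
    """

    table: pd.DataFrame
    chain: tuple
    link_pvalues: dict
    flagged_links: list

    @property
    def cell_order(self) -> np.ndarray:
        return self.table["cell"].to_numpy()


@dataclass
class ModuleSet:
    """SOM node and module assignment per retained gene."""

    table: pd.DataFrame  # gene, node, module (NaN when the module was dropped)
    module_profiles: dict  # module id -> average z-profile

    def members(self, module_id) -> list:
        return self.table.loc[self.table["module"] == module_id, "gene"].tolist()


def _segment_projection(x, a, b):
    """Scalar projection of points x onto segment a->b, clipped to [0, 1]."""
    d = b - a
    denom = float(d @ d)
    if denom == 0:
        return np.zeros(len(x))
    return np.clip((x - a) @ d / denom, 0.0, 1.0)


def _point_segment_dist(x, a, b):
    t = _segment_projection(x, a, b)
    proj = a + t[:, None] * (b - a)
    return np.linalg.norm(x - proj, axis=1)


def order_cells_on_chain(dist: np.ndarray, clusters: ClusterAssignment,
                         chain, p_threshold: float = 0.05,
                         n_perm: int = 1000, seed: int = 0) -> PseudotimeOrdering:
    """Project chain-cluster cells onto inter-medoid segments and order them.

    Cells are embedded by their distance-to-medoid vectors.  A cell of the
    j-th chain cluster is assigned to the link from its medoid to the next
    chain medoid (the last cluster to the final link) with a coordinate in
    [0, 1] given by its clipped scalar projection; cells are ordered by
    (link, coordinate).  A cell sitting at its own medoid gets coordinate 0
    (or 1 for the last cluster); one equidistant between adjacent medoids
    gets 0.5.

    Link significance is a permutation stand-in: the observed count of
    member-cluster cells whose nearest chain segment is the link, compared
    with ``n_perm`` cluster-label shuffles.
    """
    chain = tuple(chain)
    if len(chain) < 2 or any(a == b for a, b in zip(chain, chain[1:])):
        raise ValueError("chain must list >= 2 distinct consecutive clusters")
    present = set(np.unique(clusters.labels))
    unknown = [c for c in chain if c not in present]
    if unknown:
        raise ValueError(f"chain references unknown clusters: {unknown}")

    D = np.asarray(dist, dtype=float)
    emb = D[:, clusters.medoids]  # distance-to-medoid embedding
    medpos = {c: emb[clusters.medoids[c - 1]] for c in chain}

    rows = []
    links = list(zip(chain[:-1], chain[1:]))
    for j, c in enumerate(chain):
        cells = np.flatnonzero(clusters.labels == c)
        if j < len(chain) - 1:
            link = links[j]
            a, b = medpos[chain[j]], medpos[chain[j + 1]]
        else:
            link = links[-1]
            a, b = medpos[chain[j - 1]], medpos[chain[j]]
        t = _segment_projection(emb[cells], a, b)
        for cell, coord in zip(cells, t):
            rows.append({"cell": int(cell), "cluster": int(c),
                         "link": f"{link[0]}-{link[1]}",
                         "link_index": links.index(link),
                         "coordinate": float(coord)})
    table = pd.DataFrame(rows).sort_values(
        ["link_index", "coordinate", "cell"], kind="stable").reset_index(drop=True)

    link_p = _link_significance(emb, clusters.labels, medpos, links,
                                n_perm=n_perm, seed=seed)
    flagged = [lk for lk, p in link_p.items() if p > p_threshold]
    if flagged:
        logger.warning("order_cells_on_chain: links failing p<=%.3g: %s",
                       p_threshold, flagged)
    return PseudotimeOrdering(table=table, chain=chain,
                              link_pvalues=link_p, flagged_links=flagged)


def _link_significance(emb, labels, medpos, links, n_perm, seed):
    chain_clusters = list(medpos)
    eligible = np.flatnonzero(np.isin(labels, chain_clusters))
    segs = [(medpos[a], medpos[b]) for a, b in links]
    seg_dist = np.stack([_point_segment_dist(emb[eligible], a, b)
                         for a, b in segs], axis=1)
    nearest = seg_dist.argmin(axis=1)

    def counts(lab):
        out = np.zeros(len(links))
        for i, (a, b) in enumerate(links):
            member = np.isin(lab[eligible], (a, b))
            out[i] = np.sum(member & (nearest == i))
        return out

    obs = counts(labels)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(links))
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        exceed += counts(lab) >= obs
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    return {f"{a}-{b}": float(p) for (a, b), p in zip(links, pvals)}


def filter_min_transcripts(adata, min_count: int = 3):
    """Keep genes observed with at least ``min_count`` transcripts in at
    least one cell.  Idempotent; raises when nothing survives."""
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    keep = np.asarray(X).max(axis=0) >= min_count
    if not keep.any():
        raise ValueError("min-transcript filter removed every gene")
    return adata[:, keep].copy()


def zscore_pseudotime_profiles(adata, ordering: PseudotimeOrdering) -> pd.DataFrame:
    """Genes x ordered-cells matrix of z-scored pseudotime profiles.

    Each gene's expression across the ordered cells is centred and scaled
    to unit sample standard deviation; constant genes are dropped with a
    warning.
    """
    order = ordering.cell_order
    if len(order) < 2:
        raise ValueError("need at least two ordered cells")
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    X = np.asarray(X, dtype=float)[order].T  # genes x ordered cells
    sd = X.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("zscore_pseudotime_profiles: dropped %d constant genes",
                       int(constant.sum()))
    X = X[~constant]
    sd = sd[~constant]
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    genes = np.asarray(adata.var_names)[~constant]
    return pd.DataFrame(Z, index=genes)


def fit_som1d(profiles, n_nodes: int = 1000, n_iter: int | None = None,
              seed: int = 0) -> pd.Series:
    """Train a 1D self-organizing map and assign each gene to its best node.

    Standard online SOM: node weights initialised from seeded random data
    rows, Gaussian neighbourhood with radius decaying linearly from
    ``n_nodes / 10`` to 1 and learning rate from 0.05 to 0.01 over
    ``n_iter`` updates (default 10x the number of profiles).  Returns a
    Series gene -> 1-based node index; deterministic for a fixed seed.
    """
    if isinstance(profiles, pd.DataFrame):
        index = profiles.index
        X = profiles.to_numpy(dtype=float)
    else:
        X = np.asarray(profiles, dtype=float)
        index = pd.RangeIndex(len(X))
    n, d = X.shape
    if n < 1:
        raise ValueError("need at least one profile")
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if n_nodes > 10 * n:
        logger.warning("fit_som1d: %d nodes for %d profiles (map will be sparse)",
                       n_nodes, n)
    if n_iter is None:
        n_iter = 10 * n
    rng = np.random.default_rng(seed)
    W = X[rng.integers(0, n, size=n_nodes)].astype(float)
    W += rng.normal(scale=1e-6, size=W.shape)  # break ties between identical draws
    node_pos = np.arange(n_nodes, dtype=float)
    r0, r1 = n_nodes / 10.0, 1.0
    lr0, lr1 = 0.05, 0.01
    for it in range(n_iter):
        frac = it / max(n_iter - 1, 1)
        radius = r0 + (r1 - r0) * frac
        lr = lr0 + (lr1 - lr0) * frac
        x = X[rng.integers(0, n)]
        bmu = int(((W - x) ** 2).sum(axis=1).argmin())
        h = np.exp(-0.5 * ((node_pos - bmu) / radius) ** 2)
        active = h > 1e-3
        W[active] += lr * h[active, None] * (x - W[active])
    assignment = ((X[:, None, :] - W[None, :, :]) ** 2).sum(axis=2).argmin(axis=1) + 1
    return pd.Series(assignment, index=index, name="node")


def merge_som_modules(assignment: pd.Series, profiles, r_threshold: float = 0.9,
                      min_size: int = 5) -> ModuleSet:
    """Merge neighbouring occupied SOM nodes into co-expression modules.

    Occupied nodes are scanned in topological order; the next node joins
    the current module when the Pearson correlation between the module's
    running-average profile and the node's average profile exceeds
    ``r_threshold``.  Only modules with strictly more than ``min_size``
    member profiles are retained (a module with exactly ``min_size``
    profiles is discarded).
    """
    if len(assignment) == 0:
        raise ValueError("empty SOM assignment")
    if isinstance(profiles, pd.DataFrame):
        P = profiles.loc[assignment.index].to_numpy(dtype=float)
    else:
        P = np.asarray(profiles, dtype=float)
    nodes = assignment.to_numpy()
    occupied = np.unique(nodes)
    node_avg = {int(nd): P[nodes == nd].mean(axis=0) for nd in occupied}

    modules: list[list[int]] = [[int(occupied[0])]]
    running = node_avg[int(occupied[0])].copy()
    count = int(np.sum(nodes == occupied[0]))
    for nd in occupied[1:]:
        nd = int(nd)
        avg = node_avg[nd]
        r = _pearson(running, avg)
        n_nd = int(np.sum(nodes == nd))
        if r > r_threshold:
            modules[-1].append(nd)
            running = (running * count + avg * n_nd) / (count + n_nd)
            count += n_nd
        else:
            modules.append([nd])
            running = avg.copy()
            count = n_nd
    module_of_node: dict[int, int] = {}
    retained_profiles = {}
    next_id = 1
    for mod_nodes in modules:
        member = np.isin(nodes, mod_nodes)
        if int(member.sum()) > min_size:
            for nd in mod_nodes:
                module_of_node[nd] = next_id
            retained_profiles[next_id] = P[member].mean(axis=0)
            next_id += 1
    table = pd.DataFrame({
        "gene": assignment.index,
        "node": nodes,
        "module": [module_of_node.get(int(nd), np.nan) for nd in nodes],
    })
    logger.info("merge_som_modules: %d modules retained (of %d candidates)",
                next_id - 1, len(modules))
    return ModuleSet(table=table, module_profiles=retained_profiles)


def _pearson(a, b):
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])
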