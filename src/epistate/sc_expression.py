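"""Single-cell expression pipeline.

Cells are normalised by downsampling every cell to a fixed transcript total,
compared with a 1 - Spearman correlation distance, clustered by k-medoids
(PAM), with the cluster number chosen as the smallest k whose clusters are
all bootstrap-stable (Jaccard similarity > 0.6).  Per-cell transcriptome
entropy quantifies how unfocused a cell's expression program is: mature
cells dominated by a few identity genes score low, dedifferentiated cells
with flat transcriptomes score high.

Cell matrices are AnnData objects (cells x genes, integer UMI counts);
outlier detection is intentionally absent (the upstream method's outlier
probability threshold set to zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import rankdata

logger = logging.getLogger("epistate")


def _dense(adata) -> np.ndarray:
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    return np.asarray(X)


@dataclass
class ClusterAssignment:
    """k-medoids result: 1-based labels, medoid cell indices, objective."""

    labels: np.ndarray  # (n,) ints in {1..k}
    medoids: np.ndarray  # (k,) cell indices
    objective: float
    k: int
    jaccard: pd.DataFrame | None = field(default=None)  # per-k stability table


def downsample_cells(adata, target: int = 5000, seed: int = 0):
    """Normalise by subsampling every cell to exactly ``target`` transcripts.

    Cells with fewer than ``target`` total transcripts are removed (logged);
    the rest are subsampled without replacement so every retained cell's
    total is exactly ``target``.  In expectation a gene's downsampled count
    is its original count scaled by ``target / total``.
    """
    if target <= 0:
        raise ValueError("target must be positive")
    X = _dense(adata).astype(np.int64)
    totals = X.sum(axis=1)
    keep = totals >= target
    if not keep.any():
        raise ValueError("all cells fall below the downsampling target")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("downsample_cells: removed %d cells below %d transcripts",
                    n_drop, target)
    rng = np.random.default_rng(seed)
    out = adata[keep].copy()
    Xk = X[keep]
    new = np.empty_like(Xk)
    for i in range(Xk.shape[0]):
        if totals[keep][i] == target:
            new[i] = Xk[i]
        else:
            new[i] = rng.multivariate_hypergeometric(Xk[i], target)
    out.X = new
    return out


def spearman_distance(adata_or_matrix, gene_subset=None) -> np.ndarray:
    """Cells x cells distance matrix d(i,j) = 1 - Spearman rho.

    Ranks use average-rank tie handling.  A constant cell vector has an
    undefined correlation; its distances are set to 1 with a warning.
    """
    if hasattr(adata_or_matrix, "X"):
        X = _dense(adata_or_matrix)
        if gene_subset is not None:
            idx = adata_or_matrix.var_names.get_indexer(list(gene_subset))
            X = X[:, idx[idx >= 0]]
    else:
        X = np.asarray(adata_or_matrix, dtype=float)
        if gene_subset is not None:
            X = X[:, np.asarray(gene_subset)]
    if X.shape[0] < 2:
        raise ValueError("need at least two cells")
    ranks = rankdata(X, axis=1)
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("spearman_distance: %d constant cells; distance set to 1",
                       int(constant.sum()))
        ranks[constant] += np.arange(ranks.shape[1]) * 1e-9  # avoid nan; overwritten below
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    D = 1.0 - rho
    D[constant, :] = 1.0
    D[:, constant] = 1.0
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


# ---------------------------------------------------------------------------
# PAM k-medoids
# ---------------------------------------------------------------------------

def _pam_build(D: np.ndarray, k: int) -> np.ndarray:
    """Greedy BUILD initialisation: repeatedly add the medoid that most
    decreases the total distance to the nearest medoid."""
    n = D.shape[0]
    medoids = [int(D.sum(axis=1).argmin())]
    curr = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(curr[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -1.0
        best = int(gains.argmax())
        medoids.append(best)
        curr = np.minimum(curr, D[best])
    return np.array(medoids)


def _pam_run(D: np.ndarray, medoids: np.ndarray, max_iter: int = 100):
    """Alternate assignment and medoid update until the objective stops
    decreasing."""
    n = D.shape[0]
    medoids = medoids.copy()
    prev_obj = np.inf
    for _ in range(max_iter):
        assign = D[:, medoids].argmin(axis=1)
        obj = float(D[np.arange(n), medoids[assign]].sum())
        if obj >= prev_obj:
            break
        prev_obj = obj
        for c in range(len(medoids)):
            members = np.flatnonzero(assign == c)
            if len(members):
                sub = D[np.ix_(members, members)]
                medoids[c] = members[int(sub.sum(axis=1).argmin())]
    assign = D[:, medoids].argmin(axis=1)
    obj = float(D[np.arange(n), medoids[assign]].sum())
    return assign, medoids, obj


def cluster_kmedoids(dist: np.ndarray, k: int, seed: int = 0,
                     n_restarts: int = 3) -> ClusterAssignment:
    """PAM k-medoids on a precomputed distance matrix.

    The first restart uses the deterministic greedy BUILD initialisation;
    further restarts use random seeded medoid draws.  The best (lowest)
    objective wins.  Labels are 1-based.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError("k must be between 1 and the number of cells")
    best = None
    for r in range(n_restarts):
        if r == 0:
            init = _pam_build(D, k)
        else:
            init = np.random.default_rng(seed + r).choice(n, size=k, replace=False)
        assign, medoids, obj = _pam_run(D, np.asarray(init))
        if best is None or obj < best[2]:
            best = (assign, medoids, obj)
    assign, medoids, obj = best
    return ClusterAssignment(labels=assign + 1, medoids=medoids, objective=obj, k=k)


def _match_jaccard(ref_labels: np.ndarray, boot_labels: np.ndarray,
                   k_ref: int, k_boot: int) -> np.ndarray:
    """Match bootstrap clusters to reference clusters by maximum overlap
    (Hungarian assignment), then return the per-reference-cluster Jaccard
    similarity."""
    overlap = np.zeros((k_ref, k_boot))
    for i in range(k_ref):
        for j in range(k_boot):
            overlap[i, j] = np.sum((ref_labels == i + 1) & (boot_labels == j + 1))
    ri, ci = linear_sum_assignment(-overlap)
    jac = np.zeros(k_ref)
    for i, j in zip(ri, ci):
        a = ref_labels == i + 1
        b = boot_labels == j + 1
        union = np.sum(a | b)
        jac[i] = overlap[i, j] / union if union else 0.0
    return jac


def select_cluster_number(dist: np.ndarray, k_range, n_boot: int = 50,
                          threshold: float = 0.6, seed: int = 0):
    """Choose k by bootstrap cluster stability.

    For each candidate k, cells are resampled with replacement ``n_boot``
    times, reclustered, matched to the reference clustering by maximal
    overlap, and a per-cluster Jaccard similarity recorded.  The chosen k is
    the smallest with all per-cluster mean Jaccard > ``threshold``; if none
    qualifies, the k maximising the minimum Jaccard is returned (documented
    fallback).  Returns ``(chosen_k, table)`` with one row per (k, cluster).
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if np.allclose(D, 0):
        raise ValueError("degenerate (all-zero) distance matrix")
    if n_boot < 10:
        raise ValueError("n_boot must be >= 10")
    rng = np.random.default_rng(seed)
    rows = []
    chosen = None
    fallback = (None, -1.0)
    for k in k_range:
        if not 2 <= k <= n - 1:
            raise ValueError("k_range must lie within [2, n_cells - 1]")
        ref = cluster_kmedoids(D, k, seed=seed)
        jac_sum = np.zeros(k)
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)  # with replacement, multiplicities kept
            sub = cluster_kmedoids(D[np.ix_(idx, idx)], k, seed=seed)
            jac_sum += _match_jaccard(ref.labels[idx], sub.labels, k, k)
        jac = jac_sum / n_boot
        for c in range(k):
            rows.append({"k": k, "cluster": c + 1, "jaccard": jac[c]})
        if chosen is None and (jac > threshold).all():
            chosen = k
        if jac.min() > fallback[1]:
            fallback = (k, jac.min())
    table = pd.DataFrame(rows)
    if chosen is None:
        logger.warning("select_cluster_number: no k passed the stability "
                       "threshold; falling back to max-min Jaccard")
        chosen = fallback[0]
    return chosen, table


# ---------------------------------------------------------------------------
# Entropy and geneset summaries
# ---------------------------------------------------------------------------

def cell_entropy(adata_or_matrix, clusters=None):
    """Shannon entropy of each cell's transcript fraction distribution.

    For a cell with gene fractions p_g over its nonzero genes the entropy is
    ``-sum p_g ln p_g`` (natural log, no normalisation by gene count).  A
    cell with all transcripts in one gene scores 0; a uniform cell over G
    genes scores ln G.  Requires equal-total (downsampled) cells for
    between-cell comparability.  With cluster labels supplied, per-cluster
    medians are returned as well.
    """
    X = _dense(adata_or_matrix) if hasattr(adata_or_matrix, "X") \
        else np.asarray(adata_or_matrix, dtype=float)
    totals = X.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("all-zero cell has undefined entropy")
    p = X / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
    ent = pd.Series(ent, name="entropy")
    if clusters is None:
        return ent
    medians = ent.groupby(np.asarray(clusters)).median()
    medians.index.name = "cluster"
    return ent, medians


def geneset_cluster_means(adata, clusters, geneset, relative: bool = True):
    """Mean normalised expression of a gene set per cell and per cluster.

    ``relative`` divides each cluster mean by the grand mean over all cells,
    so identical clusters score 1.  Raises if the gene set does not
    intersect the matrix genes.
    """
    genes = [g for g in geneset if g in adata.var_names]
    if not genes:
        raise ValueError("gene set does not intersect the matrix genes")
    idx = adata.var_names.get_indexer(genes)
    per_cell = _dense(adata)[:, idx].mean(axis=1)
    per_cell = pd.Series(per_cell, name="geneset_mean")
    cl = pd.Series(np.asarray(clusters), name="cluster")
    cluster_means = per_cell.groupby(cl.values).mean()
    cluster_means.index.name = "cluster"
    if relative:
        grand = per_cell.mean()
        if grand == 0:
            raise ValueError("gene set unexpressed in every cell")
        cluster_means = cluster_means / grand
    return per_cell, cluster_means
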