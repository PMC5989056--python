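"""Chromatin-state-stratified expression statistics.

The central intersection of the pipeline: genes are grouped by the chromatin
state of their genebody, and expression variation is summarised per state
across single-cell clusters, disease conditions, and a continuous clinical
trait (an HbA1c-like glycemic covariate) in a bulk cohort.  Bivalent
Polycomb-silenced states are the expected outliers: their genes are
derepressed in disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("epistate")


@dataclass
class CohortExpression:
    """Samples x genes normalised (log-scale) expression with a per-sample
    continuous trait and per-gene state labels."""

    expression: pd.DataFrame  # samples x genes
    trait: pd.Series  # per sample
    gene_states: pd.Series | None = None  # gene -> state label

    def __post_init__(self):
        if not np.isfinite(self.trait.to_numpy(dtype=float)).all():
            raise ValueError("trait values must be finite")
        if not self.expression.index.equals(self.trait.index):
            raise ValueError("expression and trait sample indices differ")


def _dense(adata) -> np.ndarray:
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    return np.asarray(X, dtype=float)


def _state_gene_lists(gene_state_table: pd.DataFrame) -> dict[int, list[str]]:
    return {int(s): sub["gene_id"].tolist()
            for s, sub in gene_state_table.groupby("genebody_state")}


def state_cluster_cv(adata, clusters, gene_state_table: pd.DataFrame) -> pd.DataFrame:
    """Coefficient of variation of per-gene mean expression, per state and
    cluster.

    For each state s and cluster c, every state-s gene's mean normalised
    expression over the cells of c is computed; the CV is the sample
    standard deviation over those gene means divided by their mean.  Genes
    with zero mean in the cluster are excluded (logged); a state with fewer
    than two expressed genes gets a missing value.  The CV is invariant to a
    global rescaling of the matrix.
    """
    X = _dense(adata)
    cl = np.asarray(clusters)
    states = _state_gene_lists(gene_state_table)
    gidx = {g: i for i, g in enumerate(adata.var_names)}
    rows = []
    for s, genes in sorted(states.items()):
        cols = [gidx[g] for g in genes if g in gidx]
        for c in np.unique(cl):
            means = X[np.ix_(cl == c, cols)].mean(axis=0)
            expressed = means[means > 0]
            n_zero = len(means) - len(expressed)
            if n_zero:
                logger.debug("state_cluster_cv: state %s cluster %s: %d "
                             "zero-mean genes excluded", s, c, n_zero)
            cv = (expressed.std(ddof=1) / expressed.mean()
                  if len(expressed) >= 2 else np.nan)
            rows.append({"state": s, "cluster": c, "n_genes": len(expressed),
                         "cv": cv})
    return pd.DataFrame(rows)


def state_condition_diff(adata, clusters, condition_labels, gene_state_table,
                         conditions: tuple[str, str] = ("Ctrl", "HFD")) -> pd.DataFrame:
    """Disease-minus-control difference in mean gene expression per state and
    cluster, on a log1p scale.

    For state s in cluster c: the mean over state-s genes of
    (mean log1p expression in ``conditions[1]`` cells of c) minus (the same
    in ``conditions[0]`` cells).  Clusters lacking one condition yield a
    missing value (logged).  Swapping the two condition names negates the
    statistic.
    """
    X = np.log1p(_dense(adata))
    cl = np.asarray(clusters)
    cond = np.asarray(condition_labels)
    ref, dis = conditions
    states = _state_gene_lists(gene_state_table)
    gidx = {g: i for i, g in enumerate(adata.var_names)}
    rows = []
    for s, genes in sorted(states.items()):
        cols = [gidx[g] for g in genes if g in gidx]
        for c in np.unique(cl):
            sel_d = (cl == c) & (cond == dis)
            sel_r = (cl == c) & (cond == ref)
            if not sel_d.any() or not sel_r.any():
                logger.info("state_condition_diff: cluster %s lacks a "
                            "condition; missing value", c)
                diff = np.nan
            else:
                diff = float((X[np.ix_(sel_d, cols)].mean(axis=0)
                              - X[np.ix_(sel_r, cols)].mean(axis=0)).mean())
            rows.append({"state": s, "cluster": c, "diff": diff})
    return pd.DataFrame(rows)


def map_orthologs(mapping: pd.DataFrame, gene_state_table: pd.DataFrame) -> pd.DataFrame:
    """Transfer state labels across species along 1:1 orthologs.

    ``mapping`` is a two-column table (source gene id, target gene id).
    Genes involved in 1:many or many:many pairings are dropped (count
    logged); unmapped targets carry no state label.  Returns a gene-state
    table over target gene ids.
    """
    if len(mapping) == 0:
        raise ValueError("empty ortholog mapping")
    src_col, tgt_col = mapping.columns[:2]
    m = mapping[[src_col, tgt_col]].drop_duplicates()
    src_counts = m[src_col].value_counts()
    tgt_counts = m[tgt_col].value_counts()
    one2one = m[m[src_col].map(src_counts).eq(1) & m[tgt_col].map(tgt_counts).eq(1)]
    n_dropped = len(m) - len(one2one)
    if n_dropped:
        logger.info("map_orthologs: dropped %d non-1:1 ortholog pairs", n_dropped)
    merged = one2one.merge(gene_state_table, left_on=src_col, right_on="gene_id")
    out = merged[[tgt_col, "genebody_state", "tss_state"]].rename(
        columns={tgt_col: "gene_id"})
    return out.reset_index(drop=True)


def gene_trait_slopes(cohort: CohortExpression) -> pd.Series:
    """Ordinary least-squares slope of each gene's expression on the trait."""
    x = cohort.trait.to_numpy(dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 samples")
    xc = x - x.mean()
    ssx = float(xc @ xc)
    if ssx == 0:
        raise ValueError("trait does not vary")
    Y = cohort.expression.to_numpy(dtype=float)
    slopes = (xc @ (Y - Y.mean(axis=0))) / ssx
    return pd.Series(slopes, index=cohort.expression.columns, name="slope")


def state_trait_regression(cohort: CohortExpression,
                           state_sets: dict | None = None) -> pd.DataFrame:
    """Per-state summary of gene-wise expression-on-trait regressions.

    Each member gene is regressed on the trait by OLS; a state is summarised
    by the median of its member-gene slopes and a two-sided one-sample
    t-test of those slopes against zero, with Benjamini-Hochberg correction
    across states.  States with fewer than 3 genes present in the expression
    matrix are skipped with a warning.
    """
    if state_sets is None:
        if cohort.gene_states is None:
            raise ValueError("no state labels supplied")
        state_sets = {s: idx.tolist() for s, idx in
                      cohort.gene_states.groupby(cohort.gene_states).groups.items()}
    slopes = gene_trait_slopes(cohort)
    rows = []
    for s in sorted(state_sets):
        members = [g for g in state_sets[s] if g in slopes.index]
        if len(members) < 3:
            logger.warning("state_trait_regression: state %s has < 3 genes; skipped", s)
            continue
        sl = slopes[members].to_numpy()
        t, p = stats.ttest_1samp(sl, 0.0)
        rows.append({"state": s, "n_genes": len(members),
                     "slope": float(np.median(sl)), "t": float(t), "p": float(p)})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def count_up_down(de: pd.DataFrame, p_threshold: float = 0.05,
                  fc_threshold: float = 2.0) -> tuple[int, int]:
    """Count significantly up-/downregulated genes at the stated thresholds.

    Up: adjusted p strictly below ``p_threshold`` and fold change strictly
    above ``fc_threshold``; down analogously below ``1/fc_threshold``.
    Boundary values are excluded.  ``de`` needs ``log2fc`` and ``padj``
    columns.
    """
    for col in ("log2fc", "padj"):
        if col not in de.columns:
            raise ValueError(f"DE table lacks required column {col!r}")
    lfc = de["log2fc"].to_numpy(dtype=float)
    padj = de["padj"].to_numpy(dtype=float)
    thr = np.log2(fc_threshold)
    sig = padj < p_threshold
    return int(np.sum(sig & (lfc > thr))), int(np.sum(sig & (lfc < -thr)))


def marked_vs_unmarked_change(de: pd.DataFrame, marked_set) -> dict:
    """Compare fold-change distributions of marked vs unmarked genes.

    Returns the median log2 fold change of each group, their difference
    (marked minus unmarked), and the two-sided rank-sum (Mann-Whitney) p
    value.  ``de`` must have ``gene_id`` and ``log2fc`` columns; both groups
    must be non-empty.
    """
    marked_set = set(marked_set)
    in_set = de["gene_id"].isin(marked_set).to_numpy()
    marked = de.loc[in_set, "log2fc"].to_numpy(dtype=float)
    unmarked = de.loc[~in_set, "log2fc"].to_numpy(dtype=float)
    if len(marked) == 0 or len(unmarked) == 0:
        raise ValueError("both marked and unmarked groups must be non-empty")
    stat, p = stats.mannwhitneyu(marked, unmarked, alternative="two-sided")
    med_m, med_u = float(np.median(marked)), float(np.median(unmarked))
    return {"median_marked": med_m, "median_unmarked": med_u,
            "shift": med_m - med_u, "p": float(p)}
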