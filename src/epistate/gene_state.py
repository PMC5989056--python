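"""Assigning chromatin states to genes and per-gene signal features.

A decoded state track is intersected with gene models to give each gene a
genebody state (the state with maximum bp coverage over the gene), a TSS
state (the state of the bin containing the TSS), and a full state-coverage
vector.  Peak-breadth ranking and TSS area-under-curve scoring identify the
exceptionally broadly marked lineage-defining genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import StateTrack

logger = logging.getLogger("epistate")

AUTOSOMES = frozenset(
    [str(i) for i in range(1, 20)] + [f"chr{i}" for i in range(1, 20)]
)
DEFAULT_BIOTYPES = frozenset({"protein_coding", "lincRNA", "antisense"})


@dataclass(frozen=True)
class GeneModel:
    """A gene interval, stored 0-based half-open."""

    gene_id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"
    basic: bool = True

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        """Transcription start: leftmost base on +, rightmost on -."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


def load_gene_models(gtf_path, allowed_biotypes=DEFAULT_BIOTYPES,
                     require_basic: bool = True,
                     allowed_chroms=AUTOSOMES) -> list[GeneModel]:
    """Read gene features from a GTF and apply the standard filters.

    Keeps genes with an allowed biotype (protein_coding / lincRNA /
    antisense by default), carrying the "basic" tag, on the allowed
    chromosomes (mouse autosomes 1-19 by default; pass ``None`` to disable a
    filter).  GTF 1-based closed coordinates are converted to 0-based
    half-open.  Counts of filtered genes are logged.
    """
    import gffutils

    genes: list[GeneModel] = []
    dropped = {"biotype": 0, "basic": 0, "chrom": 0}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            if line.rstrip("\n").count("\t") < 7:
                raise ValueError(f"malformed GTF line {lineno}: fewer than 8 fields")
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:
                raise ValueError(f"malformed GTF line {lineno}: {exc}") from exc
            if feat.featuretype != "gene":
                continue
            attrs = feat.attributes
            biotype = (attrs.get("gene_biotype") or attrs.get("gene_type") or [""])[0]
            basic = "basic" in (attrs.get("tag") or [])
            if allowed_biotypes is not None and biotype not in allowed_biotypes:
                dropped["biotype"] += 1
                continue
            if require_basic and not basic:
                dropped["basic"] += 1
                continue
            if allowed_chroms is not None and feat.seqid not in allowed_chroms:
                dropped["chrom"] += 1
                continue
            genes.append(GeneModel(
                gene_id=(attrs.get("gene_id") or [f"line{lineno}"])[0],
                name=(attrs.get("gene_name") or attrs.get("gene_id") or [""])[0],
                chrom=feat.seqid, start=feat.start - 1, end=feat.end,
                strand=feat.strand, biotype=biotype, basic=basic,
            ))
    logger.info("load_gene_models: kept %d genes (dropped %s)", len(genes), dropped)
    return genes


def assign_gene_states(genes: list[GeneModel], states: StateTrack) -> pd.DataFrame:
    """Per-gene state-coverage vector, genebody state, and TSS state.

    Coverage of each state is the fraction of genebody bp overlapping bins
    of that state (partial bins weighted by overlap).  The genebody state is
    the argmax of the coverage vector, ties broken to the lowest state
    index; the TSS state is the state of the bin containing the TSS.  Genes
    with no overlap with the segmented region are excluded with a warning.
    Returns a DataFrame with ``cov_state_{k}`` columns summing to 1 per row.
    """
    K = states.K
    bsz = states.bins.bin_size
    chrom_len = states.bins.length
    rows = []
    n_skipped = 0
    for g in genes:
        if g.chrom != states.bins.chrom or g.start >= chrom_len or g.end <= 0:
            n_skipped += 1
            continue
        start, end = max(g.start, 0), min(g.end, chrom_len)
        first, last = start // bsz, (end - 1) // bsz
        cov = np.zeros(K)
        for b in range(first, last + 1):
            ov = min(end, (b + 1) * bsz) - max(start, b * bsz)
            cov[states.states[b] - 1] += ov
        cov /= cov.sum()
        tss_state = (int(states.states[g.tss // bsz])
                     if 0 <= g.tss < chrom_len else int(np.argmax(cov)) + 1)
        rows.append({"gene_id": g.gene_id, "name": g.name,
                     "genebody_state": int(np.argmax(cov)) + 1,
                     "tss_state": tss_state,
                     **{f"cov_state_{k + 1}": cov[k] for k in range(K)}})
    if n_skipped:
        logger.warning("assign_gene_states: excluded %d genes with no overlap",
                       n_skipped)
    return pd.DataFrame(rows)


def gene_state_vector_matrix(table: pd.DataFrame) -> np.ndarray:
    """Genes x K row-normalized state-coverage matrix (embedding input)."""
    if len(table) == 0:
        raise ValueError("empty gene-state table")
    cols = [c for c in table.columns if c.startswith("cov_state_")]
    mat = table[cols].to_numpy(dtype=float)
    return mat / mat.sum(axis=1, keepdims=True)


def peak_breadth_rank(peaks: pd.DataFrame, genes: list[GeneModel],
                      tss_window: int = 500) -> pd.DataFrame:
    """Per-gene TSS-associated peak breadth with a descending rank.

    Breadth is the start-to-end length of the widest called peak overlapping
    TSS +/- ``tss_window``; genes without an overlapping peak get breadth 0.
    Rank 1 is the broadest; ties share the minimum rank.  Peak input order
    does not affect the result.
    """
    from scipy.stats import rankdata

    if tss_window < 0:
        raise ValueError("tss_window must be nonnegative")
    pstart = peaks["start"].to_numpy(dtype=np.int64)
    pend = peaks["end"].to_numpy(dtype=np.int64)
    pchrom = peaks["chrom"].to_numpy() if "chrom" in peaks.columns else None
    rows = []
    for g in genes:
        lo, hi = g.tss - tss_window, g.tss + tss_window + 1
        ok = (pstart < hi) & (pend > lo)
        if pchrom is not None:
            ok &= pchrom == g.chrom
        breadth = int((pend[ok] - pstart[ok]).max()) if ok.any() else 0
        rows.append({"gene_id": g.gene_id, "name": g.name, "breadth": breadth})
    df = pd.DataFrame(rows)
    df["rank"] = rankdata(-df["breadth"], method="min").astype(int)
    return df.sort_values(["rank", "gene_id"], kind="stable").reset_index(drop=True)


def top_broad_geneset(ranked: pd.DataFrame, top_pct: float = 2.0,
                      exclude=()) -> list[str]:
    """Top ``top_pct`` percent of genes by peak breadth.

    Excluded names (e.g. expression outliers such as Ins1/Ins2) are removed
    before taking the slice, so an exclusion inside the top slice is
    replaced by the next-ranked gene.  Set size is
    ``ceil(top_pct/100 * n_remaining)``.
    """
    if not 0 < top_pct <= 100:
        raise ValueError("top_pct must be in (0, 100]")
    if len(ranked) == 0:
        raise ValueError("empty ranked table")
    kept = ranked[~ranked["name"].isin(set(exclude))]
    n_top = math.ceil(top_pct / 100.0 * len(kept))
    return kept.sort_values(["rank", "gene_id"], kind="stable")["name"].head(n_top).tolist()


def tss_auc(coverage: np.ndarray, gene: GeneModel, flank: int = 100,
            library_size: int = 1_000_000) -> float:
    """Depth-normalised signal area under the curve at TSS +/- ``flank`` nt.

    Sums per-bp coverage over the ``2*flank + 1`` bp window and scales to
    counts per million (1e6 / library_size).  Windows extending past the
    chromosome are truncated with a warning.
    """
    if flank < 0:
        raise ValueError("flank must be nonnegative")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    lo, hi = gene.tss - flank, gene.tss + flank + 1
    if lo < 0 or hi > len(coverage):
        logger.warning("tss_auc: window truncated for %s", gene.gene_id)
        lo, hi = max(lo, 0), min(hi, len(coverage))
    return float(coverage[lo:hi].sum()) * 1e6 / library_size


def metagene_profile(coverage: np.ndarray, genes: list[GeneModel],
                     upstream: int = 2000, body_bins: int = 100,
                     downstream: int = 2000, library_size: int = 1_000_000,
                     flank_bin_size: int = 50) -> np.ndarray:
    """Average strand-oriented TSS-to-TES profile over a gene set.

    Flanks are averaged in fixed ``flank_bin_size`` bp bins; the genebody is
    rescaled to ``body_bins`` points by linear interpolation (genes shorter
    than ``body_bins`` bp are interpolated up, and logged).  Minus-strand
    genes are reversed before averaging; values are in mean coverage per bp,
    scaled to counts per million.  The profile of a union of gene sets is
    the size-weighted mean of the per-set profiles.
    """
    if len(genes) == 0:
        raise ValueError("metagene_profile needs at least one gene")
    n_up = upstream // flank_bin_size
    n_down = downstream // flank_bin_size
    L = len(coverage)
    profiles = []
    for g in genes:
        body = coverage[max(g.start, 0):min(g.end, L)].astype(float)
        if len(body) < body_bins:
            logger.info("metagene_profile: %s shorter than body_bins; interpolating",
                        g.gene_id)
        xp = np.linspace(0.0, 1.0, num=len(body))
        body_prof = np.interp(np.linspace(0.0, 1.0, num=body_bins), xp, body)
        up = _flank_bins(coverage, g.start - upstream, g.start, n_up, flank_bin_size)
        down = _flank_bins(coverage, g.end, g.end + downstream, n_down, flank_bin_size)
        prof = np.concatenate([up, body_prof, down])
        if g.strand == "-":
            prof = prof[::-1]
        profiles.append(prof)
    return np.mean(profiles, axis=0) * 1e6 / library_size


def _flank_bins(coverage, lo, hi, n_bins, bin_size):
    out = np.zeros(n_bins)
    L = len(coverage)
    for i in range(n_bins):
        a, b = lo + i * bin_size, lo + (i + 1) * bin_size
        a2, b2 = max(a, 0), min(b, L)
        if b2 > a2:
            out[i] = coverage[a2:b2].sum() / bin_size
    return out
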