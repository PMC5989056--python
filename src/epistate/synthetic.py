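"""Synthetic data generator with known ground truth.

Emulates the statistical structure of the study's inputs so every pipeline
stage is testable without external data:

* a hidden-state genome (Markov chain over chromatin states) emitting
  overdispersed (negative binomial) histone-mark counts per 200 bp bin plus
  a per-CpG %methylation table;
* gene models placed (mostly) inside state-homogeneous runs, so the true
  genebody/TSS states are known;
* clustered UMI count matrices in which designated "disease" clusters
  derepress the bivalent-state gene program and lose the identity program;
* a bulk cohort whose genes respond to a continuous HbA1c-like trait with
  state-specific slopes (positive, by default, only for the bivalent state).

Defaults reflect the study conditions: 3 ground-truth states standing for
active (A-like), bivalent (M-like) and silent (S-like) chromatin; 5 marks;
~300 cells in 5 clusters with disease cells enriched in the
dedifferentiated clusters; a 62-sample cohort (11 diabetic-range + 51
non-diabetic-range trait values).  All draws are reproducible for a fixed
seed.  Truth labels are returned (and serialised) alongside the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gene_state import GeneModel
from .segmentation import GenomeBins, StateTrack, TrackMatrix
from .state_integration import CohortExpression

logger = logging.getLogger("epistate")

DEFAULT_MARKS = ("H3K4me3", "H3K27ac", "H3K27me3", "Pol2", "H3K9me3")

# expected counts per 200 bp bin per mark; rows = states A (active),
# M (bivalent), S (silent)
DEFAULT_EMISSION_MEANS = np.array([
    [25.0, 18.0, 1.0, 12.0, 1.0],   # active: promoter/enhancer marks + Pol2
    [15.0, 2.0, 12.0, 1.0, 1.0],    # bivalent: H3K4me3 + H3K27me3, no Pol2
    [0.5, 0.5, 2.0, 0.5, 6.0],      # silent: heterochromatin
])
DEFAULT_TRANSITION = np.array([
    [0.90, 0.05, 0.05],
    [0.05, 0.90, 0.05],
    [0.05, 0.05, 0.90],
])
# mean %methylation per state: active genebodies moderately methylated,
# bivalent domains accessible/unmethylated, silent background methylated
DEFAULT_METH_LEVELS = (70.0, 5.0, 95.0)

# per-cluster multipliers on the gene programs; each sub-type carries its
# own marker program (as distinct beta-cell sub-states do), and clusters 4
# and 5 are the dedifferentiated ("disease") clusters that derepress the
# bivalent program and lose the identity program
DEFAULT_CLUSTER_PROFILES = {
    1: {"identity": 1.2, "bivalent": 0.05, "marker_1": 8.0},
    2: {"identity": 1.0, "bivalent": 0.05, "marker_2": 8.0},
    3: {"identity": 0.6, "bivalent": 0.10, "marker_3": 8.0},
    4: {"identity": 0.15, "bivalent": 2.5, "marker_4": 8.0},
    5: {"identity": 0.10, "bivalent": 3.5, "marker_5": 8.0},
}
DEFAULT_CLUSTER_SIZES = {1: 100, 2: 90, 3: 50, 4: 35, 5: 25}
DEFAULT_DISEASE_PROB = {1: 0.30, 2: 0.30, 3: 0.40, 4: 0.85, 5: 0.95}


@dataclass
class SimulationSpec:
    """Ground-truth parameters for all generators.

    ``slope_per_state`` is the true effect of the trait on log-expression
    for genes of each state; by default only the bivalent state responds
    (positively), mirroring derepression of Polycomb-silenced genes with
    worsening glycemia.
    """

    n_bins: int = 20_000
    bin_size: int = 200
    K_true: int = 3
    transition: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITION.copy())
    emission_means: np.ndarray = field(default_factory=lambda: DEFAULT_EMISSION_MEANS.copy())
    dispersion: tuple = (8.0, 8.0, 8.0)
    meth_levels: tuple = DEFAULT_METH_LEVELS
    mark_names: tuple = DEFAULT_MARKS
    cpg_rate: float = 1.0 / 50.0  # CpGs per bp (Poisson-placed)
    meth_sd: float = 8.0
    chrom: str = "chrS"
    # single-cell block
    n_cells: int = 300
    cluster_profiles: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_CLUSTER_PROFILES.items()})
    cluster_sizes: dict = field(default_factory=lambda: dict(DEFAULT_CLUSTER_SIZES))
    disease_prob: dict = field(default_factory=lambda: dict(DEFAULT_DISEASE_PROB))
    depth_mean: float = 15_000.0
    cell_dispersion: float = 2.0
    # cohort block
    n_samples: int = 62
    trait_range: tuple = (4.0, 10.0)
    slope_per_state: tuple = (0.0, 0.05, 0.0)
    cohort_noise_sd: float = 0.5
    seed: int = 0

    def validate(self):
        A = np.asarray(self.transition, dtype=float)
        if A.shape != (self.K_true, self.K_true):
            raise ValueError("transition must be K x K")
        if np.abs(A.sum(axis=1) - 1.0).max() > 1e-12 or (A < 0).any():
            raise ValueError("transition matrix must be row-stochastic")
        M = np.asarray(self.emission_means, dtype=float)
        if M.shape[0] != self.K_true or (M < 0).any():
            raise ValueError("emission_means must be K x M and nonnegative")
        meth = np.asarray(self.meth_levels, dtype=float)
        if len(meth) != self.K_true or meth.min() < 0 or meth.max() > 100:
            raise ValueError("meth_levels must be K values in [0, 100]")
        if np.asarray(self.dispersion, dtype=float).min() <= 0:
            raise ValueError("dispersion must be positive")
        return self


def _rng(spec_seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec_seed, offset]))


# ---------------------------------------------------------------------------
# Genome track
# ---------------------------------------------------------------------------

def simulate_state_track(spec: SimulationSpec,
                         initial_state: int | None = None) -> StateTrack:
    """Sample the hidden chromatin-state chain over the binned genome.

    ``initial_state`` (1-based) fixes the first bin's state; by default it
    is drawn uniformly.
    """
    spec.validate()
    rng = _rng(spec.seed, 1)
    A = np.asarray(spec.transition, dtype=float)
    K = spec.K_true
    states = np.empty(spec.n_bins, dtype=int)
    states[0] = (initial_state - 1) if initial_state is not None \
        else rng.integers(0, K)
    cum = A.cumsum(axis=1)
    u = rng.random(spec.n_bins)
    for t in range(1, spec.n_bins):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t])
    bins = GenomeBins(chrom=spec.chrom, n_bins=spec.n_bins, bin_size=spec.bin_size)
    return StateTrack(bins=bins, states=states + 1)


def _nb_draw(rng, mean, size_param, shape):
    """Negative binomial with mean/size parameterisation (Poisson in the
    infinite-dispersion limit)."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), shape)
    if np.isinf(size_param):
        return rng.poisson(mean)
    p = size_param / (size_param + mean)
    out = np.zeros(shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(size_param, p[pos])
    return out


def simulate_tracks(state_track: StateTrack, spec: SimulationSpec):
    """Per-bin mark counts and a raw per-CpG methylation table.

    Mark counts are negative binomial with state-specific means and a
    shared per-state dispersion.  CpG sites are Poisson-placed (one per 50
    bp on average); their %methylation is drawn around the state mean and
    clipped to [0, 100].  Returns ``(TrackMatrix, cpg_table)``; the
    methylation channel of the TrackMatrix is left for
    :func:`epistate.segmentation.transform_methylation`.
    """
    spec.validate()
    if len(state_track.states) != spec.n_bins:
        raise ValueError("state track length does not match spec.n_bins")
    rng = _rng(spec.seed, 2)
    z = state_track.states - 1
    M = np.asarray(spec.emission_means, dtype=float)
    counts = np.zeros((spec.n_bins, M.shape[1]), dtype=np.int64)
    for k in range(spec.K_true):
        sel = z == k
        counts[sel] = _nb_draw(rng, M[k], float(np.asarray(spec.dispersion)[k]),
                               (int(sel.sum()), M.shape[1]))
    track = TrackMatrix(bins=state_track.bins, marks=list(spec.mark_names),
                        counts=counts)

    L = state_track.bins.length
    n_cpg = rng.poisson(spec.cpg_rate * L)
    pos0 = np.sort(rng.integers(0, L, size=n_cpg))
    state_at = z[pos0 // spec.bin_size]
    meth = np.clip(rng.normal(np.asarray(spec.meth_levels)[state_at], spec.meth_sd),
                   0.0, 100.0)
    coverage = 1 + rng.poisson(9, size=n_cpg)
    cpg = pd.DataFrame({"chrom": spec.chrom, "pos": pos0 + 1,
                        "meth": meth, "coverage": coverage})
    return track, cpg


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def simulate_gene_models(state_track: StateTrack, n_genes: int, seed: int = 0,
                         min_len_bins: int = 3, max_len_bins: int = 10,
                         frac_homogeneous: float = 0.9):
    """Place gene models on the simulated genome with known true states.

    A fraction ``frac_homogeneous`` of genes is placed wholly inside
    state-homogeneous runs (their true genebody and TSS state is the run's
    state); the rest are placed uniformly and may straddle boundaries
    (their truth is computed from bp-majority over the true track).
    Returns ``(genes, truth)`` where truth is a DataFrame with the true
    states and a ``homogeneous`` flag.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    bsz = state_track.bins.bin_size
    L = state_track.bins.length
    states = state_track.states

    # run-length encode the true track
    change = np.flatnonzero(np.diff(states)) + 1
    run_starts = np.concatenate([[0], change])
    run_ends = np.concatenate([change, [len(states)]])
    run_states = states[run_starts]
    long_enough = (run_ends - run_starts) >= min_len_bins + 1
    if not long_enough.any() or L < (min_len_bins + 1) * bsz:
        raise ValueError("genome too short to place genes")
    eligible = np.flatnonzero(long_enough)

    genes, truth_rows = [], []
    for i in range(n_genes):
        homogeneous = rng.random() < frac_homogeneous
        if homogeneous:
            r = eligible[rng.integers(0, len(eligible))]
            lo_bp, hi_bp = run_starts[r] * bsz, run_ends[r] * bsz
            max_len = min(max_len_bins * bsz, hi_bp - lo_bp - 1)
            length = int(rng.integers(min_len_bins * bsz, max_len + 1))
            start = int(rng.integers(lo_bp, hi_bp - length))
        else:
            length = int(rng.integers(min_len_bins * bsz, max_len_bins * bsz + 1))
            start = int(rng.integers(0, L - length))
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"SIMG{i:05d}"
        g = GeneModel(gene_id=gid, name=gid, chrom=state_track.bins.chrom,
                      start=start, end=end, strand=strand,
                      biotype="protein_coding", basic=True)
        genes.append(g)
        # bp-majority truth over the true track
        first, last = start // bsz, (end - 1) // bsz
        cov = np.zeros(state_track.K)
        for b in range(first, last + 1):
            ov = min(end, (b + 1) * bsz) - max(start, b * bsz)
            cov[states[b] - 1] += ov
        truth_rows.append({
            "gene_id": gid, "start": start, "end": end, "strand": strand,
            "true_genebody_state": int(np.argmax(cov)) + 1,
            "true_tss_state": int(states[g.tss // bsz]),
            "homogeneous": bool(homogeneous),
        })
    return genes, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Single cells
# ---------------------------------------------------------------------------

def derive_genesets(gene_state_table: pd.DataFrame, identity_state: int = 1,
                    bivalent_state: int = 2, n_identity: int = 8,
                    n_clusters: int = 5, n_marker: int = 25) -> dict:
    """Gene programs for the cell simulation, from the gene-state table.

    The identity set is a small subset of active-state genes (mirroring the
    eight mature-lineage transcription factors); the bivalent set is every
    bivalent-state gene; each cluster additionally gets a disjoint
    sub-type marker program (``marker_1`` .. ``marker_{n_clusters}``) drawn
    from the remaining genes, as distinct cell sub-states do.
    """
    active = gene_state_table.loc[
        gene_state_table["genebody_state"] == identity_state, "gene_id"].tolist()
    bivalent = gene_state_table.loc[
        gene_state_table["genebody_state"] == bivalent_state, "gene_id"].tolist()
    if not active or not bivalent:
        raise ValueError("gene-state table lacks active or bivalent genes")
    sets = {"identity": active[:n_identity], "bivalent": bivalent}
    taken = set(sets["identity"]) | set(bivalent)
    pool = [g for g in gene_state_table["gene_id"] if g not in taken]
    n_marker = max(1, min(n_marker, len(pool) // n_clusters))
    for c in range(1, n_clusters + 1):
        sets[f"marker_{c}"] = pool[(c - 1) * n_marker:c * n_marker]
    return sets


def simulate_cells(gene_state_table: pd.DataFrame, spec: SimulationSpec,
                   genesets: dict | None = None):
    """Clustered UMI count matrix with truth labels.

    Cells belong to one of the specified clusters; the dedifferentiated
    ("disease"-enriched) clusters express the bivalent program at elevated
    multipliers and the identity program at reduced multipliers.  Identity
    genes carry a high baseline (an insulin-like dominance), so mature
    clusters have focused, low-entropy transcriptomes and dedifferentiated
    clusters flat, high-entropy ones.  Counts are negative binomial around
    each cell's cluster-specific expected profile.  Returns an AnnData with
    ``obs['true_cluster']`` and ``obs['condition']`` ("Ctrl"/"HFD").
    """
    import anndata as ad

    spec.validate()
    if len(spec.cluster_profiles) < 2:
        raise ValueError("need at least 2 clusters")
    if genesets is None:
        genesets = derive_genesets(gene_state_table)
    if any(len(v) == 0 for v in genesets.values()):
        raise ValueError("empty genesets")
    rng = _rng(spec.seed, 3)
    gene_ids = gene_state_table["gene_id"].tolist()
    n_genes = len(gene_ids)
    set_of_gene = {}
    for name, members in genesets.items():
        for g in members:
            set_of_gene[g] = name

    # baseline rates: lognormal background, identity genes strongly expressed
    base = rng.lognormal(mean=1.0, sigma=1.0, size=n_genes)
    for j, g in enumerate(gene_ids):
        if set_of_gene.get(g) == "identity":
            base[j] = rng.lognormal(mean=5.0, sigma=0.3)

    clusters = sorted(spec.cluster_profiles)
    sizes = np.array([spec.cluster_sizes.get(c, 0) for c in clusters], dtype=float)
    probs = sizes / sizes.sum()
    labels = rng.choice(clusters, size=spec.n_cells, p=probs)

    X = np.zeros((spec.n_cells, n_genes), dtype=np.int64)
    conditions = np.empty(spec.n_cells, dtype=object)
    for i in range(spec.n_cells):
        c = int(labels[i])
        mult = spec.cluster_profiles[c]
        lam = base.copy()
        for j, g in enumerate(gene_ids):
            m = mult.get(set_of_gene.get(g, "other"), 1.0)
            lam[j] *= m
        depth = max(int(rng.normal(spec.depth_mean, spec.depth_mean / 8)), 1000)
        mu = lam / lam.sum() * depth
        X[i] = _nb_draw(rng, mu, spec.cell_dispersion, (n_genes,))
        conditions[i] = "HFD" if rng.random() < spec.disease_prob.get(c, 0.5) else "Ctrl"

    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame({"true_cluster": labels.astype(int),
                          "condition": conditions},
                         index=[f"cell{i:04d}" for i in range(spec.n_cells)]),
        var=pd.DataFrame({"biotype": "protein_coding"}, index=gene_ids),
    )
    adata.uns["genesets"] = {k: list(v) for k, v in genesets.items()}
    return adata


# ---------------------------------------------------------------------------
# Bulk cohort
# ---------------------------------------------------------------------------

def simulate_cohort(gene_state_table: pd.DataFrame, spec: SimulationSpec) -> CohortExpression:
    """Bulk cohort with a continuous trait and state-specific slopes.

    Per-gene log-expression is baseline + slope_per_state[state] * trait +
    Gaussian noise.  Trait values emulate the cohort design: with the
    default 62 samples, 51 fall in the non-diabetic range (lower ~40% of
    ``trait_range``) and 11 in the diabetic range (upper part); other
    sample sizes spread the trait uniformly.
    """
    spec.validate()
    lo, hi = spec.trait_range
    if not lo < hi:
        raise ValueError("degenerate trait_range")
    if spec.n_samples < 4:
        raise ValueError("need at least 4 samples")
    rng = _rng(spec.seed, 4)
    n = spec.n_samples
    if n == 62:
        healthy = rng.uniform(lo, lo + 0.4 * (hi - lo), size=51)
        diabetic = rng.uniform(lo + 0.5 * (hi - lo), hi, size=11)
        trait = np.concatenate([healthy, diabetic])
    else:
        trait = rng.uniform(lo, hi, size=n)
    samples = [f"S{i:03d}" for i in range(n)]
    gene_ids = gene_state_table["gene_id"].tolist()
    states = gene_state_table["genebody_state"].to_numpy()
    slopes = np.asarray(spec.slope_per_state, dtype=float)[states - 1]
    baseline = rng.normal(5.0, 1.0, size=len(gene_ids))
    noise = (rng.normal(0.0, spec.cohort_noise_sd, size=(n, len(gene_ids)))
             if spec.cohort_noise_sd > 0 else 0.0)
    Y = baseline[None, :] + np.outer(trait, slopes) + noise
    expr = pd.DataFrame(Y, index=samples, columns=gene_ids)
    return CohortExpression(
        expression=expr,
        trait=pd.Series(trait, index=samples, name="trait"),
        gene_states=pd.Series(states, index=gene_ids, name="state"),
    )
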