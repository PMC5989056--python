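# Methods

`epistate` implements an integrated epigenome–transcriptome analysis for
studies of β-cell dysfunction: chromatin-state segmentation of binned
histone-mark signal with a DNA-methylation channel, assignment of states to
genes, chromatin-state-stratified single-cell and cohort expression
statistics, pseudotemporal co-expression modules, and peak-breadth/TSS
signal scoring. Every stage is exercised end-to-end on a bundled synthetic
generator with known ground truth.

## Chromatin-state segmentation

Signal is summarised in fixed-width genome bins (default 200 bp). Fragments
are assigned to exactly one bin — the bin containing the fragment midpoint —
and replicate tracks are averaged element-wise and rounded half-up, so bin
counts stay integers.

DNA methylation enters as an extra count-like column. For each bin we take
the CpGs in a 600 bp window centred on the bin (bin ± 200 bp; the window
advances by one bin width), compute the median %methylation, and invert and
scale it: `round(scale · (100 − median)/100)` with `scale = 10` by default.
Accessible, unmethylated regions (promoters, bivalent domains) therefore
score high while the methylated genomic background scores 0; windows with no
CpG coverage also score 0, consistent with a fully methylated background.
The transform is monotone decreasing in the median and invariant to CpG
order. The scale constant only sets the dynamic range of the channel
relative to the mark counts; it is configurable.

The segmentation model is a K-state hidden Markov model over the binned
channels. Emissions are per-state **negative multinomial**: the per-bin
total count follows a negative binomial with state-specific mean μ_k and
size (dispersion) r_k, and is split across channels by state-specific
proportions. This captures the overdispersion of ChIP-seq bin counts while
coupling channels through a shared per-bin intensity. An
independent-Poisson-per-channel emission is selectable (`emission="poisson"`).

Fitting is Baum–Welch EM with a Rabiner-scaled forward–backward pass.
Details that matter:

* **Initialisation** — k-means on log1p counts seeds the state means; three
  EM restarts with different k-means seeds are run and the best final
  log-likelihood kept (EM converges to local optima).
* **Dispersion M-step** — r_k is updated by 1-D bounded maximisation of the
  expected complete-data log-likelihood (bounds 1e-3..1e8 on r). A
  moment-matching update would be cheaper but does not guarantee the EM
  ascent property; the numeric M-step keeps the per-iteration
  log-likelihood non-decreasing, which the tests assert.
* **Numerics** — per-bin emission rows are max-shifted before
  exponentiation; scaled probabilities are floored at 1e-300. A bin that is
  impossible under every state (positive count in a channel whose mean is
  exactly zero) makes the forward log-likelihood −∞, returned as a sentinel.
* **Decoding** — the default is the per-bin argmax of the forward–backward
  marginals (posterior decoding), because downstream statistics are per-bin
  coverage fractions; the Viterbi path is available. Argmax ties break to
  the lowest state index for determinism.
* **Convergence** — relative log-likelihood change below `tol` (default
  1e-6) or `max_iter`. An all-zero track with K > 1 converges to a
  degenerate model; this is logged, not raised.

On simulated 3-state genomes of 20,000 bins (five marks plus methylation,
generator defaults) posterior decoding recovers >99% of bins after Hungarian
label matching and per-state emission means within a few percent; the
acceptance thresholds (90% / 10%) are deliberately loose relative to this.

## Gene-state assignment and signal features

Gene models come from GTF (1-based closed, converted internally to 0-based
half-open) and are filtered the way the segmentation consumers expect:
biotypes protein_coding / lincRNA / antisense, the "basic" annotation tag,
autosomes 1–19. Each filter is optional.

Per gene we compute the fraction of genebody bp covered by each state
(partial bins weighted by overlap, which removes bin-phase artefacts for
short genes). The **genebody state** is the argmax of this vector (ties to
the lowest state index); the **TSS state** is the state of the bin holding
the TSS (leftmost base on +, rightmost on −). Genes simulated inside
state-homogeneous runs are recovered exactly.

**Peak breadth** is the start-to-end length of a called peak; a gene's
TSS-associated breadth is the widest peak overlapping TSS ± 500 bp (window
configurable; the widest-peak rule resolves multi-peak TSSs
deterministically). Ranks descend from the broadest, ties sharing the
minimum rank. The top-2% slice is taken after removing excluded names
(expression outliers such as Ins1/Ins2), so an exclusion inside the slice is
replaced by the next-ranked gene and the set size is
`ceil(pct · n_remaining)`.

**TSS AUC** sums per-bp coverage over TSS ± 100 nt and scales by
1e6/library size (counts per million), making it invariant to proportional
changes of coverage and depth. **Metagene profiles** average strand-oriented
per-gene profiles: flanks in fixed 50 bp bins, genebody linearly rescaled to
a fixed number of points; the profile of a union of gene sets is the
size-weighted mean of the per-set profiles.

## Single-cell pipeline

Cells are normalised by downsampling to a fixed total (default 5,000
transcripts) without replacement (multivariate hypergeometric); cells below
the target are removed, because entropy and geneset means are only
comparable between equal-total cells. In expectation each gene's
downsampled count is its original count × target/total.

Cell–cell distance is 1 − Spearman correlation over genes (average-rank
ties; a constant cell gets distance 1 with a warning). Clustering is PAM
k-medoids on the precomputed distance matrix: greedy BUILD initialisation
plus two random-restart inits, then alternating assignment/medoid updates
until the objective stops decreasing.

The cluster number is chosen by bootstrap stability: cells are resampled
with replacement (multiplicities kept), reclustered, matched to the
reference clustering by maximum-overlap Hungarian assignment, and a
per-cluster Jaccard similarity recorded; the chosen k is the smallest whose
clusters all average Jaccard > 0.6, falling back to the k maximising the
minimum Jaccard when none qualifies. **Known limitation:** this
minimum-k rule identifies the finest stable partition only when coarser
partitions are ambiguous. If the data carry a strong hierarchical
super-structure — e.g. a dominant mature-vs-dedifferentiated axis on top of
five sub-types — the coarse split is itself bootstrap-stable and the rule
stops there. The selection tests therefore use equidistant planted clusters,
where under-merged partitions flip between bootstrap samples and score well
below the threshold while the true k scores ≈ 1.

Per-cell **transcriptome entropy** is −Σ p_g ln p_g over the cell's nonzero
gene fractions (natural log, no normalisation by gene count — the upstream
literature does not print the formula, so the plain Shannon form is the
documented default). It is 0 for a single-gene cell, ln G for a uniform
cell, and higher in unfocused, dedifferentiated transcriptomes than in
mature cells dominated by identity genes. Geneset summaries report per-cell
mean normalised expression over a gene set, per-cluster means, and
"relative" values (cluster mean / grand mean). Outlier detection is
intentionally absent.

## State-stratified integration

All statistics are invariant to cluster-label and gene-order permutations.

* **Per-state CV across clusters** — for state s and cluster c, each
  state-s gene's mean normalised expression over the cells of c is taken;
  the CV is the sample sd over those gene means divided by their mean
  (zero-mean genes excluded; fewer than two expressed genes → missing).
  Computed across gene means (not cells), which is the documented default
  where the axis is ambiguous.
* **Condition differences** — disease-minus-control difference of per-gene
  mean expression, averaged over the state's genes, on a log1p scale
  (stabilises heavy-tailed UMI means). Swapping condition labels negates
  the statistic.
* **Ortholog transfer** — state labels cross species only along 1:1
  ortholog pairs; 1:many and many:many pairs are dropped with a logged
  count.
* **Trait regression** — each gene's (log-scale) expression is regressed on
  the continuous trait (HbA1c-like) by OLS; a state is summarised by the
  median member-gene slope and a two-sided one-sample t-test of member
  slopes against zero, BH-corrected across states. This per-gene-then-
  aggregate scheme was chosen because the summary reported per state is "a
  slope with a significance"; with independent gene noise the t-test is
  exact, and the type-I error at α = 0.05 measures 5 ± 1% over 1,000 null
  cohorts. States with fewer than 3 genes are skipped.
* **DE counting** — up/down counts use strict inequalities at adjusted
  p < 0.05 and fold change beyond ±2; boundary genes are excluded.
  Marked-vs-unmarked comparisons report group medians of log2 fold change,
  their difference, and a two-sided Mann–Whitney p. DE tables are consumed
  as input, never fitted here.

## Pseudotime and SOM modules

Cells of an ordered cluster chain are embedded by their vector of distances
to the cluster medoids (defined purely from the distance matrix). Each cell
is assigned to one link — the segment from its cluster's medoid to the next
chain medoid (the last cluster to the final link) — with a coordinate in
[0, 1] given by its clipped scalar projection; the output order sorts by
(link, coordinate), so coordinates are monotone within each link and reset
at link boundaries. A cell at its own medoid gets coordinate 0; one
equidistant between adjacent medoids gets 0.5.

Link significance is a permutation stand-in for full lineage-tree scoring
(which is out of scope): the observed number of member-cluster cells whose
nearest chain segment is the link, compared against cluster-label shuffles
(default 1,000, seed-controlled); links with p above 0.05 are flagged.

Gene modules: genes seen with ≥3 transcripts in ≥1 cell are kept; each
gene's expression across the ordered cells is z-scored (constant genes
dropped); profiles are mapped onto a 1,000-node one-dimensional
self-organizing map (online training, Gaussian neighbourhood, radius
decaying linearly from n_nodes/10 to 1, learning rate 0.05 → 0.01, 10×
n_profiles updates, seeded random-row initialisation — conventional
settings, all configurable). Neighbouring occupied nodes are merged into a
module while the Pearson correlation between the module's running-average
profile and the next node's average exceeds 0.9 (the running average gives
chained merges a stable reference); only modules with strictly more than 5
member profiles are retained. On planted rising/falling programs the
retained modules separate the programs with 100% membership purity in the
bundled experiments.

## The synthetic generator

The generator emulates the statistical structure of the study's inputs; its
defaults are the study conditions, fixed once:

* **Genome** — a single chromosome ("chrS") of 20,000 × 200 bp bins; a
  3-state Markov chain (self-transition 0.9) standing for active (A-like),
  bivalent (M-like) and silent (S-like) chromatin; five marks (H3K4me3,
  H3K27ac, H3K27me3, Pol2, H3K9me3) with state means chosen to mimic the
  respective mark classes; negative-binomial counts with per-state size 8.
  CpGs are Poisson-placed at one per 50 bp (so the 600 bp median window sees
  realistic sparsity) with %methylation Normal(state mean, 8) clipped to
  [0, 100]: 70 for active genebodies, 5 for accessible bivalent domains, 95
  for silent background.
* **Genes** — 90% placed wholly inside state-homogeneous runs (truth =
  run state), the rest uniformly (truth = bp-majority over the true track);
  lengths 3–10 bins, random strand.
* **Cells** — 300 cells in five sub-types with paper-like size imbalance
  (100/90/50/35/25) and mean depth 15,000 UMIs; an identity program (8
  active-state genes with insulin-like dominant baselines), the bivalent
  program (all bivalent-state genes), and one disjoint marker program per
  sub-type. Dedifferentiated clusters 4–5 express the bivalent program at
  2.5–3.5× and the identity program at 0.10–0.15×, and are enriched for the
  disease condition (HFD probability 0.85–0.95 vs 0.30 in mature clusters).
  The marker programs are required for the sub-types to be separable at
  all; without them no clustering method can tell the planted sub-types
  apart, and the simulation would not emulate the five-sub-type structure
  it stands in for.
* **Cohort** — 62 samples; with the default size, 51 trait values fall in
  the lower (non-diabetic-like) range and 11 in the upper (diabetic-like)
  range of 4–10, matching the cohort design; per-gene log-expression is
  baseline + slope(state) · trait + N(0, 0.5), with a positive slope (0.05
  per trait unit) only for bivalent-state genes by default.

What the generator does **not** emulate: raw reads and fragment-length
effects, copy-number artefacts, doublets, batch effects, cell-cycle
structure, zero-inflation beyond the NB, or inter-gene expression
correlation within programs. Passing tests therefore demonstrate
correctness of the algorithms under the stated noise models, not robustness
to every artefact of real data.

## Problem sizes in the bundled experiments

The test suite and `scripts/acceptance.py` run the genome at 20,000 bins,
cells at 300, the cohort at 62 samples with 1,000 null replicates, the
SOM at 1,000 nodes over 120-gene gradient data, and stability selection at
8 × 25 cells — sizes chosen so each experiment's Monte-Carlo error is well
inside the asserted margins while the whole suite runs in a couple of
minutes.
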