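# epistate

Chromatin-state segmentation and chromatin-state-stratified transcriptome
analysis for studies of β-cell dysfunction and dedifferentiation.

Loss of cell identity in type 2 diabetes leaves chromatin-level
fingerprints: bivalent, Polycomb-silenced domains (H3K4me3 + H3K27me3,
accessible but transcriptionally quiescent) become ectopically active, while
an epigenomically distinctive class of broadly marked lineage genes loses
expression. Detecting these signatures requires joining several analyses
that are usually run separately, and `epistate` packages that chain:

* **Segmentation** — a K-state hidden Markov model over binned histone-mark
  counts (200 bp bins) with a transformed DNA-methylation channel appended
  as an extra column. Emissions are per-state negative multinomial: the bin
  total is negative binomial with state mean μ_k and dispersion r_k, split
  across channels by state-specific proportions. Fitting is Baum–Welch EM;
  decoding is posterior (max-marginal) or Viterbi. The methylation channel
  is the inverted, scaled median %methylation of a 600 bp sliding window —
  `round(10 · (100 − median)/100)` — so accessible unmethylated loci score
  high and the methylated background scores 0.
* **Gene states** — each gene gets a state-coverage vector over its
  genebody (bp-weighted), a genebody state (argmax), and a TSS state;
  plus TSS-associated peak-breadth rankings and depth-normalised TSS ± 100
  nt area-under-curve scores that flag broadly marked lineage genes.
* **Single cells** — downsampling normalisation to 5,000 transcripts per
  cell, 1 − Spearman k-medoids (PAM) clustering with bootstrap-Jaccard
  cluster-number selection (> 0.6 stability rule), per-cell transcriptome
  entropy −Σ p ln p, and geneset/cluster summaries.
* **Integration** — per-state expression CV across clusters, disease-minus-
  control differences, 1:1 ortholog state transfer, per-state OLS regression
  of cohort expression on a continuous HbA1c-like trait (median member-gene
  slope + one-sample t-test, BH-corrected), and DE up/down counting at
  adjusted p < 0.05 and ±2-fold.
* **Trajectories** — pseudotemporal ordering of cells along a cluster chain
  by projection onto inter-medoid segments, and co-expression modules from a
  1,000-node 1D self-organizing map over z-scored pseudotime profiles,
  merging neighbouring nodes at Pearson r > 0.9 and keeping modules with
  more than 5 profiles.
* **Synthetic data** — a generator producing every input with known ground
  truth (hidden-state genome, overdispersed mark counts, per-CpG
  methylation, gene models, clustered UMI matrices with a derepressed
  bivalent program in disease cells, and a trait-sloped bulk cohort), so the
  whole pipeline is testable without external data.

See `docs/methods.md` for the models, defaults, and their rationale.

## Worked example

```python
import epistate as es

spec = es.SimulationSpec(seed=1)                 # study-condition defaults
truth = es.simulate_state_track(spec)            # hidden 3-state genome
track, cpg = es.simulate_tracks(truth, spec)     # mark counts + CpG table
track.meth_channel = es.transform_methylation(cpg, track.bins)

model = es.fit_hmm(track, K=3, seed=1)           # Baum-Welch EM
decoded = es.decode_states(model, track)         # posterior decoding
# manual annotation from the emissions: K4me3+K27me3 together = bivalent M,
# K4me3/K27ac/Pol2 = active A, K9me3 = silent S
print(es.emission_summary(model, track.channel_names, {1: "M", 2: "S", 3: "A"}).round(1))
```

```
      label  H3K4me3  H3K27ac  H3K27me3  Pol2  H3K9me3  meth
state
1         M     15.0      2.0      12.0   1.0      1.0   9.2
2         S      0.5      0.5       2.0   0.5      6.1   0.7
3         A     25.0     18.0       1.0  11.9      1.0   3.0
```

EM has recovered the three chromatin classes: state 1 carries H3K4me3 and
H3K27me3 together with a high (unmethylated) methylation-channel score —
the bivalent signature; state 3 is the active class; state 2 the silent,
methylated background. Continuing through the transcriptome stages:

```python
genes, gene_truth = es.simulate_gene_models(truth, 500, seed=1)
table = es.assign_gene_states(genes, truth)      # per-gene genebody/TSS state

cells = es.simulate_cells(table, spec)           # 300 cells, 5 sub-types
norm = es.downsample_cells(cells, target=5000, seed=1)
D = es.spearman_distance(norm)
clusters = es.cluster_kmedoids(D, 5, seed=1)
ent, med = es.cell_entropy(norm, clusters.labels)
print(med.round(2))

cohort = es.simulate_cohort(table, spec)         # 62 samples, HbA1c-like trait
print(es.state_trait_regression(cohort).round(4).to_string(index=False))
```

```
cluster
1    4.20
2    5.17
3    4.31
4    5.26
5    4.70
Name: entropy, dtype: float64
 state  n_genes  slope       t      p      q
     1      162 0.0102  2.0935 0.0379 0.0568
     2      166 0.0542 16.8455 0.0000 0.0000
     3      172 0.0009  0.2987 0.7655 0.7655
```

Two of the five recovered cell clusters (here 2 and 4, the simulated
dedifferentiated sub-types) show clearly elevated median transcriptome
entropy — the unfocused-expression signature of identity loss. In the
62-sample cohort, only bivalent-state genes (state 2 of the generator's
truth labelling) rise significantly with the glycemic trait (median slope
0.054 per trait unit, q < 1e-30 after BH), recovering the planted
derepression while the other states stay at baseline.

A thin CLI mirrors the pipeline (`epistate simulate`, `segment`,
`genestate`, `breadth`, `sc-cluster`, `sc-entropy`, `integrate`,
`pseudotime`, `modules`); run `epistate --help`.

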