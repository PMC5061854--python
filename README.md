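# benthonet

Co-occurrence network analysis of chronically PAH-impacted coastal sediment
microbiomes.

Coastal sediments receive chronic inputs of polycyclic aromatic hydrocarbons
(PAHs), mostly pyrogenic (combustion-derived) material arriving by
atmospheric deposition. `benthonet` is a pipeline for asking, from an OTU
count table, a taxonomy table and per-sample chemistry, whether such
contamination restructures the benthic microbial community: which taxa form
an environmentally structured *core* community, how those taxa co-occur
across the three domains of life, and whether networks built from
contaminated sediments are structurally degraded relative to pristine ones.
It is aimed at microbial ecologists working with amplicon surveys of
contaminated habitats, and ships a synthetic community generator with
planted ground truth so every stage can be validated by recovery
experiments.

## Methods at a glance

- **Contamination classification** — samples are clustered (Ward HAC on
  Euclidean distances of log10(x+1) 11-compound PAH profiles, per region);
  the cluster with the higher Σ PAH₉ is *contaminated*. Diagnostic source
  ratios (P/A = phenanthrene/anthracene, F/P = fluoranthene/pyrene; P/A < 10
  and F/P > 1 ⇒ pyrogenic), sediment-quality-guideline exceedance (PEL /
  ERL / T50, user-supplied thresholds), and Wilcoxon–Mann–Whitney group
  comparisons.
- **Core/satellite partition** — for each OTU with counts *x₁…x_n* over
  samples, the index of dispersion is VMR × occurrence, where
  VMR = s²/x̄ (variance-to-mean ratio) and occurrence is the number of
  samples with *x* > 0. Under Poisson (random) dispersal the statistic
  falls inside the central 95% band of a χ² distribution (df = occurrence
  by default); OTUs above the 97.5% limit are *core*, all others
  *satellite*.
- **Association network** — all-pairs Spearman ρ among core OTUs
  (prevalence-filtered); edges where |ρ| ≥ 0.6 and p < 0.001, sign kept as
  an attribute.
- **Null models** — checkerboard C-score
  C_ij = (R_i − S_ij)(R_j − S_ij) averaged over OTU pairs, compared with
  5000 null matrices preserving per-site richness;
  SES = (obs − null mean)/null sd, with |SES| ≤ 2 the chance band.
- **Topology & modules** — Louvain modularity modules; average degree
  (2E/N), average local clustering, modularity Q, average shortest path on
  the largest component, log–log degree-distribution diagnostic; paired
  contaminated vs pristine network comparison with per-node rank-sum
  tests.
- **Module–environment** — each module summarized by its eigengene (first
  right-singular vector of the standardized OTU × sample matrix),
  correlated with (transformed) environmental variables; PERMANOVA
  (sequential pseudo-F on Gower-centered Bray–Curtis distances, free
  permutations) partitions community variance among predictors.

## Worked example

Simulate the default 42-sample community (120 core OTUs in 6 modules, 900
satellites, half the sites contaminated at 20× PAH) and run the full
pipeline:

```
$ benthonet simulate --seed 3 --out sim/
wrote 1020 OTUs x 42 samples to sim

$ benthonet run --counts sim/counts.tsv --taxonomy sim/taxonomy.tsv \
      --meta sim/meta.tsv --out results/
INFO classify_sites_hac: 22 contaminated / 20 pristine
INFO partition: 122 core / 898 satellite OTUs; core reads 98.9%
INFO edge_table: prevalence filter kept 120/122 OTUs (>= 25% of samples)
INFO build: network with 119 nodes, 903 edges
completed stages: contamination, sad_partition, association, nullmodels, network, module_env
```

What the numbers mean: the dispersion test recovers essentially the 120
planted core OTUs (122 called, i.e. two satellites leak past the 97.5%
χ² limit); the co-occurrence network over them has 119 nodes and 903
edges organized into modules (modularity Q ≈ 0.78). The C-score SES for
this community is **−4.16** (p_less ≈ 0.003): strongly *negative*, i.e.
more co-occurrence than chance — as expected for a community whose core
is driven by shared environmental gradients and planted consortia. In
`env_correlations.tsv` the planted PAH-sensitive consortium is the module
whose eigengene correlates negatively with fluoranthene
(r = −0.69, p = 3.6 × 10⁻⁷), and `permanova.tsv` attributes ~10% of
Bray–Curtis community variance to salinity and ~7% to fluoranthene.

Each stage is also available standalone (`benthonet partition`,
`network`, `nullmodel`, `classify`, `simulate`) and as plain library
calls (`benthonet.partition`, `benthonet.edge_table`, `benthonet.ses`,
`benthonet.permanova`, ...).

## Layout

```
src/benthonet/
  io_core.py              tables, config, rarefaction, GraphML, pipeline driver
  synthetic_community.py  generator with planted ground truth
  contamination.py        PAH sums, ratios, SQG, HAC classification
  sad_partition.py        dispersion-index core/satellite partition
  association.py          Spearman edge inference
  nullmodels.py           C-score, null matrices, SES
  network.py              graph build, modules, topology, group comparison
  module_env.py           eigengenes, environment correlation, PERMANOVA
  cli.py                  `benthonet` command group
docs/methods.md           model/assumption notes
```
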