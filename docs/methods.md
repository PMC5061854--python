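# Methods notes

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions a maintainer would need to
reproduce results exactly.

## Core/satellite partition

For OTU counts x₁…x_n across samples, the dispersion statistic is
VMR × occurrence with VMR = s²/x̄ (unbiased n−1 variance over **all**
samples, zeros included; VMR ≡ 0 when x̄ = 0). The statistic is compared
to the (2.5%, 97.5%) quantiles of χ² with df equal to the occurrence by
default; `occurrence_minus_1` and `n_samples_minus_1` (the classical
index-of-dispersion convention) are selectable in `PipelineConfig`. An
OTU is *core* iff its statistic exceeds the upper limit; OTUs inside the
band or below the lower limit (underdispersed) are both *satellite* — the
partition is binary. Records with df < 1 after the convention (all-zero
OTUs) are forced satellite with a warning.

A known tension in the field's usage of this test: descriptions of
random dispersal sometimes place Poisson taxa *between* both limits and
sometimes *below the 2.5% limit line*. We use the upper limit as the
core boundary and classify everything else satellite, which makes the
two readings operationally identical.

Under a pure Poisson table the core-call rate estimates the upper-tail
mass (≈2.5%); simulation at λ ∈ {2, 5, 20} over 42 samples gives rates
slightly below the nominal mass (the statistic's χ² reference is
approximate for finite λ), around 2.3–2.9% at λ = 5.

## PAH chemistry and contamination classification

Σ PAH₉ sums the nine guideline-covered compounds (fluoranthene, pyrene,
anthracene, benz[a]anthracene, benzo[a]pyrene, chrysene,
dibenz[a,h]anthracene, fluorene, phenanthrene), excluding
benzo[g,h,i]perylene and indeno[1,2,3,c-d]pyrene. Guideline (PEL / ERL /
T50) thresholds are **not** hard-coded: they are licensed tabulations
that vary by jurisdiction, so they are user configuration, compared by
strict inequality (a sum exactly at the threshold does not exceed).

Sites are labeled by agglomerative clustering of 11-compound profiles cut
at k = 2, independently per region so that regional environmental
differences do not masquerade as contamination. Ward linkage on Euclidean
distances of log10(x+1) concentrations is the default: concentrations are
heavy-tailed over orders of magnitude and the log makes the labels
invariant to uniform rescaling. Both linkage and transform are config
knobs recorded in the run manifest. The cluster with the higher mean
Σ PAH₉ is *contaminated*.

Collinearity grouping connects variables with |Spearman ρ| ≥ 0.75
("collinearity up to 0.75" read as a magnitude threshold, strictness
configurable) and picks per-group proxies by highest mean |ρ| to the
group, with manual override (e.g. fluoranthene for the PAH block,
salinity for the salinity/latitude/temperature block).

The Mann–Whitney U comparison uses exact enumeration when both groups
have n ≤ 8 without ties, otherwise the normal approximation with tie
correction.

## Association edges

Spearman ρ with average ranks; two-sided p by the t approximation for
n > 9 and exact permutation enumeration for n ≤ 9. The edge gate is
|ρ| ≥ 0.6 **and** p < 0.001. The threshold is applied to |ρ| — negative
edges (predation, exclusion) are biologically central to the
PAH-sensitive consortium motif, so they are retained and the sign kept
as an edge attribute. No multiple-testing correction is applied by
default (the stringent joint gate is the filter); a Benjamini–Hochberg
mode exists but is off. A prevalence filter (presence in ≥ 25% of
samples, configurable) precedes correlation, which trades sensitivity
for specificity on sparse profiles. Correlations are computed on
(rarefied) counts, not relative abundances; rank correlations on
compositional data carry a residual closure bias that this pipeline does
not correct (SparCC-style inference is out of scope).

## C-score null models

C_ij = (R_i − S_ij)(R_j − S_ij) per OTU pair; the community score is the
mean over unordered pairs, and the normalized variant divides each pair
by R_i R_j (its maximum given the occupancies), giving a 0–1 scale;
pairs with an all-absent member are skipped there. The normalization is
a stated convention of this package.

"Preserving site frequencies" is implemented as fixed per-site (column)
totals with presences reassigned to equiprobable rows — sampled exactly
uniformly over the reachable set (verified by exhaustive enumeration on
small matrices). Alternatives: `fixed_occupancies` (row totals) and
`swap` (both margins, sequential 2×2 checkerboard swaps, default 10 ×
presences attempts). SES = (obs − μ_null)/σ_null; p-values use the
add-one estimator p = (1 + #{null ≥ obs})/(1 + n_null), so p > 0 always
and p_greater + p_less ≥ 1. A degenerate null ensemble (σ = 0) yields
SES = NaN with a warning rather than ±∞.

## Network topology and comparison

Modules come from Louvain modularity maximization on the unweighted,
sign-ignored graph (the convention of common network GUIs), numbered by
decreasing size, deterministic given the seed. Topology reports
average degree 2E/N, average local clustering (degree < 2 counts 0),
modularity Q of the partition, average shortest path on the largest
connected component (the choice for disconnected graphs is ours and is
documented here), and a descriptive log–log regression of the degree
histogram as the scale-free diagnostic — deliberately not a maximum-
likelihood power-law fit.

The contaminated/pristine comparison **rebuilds** correlations within
each sample group over the same core OTU set (rather than inducing
subgraphs of the pooled network), because group-specific covariation is
exactly what contamination is hypothesized to disrupt. Per-node degree
and clustering distributions are compared by two-sided rank-sum tests at
p < 0.05; this significance convention is this package's, since no
standard exists.

## Module eigengenes and PERMANOVA

OTU profiles are standardized (zero mean, unit variance across samples;
constant rows dropped), and the eigengene is the first right-singular
vector, sign-oriented to correlate positively with the module's mean
standardized profile so heat-map signs are reproducible. Variance
explained is s₁²/Σs². Eigengene–environment correlations are Pearson on
transformed variables (defaults: log salinity, log fluoranthene, squared
F/P — the transforms that linearize those predictors); Spearman is
selectable.

PERMANOVA operates on the Gower-centered matrix G = −½ J D² J with a
sequential (ordered-entry) decomposition via projection hat matrices:
SS(term k) = tr((H_k − H_{k−1}) G), pseudo-F = (SS_k/df_k)/(SS_res/df_res),
p by free (unrestricted) permutation of sample identities with the
add-one estimator. Terms are complete-case filtered (n is logged);
categorical terms are dummy-coded. Term + residual R² sum to 1 by
construction. Community distances are Bray–Curtis on counts; weighted
UniFrac would need phylogenetic trees, which the pipeline deliberately
does not compute, and this substitution should be kept in mind when
comparing variance fractions to tree-aware analyses.

## Synthetic community generator

What it emulates: (i) three correlated environmental gradients via a
Gaussian copula (salinity/temperature vs latitude, target rank
correlation −0.8); (ii) an 11-compound PAH suite sharing a log-normal
per-site factor (sd 0.8 on the log scale, spanning over an order of
magnitude across sites) with per-compound noise sd 0.4, giving pairwise
inter-compound rank correlations above 0.75, multiplied by 20 at
contaminated sites (half the samples, balanced within region); baseline
compound levels put P/A ≈ 6 and F/P ≈ 1.3, the pyrogenic regime typical
of chronic atmospheric deposition; (iii) core OTUs with log-linear
environmental responses (β ~ N(0, 0.35²) per gradient) and shared module
latent factors (sd 1.5–1.8 log units), one module tied negatively to
standardized log fluoranthene (loading 0.9) and containing a
predator–prey pair coupled by an antisymmetric latent term (sd 2.0);
(iv) satellites occupying Binomial(n, 0.1) sample subsets with
per-present-sample Poisson mean 2 before depth scaling; (v) sequencing
depth 3000 by per-sample multinomial resampling of expected relative
abundances, preserving compositionality, with an optional gamma
multiplier for negative-binomial overdispersion.

Module latent factors are residualized to be exactly orthogonal to the
environmental drivers and to one another: each consortium has a distinct
driver, and without residualization finite-sample chance correlations
between factors blur the planted module boundaries at small n.
Contamination attenuates non-PAH module factors to 25% of their sd in
contaminated samples — contamination damping the covariation that binds
a consortium — which is what makes contaminated-group networks sparser
and less clustered while the pooled network keeps its modules. Effect
sizes were fixed once so that the planted structure is recoverable by
the pipeline's own defaults (core recall, module ARI, eigengene response,
network degradation) and are not meant to be tuned per analysis.

What it does **not** emulate: sequence-level error, chimeras, OTU
clustering artifacts, phylogenetic relatedness, true compositional
closure effects beyond multinomial sampling, spatial autocorrelation,
or taxon-specific PCR bias. Recovery results on this generator therefore
validate the statistical machinery, not the end-to-end performance on
raw amplicon data.

`fixture_small()` is a deterministic 12-sample × 40-OTU miniature with
two undamped, stronger-effect modules: with only 12 samples the p < 0.001
edge gate requires |ρ| ≳ 0.82, so a recoverable miniature must be
near-deterministic. `reduced_design()` (30 samples × 300 OTUs, 4 modules)
is the replicated-experiment scale; the full default design is
42 × 1020.

## Numerical conventions and degenerate inputs

- Rarefaction uses multivariate hypergeometric draws (without
  replacement); samples below depth are dropped with a warning, not
  padded. Single-draw with a recorded seed (repeated-subsample averaging
  is not implemented).
- All stochastic stages take seeds from `PipelineConfig.random_seed`;
  identical seeds give byte-identical outputs.
- Spearman of a constant vector is NaN; edges involving NaN correlations
  are never retained.
- VMR of an all-zero OTU is 0 (avoids 0/0); χ² limits with df < 1 are
  NaN and force satellite.
- Ties in ranks use average ranks throughout.
- p-value estimators from permutations/null ensembles always include the
  observed arrangement (no p = 0).
- HAC on all-identical profiles raises "no separation" rather than
  returning an arbitrary split.

## Problem sizes used in the test and calibration suites

Replicated experiments run at the reduced design (30 × 300, 100
replicates for recovery; medians reported), SES calibration at
20 OTUs × 15 sites with 200 null matrices × 200 replicates, the Poisson
core-call rate at 10,000 OTUs × 42 samples, exhaustive null enumeration
at 3 × 4, and brute-force oracle comparisons at ≤ 12 nodes / 8 samples.
These sizes give stable Monte-Carlo estimates while keeping the full
suite fast enough to run routinely.
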