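# Methods

`mycomotif` analyses how non-photosynthetic "cheater" plants
(mycoheterotrophs, MH) embed in the otherwise mutualistic network between
autotrophic plants and arbuscular mycorrhizal (AM) fungi. The data model is
a tripartite network: two binary incidence blocks — MH x fungi (the
antagonist block) and autotroph x fungi (the mutualist block) — over one
shared, aligned fungal axis. This note records the statistical model, the
preprocessing conventions, the synthetic-data generator, and the numerical
and design choices that were genuinely open.

## Preprocessing

A sample x OTU read-count table is turned into species-level rarefied
binary incidence matrices in a fixed order:

1. **Cell mask** (`min_otu_reads`, default 6): cells with `0 < count < 6`
   are zeroed. This is the standard tag-switching guard; it is applied per
   cell rather than deleting whole OTU columns, so an OTU genuinely present
   in other samples survives. Whether per-cell masking or table-wide OTU
   deletion is more faithful to common practice is genuinely ambiguous; the
   choice is logged at run time.
2. **Sample filter** (`min_sample_reads`, default 500): samples with fewer
   total reads are removed (strictly-below semantics).
3. **Species aggregation**: samples of one plant species are pooled by
   elementwise summation; the number of pooled samples is recorded.
4. **Species filter** (`min_species_reads`, default 500): species with
   fewer pooled reads are removed. Losing an entire guild aborts the run,
   because the tripartite analysis needs both.
5. **Rarefaction** (`rarefy_depth`, default 844): every species is
   subsampled to the common depth *without replacement* (one multivariate
   hypergeometric draw per species). Row sums equal the depth exactly and
   no cell can exceed its original count. A species below the depth raises
   an error naming it rather than being silently dropped — the default
   depth is meant to be at most the minimum species total.
6. **Binarisation**: presence/absence; fungal columns that end up empty are
   dropped.

Analyses are repeated over an ensemble of independent rarefactions
(default 100) and reported as mean ± SD.

## Network descriptors

* **Normalised degree**: a node's partner count divided by the number of
  possible partners in its matrix.
* **Phylogenetic species variability (psv)** of a plant's fungal
  community: `psv = (n tr(C) - sum C) / (n (n-1))` where `C` is the tip
  correlation matrix. 1 means the community's fungi are phylogenetically
  unrelated; values near 0 mean high relatedness. `C` is built as
  (shared root-to-MRCA path length) / sqrt(depth_i * depth_j), which equals
  the classic shared-branch-length correlation on ultrametric trees and
  remains a valid correlation on non-ultrametric ones. psv is undefined
  (returned as `None`, never a crash) for communities of fewer than two
  fungi, and for tips at zero distance from the root.
* **Plant-plant overlap**: for every unordered plant pair, the number of
  shared fungi, tagged MH-MH / MH-A / A-A.
* **Fungal ecological similarity** within one guild block: Jaccard
  `C_ij / (d_i + d_j - C_ij)` and overlap `C_ij / min(d_i, d_j)`, where
  `C_ij` is the number of shared plants and `d` the fungal plant-degrees.
  Zero-degree fungi are excluded (both formulas are 0/0) with a logged
  warning; the diagonal is fixed at 1 and never enters Mantel
  vectorisation. When the two guilds' similarity matrices are correlated
  against each other they are first restricted to the fungi shared by both
  guilds — the only choice that makes them conformable.

## Phylogenetic signal and matrix correlation

Phylogenetic distances are cophenetic (tip-to-tip path lengths);
community dissimilarity is the Jaccard distance between binary interaction
profiles. The **Mantel statistic** is the Pearson correlation of the
strictly-lower-triangle vectors; its p-value comes from jointly permuting
the row/column labels of the second matrix, one-tailed for positive
association (the ecological hypothesis), with the observed statistic
included in the reference set: `p = (1 + #{r_perm >= r_obs}) / (1 +
n_perm)`. p is therefore never exactly 0 and never below
`1/(1 + n_perm)`. The **partial Mantel** statistic is the first-order
partial correlation `r12.3`, fully recomputed (including the permuted
`r23`) for each permutation of the second matrix. The default permutation
count is 999 and configurable; the number used in the original analyses of
this kind is typically unstated, so it is exposed rather than fixed.

## The diamond-motif test

A **diamond-shaped module** is an unordered pair of distinct fungi linked
to the same MH plant and the same autotroph plant (4 nodes, 4 edges) —
"apparent competition" in food-web terms, here the signature of a cheater
and a mutualist exploiting the same fungus pair. With shared-partner
matrices `P = M^T M` and `Q = A^T A`, the count is
`sum_{f1<f2} P[f1,f2] Q[f1,f2]`, identical to exhaustive quadruple
enumeration but quadratic instead of quartic. A plant pair sharing a
*single* fungus is not a module.

The null model is the degree-proportional Bernoulli null: each
plant-fungus link is drawn independently with probability equal to the
arithmetic mean of the plant's and the fungus's fill fractions,
`p_ij = (k_i/C + k_j/R)/2`, which conserves the block's expected link
count exactly. Because the two guilds have very different sizes, the two
blocks are randomised **separately** from their own specs and recombined
before the module search. Two fungal scopes are tested: *all* fungi, and
*shared* fungi only (the empirical network is first restricted to fungi
present in both guilds and the null probabilities recomputed on the
restricted blocks).

Each test draws `n_null` (default 1000) null networks and reports the
observed count, null mean ± SD, `z = (obs - mean)/SD`, the empirical
p-value (+1/+1 convention), and the 2.5th-97.5th percentile interval of
null counts. **Overrepresentation is declared by the percentile interval**
(observed above the 97.5th percentile); z and p are reported alongside and
the percentile rule governs when they disagree.

### Numerical choices

* Null draws with an **empty plant row** are rejected and the whole matrix
  redrawn (cap 1000 retries), because an observed network cannot contain a
  plant with no fungi; whole-matrix redraw avoids biasing individual
  cells. Empty fungal *columns* are allowed by default: the empirical
  guild blocks themselves contain zero-degree fungal columns (fungi used
  only by the other guild), and for study-shaped blocks a draw with every
  positive-degree column occupied is astronomically rare. Full
  row-and-column rejection remains available (`forbid_empty="rows+cols"`).
* `z` is reported as undefined (not 0, not infinity) when the null counts
  are constant; the empirical p is still valid.

### A known limitation: the null is not self-consistent

The additive null is **not a fixed point of its own fitting operator**:
for a block with additive cell probabilities `p_ij = (r_i + c_j)/2`, the
expected row fill is `(r_i + c̄)/2`, so refitting
`p̂ = (rowfill + colfill)/2` to a network *drawn from* an additive null
halves the amplitude of the degree heterogeneity. Consequently, when the
full test (refit + resample) is applied to networks generated by the null
itself, the z-score is biased upward (≈ +0.9 on study-shaped networks)
even though nothing but degree structure is present; the percentile flag
remains conservative (empirical flag rate ≈ 0 at nominal 2.5%) because
the refit null distribution is also wider. Two practical consequences:
z-scores from this test should be read as descriptive effect sizes, not
calibrated test statistics, and the percentile flag is the inferential
output. The calibration test in the suite therefore draws both the
"observed" network and its reference counts from one fixed spec — the
exchangeable design under which flag rate and mean z have their nominal
values. A related corollary: under the null, randomised row degrees are
centred on the *spec's* row sums (shrunk toward the block mean), not on
the empirical degrees; only the total link count is conserved in
expectation.

## Robustness ensembles

* **Rarefaction ensemble**: any metric or motif test repeated over
  independent rarefy → binarise draws; mean, SD and (for motif tests) the
  fraction of replicates flagged overrepresented.
* **Sample resampling**: k (default 3) samples per species drawn without
  replacement, species with fewer than k samples discarded; each replicate
  is aggregated, rarefied to *that replicate's* minimum species total (a
  choice the procedure leaves open; the depth is logged per replicate) and
  analysed.
* **Depth sweep**: the rarefaction ensemble repeated at several depths;
  infeasible depths are skipped with a warning. For motif tests the sweep
  reports whether the overrepresentation verdict is stable across depths.

## Synthetic data generator

The generator emulates the post-clustering state of a root-tip sequencing
survey of a tropical-forest plot: by default 21 autotrophic species with
1-9 root-tip samples each, 5 mycoheterotrophic species with 3-9 samples,
115 fungal OTUs, and per-sample read totals of 900 + lognormal (median
≈ 3.3k reads) so that default datasets clear the 500-read filters and the
844-read rarefaction depth.

Ground truth is a **species-level** incidence probability matrix:

* Autotroph block: `p = (plant generality + fungal generality)/2`, with
  plant generality ~ U(0.05, 0.25) and fungal generality a truncated
  power-law (Pareto exponent 1.0, scale 0.10, cap 0.9) — a minority of
  generalist fungi sits at the cap, the generalist core typical of AM
  communities. A phylogenetic component (one Brownian realisation per
  plant down the fungal tree, mapped through a logistic with slope 2.5) is
  mixed in with weight `phylo_signal_strength` (default 0.2, a weak
  signal; at strength 1 the signal is reliably detectable by the Mantel
  test).
* MH block: attachment probability proportional to (expected autotroph
  degree of the fungus)^gamma, scaled to a species-level target richness
  ~ U(25, 45) and capped at 0.97. `gamma` is the experimental dial:
  0 gives degree-independent attachment (and empirically a flag rate of
  ~0 with mean z ≈ 0), 2 (the default) concentrates MH on the
  best-connected fungi and produces strong, reliably detected
  overrepresentation.

A species observed through k samples uses per-sample detection
`q = 1 - (1-p)^(1/k)`, so the union of its samples is Bernoulli(p)
regardless of sampling effort — uneven sample numbers change read depth,
not expected species-level incidence. (An earlier per-sample design
created a sampling-effort x fungal-generality interaction that the
additive null does not model, biasing the gamma = 0 case; the union-exact
construction removes it.) Reads are spread over a sample's realised fungi
by a symmetric-Dirichlet-weighted multinomial; every sample is guaranteed
at least one fungus. A `stress` flag injects filter-violating shallow
samples for testing the filters themselves.

What the generator does **not** emulate: read-level noise (chimeras, OTU
clustering artefacts), spatial structure between subplots, abundance
information carrying interaction strength, plant-side phylogenetic signal,
and fungus-fungus co-occurrence beyond what degrees and the fungal tree
induce. Passing tests on synthetic data therefore demonstrate the
statistical machinery under known truth, not ecological conclusions about
any real community.

## Problem sizes and reproducibility

Library and CLI defaults are the full study-scale parameters
(6/500/500 read filters, depth 844, 100 rarefactions, 1000 null networks,
999 permutations, k = 3 with 1000 resamples). The test suite and the
acceptance script run the same machinery at reduced replicate counts
(typically 200 null networks, 20 rarefactions, 60 resamples), chosen as
the package's own desk-scale working sizes. All randomness flows from one
explicit seed through named `SeedSequence` substreams, so any run —
including the full pipeline report — is bit-reproducible from config plus
inputs; two runs with the same seed produce byte-identical result files.
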