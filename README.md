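# mycomotif

Tripartite mycorrhizal network analysis: do cheater plants preferentially
target the best-connected mutualistic fungi?

Mycoheterotrophic plants (MH) have abandoned photosynthesis and draw
carbon from arbuscular mycorrhizal (AM) fungi — fungi that are
simultaneously engaged in ordinary carbon-for-nutrients mutualism with
autotrophic plants. The three guilds form a tripartite network: an
MH x fungus "antagonist" incidence block and an autotroph x fungus
"mutualist" block sharing one fungal axis. `mycomotif` builds these
networks from OTU read-count tables and tests a specific structural
hypothesis: that **diamond-shaped modules** — an unordered pair of fungi
linked to the same MH plant *and* the same autotroph plant — occur more
often than expected by chance, which is the signature of cheaters
targeting fungi that are well connected to autotrophs.

With incidence blocks `M` (MH x fungi) and `A` (autotrophs x fungi) the
observed module count is

    D = sum over fungus pairs f1 < f2 of (M^T M)[f1,f2] * (A^T A)[f1,f2]

and it is compared against Bernoulli null networks in which each
plant-fungus link appears with probability

    p_ij = 1/2 * (k_i / C + k_j / R)

(the arithmetic mean of the plant's and the fungus's fill fractions; the
classic degree-proportional bipartite null), the two guild blocks being
randomised separately and recombined. The test reports the observed
count, null mean ± SD, z-score, empirical p-value, and the 95% percentile
interval of null counts that governs the overrepresentation verdict.

The package also provides the surrounding analysis: read filtering and
species aggregation, rarefaction without replacement, normalised degrees,
phylogenetic species variability (psv) of each plant's fungal community,
plant-plant fungal overlap, Jaccard/overlap fungal similarity, Mantel and
partial Mantel permutation tests of phylogenetic signal, rarefaction and
sample-resampling robustness ensembles, multi-depth sweeps, and a
synthetic-data generator with controllable MH preference strength
(`gamma`) and fungal phylogenetic signal. See `docs/methods.md` for the
full model description.

## Worked example

```python
import numpy as np
from mycomotif import SimConfig, generate_dataset
from mycomotif.preprocess import preprocess_pipeline, rarefy, binarize
from mycomotif.networks import TripartiteNetwork
from mycomotif.motifs import DiamondMotifTest

# a study-shaped synthetic dataset: 21 autotrophs, 5 mycoheterotrophs,
# 115 fungal OTUs, uneven sampling, strong MH preference (gamma = 2)
ds = generate_dataset(SimConfig(seed=1))

# read filters (6 / 500 / 500), species aggregation, one rarefaction to 844
comm = preprocess_pipeline(ds.counts, ds.metadata, 6, 500, 500)
rng = np.random.default_rng(1)
net = TripartiteNetwork.from_incidence(binarize(rarefy(comm, 844, rng)), comm.guild)

result = DiamondMotifTest(net, scope="all").fit(n_null=1000, rng=rng)
print(result.summary())
```

prints

```
Diamond-motif null-model test (scope: all fungi)
  observed modules     : 4458
  null mean +- SD      : 3074.51 +- 498.17  (1000 null networks)
  null 95% interval    : [2224.8, 4135.3]
  z-score              : 2.777
  empirical p          : 0.00999
  verdict              : OVERREPRESENTED
```

The empirical network contains 4458 diamond modules; degree-matched
random networks contain about 3075 ± 498, and the observed count lies
above the null's 97.5th percentile, so fungus pairs shared between a
cheater and an autotroph are overrepresented — exactly the structure the
generator's `gamma = 2` preference injects. Re-running with `gamma = 0`
(degree-independent attachment) leaves the verdict within the null
interval.

## Command line

```sh
mycomotif simulate --seed 1 --out data/
mycomotif run --counts data/counts.tsv --samples data/samples.tsv \
    --fungal-tree data/fungi.nwk --plant-tree data/plants.nwk \
    --seed 1 --out results/
mycomotif motif --counts data/counts.tsv --samples data/samples.tsv --seed 1
```

`run` executes the whole pipeline (rarefaction ensemble, both fungal
scopes of the motif test, Mantel tests, resampling, optional depth sweep)
and writes `results.json` plus per-replicate TSV tables, with the seed and
configuration echoed for reproducibility.

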