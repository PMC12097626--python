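# mesofish

Community analysis for fish eDNA metabarcoding surveys, built for
comparing mesophotic reef assemblages between regions (islands) from
MiFish-style 12S amplicon data.

The pipeline starts where raw-read processing ends — at a denoised
ZOTU-by-sample table — and carries it through:

1. **Filtering** — per-sample low-abundance removal (threshold = 0.025 %
   of each sample's read depth by default) and blocklist exclusion of
   implausible taxa (e.g. freshwater genera in marine samples).
2. **Taxonomic assignment** — gated reference hits (e-value ≤ 1e-20,
   query coverage ≥ 90 %) passed through tiered similarity rules
   (≥ 99 % → species, ≥ 97 % → genus, ≥ 95 % → LCA capped at family),
   regional occurrence validation, and neighbour-joining phylogenetic
   refinement (number-of-differences distances, complete deletion,
   bootstrap support, midpoint-rooted MRCA calls) for designated
   families; the phylogenetic call wins on conflict.
3. **Barcoding-gap clustering** — a threshOpt-style scan that counts
   false positives + false negatives of leave-one-out identification per
   candidate threshold on a species-labelled reference library, then
   complete-linkage clustering of ZOTUs at the optimum (within-cluster
   diameter ≤ threshold).
4. **Functional entities** — five qualitative traits (activity,
   schooling, position, diet, body shape) with most-prevalent-value
   imputation for genus/family-rank ZOTUs; each complete trait
   combination is a functional entity (FE).
5. **Diversity statistics** — incidence-based Hill numbers
   (q = 0, 1, 2) with rarefaction/extrapolation and Chao2 asymptotes;
   Jaccard/Bray-Curtis/Gower dissimilarities; NMDS (Kruskal stress-1);
   one-way PERMANOVA and multivariate dispersion tests with permutation
   p-values; envfit vector/factor fitting; VIF screening; group-equalized
   IndVal indicator analysis (stat = √(A·B), A specificity,
   B sensitivity/fidelity) with multi-level pattern permutation tests;
   sensitivity re-runs excluding families or dropping traits.

A fully seeded synthetic module generates two-island studies with the
statistical structure the analysis assumes — a reference library with a
built-in barcoding gap, island-structured communities with planted
indicator families, trait tables with missing rows, and station
environment tables — so every stage runs and is testable at desk scale.

## Worked example

```python
import pandas as pd
from mesofish import (SynthConfig, generate_reference_library,
                      generate_community, optimize_threshold,
                      pairwise_distance_matrix, complete_linkage_cluster,
                      aggregate, dissimilarity, permanova, ZotuTable)

cfg = SynthConfig(seed=42)
records, taxonomy, truth = generate_reference_library(cfg)
opt = optimize_threshold(records, truth.variant_to_species)
print(f"optimal threshold: {100 * opt.optimum:.1f}%  "
      f"(cumulative error {int(opt.cumulative_error.min())})")

dm = pairwise_distance_matrix(records, proportional=True)
part = complete_linkage_cluster(dm, opt.optimum)
print(f"{part.n_clusters} clusters for {len(truth.species)} true species")

tables, island_of = generate_community(cfg, truth)
combined = ZotuTable(pd.concat(
    [tables[i].data for i in sorted(tables)]).fillna(0).astype(int))
families = {z: sp.rsplit("-", 2)[0]
            for z, sp in truth.zotu_to_species.items()}
counts = aggregate(combined, families, drop_unmapped=True)
res = permanova(dissimilarity(counts, "bray_curtis"), island_of,
                n_perm=999, seed=0)
print(f"family Bray-Curtis PERMANOVA: F = {res.F:.2f}, "
      f"R2 = {res.R2:.2f}, p = {res.p:.3f}")
```

prints

```
optimal threshold: 1.2%  (cumulative error 0)
40 clusters for 40 true species
family Bray-Curtis PERMANOVA: F = 5.80, R2 = 0.27, p = 0.001
```

The threshold scan finds a zero-error cut inside the barcoding gap
(between the conspecific and congeneric divergence distributions);
complete-linkage clustering at that cut recovers the 40 simulated
species exactly; and the family-level Bray-Curtis PERMANOVA detects the
planted between-island difference in assemblage structure (27 % of the
distance variation, permutation p at its 999-permutation floor).

## Command line

`mesofish simulate --seed 1 --out data/` writes a complete synthetic
input set plus a ready `config.yaml`; `mesofish run-all --config
data/config.yaml --out run/` executes every stage (filtering through
sensitivity analysis) and writes TSV outputs with a JSON manifest of
parameters, seeds and content hashes. Individual stages are available as
`filter`, `assign`, `thresh-opt`, `cluster`, `diversity`, `beta` and
`indicators` subcommands.

## Documentation

`docs/methods.md` describes the models, estimators, numerical choices
and the synthetic generator's design; `docs/hill_formulas.md` is the
formula sheet for the incidence-based Hill-number estimators.
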