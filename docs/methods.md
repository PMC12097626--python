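# Methods

## Scope and model

`mesofish` implements the community-analysis stages of a two-region
fish eDNA metabarcoding study. The unit of observation is the ZOTU
(zero-radius OTU, a denoised exact amplicon variant) in a sample
(station); the pipeline's entry point is the ZOTU-by-sample read-count
table, together with amplicon sequences, a reference-hit table, a
species-keyed trait table, a station environment table and a regional
occurrence list. Everything upstream (filtration, PCR, sequencing,
merging, denoising) is out of scope.

The analysis assumes one water sample per station, stations
exchangeable within a region under the null, and amplicons of
near-uniform length (MiFish-like, ~140–200 bp) so that positional
alignment is trivial and distances can be computed per site.

## Filtering

Low-abundance detections are zeroed per sample when reads fall below
`rate × depth(sample)`, with `rate = 0.00025` (0.025 %) by default and
depth taken as the column sum of the *input* table. The comparison is
`≥` (a detection exactly on the threshold is kept), the filter is a
single pass (depths are not recomputed after zeroing, making it
idempotent), and ZOTUs left with all-zero rows are dropped. Taxon
exclusion removes ZOTUs whose final assignment matches a blocklist
entry at the entry's rank — the mechanism for discarding ecologically
implausible detections such as freshwater genera in marine samples.

## Taxonomic assignment

Hits are gated at e-value ≤ 1e-20 and query coverage ≥ 90 %. Tiers are
cumulative lower bounds on percent identity: ≥ 99 % with a single
consistent species gives a species call; otherwise ≥ 97 % with a single
genus gives a genus call; otherwise the lowest common ancestor (LCA) of
all hits ≥ 95 % is taken, capped at family — at 95 % identity on a
short 12S fragment a genus- or species-level claim is not supportable.
The LCA ignores absent ranks (reference annotation depth varies) but is
vetoed by any disagreement at a higher rank. Species calls absent from
the regional occurrence list are demoted to genus and flagged
`region_unvalidated`; demotion (rather than mere flagging) is this
package's codification of manual occurrence-based curation.

Phylogenetic refinement, applied to configurable families: each
family's ZOTUs and the top ten gated hits per ZOTU (ordered by
ascending e-value, then descending identity) are aligned (inputs of
uniform length pass through; otherwise a center-star alignment around
the medoid — adequate for near-identical amplicons), distances are
numbers of differences under complete deletion (every column containing
a gap or N removed), trees are built by neighbour joining with a
deterministic lowest-index tie-break and negative branch lengths
clamped to zero, and support comes from column-resampling bootstrap
(default 1000 replicates; configurable — runtime scales linearly).
The assignment is read from the smallest midpoint-rooted clade
containing the ZOTU and at least one reference: the LCA of the clade's
references, flagged `low_bootstrap` below 70 % support. Midpoint
rooting is a documented convention — NJ trees are unrooted and MRCA
extraction needs a root. When automatic and phylogenetic calls both
exist, agreement keeps the more precise rank and conflict is resolved
in favour of the phylogenetic call.

## Barcoding-gap threshold and clustering

Distances for clustering are proportional (differences ÷ compared
sites) so the threshold is length-independent. On a species-labelled
reference library, every sequence is queried against all others
(leave-one-out): at threshold `t`, a query with conspecifics present is
a true positive if its ≤ t neighbourhood is non-empty and purely
conspecific, a false positive if it contains a heterospecific, a false
negative if empty; singleton species score true negative on empty
neighbourhoods and false positive otherwise. The optimum minimizes
false positives + false negatives, ties resolving to the smallest
threshold; the default grid is 0.1 %–5 % in 0.1 % steps, which covers
the range of plausible 12S minibarcode cutoffs. ZOTUs are then
clustered by complete linkage cut at the optimum, which guarantees the
within-cluster maximum pairwise distance never exceeds the threshold.
Distance-by-rank summaries categorize every sequence pair by its lowest
shared rank (Intra-species … Class), the standard barcoding-gap
diagnostic.

## Traits and functional entities

Five qualitative traits with closed vocabularies: activity (diurnal /
nocturnal / both), schooling (five ordinal categories from solitary to
> 50), position in the water column (benthic / pelagic / bentho-pelagic
/ bathypelagic — bathypelagic kept as a fourth level rather than folded
into pelagic, since the position categories are used as distinct
levels), diet (five categories) and body shape (four categories).
Species-rank ZOTUs take their species row; genus/family-rank ZOTUs take
the per-trait most prevalent value among the species of their taxon,
with ties broken deterministically in favour of the value held by the
lexicographically smallest species and flagged `ambiguous`; ZOTUs above
family are excluded from functional analyses. Remaining gaps are filled
from a local supplement table (the stand-in for interactive database
lookups — no network access at run time). A functional entity (FE) is a
unique complete trait combination; ids are assigned in first-appearance
order, so the FE *partition* is input-order invariant even though ids
may permute. Dropping a trait (sensitivity analysis) rebuilds the
registry on four traits and can only merge FEs.

## Diversity statistics

**Hill numbers.** Incidence-based, per island: `Y_i` counts the
stations where cluster `i` was detected. Orders q = 0 (richness),
1 (Shannon), 2 (Simpson) are interpolated exactly under hypergeometric
subsampling and extrapolated with Chao2-based unseen-cluster estimates;
`docs/hill_formulas.md` has the algebra, including the harmonization
that keeps the reported profile ordered (q0 ≥ q1 ≥ q2) and the
convention that `Q1 = 0` (no uniques) means no extrapolated surplus.
Extrapolation is capped at 2T by default.

**Dissimilarities.** Jaccard on presences, Bray-Curtis on cumulative
occurrence counts (the number of distinct ZOTUs of a family/FE detected
per sample — not reads), Gower on mixed environment tables
(range-scaled quantitative differences, 0/1 categorical mismatches,
averaged over non-missing variables). Bray-Curtis between two all-zero
samples is defined as 0 with a warning.

**NMDS.** SMACOF iterations with isotonic (pool-adjacent-violators)
disparities, minimizing Kruskal stress-1
`√(Σ(d−θ)²/Σd²)`; best of 20 random restarts plus one
principal-coordinates start, 200 iterations each, convergence at
stress change < 1e-7; the final configuration is centered, rotated to
principal axes, and sign-fixed (largest loading positive). All defaults
are configurable and the seed is recorded in the result.

**PERMANOVA.** One-way, with `SS_total = Σ_{i<j} d²/n`,
`SS_within = Σ_g Σ_{i<j∈g} d²/n_g`, pseudo-F on (a−1, n−a) degrees of
freedom and R² = SS_between/SS_total. p-values permute raw labels;
Monte-Carlo p uses the add-one convention (1+hits)/(1+n_perm) — hence
the 0.001 floor at 999 permutations — and `n_perm=None` enumerates all
permutations for an exact p (identity included). The implementation is
cross-checked against scikit-bio and vegan's `adonis2` in the tests.

**Dispersion homogeneity.** Principal-coordinates embedding retaining
negative-eigenvalue axes; a sample's distance to its group centroid is
`√(max(0, d²_pos − d²_neg))`; F is the one-way ANOVA F on those
distances, with the permutation p obtained by shuffling labels over the
fixed distances (the reference implementation's convention) and the
parametric F-test p reported alongside. Centroids, not spatial medians.

**envfit.** Vectors: least-squares regression of the variable on the
(centered) ordination coordinates, r² = 1 − SS_res/SS_tot, arrow =
normalized coefficients. Factors: r² from within-level coordinate
deviations, with level centroids. p by permuting the variable.

**VIF screen.** Categoricals one-hot encoded against a reference
level; VIF_j = 1/(1−R²_j) from regressing column j on the rest; the
variable owning the largest VIF ≥ 5 is dropped (all its dummies
together; ties → later column, perfect collinearity first) and the
screen iterates.

**Indicators.** Group-equalized IndVal: A_g = x̄_g / Σ_k x̄_k (means of
cumulative occurrence counts — group-equalized, so unequal island sizes
do not bias specificity), B_g = occurrence fraction within g,
stat = √(A·B). Candidate site-group combinations are all non-empty
proper subsets (for two islands: each island); each unit is associated
with its argmax combination, and the permutation p recomputes the best
combination's statistic per label shuffle (add-one convention). Units
absent everywhere are skipped with a log line.

## Synthetic data generator

The generator emulates the study design the analysis assumes, fully
seeded (one RNG stream per operation, keyed by `(seed, operation)`, so
adding an operation never perturbs another's draws).

*Reference library.* Sequences evolve along the taxonomy by per-site
substitution without indels (amplicons born aligned). Inter-tier minima
are **guaranteed**: family/genus/species branches mutate
`ceil(L·tier/2)` sites drawn from level-specific, sibling-disjoint
pools, so any cross-family pair differs at ≥ L·interfamily sites, etc.
The intra-species tier is a **rate**: each variant branch mutates
`Binomial(L, intra_species_max/2)` sites (capped at `m_species − 1` so
conspecific divergence can never reach the congeneric floor), giving
expected conspecific divergence ≈ `intra_species_max` — on a 170-bp
amplicon conspecific variants differ by ~1 bp, the regime in which a
sub-percent clustering threshold is the right answer and the optimizer
recovers a cut inside the gap. Defaults: 10 families × 2 genera × 2
species × 2 variants, 170 bp, ladder 0.004 / 0.02 / 0.06 / 0.10
substitutions per site.

*Communities.* Two islands with 10 and 8 stations. Family occupancy per
sample is island-specific: a shared core at baseline 0.5, two
island-exclusive families per island (turnover), and planted indicator
families whose target-island occupancy is B* and whose off-island
occupancy is `B*(1−A*)/A*` — so the group-equalized specificity and the
sensitivity equal A* and B* in expectation (verified by Monte-Carlo).
Given family presence, each species is present with probability 0.6
(at least one forced), and all variants of a present species are
detected. Reads for present ZOTUs are Dirichlet-multinomial over a
log-normal depth centred on 50,000 reads (study-scale depths are
unnecessary to exercise the filter and proportion logic). ZOTUs shared
between islands carry one id per island, as in real two-island tables.

*Traits and environment.* Trait values are phylogenetically structured
(family base vector, perturbed per genus with p = 0.2 and per species
with p = 0.1) so genus/family consensus imputation is usually correct;
row-level masking (default 20 %) never masks a genus's last unmasked
species. Station tables draw depth inside [68, 107] m with
island-specific windows, and categorical habitat variables with
island-skewed probabilities; an `env_island_effect` dial interpolates
to a common null distribution at 0 (used for permutation-test
calibration).

*What the generator does not emulate* — PCR/sequencing error, chimeras,
tag jumping, abundance-dependent detection, indels, spatial
autocorrelation among stations, and correlations between habitat and
community composition beyond the island label. Passing tests therefore
demonstrate correctness of the statistical machinery and
recoverability of planted structure at desk scale, not robustness to
upstream artefacts in real data.

## Problem sizes and runtime choices

Tests and the acceptance script run the default desk-scale study
(80 reference sequences, ~120 ZOTUs over 18 samples). Permutation
tests use 999 permutations in single analyses and 199 inside
replicated simulations; bootstrap trees default to 1000 replicates in
the library API and 100 in the bundled pipeline configuration;
replicated calibrations use 100–500 datasets. The acceptance script's
indicator-recovery block reports detection sensitivity and false-flag
rate over 100 replicate datasets at the planted effect size
(A* = 0.8, B* = 0.7); note that with 10 + 8 stations the information in
per-sample presences bounds any valid α = 0.05 test's sensitivity well
below 1 at that effect size — with four or fewer target-island
presences the smallest achievable permutation p is
C(10,4)/C(18,4) ≈ 0.069 — so moderate detection rates there reflect the
statistics of the design, not an implementation deficit.

## Known limitations

* The center-star fallback aligner is not a general MSA tool; it is
  intended for near-identical amplicons only.
* The NJ implementation is O(n⁴) in pure Python; fine for the ≤ ~40-leaf
  family trees it serves, not for large phylogenies.
* `multilevel_pattern` implements the group-equalized IndVal statistic
  only; point-biserial and non-equalized variants are out of scope.
* PERMANOVA is one-way; there are no nested or multi-factor designs.
* No confidence intervals on rarefaction/extrapolation curves.
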