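# Methods

## The question and the procedure

Phylosymbiosis is the pattern in which the hierarchical clustering of host
taxa by their microbial community composition mirrors the hosts' phylogeny.
It is a statement about congruence of two trees, not about co-speciation or
vertical transmission. `phylosym` tests it for a four-species waterbird gut
survey (great cormorant, little egret, black-crowned night heron,
black-headed gull) with the following chain:

1. **Depth filtering and rarefaction.** Samples with fewer than 20,000
   reads are dropped (the boundary is inclusive: a sample at exactly the
   depth is kept). Every retained sample is subsampled to exactly 20,000
   reads *without replacement* — a single multivariate-hypergeometric draw
   per sample, not an average over repeated draws. This matches the
   semantics of mothur's `sub.sample` and makes every downstream row sum
   identical.
2. **Section merging.** Each bird was sampled in three intestinal sections
   (anterior, middle, posterior). For species-level analyses the section
   samples of one individual are averaged arithmetically; the average may
   be fractional, and downstream statistics accept non-integer abundances.
   Individuals with fewer than three sections are averaged over whatever is
   present.
3. **Species profiles and dendrogram.** Community profiles are averaged per
   host species, Bray–Curtis dissimilarities
   `d(x, y) = Σ|x_i − y_i| / Σ(x_i + y_i)` are computed among the four
   species, and a UPGMA dendrogram is built. Merge heights are half the
   between-cluster average distance (so cophenetic distances equal the
   averaged input distances); distance ties are broken by the
   lexicographically smallest member label for bit-reproducibility.
4. **Tree congruence.** The dendrogram is compared to the host phylogeny
   `(((egret, night_heron), cormorant), gull)` with two rooted-tree
   metrics computed on *cluster sets* (all clades of size 2..n−1):
   - **Robinson–Foulds (RF)**: the size of the symmetric difference of the
     two cluster sets, normalized by its rooted-binary maximum `2(n−2)`.
   - **Matching Cluster (MC)**: pad the smaller cluster set with empty
     sets, define the cost of pairing two clusters as the symmetric
     difference of their leaf memberships, and take the minimum-cost
     perfect matching (Hungarian algorithm via
     `scipy.optimize.linear_sum_assignment`). MC refines RF by charging
     near-miss clades less than complete mismatches. It is normalized by
     the maximum MC observed over the null topology ensemble (no closed
     form for the maximum is available); in Monte-Carlo mode the observed
     value is included in the maximum so nMC ≤ 1 always.
5. **Null model.** Significance is assessed against the uniform
   distribution over *labeled rooted binary topologies*: exhaustive
   enumeration of all `(2n−3)!!` topologies for n ≤ 7 (15 trees for n = 4),
   uniform Monte-Carlo sampling (via sequential random leaf insertion,
   which is exactly uniform) otherwise. The p-value is the fraction of null
   topologies whose distance to the host tree is ≤ the observed distance;
   ties count as successes, so p > 0 and the test is conservative on a
   discrete null.

### Why rooted cluster sets

Both inputs are rooted: UPGMA output is rooted by construction and the
host phylogeny has a defined outgroup. Under rooted normalization the
4-taxon nRF takes values {0, 0.5, 1.0}; an unrooted 4-taxon RF has maximum
2 and can only give 0 or 1, which could not express the intermediate value
0.5 that the posterior-section comparison produces.

A related subtlety: a 4-taxon topology sharing exactly one nontrivial
clade with the host (nRF = 0.5) has MC = 2 when it is a caterpillar but
MC = 3 when it is the balanced topology pairing the remaining two taxa.
With the exhaustive-null maximum of 6, the caterpillar case gives
nMC = 2/6 ≈ 0.333. UPGMA on the data configurations of interest produces
caterpillars, which is why (0.5, 0.333) appear together.

The exact null for perfect congruence at n = 4 is p = 1/15 ≈ 0.0667
(exactly one of the 15 topologies attains distance 0). Alternative null
generators (e.g. permuting leaf labels of a fixed caterpillar shape) give
2/24 ≈ 0.083; no documented uniform null gives smaller values, and this
package reports its null composition in every result rather than assuming
any other generator.

## Community statistics

- **PERMANOVA / adonis.** The Gower-centered inner-product matrix
  `G = −½ C d² C` is partitioned by sequential (Type-I) projections of the
  model terms in the order species, section, individual, then all
  interactions — the vegan `adonis` convention. Pseudo-F per term is
  `(SS_term/df_term)/(SS_res/df_res)`; p-values permute sample labels of
  the distance matrix. String design columns are dummy-coded factors;
  numeric columns enter as single-df centered covariates — the individual
  bird is coded as a numeric covariate (df = 1), matching the df structure
  of a species + section + individual model on this design. Rank-deficient
  terms are absorbed with a warning. A one-way call reduces exactly to the
  direct-sums formula `SS_W = Σ_g Σ_{i<j∈g} d²_ij/n_g`, which the tests use
  as an independent oracle alongside scikit-bio's one-way implementation.
- **ANOSIM.** Clarke's `R = (r̄_B − r̄_W)/(M/2)` on tied ranks of the
  distance vector, with Monte-Carlo label permutations and Bonferroni
  correction over pairwise group comparisons. Groups of size 1 are excluded
  from pairwise tests with a warning.
- **Permutation p-values** everywhere use `(1 + #exceedances)/(1 + B)`,
  which cannot return 0 and is the standard Monte-Carlo estimator.
- **Indicator values** follow Dufrêne–Legendre: specificity
  `A = mean abundance in group / Σ group means`, fidelity `B = occurrence
  fraction`, `IndVal = 100·max_g(A·B)`, permutation-tested per taxon
  against its own maximum.
- **Alpha diversity** uses the conventions of the PAST software that the
  study field commonly reports: dominance is `D = Σp²` (so a community with
  one 59% genus has D ≈ 0.35–0.6 at genus level), evenness is Buzas–Gibson
  `e^H/S` (small for OTU tables with hundreds of taxa), and Chao1 is the
  bias-corrected `S + F1(F1−1)/(2(F2+1))`, which is defined when there are
  no doubletons and collapses to S when F1 ≤ 1. Rarefaction interpolation
  is the exact hypergeometric expectation
  `E[S_m] = S − Σ_i C(N−N_i, m)/C(N, m)` computed with log-binomials;
  extrapolation beyond the sample total is deliberately not implemented.
- **Kruskal–Wallis** (tie-corrected, via scipy) with Dunn's z post hoc
  using the pooled tie-corrected rank variance; one-way ANOVA with
  Bonferroni-adjusted pairwise t-tests. Whether PAST applies exactly the
  same tie handling in Dunn's test is not verifiable; the standard
  tie-corrected form is used and documented here.
- **nMDS** delegates to `sklearn.manifold.smacof` in non-metric mode
  (stress majorization with monotone regression), 20 random starts by
  default, reporting Kruskal stress-1.

## The synthetic generator

The generator emulates the *post-OTU-calling* state of the survey — it is
the package's test bed, not a read simulator.

- **Mean profiles.** Each species has a fixed genus-level mean composition.
  Named dominant genera carry the reported prevalences (gull:
  *Catellicoccus* 58.86%, *Lactobacillus* 6.45%, *Clostridium sensu
  stricto* 4.75%; cormorant: *Fusobacterium* 32.43%, *Clostridium s.s.*
  8.69%, *Campylobacter* 8.16%; egret: *Fusobacterium* 19.81%,
  *Cetobacterium* 10.67%, *Helicobacter* 7.20%; night heron:
  *Fusobacterium* 27.30%, *Cetobacterium* 13.33%, *Helicobacter* 11.10%).
  The unclassified-Clostridiaceae bin is reported only as a cross-species
  range (8.18–14.06%); the midpoint 11.12% is the default in every species,
  configurable. *Clostridium s.s.* in egret and night heron is set to the
  midpoint 6.72% of the reported all-species occurrence range 4.75–8.69%.
- **Phylum totals.** The dominant-phylum totals are the reported ones
  (gull 90.3/9.2/0.3% Firmicutes/Proteobacteria/Fusobacteria; cormorant
  Fusobacteria 39.4%; night heron Fusobacteria 48.6%; egret Firmicutes
  40.0%). The remaining per-species mass, which is only described
  qualitatively (Fusobacteria/Firmicutes/Proteobacteria dominant, all other
  phyla < 1%), is completed as: cormorant 34.0% Firmicutes / 25.6%
  Proteobacteria, egret 34.0% Fusobacteria / 25.0% Proteobacteria, night
  heron 28.0% Firmicutes / 22.4% Proteobacteria, each plus 0.6%
  Spirochaetae and 0.4% Bacteroidetes (0.1%/0.1% in gulls). These splits
  were fixed once, before any downstream testing, to be consistent with the
  qualitative description; phylum aggregates of each profile equal them to
  1e-9.
- **Background genera.** Mass not assigned to a named genus is split evenly
  over 6 background genera unique to the species plus 2 genera shared by
  all species, per phylum. Species-specific backgrounds reproduce the
  finding that most OTUs are species-specific; the shared set keeps
  cross-species Bray–Curtis away from 1.
- **Individuals, sections, reads.** An individual's genus composition is a
  Dirichlet draw with `alpha = concentration × mean` (default concentration
  50, giving e.g. a between-gull SD of ≈ 0.07 on the *Catellicoccus*
  fraction — individuals are distinct but species remain separated). Each
  genus is expanded to 4 OTUs by a fixed geometric (ratio 0.5) split,
  giving a rank-abundance tail without extra parameters. Each section
  sample is one multinomial draw from its individual's OTU composition —
  sections share the individual's composition exactly, because the study
  design found no section effect. Library sizes are log-normal
  (mean 50,000, σ_log = 0.35) truncated below at 20,000, except a default
  10% of samples drawn uniformly in [5,000, 20,000) so the depth filter has
  work to do; the observed survey had 87/93 usable samples and ~78 analyzed,
  i.e. a comparable shallow fraction.
- **Default survey size** is 7/11/8/5 individuals
  (cormorant/egret/night_heron/gull) × 3 sections = 93 samples.

What the generator does *not* emulate: sequencing error, chimeras,
taxonomy-classification error, zero-inflation beyond multinomial sampling,
within-individual section heterogeneity, and any covariance between
library size and composition. Passing recovery tests therefore shows the
pipeline is correct and well-calibrated under clean compositional
sampling; it does not show robustness to those artifacts.

## Numerical and design choices

- Distances are computed on rarefied counts, not relative abundances; at
  equal depths Bray–Curtis is identical either way.
- UPGMA ties break on the lexicographically smallest member label;
  generation, rarefaction and all permutation tests take explicit seeds, so
  the whole pipeline is bit-reproducible.
- `DistanceMatrix` construction validates symmetry and zero diagonal; two
  all-zero samples make Bray–Curtis undefined and raise.
- Degenerate inputs are flagged, not silently passed: all-identical values
  give H = 0/p = 1 in Kruskal–Wallis; zero within-group variance with
  unequal means gives an infinite F flagged `degenerate`; a dendrogram
  built from all-equal distances warns that its topology is a tie-break
  artifact.
- Problem sizes in the validation suite were chosen at desk scale: 20
  seeded replicates for topology recovery, 200 samples for profile
  recovery, 500 replicates × 99 permutations for type-I error checks.

## Known limitations

- The congruence null is uniform over labeled rooted binary topologies.
  Prior work this analysis style descends from used an unspecified
  topology generator whose reported p for perfect 4-taxon congruence
  (0.045) is smaller than the exact uniform-null value 1/15 ≈ 0.0667; this
  package reports the exact value for its documented null and makes no
  attempt to match the other number.
- With four leaves the null has 15 members, so attainable p-values are
  coarse ({1/15, …, 1}); congruence "significance" at n = 4 should be read
  as "the single best of 15 possible topologies", nothing stronger.
- MC's triangle inequality is exercised empirically in the tests on random
  topology triples, not proven here.
- The multi-term PERMANOVA permutes raw labels (freely), the common default;
  restricted permutation schemes for nested designs are not implemented.
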