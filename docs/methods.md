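# Methods

## The design

`sibnet` implements a family-based rare-variant analysis for phenotype-
discordant affected sib pairs.  The motivating setting is autism multiplex
families in which both sibs are affected but differ sharply in one core
behavioural domain — here reciprocal social interaction, measured by the
ADI-R total cumulative social score (SOCT_CS, integer, higher = more severe).
The working hypothesis is quantitative: the sib with the more severe social
deficit carries an excess burden of rare, predicted-deleterious variants that
the mild sib does not share, and this excess is larger in pairs whose score
difference Δ is large.

The pipeline stages are:

1. **Qualifying-variant filter** (`sibnet.filters`).  Site QC plus a
   rarity/deleteriousness definition applied in a fixed order, each removed
   variant attributed to its first failing rule:
   * missingness — remove if the fraction of missing genotype calls exceeds
     `missingness_max` (default 0.10; strict `>`);
   * Hardy–Weinberg — remove if the exact two-sided Levene–Haldane test gives
     p < `hwe_alpha` (default 10⁻⁶), computed across all supplied samples
     (the original design pooled cases and controls; we document this as a
     scope simplification);
   * rarity — remove if the allele frequency exceeds `maf_max` (default 0.01)
     in **any** annotated reference panel (ESP EA/ALL, 1000G EA/ALL);
     missing panel entries never disqualify;
   * deleteriousness — keep loss-of-function classes (stopgain, stoploss,
     frameshift, splicing) unconditionally; keep missense only when
     SIFT > 0.95 **or** PolyPhen-2 > 0.85 (the `either` rule; `both`
     available).  SIFT is carried on a damaging-confidence scale so that the
     published ">0.95" threshold is well defined; conventional SIFT scores
     (damaging when small) are accepted via `sift_conventional=True`, which
     maps s → 1 − s.  Missense variants with missing scores are treated as
     non-damaging (conservative, configurable).
2. **Cohort construction** (`sibnet.cohorts`).  Within each pair the sib with
   the higher SOCT_CS is labelled severe; Δ = |score difference|.  Pairs are
   stratified with inclusive thresholds into large-Δ (Δ ≥ 10) and small-Δ
   (Δ ≤ 4) cohorts; 4 < Δ < 10 is excluded.  Δ = 0 ties stay in the small
   cohort for score summaries but are excluded from burden extraction by
   default because "severe-only" is undefined for them (a deterministic
   lexicographic tie-break is available as an explicit override).
3. **Unshared burden** (`sibnet.burden`).  A pair's unshared set is the
   qualifying sites where the severe sib carries ≥ 1 alternate allele and
   the mild sib carries 0.  Sites at which the mild sib's call is missing are
   excluded (treating missing as reference would overcall unshared variants)
   and tallied separately.  The default burden unit is distinct sites
   (homozygotes count once); an allele-count mode exists because published
   per-sib means do not disambiguate the unit.  Cohort burdens are compared
   with a two-sided Welch t-test (the unequal-variance form is the safer
   default when only "t-test" is specified) or a label-permutation test with
   the +1-corrected empirical p, p = (1 + #{|Δ̄_perm| ≥ |Δ̄_obs|})/(1 + B).
   Gene recurrence counts, per gene, the pairs contributing ≥ 1 severe-only
   variant (deduplicated within pair); the recurrent-gene list is ranked by
   (recurrence desc, variant count desc, symbol asc) and truncated
   (defaults: ≥ 3 pairs, top 250).  Risk-gene-set enrichment is an exact
   upper-tail hypergeometric test; the universe is an explicit argument
   defaulting to the analysed gene panel, since the enrichment question is
   posed within sequenced genes.
4. **Network analysis** (`sibnet.network`).  The recurrent-gene list is
   projected onto a protein–protein interaction graph (simple, undirected).
   Connectivity significance uses a within-degree node-label permutation:
   nodes are binned by degree quantiles (default 10 bins; exact-degree
   matching available), each listed gene is replaced by a uniformly drawn
   non-listed node from its bin (without replacement; underpopulated bins are
   widened by merging neighbours, logged), and the induced edge count is
   compared with the observed one, p = (1 + #{null ≥ obs})/(1 + B), B = 1000
   by default.  Density is edges over n(n−1)/2.  Communities are found by
   greedy modularity maximisation with deterministic tie-breaking (ids by
   decreasing size, then smallest member); isolated nodes become singletons.
   The published analysis used a proprietary trained pathway-membership
   classifier for this step; community detection plus the permutation null
   preserves the testable outputs (communities, density, connectivity p,
   enrichment) without inventing a trained model, and candidate-gene
   prediction is dropped.  Gene-set collections are first de-redundified by a
   greedy pass (size desc, name asc) keeping a set iff its Jaccard index with
   every kept set is ≤ 0.5; each community is then tested against each kept
   set by the exact hypergeometric upper tail with Bonferroni correction over
   the number of sets tested (the most conservative reading at the reported
   granularity; configurable).
5. **Membership report** (`sibnet.membership`).  For genes in communities
   passing the connectivity cutoff (default p ≤ 2×10⁻³, applied to the
   community permutation p), a boolean gene × signaling-network matrix with
   per-gene patient counts (large-Δ pairs whose severe-only set hits the
   gene).  Both tallies are defined as column sums: member-gene count and sum
   of member patient counts.  The packaged worked example of this table (20
   genes × 6 networks, 126 patients) contains two internal inconsistencies in
   its published form: the AVB3-integrin patient tally is printed as 47 while
   its column sums to 48, and the accompanying text says 68 patients for the
   PI3K column whose printed and recomputed tally is 62.  We define the tally
   as the column sum and surface whatever the sum yields.

## The synthetic-study generator

Real cohort data (AGRE samples) and the external resources (InWeb, MSigDB,
SFARI) are not redistributable, so `sibnet.synthdata` generates complete
studies with recorded ground truth.  What it emulates:

* **Phenotypes.**  Male affected sib pairs; SOCT_CS discrete on 0–30.  The
  severe sib's score is drawn per stratum (large: mean 25.3, SD 2.7; small:
  mean 24.6, SD 4.6 — the published cohort moments), and Δ is drawn so strata
  are respected by construction: large-Δ pairs have Δ = 10 + Poisson(1.6),
  small-Δ pairs Δ ~ Binomial(4, 2.1/4).  Defaults: 92 large-Δ and 108
  small-Δ pairs.
* **Genotypes.**  Per-sib qualifying-variant counts are Poisson.  Each pair
  shares a family pool of Poisson(λ_bg·s) variants (s = 0.5 by default,
  reflecting expected sib genome sharing — no generative model is published,
  so this is a package choice) and each sib draws Poisson(λ_bg·(1−s)) private
  variants, uniformly over a synaptome-sized panel (1,886 genes).  In large-Δ
  pairs the severe sib draws Poisson(λ_eff) extra variants uniformly over the
  risk genes (default 100), absent in the mild sib.  Defaults λ_bg = 700,
  λ_eff = 37 put per-sib totals and the between-cohort mean gap at the
  published order of magnitude.  Every site is unique to its carrier event
  (no linkage, no per-gene rate heterogeneity — genes are exchangeable), and
  carriers are heterozygous except for a 2% homozygote fraction.
* **Annotations.**  Planted variants always pass the default filter
  (functional-class mix 70% missense / 30% LoF classes; missense scores clear
  both SIFT and PolyPhen thresholds so the truth is invariant to the
  either/both rule; panel frequencies, when present, are < 1%).  Controlled
  decoy variants fail exactly one rule each — a high panel frequency, a
  benign class or sub-threshold scores, > 10% missing calls, or an all-
  heterozygote genotype column (planted only when the cohort is large enough
  that the all-het configuration is actually rejected at the HWE α).
* **Interactome and gene sets.**  A planted-partition (stochastic block
  model) graph over the gene panel with the risk genes concentrated in
  module 0 (defaults: 8 modules, p_in = 0.1, p_out = 0.002); a gene-set
  collection in which one set overlaps the risk module at a configured
  fraction and the rest are drawn outside it.

What it does **not** emulate, hence what green tests do not certify about
real data: burden overdispersion (real per-sib burdens have SD far above
Poisson — the published cohort SEMs imply SD ≈ 150 at mean ≈ 700), linkage
and sharing of identical sites across families, per-gene mutation-rate
variation, ancestry structure, batch effects, and the content of the real
interactome and pathway databases.  Published database-dependent numbers
(connected-gene counts, pathway eScores, the reported SFARI enrichment
p-value) are therefore out of reach by construction and are not targeted.

All randomness flows from per-purpose substreams of one seed
(`SeedSequence([seed, purpose_id])`), so identical configs are byte-identical
on disk and stages do not perturb one another.

## Numerical choices

* **HWE exact test.**  Levene–Haldane conditional distribution of the
  heterozygote count given allele counts, enumerated in log space; the
  two-sided p sums all configurations no more probable than the observed one
  (with a 1+10⁻¹² tolerance factor against floating-point ties).  Monomorphic
  sites return 1.  Results are memoised on the genotype-count triple, and the
  filter evaluates only the unique triples of a cohort.
* **Hypergeometric tails** use `scipy.stats.hypergeom.sf(k−1, …)` — exact
  summation, no normal approximation; the suite cross-checks every universe
  ≤ 12 against rational-arithmetic enumeration.
* **Empirical p-values** always use the +1 correction, so p > 0 and a gene
  list covering every node (no replacement candidates) yields p = 1.
* **Discreteness of the permutation null.**  The connectivity statistic is an
  integer edge count; for short gene lists ties between null and observed
  values make the +1-corrected p visibly conservative (stochastically larger
  than uniform).  The calibration study therefore uses 40-gene lists on the
  300-node benchmark graph, where the statistic is spread widely enough that
  the null p-value distribution is uniform to Kolmogorov–Smirnov precision.
* **Degenerate inputs.**  Density of a < 2-node graph, SEMs of single-pair
  cohorts and t-tests of < 2-pair cohorts are reported as missing rather than
  raised; zero-variance equal-mean score vectors give t = 0, p = 1.
* **Problem sizes.**  The replicated calibration studies run at a reduced
  scale chosen as the package's benchmark conditions — 92 + 108 pairs (the
  published cohort sizes, which set the test's power), a 300-gene panel and
  λ_bg = 60 — with 1000 null replicates for the type-I rate and 200 for
  power; the one-shot demonstration study runs at full default scale.  The
  planted power effect shifts the severe-only burden mean by 0.5 pooled SD
  (λ_eff = 0.5·√30), at which the Welch test's analytic power at these cohort
  sizes is ≈ 0.93.

## Known limitations

* The burden model is Poisson; real burdens are overdispersed, so the
  simulated power at a given mean shift overstates power on real data.
* HWE is computed on whatever sample set is supplied, not on a separate
  control pool.
* One pair per family; larger sibships must be pre-expanded into an explicit
  pairs file.
* The community step is a standard modularity heuristic, not a reimplementation
  of the proprietary classifier used in the original analysis; absolute
  community boundaries will differ even on identical inputs.
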