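# Methods

This note documents the statistical conventions, the synthetic-data model,
and the numerical choices behind `cryptodelim`.

## Cluster assignment and concordance

An individual is assigned to the cluster with its largest membership
coefficient only when that coefficient *strictly* exceeds the threshold
(default 0.5); a tie at exactly 0.5 leaves the individual UNDEFINED. When
two marker sets are compared, their cluster labels are arbitrary, so the
cross-tabulation is matched one-to-one with the Hungarian algorithm
(`scipy.optimize.linear_sum_assignment`), maximising the summed matched
cells. This replaces greedy label-switching heuristics: for the K ≤ 10
clusters this package targets, the exact optimum is cheap and
deterministic (labels are pre-sorted, so objective ties resolve by
lexicographic order). Two conventions matter for reproducing published
counts: UNDEFINED×UNDEFINED agreements are *not* concordant (an individual
that neither marker set can place is no evidence of agreement), while the
concordance denominator is *all* individuals, undefined included.
Replicate-run alignment uses the same matching on the K×K matrix of
q-column dot products, then averages.

## Diversity and differentiation

All statistics work from gene-copy counts with pairwise deletion: a
missing genotype removes that individual from that locus only, and no
imputation is performed. Loci monomorphic within a group are kept
(He = 0), since dropping them would inflate the diversity of depauperate
groups — exactly the quantity of interest under ascertainment bias.

* Gene diversity: He_l = n/(n−1)(1 − Σ_a p_a²); multilocus He is the
  unweighted mean over loci with n ≥ 2 gene copies.
* Effective alleles: NAe_l = 1/Σp²; unweighted mean.
* Allelic richness at k gene copies:
  AR_k = Σ_a [1 − C(n−n_a, k)/C(n, k)], the exact hypergeometric
  expectation of the allele count in a subsample of k copies. By default
  each locus is rarefied to the smallest gene-copy count over groups at
  that locus, so comparisons are depth-matched locus by locus.
* θ (F_ST): Weir & Cockerham's variance-component estimator, with the
  within-individual component taken from observed heterozygote
  frequencies. Multilocus/multiallele combining is ratio-of-sums
  (Σa / Σ(a+b+c)). Small negative estimates are reported as-is — they are
  the price of unbiasedness — and the multi-group "global" value pools all
  groups into one estimate rather than averaging pairs.
* D_S: Nei's standard distance with unbiased within-group identities
  J_X = (2n Σp² − 1)/(2n − 1); identities are averaged arithmetically over
  loci before the logarithm. Disjoint allele sets give +inf. The
  self-distance of a group is defined as exactly 0: applying the unbiased
  correction to only the within terms would otherwise make D_S(X,X)
  slightly negative, which is a statement about the estimator, not the
  population.
* (δμ)²: mean over SSR loci of the squared difference in mean repeat
  count. It is invariant under shifting all allele sizes at a locus and
  refuses SNP loci, whose codes carry no size information.
* Wilcoxon matched-pairs |Z|: zero differences dropped, average ranks on
  ties, W = min(W+, W−), normal approximation *without* continuity
  correction — this exact convention is needed to reproduce the published
  marker-comparison Z values from the distance tables.

## Divergence dating

Under the single-step stepwise mutation model the expected squared
difference of population mean allele sizes grows as E[(δμ)²] = 2μT once
the ancestor is at mutation–drift equilibrium. Dating inverts this:
G = (δμ)²/(2μ), evaluated at both ends of the mutation-rate range
(default 5·10⁻⁶ to 10⁻³ per locus per generation — the span commonly
quoted for plant microsatellites) and multiplied by the generation time
(default 100 years, appropriate for long-lived canopy trees). Both
generations and years are reported; the years output is always the product
of these two numbers and nothing else.

## Neighbour joining and bootstrap

NJ follows Saitou & Nei's Q-criterion agglomeration. Ties in Q are broken
by the lexicographically smallest joined pair, making the algorithm fully
deterministic. Negative branch lengths (possible on non-additive input)
are clamped to zero in reported lengths; the raw estimates stay on the
edges as `raw_length`. Bootstrap support resamples loci with replacement,
rebuilds the distance matrix and tree, and counts bipartitions under a
canonical encoding (smaller-side label set; equal sides resolved by sorted
order). A replicate in which some pair shares no alleles gets its infinite
D_S capped above the largest finite entry, preserving its rank as
"largest" without breaking the tree computation. A single-locus bootstrap
is degenerate and reports all supports as 1.0 with a warning.

## Haploweb and fields for recombination

Haplotype identity treats the alignment gap as a fifth character state, so
length variants are distinct haplotypes. The haploweb connects the two
haplotypes of every heterozygous individual; fields for recombination are
the connected components of this graph. An individual can never straddle
two FFRs: its haplotypes are either identical or joined by its own edge.
Haplotypes carried only by homozygotes are genuinely uninformative about
gene flow; they are reported as separate FFRs flagged `unconnected` rather
than silently merged. A minimum spanning network over Hamming distances
(all within-weight-class ties kept) is emitted for layout only and plays
no role in delimitation.

## Niche overlap and the Mantel test

The environmental space is defined by the *background* sample: covariates
are standardised to background mean/variance and the first two principal
components of the background are the axes onto which occurrences are
projected. Each cluster's occurrences are smoothed with a Gaussian product
kernel onto an R×R grid (default 100×100) spanning the background bounding
box plus 5% per side. Bandwidths follow the two-dimensional Silverman rule
σ n^(−1/6) per axis with a robust spread estimate, multiplied by an
oversmoothing factor of 1.5: overlap between two finite samples of the
*same* niche is otherwise visibly depressed by kernel-level noise at
typical occurrence sample sizes (with ~200 records per cluster the
oversmoothed estimator returns D ≈ 0.9 for identical niches, versus
≈ 0.85 without the factor). Schoener's D is computed on the normalised
grids; any user-supplied per-cell probability surfaces (e.g. from a
habitat-suitability model) can substitute for the kernel grids, both being
renormalised first.

The Mantel statistic is the plain Pearson correlation of the n(n−1)/2
off-diagonal pairs; the reported slope is the least-squares slope of the
second matrix's values on the first's. The permutation null jointly
permutes rows and columns of the second matrix; the p-value
(1 + #{|r_perm| ≥ |r_obs|})/(1 + n_perm) is two-sided on |r|, a
deliberately conservative default since the original analysis does not
state its tail convention. p-values are therefore reported but never used
as reference numbers.

## Synthetic data

The generators are forward Wright–Fisher simulations, chosen over a
coalescent because they are transparent, fast at the effective sizes used
(N_e ≤ 1000 diploids), and expose the dating expectation 2μT directly.

* **SSRs.** Allele sizes are repeat counts starting at 20; each generation
  resamples 2N_e gene copies and applies ±1 mutations at rate μ per copy.
  The ancestral population is burned in for 8 N_e generations so that the
  within-population variance (equilibrium value 2N_eμ) is established
  before the first split — without this, (δμ)² undershoots 2μT because
  drift variance scales with the still-growing within-population variance.
  Populations then evolve independently along the configured split tree.
* **SNPs.** Candidate loci draw ancestral frequencies from U(0.05, 0.95)
  and drift by binomial resampling without recurrent mutation. A locus is
  retained only if both alleles appear in genotypes drawn from the
  discovery panel (a configurable, deliberately small sample — the default
  scenario uses one individual from each of two clusters of the widespread
  species, mirroring how such panels are built in practice). The SNP drift
  uses its own effective size (`snp_n_e`), larger than the SSR one: SNP
  diversity depends on drift *per generation* while the SSR side also
  needs mutation–drift equilibrium within runtime, and decoupling the two
  lets the scenario hold realistic diversity in the panel lineage while
  the deep-split species lose theirs — the ascertainment asymmetry.
* **Haplotypes.** Each species pool derives private haplotypes from a
  pool ancestor mutated within a pool-specific alignment block, so pools
  never share sequences. One haplotype is common (frequency 0.55) and the
  rest split the remainder equally; this keeps each pool's haploweb
  connected through heterozygotes with overwhelming probability at the
  sample sizes used (the residual chance that a haplotype appears only in
  homozygotes, creating a spurious singleton FFR, is of order 10⁻⁴ per
  pool). Migration, when enabled, replaces an individual's second
  haplotype with one drawn from another pool.
* **Environment.** Each cluster's niche is a bivariate Gaussian in a
  latent 2-D climate space; the two axes are mixed into four observed
  covariates with additive noise, and the background adds a uniform pad
  over the bounding box, so the PCA step has genuine work to do.

The bundled scenario (`milicia_like_scenario`) uses 435 individuals in six
clusters (50/34/226/77/34/14 — the published per-cluster sizes scaled up
proportionally so every individual carries a true label), seven SSRs,
67 ascertained SNPs, and three species pools. Split times run from 175
generations for the shallowest pair — the depth implied by the smallest
published (δμ)² at μ = 10⁻³ — to 6000 generations for the most divergent
cluster. Q matrices are synthesised from the true labels with 5%
independent label noise per marker set (mixing a one-hot row with a
Dirichlet draw at weight ≤ 0.5, so assignment errors are governed by the
label noise alone); the expected cross-marker concordance
(1−ε)² + ε²/(K−1) ≈ 0.90 then brackets the published 87%.

### What the generators do not emulate

No linkage, no admixture/IBD within clusters, no genotyping error, no
spatial sampling structure, and SSR mutation is strictly single-step.
Passing tests therefore demonstrate that the *estimators and the
delimitation logic* behave correctly under the idealised processes they
assume — not that the original field data would reproduce identically.
The published summary tables, which ship with the package, are the bridge
to the real system: every statistic that can be recomputed from them is,
at its printed precision.

## Problem sizes and runtime choices

Simulation-based checks are sized for a desk machine: 500 loci for the
2μT recovery (standard error ≈ 6% of the mean), 100 replicates for FFR
recovery, 200 for the θ null, 1000 for Mantel type-I error at 199
permutations, and bootstrap counts of 300–1000 in tests (the full 10,000
of the original analysis is supported and takes proportionally longer).
Published-table Mantel statistics use the full 10,000 permutations.

## Known limitations

* D_S saturates (and its estimator becomes noisy) at deep divergence with
  few loci; on the bundled scenario the D_S tree is stable for the shallow
  split but support values for deep edges fluctuate across seeds, exactly
  as they would in a real 7-locus dataset.
* The Wilcoxon attribution of the two published |Z| values to F_ST vs D_S
  could not be confirmed from the distance tables (the recomputation
  yields the same pair with attributions swapped), so the package reports
  the smaller/larger pair without asserting an attribution.
* The published "0.07–1.41 mya" age for the deepest split is not
  arithmetically consistent with (δμ)² = 2μG under the stated constants;
  dating output is therefore always derived from the formula, and the
  published string is not used as a reference value.
* GENEPOP input carries no marker metadata, so loci read from it default
  to SSR with motif length 1; callers must override types when needed.
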