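# Methods

## The question and the statistic

A marine and a freshwater bacterial community are compared through their 16S
rRNA V4 sequences. If a lineage crossed the salinity divide recently, the
two habitats should still contain near-identical sequences from it; as the
split ages, the finest identity cutoff at which the habitats share a
cluster drifts downward. The package's core statistic formalizes this: for
a group of sequences (a phylum, or a proteobacterial class) clustered by
farthest-neighbor linkage at every distance cutoff `t` on a 0.001 grid, and
for one marine and one freshwater sample, the **maximum shared-identity
threshold** is `1 − t*` where `t*` is the smallest grid cutoff at which
some cluster contains a sequence observed in each sample. It equals 1.0
exactly when the two samples contain an identical sequence, and it is the
largest identity at which the pair's cluster-level Jaccard distance falls
below 1. The statistic is a proxy for time since the most recent
transition, not a calendar date; no molecular-clock calibration is
attempted.

## Distances and clustering

Pairwise distances follow the mothur-style one-gap convention: terminal
gaps are ignored (the comparison is confined to the two sequences' shared
non-terminal span), columns gapped in both sequences are skipped, a maximal
run of gap columns in one sequence counts as a single difference, and the
denominator is the number of compared columns. Columns containing `N` in
either sequence are excluded from numerator and denominator; both choices
are conventions of this package, stated here because alignment tools vary.

Farthest-neighbor (complete-linkage) clustering merges, at every step, the
pair of clusters whose maximum cross-pair distance is smallest, so a
cluster at cutoff `t` has diameter ≤ `t`. Because distances live on a
`k/L` lattice (L = alignment length), ties are common and the merge order
is fixed deterministically: among tied merges, the pair whose smallest
member comes earliest in the input ordering wins, then the other member.
Partitions are emitted at every grid cutoff (default step 0.001, the
"precision of 1,000" convention; a 1/290 grid is subsumed by it) from 0 up
to the first grid point at which a single cluster remains. Partition
nesting and non-increasing cluster counts along the grid are asserted at
run time in the pipeline. An abundance-sorted greedy precluster step
(merge into the most abundant representative within `max_diffs` raw
differences) is available for denoising, mirroring common practice.

The implementation is an in-house O(n³) agglomerator rather than a library
call because the tie-break rule is part of the contract; the test suite
checks it against an independently coded pure-Python agglomerator on
tie-rich lattice inputs.

## UniFrac, null models, PerMANOVA

Unweighted UniFrac is the fraction of tree branch length leading
exclusively to tips of one assemblage, among branches leading to tips of
either; weighted UniFrac is the normalized branch-proportion form
`Σ b·|p_A − p_B| / Σ b·(p_A + p_B)`. Both are computed by a single
postorder accumulation over the rooted tree (root stem excluded) and are
checked in tests against explicit per-branch descendant-set enumeration
and against scikit-bio. Identical assemblages give 0; assemblages whose
supported tips induce no shared branch give exactly 1 — the signature of a
family whose marine and freshwater members occupy disjoint subtrees.

Group-level analyses pool all marine samples into one assemblage and all
freshwater samples into another, shear the group's subtree, and report the
pooled unweighted UniFrac plus the median and range of per-sample-pair
values. Groups are included when, after dropping samples with fewer than
500 group sequences, they appear in at least 3 samples per habitat with at
least 5 taxa (all three thresholds configurable). A monotypic group present
in both habitats has identical pooled assemblages and distance 0 by
definition; the shear step is skipped for that degenerate case.

Significance is assessed two ways:

- **Independent-swap nulls.** The group's taxon × sample presence matrix is
  randomized by 2×2 checkerboard swaps that preserve every row and column
  sum exactly (burn-in 10× the cell count in attempted swaps, one draw per
  1× cells thereafter; both factors are this package's choices — only the
  algorithm family and the ensemble size of 1,000 are canonical). Each
  draw is re-pooled by habitat and the pooled unweighted UniFrac
  recomputed; the observed value is tested with a one-sample z-test,
  one-sided upper tail (habitat structure inflates between-habitat
  distance above the null), Bonferroni-corrected across groups. Margin
  preservation is asserted for every draw. Whether the randomization
  should act before or after pooling is genuinely open; this package
  randomizes the taxon × sample matrix and re-pools.
- **PerMANOVA.** pseudo-F = (SS_B/(k−1))/(SS_W/(N−k)) with
  SS_T = Σ_{i<j} d²_ij/N and SS_W accumulated per group from within-group
  pairs; R² = SS_B/SS_T; p-values by label permutation,
  p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm), default 999 permutations.
  Perfectly separated groups yield infinite F and R² = 1; permutations
  reproducing the observed partition count as ties, so the attainable
  minimum p is set by the permutation count and group sizes.

Rarefaction subsamples each library without replacement to an even depth
(pipeline default 9,827 reads; the packaged smoke configuration uses a
depth matched to its small synthetic libraries), dropping shallower
samples with a warning. Sharing analyses always use unrarefied counts.

## Sharing, accumulation, enrichment

A taxon is shared when observed (count > 0) in at least one marine and one
freshwater sample of the unrarefied table. Accumulation curves hold the
full opposite-habitat site set fixed and add the axis habitat's sites in
random order (default 100 orderings), recording the shared-taxon count and
the shared fraction of axis-habitat taxa observed so far; the mean curve is
non-decreasing and its endpoint equals the full shared count. Fixing the
opposite habitat (rather than accumulating both axes jointly) is this
package's reading of the procedure. Fold enrichment per group is
log10(median freshwater relative abundance / median marine relative
abundance); a zero median is replaced by half the smallest nonzero
per-sample group relative abundance in the table so the ratio stays finite
— the statistic is antisymmetric under habitat swap whenever no
pseudo-abundance is triggered. A Wald-test differential-abundance analysis
is deliberately out of scope; the median-based summary is the implemented
statistic.

## Detection limits and the drift barrier

With sequencing proportional to cell abundance, reads from a population at
density ρ in a community at density ρ_c follow Binomial(N, p = ρ/ρ_c) for a
library of N reads. The binomial is the canonical form; the Poisson
approximation e^(−Np)(Np)^k/k! is exposed and agrees to four decimals for
p < 1e−4. At ρ = 1 cell/ml, ρ_c = 500,000 cells/ml and N = 150,000 the
population is missed (k = 0) 74% of the time and seen exactly once 22% of
the time — while its census size, density × 10⁶ ml/m³ × area × depth, runs
to billions of cells in a 1 m layer of a small lake. On the establishment
side, a variant with selective advantage s escapes drift with probability
≈ 2s (branching-process approximation), so it appears on average 1/(2s)
times before establishing: 5 appearances at s = 0.1, 500 at s = 0.001.

## The synthetic generator

The generator emulates the data structure the analyses assume: habitat-
labeled clades diverging at controlled sequence distances, log-normal-ish
abundances with many near-detection-limit taxa, and uneven library sizes.

- **Tree**: pure-birth (Yule) with unit rate, ultrametric, branch lengths
  scaled so the mean tip-to-tip path equals `baseline_divergence` (default
  0.45 expected substitutions/site — deep enough that background lineages
  do not collide with planted transitions at ≤ 23% divergence).
- **Habitats**: marine root state; `n_transitions` disjoint internal-node
  clades flip to freshwater. Children of the root are excluded as
  candidates so each top-level clade (the derived phylum) keeps
  ancestral-habitat members; basal flips remain available by naming nodes
  explicitly. Transitions are clade flips; sporadic tip-level immigration
  is modeled in the count stage instead.
- **Sequences**: 290-position alignments (the V4 amplicon size) evolved
  site-independently under an equal-rates 4-state model with the exact
  per-branch substitution probability ¾(1 − e^(−4b/3)). Rate
  heterogeneity, indels, chimeras and primer bias are out of scope.
- **Controlled divergences**: each transition event re-derives the clade's
  ancestral sequence from a designated ancestral-habitat focal tip's
  realized sequence with exactly round(d·L) substitutions at distinct
  sites; the nearest clade tip keeps that sequence verbatim and the rest
  of the clade radiates shallowly (5e-4 substitutions/site deep) around
  it. Plain stochastic evolution would scatter the realized distance with
  SD ≈ sqrt(d(1−d)/L) — seven sites at d = 0.23, L = 290 — and complete
  linkage would inflate merge heights whenever a third sequence interposes;
  the imposition pins the realized nearest cross-habitat distance to
  within half a site, and a local isolation rescale (pendant extension of
  the focal ancestral tip, stem set so no third sequence is expected
  within a 5%-distance margin of the pair) keeps the focal pair the first
  cross-habitat join in the merge tree. The cost is a local inconsistency
  between the focal tip's tree position and its sequence, accepted
  deliberately: the scan operates on sequences, and the truth record
  stores the realized minimum cross-habitat distance computed exhaustively
  from the final alignment. Requested divergences below 0.5/L (one
  substitution cannot be halved) or above 0.70 (near the 0.75 saturation
  ceiling of an equal-rates model) are rejected as infeasible.
- **Counts**: log-normal relative abundances (default μ = 0, σ = 1.5; the
  real systems' abundance distribution is unknown and log-normal is a
  modeling choice). The lowest-abundance `rare_fraction` of taxa (default
  0.3) is rescaled so their expected per-sample count is below one read.
  Within a sample, other-habitat taxa carry `immigrant_weight` (default
  1e-3) times their base abundance, placing some shared taxa at the
  detection limit; library sizes are uniform on [5,000, 15,000] and every
  column sums to its drawn size exactly. A habitat with no resident taxa
  and no immigration yields an empty library with a warning.
- **Determinism**: one integer seed; each stage draws from its own tagged
  child stream, so identical specs give byte-identical FASTA/newick/TSV
  outputs and stages can be rerun independently.

What passing tests on this generator do **not** show: robustness to
alignment error, chimeras, primer bias, compositional rate variation, or
taxonomic misannotation — none of which the generator emulates. Results on
real surveys inherit those upstream caveats.

## Problem sizes and numerical choices

The default test and analysis runs use communities of 24–60 taxa, 8–16
samples and libraries of 10³–10⁴ reads — sizes chosen so the full pipeline
is exercised end-to-end in seconds while every scientific property under
test (divergence recovery to ±0.01, UniFrac against brute-force oracles to
1e-12, swap-margin preservation over 1,000 draws, PerMANOVA type-I
calibration over 500 label shuffles at 199 permutations) is measured at
full strength. Grid comparisons use a 1e-12 tolerance when mapping merge
heights to cutoffs; cluster labels are the smallest member's position;
empty distance comparisons and zero-total samples raise rather than
guess. The divergence-recovery experiment disables sporadic immigration
and the rare-taxon class: an immigrant's identical sequence makes every
pair share at identity 1.0 by definition, and a focal lineage below the
detection limit drops out of the libraries — both would measure something
other than the threshold statistic the experiment isolates.
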