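# Methods

## Mixture model of a sequenced tumor

A bulk sample contains normal cells at fraction 1 − ρ and tumor cells at
fraction ρ (purity, taken as given together with tumor ploidy ψ, e.g. from
an ASCAT-style analysis). A somatic mutation carried at multiplicity m by
a fraction π of tumor cells, at a locus of tumor copy number η_T and
normal copy number η_N, produces variant reads at expected fraction
`m·π·ζ` with `ζ = ρ/(ρη_T + (1−ρ)η_N)`. The cancer cell fraction of an
observed mutation is the inverse, `f = min(1, (r/R)/ζ)`, capped at 1
because sampling noise can push the raw ratio above it. f is undefined at
zero depth (an error, never a default).

## Dirichlet-process clustering

Mutations are modeled as draws from an unknown number of clusters:
`y_i ~ Binomial(N_i, ζ_i π_i)`, `π_i ~ DP(α P₀)`, with `P₀ = U(0,1)`,
`α ~ Gamma(0.01, 0.01)`, truncated stick-breaking representation
`κ_h = V_h ∏_{l<h}(1 − V_l)`, `V_h ~ Beta(1, α)`, and truncation H = 30.

Because mutations at low subclonal fraction are called with probability
S(π) < 1, the observed mutations are a biased sample. The stick weights
κ_h model the true cluster proportions; the observed data are allocated
with the corrected weights `ω_h = κ_h S(π_h)/Σ_i κ_i S(π_i)`. With flat
sensitivity ω ≡ κ. Reported mutation counts per cell-fraction band divide
observed counts by S at the cluster location; both corrections agree in
expectation.

Sampler (all conjugate except the locations):

* Allocations: categorical with probabilities ∝ ω_h × Binomial likelihood.
* Sticks: `V_h | z ~ Beta(1 + n_h, α + Σ_{l>h} n_l)`, with `V_H = 1` so
  weights sum to 1 at machine precision every sweep.
* Concentration: conjugate Gamma update from the stick log-complements.
* Locations π_h: the U(0,1) base measure is discretized to a 400-point
  uniform grid, making the conditional posterior an exact categorical over
  the grid. This lets the entire Binomial log-likelihood matrix
  (mutations × grid) be precomputed once, so each sweep is a handful of
  vectorized scatter-adds; it also mixes better than a random-walk update
  because empty clusters resample directly from the prior. Grid
  resolution 1/400 = 0.25 percentage points is well below every tolerance
  used downstream.

Default chain: 20,000 sweeps, 13,000 burn-in (tests and the acceptance
analyses use 5,000/2,000, which the convergence diagnostic accepts for the
problem sizes involved). Convergence is monitored by a split-chain
potential scale reduction factor on the total log-likelihood; PSRF > 1.1
sets `converged=False` and logs a warning — never silently.

The posterior cluster-location density is the κ-weighted Gaussian-kernel
density over monitored (π_h, κ_h) draws; each kept sweep contributes one
curve, and the median with 2.5/97.5 percentile curves forms the band. The
kernel bandwidth follows Silverman's rule on the pooled weighted draws
(the bandwidth is not prescribed by the model; Silverman is the standard
default). Cluster-level summaries (locations, weights, corrected counts
and their 95% intervals) come from the same draws. Because mixture labels
can drift along the chain, mode finding works on the density itself: local
maxima are ranked by the posterior mass of their basins, and the dominant
subclone is the largest-mass peak below the clonal cutoff (0.95).

## Detection sensitivity

`spike_in_sensitivity` plants synthetic mutations at subclonal level θ
into simulated wild-type pileups: depth Poisson around the configured
coverage, per-read sequencing errors at a flat rate (default 10⁻³), and a
per-read uniform draw against ζθ that converts reference calls to the
variant while preserving the error profile (error reads already showing
the variant are converted away). The caller predicate is pluggable; the
default (≥ 4 variant reads and VAF ≥ 0.05) stands in for a production
caller plus post-processing filters, so absolute sensitivities are
caller-dependent — only the shape is load-bearing downstream. The
detected fractions are summarized by the three-parameter logistic
`S(θ) = A/(1 + exp((χ − log θ)/σ))` fit by nonlinear least squares
(starting values: A = max response, χ = log of the half-max level,
σ = 0.5), which feeds the DP weight correction.

## Timing chromosomal gains

A gain duplicates mutations already on the gained allele, so they appear
at ploidy (multiplicity) 2 afterwards. Per-mutation multiplicity is the
Binomial maximum-likelihood choice among m = 1..n_A, except that a VAF
below 75% of the clonal ploidy-1 expectation classifies the mutation as
subclonal (excluded from timing). On the molecular-time scale (fraction of
point mutations accumulated):

* trisomy 2+1: `t = n₂/(n₂ + (n₁−n₂)/3)` — the pre-gain per-copy count is
  approximated by n₂, leaving (n₁−n₂)/3 per copy after the gain; n₁−n₂ is
  floored at 0 against sampling noise.
* UPD 2+0 and tetraploid 2+2: `t = n₂/(n₂ + n₁/2)` — two copies carry
  mutations in both epochs (for 2+2, ploidy-1 mutations arise on the four
  post-gain copies of two ancestral lineages; the geometry yields the same
  form).

CIs are percentile bootstrap over the region's mutations (default 10,000
resamples). Heterogeneity of timing across regions is a chi-square test
of independence on the k×2 table of (n₂, n₁) per segment — the literature
reports p-values without naming a statistic, and this is the natural
count-based test. Known simplification: pre-gain mutations on the
non-duplicated copy of a 2+1 region are counted "late"; this dilutes, and
cannot fabricate, early/late differences.

Early/late spectra aggregate the six pyrimidine substitution classes over
UPD/trisomy/tetraploid regions (ploidy > 1 = early, ploidy 1 = late,
subclonal kept separate) and are compared by chi-square independence on
the 2×6 table, dropping classes absent from both epochs.

## Subclonal allele-specific copy number

Heterozygous SNP reads are assigned to the two imputed parental
haplotypes; labels are consistent within an imputation block but flip
between blocks. For a clonal state (n_A, n_B),
`h_f = (1 − ρ + ρ n_B) / (2(1−ρ) + ρ(n_A + n_B))`, and combining h_f with
relative coverage logR inverts to real-valued allele-specific copy
numbers `n_A = (ρ − 1 + (1−h_f)ψ·2^{logR})/ρ` (n_B with h_f). The two
relations are exact inverses, which the test suite checks property-wise.

Pipeline per chromosome:

1. **Re-phasing and segmentation.** Each block is folded onto the minor
   band (flip if its mean fraction exceeds 0.5), undoing switch-points.
   Segmentation is exact least-squares PCF by dynamic programming on the
   per-block means (replicated per SNP, which weights blocks by SNP
   count), penalty 3 per breakpoint in units of the robust per-SNP noise
   variance. Because DP boundaries sit at selected noise extremes, an
   ordinary significance test would keep spurious cuts; adjacent segments
   are therefore merged while a Welch t test between their per-SNP
   fractions is non-significant at a strict α = 10⁻⁴.
2. **Fold-bias correction.** Folding biases a segment's mean fraction
   below 0.5 when the two bands overlap (balanced regions): the folded
   block mean is |N(d, s_b)| about the band separation d = 0.5 − h_f.
   Inverting the folded-normal mean recovers an unbiased h_f; for
   separated bands the correction vanishes. Without it, balanced diploid
   segments would be miscalled subclonal.
3. **Clonality test.** A segment is clonal if its h_f lies within a
   minimum deviation of 0.01 of one of the four floor/ceiling integer
   states of the real-valued (n_A, n_B), or if a two-sided one-sample
   t test of the per-SNP fractions against that state's theoretical h_f is
   non-significant at α = 0.05; otherwise subclonal. Candidate states
   whose total copy number is a full copy or more away from the
   coverage-implied total are excluded first (the error margin is well
   under ±1, and a clonal state at a different total — 2+1 against a
   1+0/1+1 mixture — can otherwise mimic the observed h_f).
4. **Subclone fraction τ.** Assuming the aberration changed exactly one
   copy of one allele, the two cell populations' states are one of four
   floor/ceiling combinations; at most two are compatible with the
   observed h_f (τ ∈ [0,1]), one mixing total copies (t, t+1) and the
   other (t+1, t+2), and the logR-implied total selects between them.
   τ follows in closed form from the mixture h_f equation; its 95% CI is
   a percentile bootstrap over per-SNP fractions (default 1,000
   resamples), re-applying the fold-bias offset to each resample mean.
5. **Balanced loss flag.** Equal-fraction loss of both parental copies
   leaves h_f at 0.5 while logR drops; segments with balanced h_f (within
   the 0.01 minimum deviation) but logR below the diploid baseline are
   flagged rather than force-fit.

Purity fine-tuning is a ±0.02 grid refinement of ρ minimizing the
deviation of a clonal reference segment's h_f from its theoretical value.

## Read-pair phasing

Mutation-to-SNP: read pairs covering both sites identify the SNP allele
linked to the mutation; an exact two-sided binomial test of that allele's
read fraction against the no-deletion baseline (0.5 on a near-diploid
chromosome) assigns the mutation to the deleted (below) or retained
(above) parental copy at α = 0.05, deferring to the block-level haplotype
when non-significant, else unphased. No spanning pairs is an unphased
outcome, not an error, and no multiple-testing correction is applied
(counts are logged for audit).

Mutation pairs within one insert size (default 700 bp): collinear
(nested) requires at least one pair reporting both variants and at least
one reporting only the ancestral one, with none reporting only the other;
mutually exclusive requires both single-variant patterns and no
double-variant pair, and is only issued at tumor copy number 1 (at higher
copy number one subclone can hold the two mutations on different parental
copies). A single read pair satisfies each existence rule by default; a
`min_support` parameter hardens the rules against sequencing errors.

## Clone tree

Two events in fractions f_a + f_b > 1 of tumor cells cannot occupy
disjoint cell subsets (pigeonhole), hence are collinear, with the strictly
larger one ancestral; equal fractions give collinearity of unknown order.
The tree is built greedily by descending fraction: each item attaches
under the deepest node forced to be its ancestor (forced ancestors
provably form a chain when processed in this order), or under the MRCA
root when nothing forces it deeper. Phasing-derived constraints add
collinearity or exclusivity; exclusivity contradicted by the fractions,
or a child set exceeding its parent's fraction by more than ε = 0.02
(estimates are noisy; printed examples sum exactly), raises a conflict
error listing the offenders. Items that could consistently nest in more
than one place are flagged `ambiguous` and left at the shallowest
consistent position — reported, never guessed. Every constraint is
re-verified exhaustively on the finished tree.

## Synthetic tumors

`simulate_tumor` draws everything from an explicit clone tree (fractions
consistent with the tree: children sum ≤ parent; MRCA fraction 1):

* Read counts follow the inference's own generative model —
  `R ~ Poisson(coverage × local relative copy number)`,
  `r ~ Binomial(R, ζ·m·π)`. The Poisson depth model is a declared
  stand-in for empirical per-locus depth distributions (recorded in the
  truth object); real data have overdispersion and mappability structure
  the simulator does not emulate, so passing recovery tests demonstrate
  correctness of the inference under its stated model, not robustness to
  real-world depth artifacts.
* Gained segments date their gain with an explicit molecular time;
  multiplicity (1 vs 2) and epoch (early/late) are drawn from the
  copy-time opportunity weights, enabling timing recovery tests.
  Early and late epochs can carry different substitution spectra.
* Phased SNPs follow the mixture h_f equation with fair-coin haplotype
  flips per 300 kb block (the observed block scale), depth scaled by
  local total copy number.
* Read pairs are generated only for mutation pairs within the insert
  size (default 700 bp): each pair samples one chromosome copy of one
  cell; nested clones share a parental copy, siblings never co-occur in a
  cell, and a flat error rate flips reported alleles.
* The truth object records every latent value (clone assignments,
  multiplicities, expected variant fractions, segment states and τ, gain
  times, the tree), sufficient for all downstream recovery checks.

Default study conditions mirror the deeply characterized scenarios the
package is tested against: purity 0.70, near-diploid genome, coverage 188
(deep) or 150 (cluster-recovery simulations), 5,000 SNPs per chromosome
at the subclonal-loss locus, four-component mixture with clusters at
100/60/30/20% of tumor cells and mutation weights proportional to
20/40/10/20 (renormalized — the printed weights sum to 90%), and a
40-uniform-subclone configuration for the flat-profile check.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed; fits are reproducible
bit-for-bit given it. The bundled analyses use 500 mutations at depth 150
and 5,000/2,000 Gibbs sweeps for cluster recovery (mode stable to ~1
percentage point across seeds), and 5,000 SNPs with 1,000 bootstrap
resamples for the subclonal copy-number recovery (τ stable to well under
1 point). These sizes were chosen as the smallest at which the Monte
Carlo scatter is comfortably inside the scientific tolerances quoted in
the tests.

## Known limitations

* Variant calling, haplotype imputation and purity/ploidy estimation are
  inputs, not components; published absolute sensitivity figures depend on
  the original caller and are not reproducible with the default predicate.
* The DP clusters a single sample; multi-sample joint clustering is out
  of scope.
* Subclonal copy-number states are restricted to one-copy differences;
  highly amplified regions violate the error-margin assumption behind the
  four-state enumeration.
* The timing formulas cover 2+1, 2+0 and 2+2 gains only, and inherit the
  "all ploidy-1 mutations are late" simplification.
* Mutations on subclonally variable segments use the cell-fraction-
  weighted mean copy number for ζ (the exact treatment would need the
  phase of each mutation relative to the copy-number event).
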