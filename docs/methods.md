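# Methods

`rhizogwas` implements genome-wide association analysis for bacterial
pangenomes of the kind exemplified by worldwide collections of
*Ensifer meliloti*: ~150 clonally structured strains carrying a
multi-replicon genome (a large chromosome plus megaplasmids), typed
for both SNPs and gene presence/absence variants (PAVs), and
phenotyped for quantitative and binary traits. This note describes
the models, the numerical choices, and what the synthetic data do and
do not emulate.

## Variant universe and filters

SNPs are read from VCF with pseudo-diploid haploid encoding
(`0/0` → 0, `1/1` → 1, `0/1` → missing; haploid `0`/`1` accepted).
Heterozygous calls in a haploid organism are read-mapping artifacts
and are converted to missing data. Multi-allelic sites are split into
one biallelic record per alt allele; multi-nucleotide substitutions
are kept as single variants; indels are dropped, as are sites with
QUAL < 20 when quality is present. PAVs come from a gene-cluster
presence/absence table; clusters absent from the reference genome have
no coordinates and live on the pseudo-replicon `unplaced`.

Association analyses use variants with minor allele frequency
MAF ≥ 0.05 and missingness ≤ 0.20. The MAF denominator excludes
missing calls (standard practice; consistent with the per-site
sample-size adjustment in the diversity estimators). For PAVs the
minor state is whichever of presence/absence is rarer. Missing
dosages are mean-imputed per variant before any matrix algebra
(kinship, association, BSLMM); the unimputed matrix is used for LD
and diversity, which handle missingness natively.

## Diversity

Watterson's θ_W = Σ_sites 1/a(n_s) / L and pairwise
θ_π = Σ_sites 2p(1−p)·n_s/(n_s−1) / L, both per callable bp, with
per-site sample sizes n_s so missing calls shrink only the affected
site's contribution. The callable length L per replicon is an input:
deciding which sites had adequate coverage happens upstream of variant
calling and is out of scope here.

## LD grouping

Strongly linked variants are statistically interchangeable in
association tests, so they are collapsed before testing. The grouping
is greedy and MAF-seeded: repeatedly take the ungrouped variant with
the highest MAF (ties: fewest missing calls, then input order) as a
seed, and group with it every ungrouped variant with r² ≥ threshold
(0.95 by default, 0.80 as the relaxed alternative) against the seed.
r² is the squared Pearson correlation of dosages over
pairwise-complete strains; pairs with fewer than two complete
observations, or constant on the complete set, are never grouped.
Groups are therefore seed-relative and disjoint: a variant can be in
high LD with the seeds of two different groups yet belong to only one.
Association tests run on seeds plus ungrouped variants; annotation
(composition, replicon set, spanned distance — defined only when all
SNP members share one replicon) uses full membership.

## Mixed-model association and chip heritability

The kinship matrix is the standardized genetic covariance
K = ZZᵀ/p over centered, unit-variance dosage columns, so
mean(diag K) = 1. The model is

    y = Xb + g + e,   g ~ N(0, σ_g² K),   e ~ N(0, σ_e² I).

One eigendecomposition K = U D Uᵀ makes every profile-likelihood
evaluation O(n) in the rotated basis. The variance ratio
λ = σ_g²/σ_e² is optimized over log₁₀ λ ∈ [−5, 5]: a 21-point grid
spanning ten equal subintervals guards against multimodal profiles,
followed by bounded Brent refinement around the best grid point
(tolerance 10⁻⁶ on log₁₀ λ).

* **Association** uses ML likelihoods: each variant adds one fixed
  effect, λ is re-optimized per variant, and the likelihood-ratio
  statistic is referred to χ²(1). Constant columns are flagged
  untestable rather than dropped. Binary traits are analyzed as 0/1
  quantitative values.
* **Chip heritability (PVE)** uses REML on the intercept-only model,
  reported as PVE = λ·d̄/(λ·d̄+1) with d̄ = mean diag K (exactly the
  genetic variance fraction for the standardized K). A 95% interval
  comes from the REML profile on the λ grid (χ²₁/2 cutoff). When K is
  nearly unstructured the genetic and residual components are not
  separately identifiable; this is reported as a wide interval plus a
  warning, not an error.
* **QQ diagnostics**: observed vs uniform −log₁₀ p quantiles and the
  genomic inflation factor median(LRT)/0.456.

Strains with missing phenotype are dropped per trait, with K rebuilt
on the remaining strains from columns that are still polymorphic.

## Sparse Bayesian mixed model (BSLMM)

For traits driven by a few large-effect variants on top of a polygenic
background, the package fits

    y = 1μ + Xβ + u + e,  u ~ N(0, σ_b²K),
    β_j = 0 with prob 1−π, else N(0, σ_a²),

and summarizes PVE = Var(Xβ+u)/(Var(Xβ+u)+σ_e²) over posterior draws.
The sampler mixes cheap indicator moves with periodic refreshes:

* per step, one add/remove/swap Metropolis–Hastings proposal on the
  inclusion indicators with the proposed effect integrated out
  analytically;
* every `heavy_every` (default 5) steps: joint conjugate redraw of the
  included effects; a marginal MH update of h = σ_b²/(σ_b²+σ_e²) with
  σ_e² integrated out under its Jeffreys prior (diagonal in the
  eigenbasis of K, so O(n) per evaluation); conjugate draws of σ_e²,
  the polygenic component, σ_a², and π.

Priors: h ~ U(0,1); log π ~ U(log(1/p), 0); σ_a² ~ InvGamma(2, var y)
(slab effects on the scale of the trait); Jeffreys on σ_e². The
spike-and-slab mixture weight and the polygenic fraction thus follow
the conventional uniform priors, while the slab variance is given a
weakly informative conjugate prior rather than a variance-partition
(ρ) parametrization; ρ = Var(Xβ)/Var(Xβ+u) is reported as a derived
trace quantity. Genotype columns are standardized before sampling.

Defaults are desk-scale — burn-in 10,000, 100,000 steps, records every
500, 5 independent chains combined — replacing the multi-million-step
runs this model family is often given; the chain length is a config
knob and the model is unchanged. Convergence is monitored by split
R-hat of the PVE trace across chains; R-hat > 1.2 flags the output
but is not fatal. Fixed seed and config give bit-identical traces.

## Permutation empirical nulls

Reassigning phenotype values to strains at random (missing entries
stay put) preserves the trait distribution, the genotypes, LD and
kinship, while destroying any true genotype–phenotype link. For each
of `n_perms` (default 100) permutations, seeded as master_seed + i,
the pipeline re-runs PVE estimation, the seed-variant scan, forward
selection and the enrichment statistics. Empirical percentiles use
linear (type-7) interpolation. Kinship and grouping are computed once:
they depend only on genotypes, which permutation leaves untouched.
BSLMM nulls are optional (they dominate runtime) and off by default.

## Forward selection, PRVE and candidate calling

From the `top_k` (default 100) most associated seed variants, forward
selection adds at each rank the variant maximizing model R², to
`max_rank` = 25. Two summaries are tracked:

* cumulative R² of the rank-r model (verified in tests against direct
  multiple regression at every rank);
* PRVE(r) — the proportion of remaining variance explained,
  (cumR²(r) − cumR²(r−1))/(1 − cumR²(r−1)), equivalently the R² of the
  rank-(r−1) residuals on the newly chosen variant after
  orthogonalizing it against the earlier selections. With correlated
  predictors, regressing residuals on the *raw* variant gives a
  slightly different number and breaks the factorization
  1 − cumR²(r) = Π_{k≤r}(1 − PRVE(k)); the orthogonalized reading is
  used so that identity holds exactly.

Candidates are the path entries before the first rank whose PRVE falls
below the rank-matched null 95th percentile; each called seed expands
to its whole LD group for reporting. The total PVE of top variants is
max_m (cumR²(m) − null median(m)), floored at 0. Enrichment of the
top 10 associated groups reports mean member MAF, mean group size
(ungrouped = size 1), and SNP proportion with mixed groups counted
fractionally — group-wise by default, with the variant-wise average
also emitted because the two conventions differ whenever group sizes
vary. Empirical enrichment p-values use the add-one rule
(r+1)/(n+1), so finite permutation sets never yield p = 0.

## Synthetic data: what it emulates, what it does not

The generator targets the statistical structure the analysis assumes,
not sequence content:

* **Clonal structure.** A star-of-clades genealogy: `n_clades`
  (default 10) clades diverge from a common ancestor; strains within a
  clade differ by `within_clade_mutations` private flips (default 50).
  This reproduces the strong relatedness the kinship correction
  exists for, without coalescent machinery.
* **Replicon-specific LD.** Each replicon is cut into haplotype
  blocks (defaults: 175 kb on the 3.5-Mb chromosome, 520 bp and 1 kb
  on the 1.8-Mb and 1.5-Mb megaplasmids, mirroring the contrast
  between long clonal chromosomal LD and short recombining
  megaplasmid blocks). SNPs within a block share one clade-level
  genealogy (nested derived-allele sets), giving high within-block
  r²; blocks are independent.
* **MAF spectrum.** Site frequencies follow a folded neutral-like
  spectrum, density ∝ 1/q on [maf_floor, 0.5]; configurations whose
  MAF floor is unattainable at the given sample size are rejected.
* **PAVs** are gain/loss events on clade branches with orderings drawn
  independently of the SNP haplotypes, so SNP–PAV linkage is weak.
  A configurable fraction (default 20%) receives reference
  coordinates; the rest are unplaced.
* **Missingness and het artifacts.** Per-site missingness rates are
  drawn U(0, missing_rate) (default cap 20%); ~1% of SNP calls are
  flagged heterozygous so the het-to-missing filter path is exercised
  on VCF round trips.
* **Phenotypes.** Polygenic component with covariance ∝ K scaled to
  `pve_background`, plus `n_large_effects` sparse effects splitting
  `large_effect_pve` equally, plus i.i.d. noise; components are
  empirically standardized so realized variance fractions track the
  requested ones (mean within ±0.05 over 50 replicates). Binary
  traits threshold the liability at the quantile giving the requested
  minority-class fraction exactly. The generator returns the causal
  ids and the realized PVE of each draw.

Known limitations. With ~10 clades there are few distinct clade-level
allele patterns, so unrelated variants (across blocks, across
replicons, SNP vs PAV) collide onto identical patterns more often
than in real data; this creates chance long-range LD groups, inflates
megaplasmid spanned distances, and means a causal variant's signal
can be absorbed by a near-duplicate pattern outside its seed-relative
LD group. Fine-mapping-style recovery tests therefore use panels with
more clades (20) and more private mutations, where patterns are
distinctive; the 10-clade default is kept for the relatedness-driven
analyses it was designed for. There is no recombination model beyond
block independence, no sequence content, and no read-level error
model.

## Problem sizes in the shipped tests

The test suite and the acceptance script run everything at desk
scale, chosen as the smallest sizes at which the statistical
assertions are stable: the permutation-null PVE bound uses the full
study-scale panel (153 strains, 10 clades, ~10,300 common variants,
100 permutations); calibration checks pool ~3,700 seed-variant tests
over 5 permutations of a 153-strain, ~1,200-variant panel (a single
permutation's tests share LD structure, so pooling independent
permutations is what makes the uniformity test valid); BSLMM checks
use 100-strain panels with a few hundred variants and short chains
(2,000–30,000 steps). Full-size runs are a matter of configuration,
not code.
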