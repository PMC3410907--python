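# Methods

This note documents the models, estimators, defaults and numerical choices
behind ldkit, what the synthetic-data generators do and do not emulate, and
the problem sizes used by the validation suite.

## Linkage disequilibrium

For biallelic sites A and B with alt-allele frequencies `pA`, `pB` and
haplotype frequency `pAB`,

    D  = pAB − pA·pB
    r² = D² / (pA(1−pA) · pB(1−pB))

`r2_phased` counts `pAB` directly from the haplotype matrix and is exact.
`r2_unphased_em` estimates the four haplotype frequencies from the 3×3
genotype table by EM: every cell except the double heterozygote contributes
a uniquely phased pair of haplotypes; the double-heterozygote count is split
between cis (AB/ab) and trans (Ab/aB) configurations in proportion to
`f_AB·f_ab / (f_AB·f_ab + f_Ab·f_aB)` at the current iterate. EM starts at
linkage equilibrium, stops when the largest frequency change is below 1e−8,
and gives up after 100 iterations with a `RuntimeWarning` (returning the
last iterate — near convergence this is indistinguishable from the fixed
point; the warning fires occasionally on very large samples where steps are
tiny from the start). Samples missing either dosage are excluded pairwise.
Monomorphic input raises: r² is undefined there, and callers that scan many
pairs (pruning, coverage) treat such pairs as r² = 0.

LD is evaluated only within a horizon (default 1 Mb); across chromosomes or
beyond the horizon r² is defined as 0. This bounds every pairwise scan and
matches the scale at which LD is negligible in outbred panels.

For pruning and selection on *unphased* genotype matrices, pairwise r² is
the squared Pearson correlation of dosages — the composite-LD surrogate
standard pruning tools use — rather than one EM fit per pair; the EM
estimator remains available per pair (`method="em"`). On phased panels all
operations use the exact haplotype r².

## Pruning, selection, coverage

`ld_prune` scans candidates in (chrom, pos) order and keeps a SNP iff its
r² with every *kept* SNP within the window (default 1 Mb) is ≤ the
threshold. Leftmost-wins tie-breaking makes the scan deterministic and
idempotent.

`select_replication_snps` ranks candidates by ascending p-value (ties by
genomic position), then greedily accepts subject to (a) r² ≤ 0.3 (default)
with every accepted SNP within the window and (b) distance > 250 kb from
every supplied known locus. The 0.3 threshold mirrors the "strong LD"
cutoff used for pruning throughout, since no separate independence
criterion is canonical.

`select_null_snps` builds the genomic-control null set on an enriched
array: replication SNPs whose submitting traits exclude the analysis trait,
minus SNPs within 250 kb of known trait loci, LD-pruned at r² > 0.3. An
optional p-value filter (e.g. keep only SNPs with trait p > 0.5 in a
supplied GWAS) implements the alternative null-set recipe; it has no
default threshold and is off unless requested. `select_structure_snps` is
the MAF > 0.05 + pruning recipe for PCA/MDS and kinship input; the
eigen-decomposition itself is delegated to standard numerics.

`coverage_fraction` counts a target covered iff it is itself a tag or some
same-chromosome tag within the horizon reaches r² ≥ threshold (default
0.8), reported overall and per MAF bin. Default bins are
{0}, (0,.01], (.01,.02], (.02,.05], (.05,.1], (.1,.2], (.2,.3], (.3,.4],
(.4,.5]; monomorphic sites always form their own bin so spectra sum to 1.

## Fine-mapping regions

`build_sfm_region` seeds on the positional span of the index SNP and all
SNPs with r² ≥ 0.5 (default) to it within the horizon. Each boundary then
moves outward independently:

1. **Hotspot rule.** If a recombination hotspot lies outward of the
   boundary with its inner (region-proximal) edge within 0.1 cM (default
   `hotspot_search_cm`), the boundary moves to that inner edge. Hotspots
   are maximal runs of inter-anchor map intervals with local rate
   (ΔcM/Δbp·10⁶) ≥ 10 cM/Mb (default) — the conventional hotspot
   definition; the inner edge is used because hotspots delimit LD blocks.
2. **Shoulder fallback.** Otherwise the boundary moves outward by 0.02 cM
   on the genetic map (≈20 kb at 1 cM/Mb). `shoulder_mode="always"` applies
   the shoulder even when a hotspot fired (taking the outermost of the
   two), for designs that want both behaviours; the default is fallback
   because the hotspot is already a natural LD-block boundary.

Every boundary decision is recorded in the region's provenance list.
`build_lfm_region` extends boundaries over all gene intervals overlapping
the region, repeated to a fixed point (a gene pulled in can overlap further
genes). `merge_regions` merges strictly overlapping same-chromosome regions
(abutting regions stay separate), concatenates traits and index SNPs, and
is idempotent and input-order-invariant. Genetic-map interpolation is
piecewise linear between anchors and constant beyond them; the inverse
query returns the leftmost bp on zero-recombination stretches, which makes
shoulder extension conservative, and cannot extend past the outermost
anchors.

## Enrichment-aware statistics

**Trend test.** Cochran–Armitage with scores (0, 1, 2); missing dosages are
excluded; monomorphic-among-called or single-class input raises. The
vectorized `trend_test_many` computes all variants at once for λ_GC scans;
tests cross-check the scalar version against the independent identity
`χ² = N·corr(phenotype, dosage)²`.

**Genomic control.** λ_GC = median(χ²)/0.4549, the χ²₁ median. On an
enriched array λ computed over all SNPs confounds enrichment with
stratification; λ over the `select_null_snps` output is the calibrated
quantity. The validation suite reproduces the qualitative phenomenon:
differentiated trait-panel SNPs under stratified sampling inflate λ to
≈1.4 while the other-trait null set stays at ≈1.0.

**Kinship.** `ibd_mom` is method-of-moments IBD estimation from
identity-by-state counts — the computation PLINK-style tools actually
perform. With per-SNP frequencies p (q = 1−p), the expected per-SNP IBS
probabilities are

    P(IBS0|IBD0) = 2p²q²            P(IBS1|IBD0) = 4p³q + 4pq³
    P(IBS1|IBD1) = 2pq              P(IBS0|IBD1) = 0

k0 is estimated from the observed IBS0 count, k1 from the IBS1 count after
subtracting the k0 contribution, k2 = 1 − k0 − k1; estimates are clipped to
[0, 1] and renormalized (standard simplex repair; near boundaries this
gives the constrained estimator a small upward bias in π̂ that shrinks with
SNP count). No small-sample IBS correction is applied, so allele
frequencies should come from a reference panel or a large sample, and only
SNPs with frequencies well inside (0, 1) should be used — exactly what
`select_structure_snps` produces. `grm` is the standardized-genotype
relationship matrix, `G_ij = mean_m (g_im−2p_m)(g_jm−2p_m)/(2p_m(1−p_m))`
over SNPs co-called in both samples. E[G_ij] equals π̂ (= 2× the kinship
coefficient), which the suite verifies against `ibd_mom` within ±0.1.

**Overlap test.** The null redraws |A| and |B| ids independently and
uniformly without replacement from an explicit universe. Under that null
the overlap count is exactly Hypergeometric(U; |A|, |B|), so replicates are
drawn as one hypergeometric variate each — distributionally identical to
materializing the sets, and fast. p = (1 + #{replicate ≥ observed}) /
(n_sim + 1), one-sided for enrichment, a valid finite-sample permutation
p-value (so p ≥ 1/(n_sim+1) always). The universe is a required argument
because it *is* the null hypothesis: the frame both consortia selected
from (union of submissions, full candidate pool, …) changes the p-value,
and silently defaulting it would bias results.

## Synthetic data

`simulate_panel` is a founder-mosaic model, not a coalescent. Founder
haplotypes draw alleles site-wise from a frequency law with density ∝ 1/x
truncated to [1/n_haplotypes, 0.5] (the 1/(2N) lower bound with N the
diploid sample size) — rare variants dominate, as in sequence-derived
catalogs. Descendant haplotypes copy a random founder and switch founders
at crossover points drawn from an inhomogeneous Poisson process whose
intensity follows the genetic map, accumulated over `mosaic_generations`
(default 50) meioses. The depth parameter matters: one meiosis on a ~1 cM
region yields ~0.01 crossovers per haplotype and hence no hotspot
structure; fifty generations give LD time to decay at hotspots while cold
blocks stay intact. The panel's LD strength scales like 1/n_founders, so
few founders (≈8–12) give strong block LD and many founders give an
effectively unlinked panel. What this model does **not** reproduce:
coalescent genealogy (no realistic allele-frequency/LD coupling, no
recurrent mutation), so passing tests demonstrate algorithmic correctness
on LD-structured data, not population-genetic realism.

`drop_pedigree` assigns founders panel haplotypes without replacement and
forms children's gametes by single-meiosis recombination of the parental
tracks (crossovers again Poisson along the map). Because every founder
haplotype carries a unique label, realized IBD segments are known exactly;
the returned truth is the length-weighted genome fraction in IBD states
0/1/2 per pair, summing to 1 exactly.

`simulate_stratified_cc` draws two subpopulation frequency vectors from the
Balding–Nichols construction — Beta(p(1−F)/F, (1−p)(1−F)/F), mean p,
variance F·p(1−p) — and genotypes as Binomial(2, subpop frequency); the
phenotype depends only on population membership, so association signal is
pure stratification. F may be per-SNP, letting differentiated
("trait-enriched") and undifferentiated (null) SNPs coexist in one study.
Note that with F > 0 even equal nominal case/control population fractions
leave residual inflation from the random realized composition; the clean
null is F = 0.

`simulate_summary_stats` is analytic: the marginal effect at SNP j is
Σ_c r_jc·β_c over causal SNPs within the horizon (signed r), the standard
error 1/√(2·n·maf(1−maf)), and the Wald z receives unit-normal noise, so
unlinked null SNPs have uniform p-values (p is floored at 1e−300 to stay in
(0, 1]). This is orders of magnitude faster than phenotype simulation and
sufficient because the selection algorithms consume only the p-value
ranking.

All generators are deterministic given their seed.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: 1,000 random pairs on
a 500-SNP/200-haplotype panel for the exact-oracle check; 200 pairs on a
1,000-haplotype collapsed panel for EM consistency (tolerance 0.02);
exhaustive post-verification of all four selection operations on a 500-SNP
fixture; 20 replicate studies of 10,000 SNPs (500 cases/500 controls) for
null-λ calibration and 20 studies of 1,000 + 1,000 SNPs (250/250,
F = 0.005, 70/30 sampling) for the enrichment ordering; 10 pedigree studies
of ~5,000 common unlinked SNPs for kinship recovery; 10,000 replicates and
1,000 trials for overlap calibration (set sizes 150/150 in a universe of
800, where the discrete null has an attainable level of .0459, closest to
the nominal .05). These sizes keep each scenario's Monte-Carlo error well
inside the asserted tolerance.

## Known limitations

- No phasing, no D′, no indel/CNP LD semantics; non-SNP array content is
  carried as annotation only.
- Milligan-style full-maximum-likelihood IBD is not implemented; the
  method-of-moments estimator is what the suite validates.
- PCA/MDS decomposition, mixed-model association and case-control loading
  projection are out of scope; ldkit produces their SNP inputs.
- The founder-mosaic generator's frequency spectrum is quantized at
  1/n_founders when the founder pool is small; spectrum-sensitive studies
  should use founder pools close to the panel size.
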