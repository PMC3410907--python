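"""Statistics for trait-enriched array data.

Because such arrays over-represent trait-associated SNPs, the usual
whole-array recipes for genomic control, PCA/kinship SNP selection and
relatedness estimation are biased. This module provides the array-aware
versions: a null SNP set built from other-trait replication SNPs (known-locus
exclusion + LD pruning), the Cochran–Armitage trend test and λ_GC, a
MAF-filtered pruned SNP set for structure analysis, method-of-moments IBD
estimation, the standardized-genotype relationship matrix (GRM), and a
permutation test for SNP-set overlap between traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import (
    ArrayDesign,
    ConfigError,
    EmptyPanelError,
    GenotypeMatrix,
    HaplotypePanel,
    InsufficientDataError,
    KinshipResult,
    LambdaGC,
    MISSING,
    MonomorphicVariantError,
    OverlapTestResult,
    SummaryStats,
)
from .ld import DEFAULT_LD_HORIZON_BP, ld_prune

#: Median of the 1-df chi-square distribution, the λ_GC denominator.
CHI2_1DF_MEDIAN = 0.4549


@dataclass
class NullSnpSet:
    """A near-independent null SNP set with an audit of how it was built."""

    ids: list[str]
    provenance: str


def select_null_snps(
    design: ArrayDesign,
    target_trait: str,
    known_assoc: list[tuple[str, int]],
    panel_or_geno: HaplotypePanel | GenotypeMatrix,
    exclusion_bp: int = 250_000,
    r2_max: float = 0.3,
    window_bp: int = DEFAULT_LD_HORIZON_BP,
    pvalue_filter: tuple[SummaryStats, float] | None = None,
) -> NullSnpSet:
    """Null SNPs for genomic control on a trait-enriched array.

    Start from replication SNPs whose submitting traits exclude the analysis
    trait, drop any within ``exclusion_bp`` of a known trait-associated
    locus, and LD-prune the rest at ``r2_max``. ``pvalue_filter`` optionally
    restricts further to SNPs with trait p-value above a threshold in a
    supplied GWAS (e.g. p > 0.5), an alternative null-set recipe.
    """
    replication = design.ids_for("replication")
    other_trait = [
        vid for vid in replication if target_trait not in design.traits_of(vid)
    ]
    steps = [
        f"{len(other_trait)} replication SNPs from traits other than {target_trait}"
    ]
    data = panel_or_geno
    positioned = [
        (vid, data.variants[data.index_of(vid)]) for vid in other_trait if _has(data, vid)
    ]
    far = [
        vid
        for vid, v in positioned
        if not any(
            v.chrom == c and abs(v.pos - p) <= exclusion_bp for c, p in known_assoc
        )
    ]
    steps.append(
        f"{len(far)} beyond {exclusion_bp} bp of {len(known_assoc)} known loci"
    )
    if pvalue_filter is not None:
        stats, threshold = pvalue_filter
        pvals = {rec[0]: rec[3] for rec in stats.records}
        far = [vid for vid in far if pvals.get(vid, 1.0) > threshold]
        steps.append(f"{len(far)} with {stats.trait} p > {threshold}")
    if not far:
        raise EmptyPanelError(
            "no null SNPs survive exclusion; relax exclusion_bp/r2_max or add traits"
        )
    pruned = ld_prune(data, far, r2_max=r2_max, window_bp=window_bp)
    steps.append(f"{len(pruned)} after LD pruning at r2 <= {r2_max}")
    if not pruned:
        raise EmptyPanelError("LD pruning removed every null SNP; relax r2_max")
    return NullSnpSet(ids=pruned, provenance="; ".join(steps))


def _has(data, vid: str) -> bool:
    try:
        data.index_of(vid)
        return True
    except KeyError:
        return False


def trend_test(
    geno: GenotypeMatrix, phenotype: np.ndarray, variant_index: int
) -> float:
    """Cochran–Armitage trend chi-square (1 df), scores (0, 1, 2).

    Missing dosages are excluded. Raises if the variant is monomorphic among
    called samples or only one phenotype class is present.
    """
    g = geno.dosages[:, variant_index]
    phen = np.asarray(phenotype)
    keep = g != MISSING
    g = g[keep].astype(np.int64)
    y = phen[keep].astype(np.int64)
    n_tot = g.size
    r_cases = int(y.sum())
    if r_cases == 0 or r_cases == n_tot:
        raise ConfigError("both phenotype classes must be present")
    n_i = np.bincount(g, minlength=3).astype(float)  # genotype totals
    r_i = np.bincount(g[y == 1], minlength=3).astype(float)  # cases per genotype
    if np.count_nonzero(n_i) < 2:
        raise MonomorphicVariantError("variant monomorphic among called samples")
    x = np.array([0.0, 1.0, 2.0])
    u = float(np.sum(x * (r_i - n_i * r_cases / n_tot)))
    var = (
        r_cases
        * (n_tot - r_cases)
        / n_tot**3
        * (n_tot * np.sum(n_i * x**2) - np.sum(n_i * x) ** 2)
    )
    return float(u * u / var)


def trend_test_many(geno: GenotypeMatrix, phenotype: np.ndarray) -> np.ndarray:
    """Cochran–Armitage trend chi-squares for every variant at once.

    Vectorized version of :func:`trend_test` for λ_GC scans over thousands of
    SNPs; variants that are monomorphic among called samples get NaN.
    """
    g = geno.dosages
    called = g != MISSING
    y = np.asarray(phenotype, dtype=float)[:, None]
    r_tot = (called * y).sum(axis=0)  # cases called, per variant
    n_tot = called.sum(axis=0).astype(float)
    if np.any(r_tot == 0) or np.any(r_tot == n_tot):
        raise ConfigError("both phenotype classes must be present at every variant")
    sum_nx = np.zeros(g.shape[1])
    sum_nx2 = np.zeros(g.shape[1])
    sum_rx = np.zeros(g.shape[1])
    n_classes = np.zeros(g.shape[1])
    for dose in (0, 1, 2):
        ind = (g == dose) & called
        n_i = ind.sum(axis=0).astype(float)
        r_i = (ind * y).sum(axis=0)
        sum_nx += n_i * dose
        sum_nx2 += n_i * dose * dose
        sum_rx += r_i * dose
        n_classes += n_i > 0
    u = sum_rx - sum_nx * r_tot / n_tot
    var = r_tot * (n_tot - r_tot) / n_tot**3 * (n_tot * sum_nx2 - sum_nx**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(n_classes >= 2, u * u / var, np.nan)
    return chi2


def lambda_gc(stats: list[float] | np.ndarray, snp_set_label: str = "") -> LambdaGC:
    """Genomic-control inflation: median chi-square over the χ²₁ median."""
    arr = np.asarray(stats, dtype=float)
    if arr.size == 0:
        raise ConfigError("empty statistic list")
    return LambdaGC(
        lam=float(np.median(arr) / CHI2_1DF_MEDIAN),
        n_snps=int(arr.size),
        snp_set_label=snp_set_label,
    )


def select_structure_snps(
    panel_or_geno: HaplotypePanel | GenotypeMatrix,
    maf_min: float = 0.05,
    r2_max: float = 0.3,
    window_bp: int = DEFAULT_LD_HORIZON_BP,
) -> list[str]:
    """Common, near-independent SNPs for PCA/MDS and kinship estimation.

    MAF > ``maf_min`` filter followed by LD pruning at ``r2_max``; the
    eigen-decomposition itself is left to standard numerics.
    """
    data = panel_or_geno
    if isinstance(data, HaplotypePanel):
        mafs = data.maf
    else:
        mafs = data.maf()
    ids = [v.id for v, m in zip(data.variants, mafs) if m > maf_min]
    if not ids:
        raise EmptyPanelError(f"no SNPs with MAF > {maf_min}")
    return ld_prune(data, ids, r2_max=r2_max, window_bp=window_bp)


def ibd_mom(
    geno: GenotypeMatrix,
    i: str | int,
    j: str | int,
    freqs: np.ndarray | None = None,
    min_snps: int = 200,
) -> KinshipResult:
    """Method-of-moments IBD state estimation from identity-by-state counts.

    Observed IBS0/IBS1 counts are equated to their expectations given allele
    frequencies under the three IBD states; the estimates are constrained to
    the simplex by truncation and renormalization. π̂ = k2 + k1/2.
    """
    si = geno.sample_index_of(i) if isinstance(i, str) else i
    sj = geno.sample_index_of(j) if isinstance(j, str) else j
    gi = geno.dosages[si].astype(np.int64)
    gj = geno.dosages[sj].astype(np.int64)
    if freqs is None:
        freqs = geno.allele_freq()
    p = np.asarray(freqs, dtype=float)
    keep = (gi != MISSING) & (gj != MISSING) & (p > 0) & (p < 1)
    gi, gj, p = gi[keep], gj[keep], p[keep]
    n = gi.size
    if n < min_snps:
        raise InsufficientDataError(
            f"{n} complete polymorphic SNPs for pair; need >= {min_snps}"
        )
    q = 1.0 - p
    ibs = 2 - np.abs(gi - gj)  # shared-allele count of a dosage pair
    n0_obs = float((ibs == 0).sum())
    n1_obs = float((ibs == 1).sum())
    e0_ibd0 = float(np.sum(2 * p**2 * q**2))
    e1_ibd0 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e1_ibd1 = float(np.sum(2 * p * q))
    k0 = n0_obs / e0_ibd0 if e0_ibd0 > 0 else 0.0
    k1 = (n1_obs - k0 * e1_ibd0) / e1_ibd1 if e1_ibd1 > 0 else 0.0
    k2 = 1.0 - k0 - k1
    k = np.clip([k0, k1, k2], 0.0, 1.0)
    k = k / k.sum()
    name_i = geno.samples[si]
    name_j = geno.samples[sj]
    return KinshipResult(
        pair=(name_i, name_j),
        k0=float(k[0]),
        k1=float(k[1]),
        k2=float(k[2]),
        n_snps_used=n,
    )


def grm(geno: GenotypeMatrix, freqs: np.ndarray | None = None) -> np.ndarray:
    """Variance-components genetic relationship matrix.

    Entry (i, j) averages (gᵢ−2p)(gⱼ−2p)/(2p(1−p)) over SNPs co-called in
    both samples; the diagonal is ≈ 1 + F. Missing dosages are excluded
    pairwise.
    """
    if freqs is None:
        freqs = geno.allele_freq()
    p = np.asarray(freqs, dtype=float)
    usable = (p > 0) & (p < 1)
    if not usable.any():
        raise EmptyPanelError("no polymorphic SNPs with frequencies in (0, 1)")
    g = geno.dosages[:, usable].astype(float)
    p = p[usable]
    called = g != MISSING
    z = np.where(called, (g - 2 * p) / np.sqrt(2 * p * (1 - p)), 0.0)
    counts = called.astype(float) @ called.astype(float).T
    with np.errstate(invalid="ignore"):
        out = (z @ z.T) / counts
    return out


def overlap_test(
    set_a: list[str],
    set_b: list[str],
    universe: list[str],
    n_sim: int = 10_000,
    seed: int = 0,
) -> OverlapTestResult:
    """Permutation test of SNP-set overlap between two traits.

    Null replicates redraw |A| and |B| ids independently and uniformly
    without replacement from the universe; under that null the overlap count
    is hypergeometric, which is how replicates are drawn. The one-sided
    enrichment p-value is (1 + #{replicates ≥ observed}) / (n_sim + 1).
    The universe — the frame both sets were selected from — must be supplied
    explicitly because it determines the null.
    """
    if n_sim < 1:
        raise ConfigError("n_sim must be >= 1")
    uni = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= uni or not b <= uni:
        raise ConfigError("both SNP sets must be subsets of the universe")
    n_overlap = len(a & b)
    n_min = min(len(a), len(b))
    rng = np.random.default_rng(seed)
    sims = rng.hypergeometric(len(a), len(uni) - len(a), len(b), size=n_sim)
    p = (1.0 + float((sims >= n_overlap).sum())) / (n_sim + 1.0)
    return OverlapTestResult(
        n_overlap=n_overlap,
        prop_max=n_overlap / n_min if n_min else 0.0,
        expected=float(sims.mean()),
        p_enrichment=p,
        n_sim=n_sim,
    )
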