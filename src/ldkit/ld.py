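"""Pairwise linkage disequilibrium, pruning, tagging coverage, MAF spectrum.

r² between two biallelic sites is the squared correlation of their allele
indicators, ``r² = D² / (pA(1−pA) pB(1−pB))`` with ``D = pAB − pA·pB``. On
phased haplotypes the haplotype frequency pAB is observed directly; on
unphased genotypes it is estimated by EM over the double-heterozygote phase
ambiguity. Everything downstream (pruning, replication-SNP independence,
null-set construction, coverage) funnels through these two estimators.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .containers import (
    MISSING,
    ConfigError,
    GenotypeMatrix,
    HaplotypePanel,
    MonomorphicVariantError,
    VariantRecord,
)

logger = logging.getLogger(__name__)

#: Default maximum distance (bp) at which LD is evaluated; beyond it, and
#: across chromosomes, r² is defined as 0.
DEFAULT_LD_HORIZON_BP = 1_000_000

#: Default MAF bin edges; monomorphic sites form their own bin.
DEFAULT_MAF_BINS = (0.0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


def _d_and_denominator(pa: float, pb: float, pab: float) -> tuple[float, float]:
    d = pab - pa * pb
    return d, pa * (1.0 - pa) * pb * (1.0 - pb)


def r2_phased(panel: HaplotypePanel, i: int, j: int) -> float:
    """Squared allelic correlation between variant columns i and j."""
    return signed_r_phased(panel, i, j) ** 2


def signed_r_phased(panel: HaplotypePanel, i: int, j: int) -> float:
    """Signed allelic correlation r (needed to propagate effects through LD)."""
    a = panel.alleles[:, i]
    b = panel.alleles[:, j]
    pa = a.mean()
    pb = b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise MonomorphicVariantError(
            f"LD undefined: variant column {i if pa in (0.0, 1.0) else j} is monomorphic"
        )
    pab = (a & b).mean()
    d, denom = _d_and_denominator(pa, pb, pab)
    return float(np.clip(d / np.sqrt(denom), -1.0, 1.0))


def r2_unphased_em(
    geno: GenotypeMatrix,
    i: int,
    j: int,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> float:
    """EM estimate of r² from unphased dosages.

    Haplotype frequencies are estimated from the 3×3 genotype table; only the
    double heterozygote cell is phase-ambiguous. EM starts at linkage
    equilibrium. Samples missing either dosage are excluded. Non-convergence
    after ``max_iter`` raises a warning and returns the last iterate.
    """
    g1 = geno.dosages[:, i]
    g2 = geno.dosages[:, j]
    keep = (g1 != MISSING) & (g2 != MISSING)
    g1 = g1[keep].astype(np.int64)
    g2 = g2[keep].astype(np.int64)
    n = g1.size
    if n == 0:
        raise MonomorphicVariantError("no complete genotype pairs")
    counts = np.bincount(g1 * 3 + g2, minlength=9).reshape(3, 3).astype(float)
    pa = g1.mean() / 2.0
    pb = g2.mean() / 2.0
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise MonomorphicVariantError(
            "LD undefined: variant monomorphic among complete pairs"
        )

    # Unambiguous haplotype contributions per genotype cell (g1, g2):
    # hap types indexed (alleleA, alleleB) in {11, 10, 01, 00}.
    fixed = np.zeros(4)  # counts of 11, 10, 01, 00 haplotypes
    for a in range(3):
        for b in range(3):
            c = counts[a, b]
            if c == 0 or (a == 1 and b == 1):
                continue
            n11 = _hap11_count(a, b)
            n10 = a - n11
            n01 = b - n11
            n00 = 2 - n11 - n10 - n01
            fixed += c * np.array([n11, n10, n01, n00])
    n_dh = counts[1, 1]

    f = np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
    converged = False
    for _ in range(max_iter):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        p_cis = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        c = fixed + n_dh * np.array([p_cis, 1 - p_cis, 1 - p_cis, p_cis])
        f_new = c / (2.0 * n)
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            converged = True
            break
        f = f_new
    if not converged:
        warnings.warn(
            f"haplotype-frequency EM did not converge in {max_iter} iterations; "
            "returning last iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    pa_hat = f[0] + f[1]
    pb_hat = f[0] + f[2]
    d, denom = _d_and_denominator(pa_hat, pb_hat, f[0])
    if denom <= 0:
        raise MonomorphicVariantError("EM collapsed to a monomorphic frequency")
    return float(np.clip(d * d / denom, 0.0, 1.0))


def _hap11_count(a: int, b: int) -> int:
    """Number of (1,1) haplotypes carried by an unambiguous genotype cell."""
    # Each individual carries two haplotypes. With a copies of allele 1 at
    # locus A and b at locus B and not both loci het, the count of 1-1
    # haplotypes is min over the forced phase: hom sites pin the phase.
    if a == 2 and b == 2:
        return 2
    if (a == 2 and b == 1) or (a == 1 and b == 2):
        return 1
    return 0


@dataclass
class R2Source:
    """Uniform pairwise-r² access over a phased panel or a genotype matrix.

    For genotype input the default estimator is the squared Pearson
    correlation of dosages (the composite-LD surrogate commonly used for
    pruning); ``method="em"`` switches to the EM haplotype estimator.
    Monomorphic columns and cross-chromosome or beyond-horizon pairs give 0.
    """

    data: HaplotypePanel | GenotypeMatrix
    method: str = "auto"
    ld_horizon_bp: int = DEFAULT_LD_HORIZON_BP

    def __post_init__(self) -> None:
        self.is_phased = isinstance(self.data, HaplotypePanel)
        if self.method == "auto":
            self.method = "phased" if self.is_phased else "dosage"
        self.variants: list[VariantRecord] = self.data.variants
        self.chroms = self.data.chroms
        self.positions = self.data.positions

    def index_of(self, variant_id: str) -> int:
        return self.data.index_of(variant_id)

    def in_horizon(self, i: int, j: int) -> bool:
        return self.chroms[i] == self.chroms[j] and abs(
            int(self.positions[i]) - int(self.positions[j])
        ) <= self.ld_horizon_bp

    def r2(self, i: int, j: int) -> float:
        if i == j:
            return 1.0
        if not self.in_horizon(i, j):
            return 0.0
        try:
            if self.method == "phased":
                return r2_phased(self.data, i, j)
            if self.method == "em":
                return r2_unphased_em(self.data, i, j)
            return self._dosage_r2(i, j)
        except MonomorphicVariantError:
            return 0.0

    def _dosage_r2(self, i: int, j: int) -> float:
        g1 = self.data.dosages[:, i]
        g2 = self.data.dosages[:, j]
        keep = (g1 != MISSING) & (g2 != MISSING)
        g1 = g1[keep].astype(float)
        g2 = g2[keep].astype(float)
        if g1.size < 2 or g1.std() == 0 or g2.std() == 0:
            return 0.0
        r = np.corrcoef(g1, g2)[0, 1]
        return float(np.clip(r * r, 0.0, 1.0))


def ld_prune(
    panel_or_geno: HaplotypePanel | GenotypeMatrix,
    ids: list[str],
    r2_max: float,
    window_bp: int = DEFAULT_LD_HORIZON_BP,
    method: str = "auto",
) -> list[str]:
    """Greedy left-to-right LD pruning.

    Candidates are scanned in (chrom, pos) order; a candidate is retained iff
    its r² with every already-retained SNP within ``window_bp`` is at most
    ``r2_max``. Ties are broken leftmost-wins, so the output is deterministic
    and idempotent.
    """
    if not (0.0 <= r2_max <= 1.0):
        raise ConfigError(f"r2_max {r2_max} outside [0, 1]")
    src = R2Source(panel_or_geno, method=method, ld_horizon_bp=window_bp)
    idx = sorted(
        (src.index_of(v) for v in ids),
        key=lambda k: (src.chroms[k], int(src.positions[k])),
    )
    kept: list[int] = []
    for i in idx:
        ok = True
        for j in reversed(kept):
            if src.chroms[j] != src.chroms[i]:
                break
            if int(src.positions[i]) - int(src.positions[j]) > window_bp:
                break
            if src.r2(i, j) > r2_max:
                ok = False
                break
        if ok:
            kept.append(i)
    return [src.variants[k].id for k in kept]


@dataclass
class CoverageResult:
    overall: float
    per_bin: dict[str, float]  # bin label -> covered fraction (NaN if empty bin)
    n_targets: int


def coverage_fraction(
    panel: HaplotypePanel,
    targets: list[str],
    tags: list[str],
    r2_threshold: float = 0.8,
    ld_horizon_bp: int = DEFAULT_LD_HORIZON_BP,
    bins: tuple[float, ...] = DEFAULT_MAF_BINS,
) -> CoverageResult:
    """Fraction of target SNPs tagged at r² ≥ threshold by the tag set.

    A target counts as covered iff it is itself a tag, or some tag on the
    same chromosome within ``ld_horizon_bp`` reaches the threshold. Fractions
    are reported overall and per MAF bin of the targets.
    """
    if not targets:
        raise ConfigError("empty target set")
    if not tags:
        raise ConfigError("empty tag set")
    src = R2Source(panel, ld_horizon_bp=ld_horizon_bp)
    tag_idx = np.array(sorted(panel.index_of(t) for t in tags))
    tag_set = set(tag_idx.tolist())
    tag_pos = panel.positions[tag_idx]
    tag_chrom = panel.chroms[tag_idx]
    covered = np.zeros(len(targets), dtype=bool)
    mafs = np.empty(len(targets))
    for k, tid in enumerate(targets):
        i = panel.index_of(tid)
        mafs[k] = panel.variants[i].maf
        if i in tag_set:
            covered[k] = True
            continue
        near = (tag_chrom == panel.chroms[i]) & (
            np.abs(tag_pos - panel.positions[i]) <= ld_horizon_bp
        )
        for j in tag_idx[near]:
            if src.r2(i, int(j)) >= r2_threshold:
                covered[k] = True
                break
    labels, assignment = _bin_mafs(mafs, bins)
    per_bin = {}
    for b, lab in enumerate(labels):
        mask = assignment == b
        per_bin[lab] = float(covered[mask].mean()) if mask.any() else float("nan")
    return CoverageResult(
        overall=float(covered.mean()), per_bin=per_bin, n_targets=len(targets)
    )


def _bin_mafs(mafs: np.ndarray, bins: tuple[float, ...]):
    edges = np.asarray(bins, dtype=float)
    if edges[0] != 0.0 or edges[-1] != 0.5 or np.any(np.diff(edges) <= 0):
        raise ConfigError(
            "MAF bins must be increasing edges from 0.0 to 0.5 (a partition of (0, 0.5])"
        )
    labels = ["monomorphic"] + [
        f"({lo:g},{hi:g}]" for lo, hi in zip(edges[:-1], edges[1:])
    ]
    # bin 0 = monomorphic; bin k>=1 = (edges[k-1], edges[k]]
    assignment = np.searchsorted(edges, mafs, side="left")
    assignment[mafs == 0.0] = 0
    return labels, assignment


def maf_spectrum(
    variants: list[VariantRecord], bins: tuple[float, ...] = DEFAULT_MAF_BINS
) -> dict[str, float]:
    """Fraction of variants per MAF bin; monomorphic sites get their own bin."""
    mafs = np.array([v.maf for v in variants], dtype=float)
    mafs = mafs[~np.isnan(mafs)]
    labels, assignment = _bin_mafs(mafs, bins)
    n = len(mafs)
    return {
        lab: (float((assignment == b).sum()) / n if n else 0.0)
        for b, lab in enumerate(labels)
    }
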