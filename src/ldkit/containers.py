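"""In-memory containers shared by every ldkit module.

Coordinate convention: all positions are 1-based inclusive (as in VCF).
BED export converts to 0-based half-open at write time, nowhere else.
Haplotype alleles are coded 0/1; genotype dosages are 0/1/2 with ``MISSING``
(-1) as the single sentinel for a no-call, excluded pairwise from every
estimator downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

MISSING: int = -1

#: Closed vocabulary of array design categories.
DESIGN_CATEGORIES = frozenset(
    {
        "replication",
        "fine_mapping",
        "prior_association",
        "cnp_tag",
        "mhc",
        "mitochondrial",
        "sex_check",
        "fingerprint",
        "wildcard",
    }
)


class LdkitError(Exception):
    """Base class for all ldkit errors."""


class FormatError(LdkitError):
    """A file violates its format contract (offending line is named)."""


class ConfigError(LdkitError):
    """Invalid configuration or parameter value."""


class EmptyPanelError(LdkitError):
    """No usable records remained after filtering."""


class MonomorphicVariantError(LdkitError):
    """LD is undefined for a monomorphic site."""


class InsufficientDataError(LdkitError):
    """Too few complete observations to estimate the quantity."""


@dataclass
class VariantRecord:
    """A biallelic SNP with its panel-level annotation."""

    id: str
    chrom: str
    pos: int
    ref_allele: str = "A"
    alt_allele: str = "G"
    maf: float = float("nan")
    designable: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ConfigError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if not np.isnan(self.maf) and not (0.0 <= self.maf <= 0.5):
            raise ConfigError(f"variant {self.id}: maf {self.maf} outside [0, 0.5]")


def _as_chrom_pos(variants: Sequence[VariantRecord]):
    chroms = np.array([v.chrom for v in variants])
    pos = np.array([v.pos for v in variants], dtype=np.int64)
    return chroms, pos


def _check_sorted(variants: Sequence[VariantRecord], what: str) -> None:
    for a, b in zip(variants, variants[1:]):
        if (a.chrom, a.pos) > (b.chrom, b.pos):
            raise ConfigError(f"{what}: variants not sorted by (chrom, pos) at {b.id}")


class HaplotypePanel:
    """Phased haplotype panel: one row per haplotype, one column per variant.

    The allele matrix is the LD substrate for every r² computation; MAF is
    always recomputed from the matrix so annotation can never drift from data.
    """

    def __init__(self, variants: Sequence[VariantRecord], alleles: np.ndarray):
        alleles = np.asarray(alleles, dtype=np.uint8)
        if alleles.ndim != 2 or alleles.shape[1] != len(variants):
            raise ConfigError(
                f"allele matrix {alleles.shape} does not match {len(variants)} variants"
            )
        if alleles.size and alleles.max() > 1:
            raise ConfigError("haplotype alleles must be coded 0/1")
        _check_sorted(variants, "HaplotypePanel")
        ids = [v.id for v in variants]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate variant ids in panel")
        self.variants = list(variants)
        self.alleles = alleles
        self._recompute_maf()
        self._index = {v.id: k for k, v in enumerate(self.variants)}
        self.chroms, self.positions = _as_chrom_pos(self.variants)

    def _recompute_maf(self) -> None:
        if self.alleles.shape[0]:
            freq = self.alleles.mean(axis=0)
        else:
            freq = np.zeros(len(self.variants))
        for v, f in zip(self.variants, freq):
            v.maf = float(min(f, 1.0 - f))
        self.alt_freq = np.asarray(freq, dtype=float)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.alt_freq, 1.0 - self.alt_freq)

    def index_of(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant id {variant_id!r} not in panel") from None

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index


class GenotypeMatrix:
    """Unphased diploid dosages over {0, 1, 2, MISSING}."""

    def __init__(
        self,
        samples: Sequence[str],
        variants: Sequence[VariantRecord],
        dosages: np.ndarray,
    ):
        dosages = np.asarray(dosages, dtype=np.int8)
        if dosages.shape != (len(samples), len(variants)):
            raise ConfigError(
                f"dosage matrix {dosages.shape} does not match "
                f"{len(samples)} samples x {len(variants)} variants"
            )
        bad = ~np.isin(dosages, [0, 1, 2, MISSING])
        if bad.any():
            raise ConfigError("dosages must be 0, 1, 2 or MISSING")
        _check_sorted(variants, "GenotypeMatrix")
        self.samples = list(samples)
        self.variants = list(variants)
        self.dosages = dosages
        self._index = {v.id: k for k, v in enumerate(self.variants)}
        self._sample_index = {s: k for k, s in enumerate(self.samples)}
        self.chroms, self.positions = _as_chrom_pos(self.variants)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def called_mask(self) -> np.ndarray:
        return self.dosages != MISSING

    def call_rate(self) -> np.ndarray:
        """Per-variant fraction of non-missing calls."""
        return self.called_mask().mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Per-variant alt-allele frequency among called samples."""
        called = self.called_mask()
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(
                n > 0, np.where(called, self.dosages, 0).sum(axis=0) / (2.0 * n), np.nan
            )

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def index_of(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant id {variant_id!r} not in genotypes") from None

    def sample_index_of(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise KeyError(f"sample id {sample_id!r} not in genotypes") from None


class GeneticMap:
    """Piecewise-linear bp↔cM map per chromosome.

    Anchors are (pos, rate, cm) triples; ``rate`` (cM/Mb) describes the
    interval to the right of the anchor. Interpolation is linear between
    anchors and constant beyond the outermost ones.
    """

    def __init__(self, anchors: dict[str, np.ndarray]):
        # anchors[chrom] is a (n, 3) float array of (pos, rate, cm)
        self.anchors: dict[str, np.ndarray] = {}
        for chrom, arr in anchors.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ConfigError(f"chrom {chrom}: anchors must be (n, 3)")
            pos, cm = arr[:, 0], arr[:, 2]
            if np.any(np.diff(pos) <= 0):
                raise FormatError(f"chrom {chrom}: positions not strictly increasing")
            if np.any(np.diff(cm) < 0):
                raise FormatError(f"chrom {chrom}: cumulative cM decreasing")
            self.anchors[chrom] = arr

    def chromosomes(self) -> list[str]:
        return list(self.anchors)

    def _chrom(self, chrom: str) -> np.ndarray:
        try:
            return self.anchors[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genetic map") from None

    def interpolate_cm(self, chrom: str, pos) -> np.ndarray | float:
        """Genetic position (cM) at physical position(s) ``pos``."""
        arr = self._chrom(chrom)
        out = np.interp(pos, arr[:, 0], arr[:, 2])
        return float(out) if np.isscalar(pos) else out

    def cm_to_bp(self, chrom: str, cm) -> np.ndarray | float:
        """Inverse query: the leftmost physical position at genetic position cM.

        Inside a zero-recombination stretch the inverse is set-valued; the
        leftmost bp is returned, which makes shoulder extension conservative.
        """
        arr = self._chrom(chrom)
        pos_a, cm_a = arr[:, 0], arr[:, 2]
        cm_arr = np.atleast_1d(np.asarray(cm, dtype=float))
        idx = np.searchsorted(cm_a, cm_arr, side="left")
        out = np.empty_like(cm_arr)
        for k, (c, i) in enumerate(zip(cm_arr, idx)):
            if i == 0:
                out[k] = pos_a[0]
            elif i >= len(cm_a):
                out[k] = pos_a[-1]
            elif cm_a[i] == cm_a[i - 1]:
                out[k] = pos_a[i - 1]
            else:
                frac = (c - cm_a[i - 1]) / (cm_a[i] - cm_a[i - 1])
                out[k] = pos_a[i - 1] + frac * (pos_a[i] - pos_a[i - 1])
        out = np.round(out)
        return float(out[0]) if np.isscalar(cm) else out


@dataclass
class HotspotInterval:
    """A run of inter-anchor intervals with elevated recombination rate."""

    chrom: str
    start: int
    end: int
    mean_rate: float


@dataclass
class Region:
    """A fine-mapping interval (1-based inclusive) with its audit trail.

    ``kind`` is "SFM" (signal fine mapping: the LD signal around an index SNP)
    or "LFM" (locus fine mapping: SFM extended over overlapping genes).
    """

    chrom: str
    start: int
    end: int
    kind: str
    index_variants: list[str] = field(default_factory=list)
    traits: list[str] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("SFM", "LFM"):
            raise ConfigError(f"region kind must be SFM or LFM, got {self.kind!r}")
        if self.start > self.end:
            raise ConfigError(f"region start {self.start} > end {self.end}")
        if self.start < 1:
            raise ConfigError(f"region start {self.start} < 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class SummaryStats:
    """Per-trait GWAS summary statistics, sorted by (chrom, pos)."""

    trait: str
    # records: (variant id, chrom, pos, p-value, effect-allele frequency)
    records: list[tuple[str, str, int, float, float]]

    def __post_init__(self) -> None:
        for rec in self.records:
            p = rec[3]
            if not (0.0 < p <= 1.0):
                raise FormatError(f"variant {rec[0]}: p-value {p} outside (0, 1]")
        self.records = sorted(self.records, key=lambda r: (r[1], r[2]))

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class DesignEntry:
    variant: VariantRecord
    tags: set[tuple[str, str]] = field(default_factory=set)  # (category, trait)


class ArrayDesign:
    """The selected SNP set of a custom array, one entry per unique variant.

    Each entry carries (category, trait) tags from the closed category
    vocabulary; unintended duplicates (same chrom/pos/alleles under different
    names) are collapsed to one entry with an alias list.
    """

    def __init__(self) -> None:
        self.entries: dict[str, DesignEntry] = {}
        self.aliases: dict[str, list[str]] = {}

    def add(self, variant: VariantRecord, category: str, trait: str) -> None:
        if category not in DESIGN_CATEGORIES:
            raise ConfigError(
                f"unknown category {category!r}; allowed: {sorted(DESIGN_CATEGORIES)}"
            )
        entry = self.entries.setdefault(variant.id, DesignEntry(variant))
        entry.tags.add((category, trait))

    def ids(self) -> list[str]:
        return list(self.entries)

    def ids_for(self, category: str, trait: str | None = None) -> list[str]:
        out = []
        for vid, entry in self.entries.items():
            for cat, tr in entry.tags:
                if cat == category and (trait is None or tr == trait):
                    out.append(vid)
                    break
        return out

    def traits_of(self, variant_id: str) -> set[str]:
        return {tr for _, tr in self.entries[variant_id].tags}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.entries


@dataclass
class KinshipResult:
    """Method-of-moments IBD estimates for one sample pair."""

    pair: tuple[str, str]
    k0: float
    k1: float
    k2: float
    n_snps_used: int

    def __post_init__(self) -> None:
        if abs(self.k0 + self.k1 + self.k2 - 1.0) > 1e-9:
            raise ConfigError("IBD state probabilities must sum to 1")
        for k in (self.k0, self.k1, self.k2):
            if not (-1e-12 <= k <= 1.0 + 1e-12):
                raise ConfigError(f"IBD state probability {k} outside [0, 1]")

    @property
    def pihat(self) -> float:
        return self.k2 + 0.5 * self.k1


@dataclass
class OverlapTestResult:
    """Permutation test of SNP-set overlap between two traits."""

    n_overlap: int
    prop_max: float
    expected: float
    p_enrichment: float
    n_sim: int


@dataclass
class LambdaGC:
    """Genomic-control inflation factor with the SNP set it was computed on."""

    lam: float
    n_snps: int
    snp_set_label: str = ""
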