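"""Replication-SNP selection and array-design assembly.

Replication SNPs are the top independent association signals of a trait:
candidates ranked by p-value and accepted greedily subject to pairwise
independence (r² below a threshold within a window) and distance from
already-established loci. Multi-trait submissions are assembled into one
deduplicated design with per-SNP category tags, and summarized by category
(counts, MAF spectrum, fraction rare).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import (
    ArrayDesign,
    ConfigError,
    HaplotypePanel,
    SummaryStats,
    VariantRecord,
)
from .ld import DEFAULT_LD_HORIZON_BP, DEFAULT_MAF_BINS, R2Source, maf_spectrum

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    """Parameters of replication-SNP selection.

    ``independence_r2`` defaults to 0.3 — the same "strong LD" cutoff used
    for pruning elsewhere in the toolkit — and ``exclusion_bp`` to 250 kb
    around known loci.
    """

    n_target: int = 5000
    independence_r2: float = 0.3
    independence_window_bp: int = DEFAULT_LD_HORIZON_BP
    exclusion_bp: int = 250_000

    def __post_init__(self) -> None:
        if self.n_target < 1:
            raise ConfigError("n_target must be >= 1")
        if not (0.0 <= self.independence_r2 <= 1.0):
            raise ConfigError("independence_r2 outside [0, 1]")


def select_replication_snps(
    stats: SummaryStats,
    panel: HaplotypePanel,
    cfg: SelectionConfig,
    exclude_loci: list[tuple[str, int]] | None = None,
) -> list[str]:
    """Top independent association signals for one trait, in acceptance order.

    Candidates absent from the panel are skipped with a logged count; p-value
    ties break by (chrom, pos). A short list (fewer than ``n_target``
    acceptances) is a warning, not an error.
    """
    if not stats.records:
        raise ConfigError("empty summary statistics")
    exclude_loci = exclude_loci or []
    src = R2Source(panel, ld_horizon_bp=cfg.independence_window_bp)
    candidates = []
    n_skipped = 0
    for vid, chrom, pos, p, _ in stats.records:
        if vid not in panel:
            n_skipped += 1
            continue
        candidates.append((p, chrom, pos, vid))
    if n_skipped:
        logger.info("select_replication_snps: %d stat variants not in panel", n_skipped)
    candidates.sort()
    accepted: list[str] = []
    accepted_idx: list[int] = []
    for p, chrom, pos, vid in candidates:
        if len(accepted) >= cfg.n_target:
            break
        if any(
            chrom == xc and abs(pos - xp) <= cfg.exclusion_bp
            for xc, xp in exclude_loci
        ):
            continue
        i = panel.index_of(vid)
        if all(src.r2(i, j) <= cfg.independence_r2 for j in accepted_idx):
            accepted.append(vid)
            accepted_idx.append(i)
    if len(accepted) < cfg.n_target:
        logger.warning(
            "select_replication_snps(%s): only %d of %d requested SNPs available",
            stats.trait,
            len(accepted),
            cfg.n_target,
        )
    return accepted


def assemble_design(
    submissions: list[tuple[str, str, list[str]]],
    catalog: list[VariantRecord],
) -> ArrayDesign:
    """Merge per-trait submissions into one deduplicated array design.

    Submissions are (category, trait, variant ids). Ids sharing
    chrom/pos/alleles under different names — unintended duplicates — are
    collapsed onto the lexicographically smallest id, with the rest recorded
    as aliases. Unknown ids raise, listing every unresolved id.
    """
    by_id = {v.id: v for v in catalog}
    unknown = sorted(
        {vid for _, _, ids in submissions for vid in ids if vid not in by_id}
    )
    if unknown:
        raise ConfigError(f"unresolved variant ids: {', '.join(unknown)}")

    # canonicalize position-duplicates: same (chrom, pos, allele pair)
    site_key = {}
    canonical: dict[str, str] = {}
    for v in sorted(by_id.values(), key=lambda v: v.id):
        key = (v.chrom, v.pos, frozenset((v.ref_allele, v.alt_allele)))
        if key in site_key:
            canonical[v.id] = site_key[key]
        else:
            site_key[key] = v.id
            canonical[v.id] = v.id

    design = ArrayDesign()
    for category, trait, ids in submissions:
        for vid in ids:
            primary = canonical[vid]
            design.add(by_id[primary], category, trait)
            if primary != vid:
                aliases = design.aliases.setdefault(primary, [])
                if vid not in aliases:
                    aliases.append(vid)
    return design


def category_counts(design: ArrayDesign) -> dict[str, int]:
    """SNPs per category (a SNP may fall into several categories)."""
    out: dict[str, int] = {}
    for entry in design.entries.values():
        for cat in {c for c, _ in entry.tags}:
            out[cat] = out.get(cat, 0) + 1
    return out


@dataclass
class CategorySummary:
    n_snps: int
    n_unevaluable: int
    mean_maf: float
    frac_monomorphic: float
    frac_maf_lt_05: float  # 0 < MAF < 0.05
    spectrum: dict[str, float] = field(default_factory=dict)


def design_summary(
    design: ArrayDesign,
    panel: HaplotypePanel,
    bins: tuple[float, ...] = DEFAULT_MAF_BINS,
) -> dict[str, CategorySummary]:
    """Per-category MAF accounting of a design, evaluated against a panel.

    Design SNPs absent from the panel are counted as unevaluable and excluded
    from the MAF summaries. Keys are category names plus "TOTAL".
    """
    groups: dict[str, list[str]] = {"TOTAL": list(design.entries)}
    for vid, entry in design.entries.items():
        for cat in {c for c, _ in entry.tags}:
            groups.setdefault(cat, []).append(vid)
    out: dict[str, CategorySummary] = {}
    for cat, ids in groups.items():
        in_panel = [vid for vid in ids if vid in panel]
        mafs = np.array(
            [panel.variants[panel.index_of(vid)].maf for vid in in_panel]
        )
        variants = [panel.variants[panel.index_of(vid)] for vid in in_panel]
        if mafs.size:
            summary = CategorySummary(
                n_snps=len(ids),
                n_unevaluable=len(ids) - len(in_panel),
                mean_maf=float(mafs.mean()),
                frac_monomorphic=float((mafs == 0).mean()),
                frac_maf_lt_05=float(((mafs > 0) & (mafs < 0.05)).mean()),
                spectrum=maf_spectrum(variants, bins),
            )
        else:
            summary = CategorySummary(
                n_snps=len(ids),
                n_unevaluable=len(ids),
                mean_maf=float("nan"),
                frac_monomorphic=float("nan"),
                frac_maf_lt_05=float("nan"),
            )
        out[cat] = summary
    return out
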