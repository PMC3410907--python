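"""Readers and writers for the formats the toolkit touches.

Phased haplotypes come from VCF (via cyvcf2); genetic maps, summary
statistics and known-association lists are tab-delimited; regions are
exported as BED (0-based half-open); array designs as a CSV manifest. All
in-memory coordinates are 1-based inclusive — BED conversion happens only
here, at the boundary.
"""

from __future__ import annotations

import csv
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import (
    ArrayDesign,
    EmptyPanelError,
    FormatError,
    GeneticMap,
    HaplotypePanel,
    Region,
    SummaryStats,
    VariantRecord,
)

logger = logging.getLogger(__name__)


def _parse_region_filter(region_filter: str) -> tuple[str, int, int]:
    try:
        chrom, span = region_filter.split(":")
        lo, hi = span.split("-")
        return chrom, int(lo), int(hi)
    except ValueError:
        raise FormatError(
            f"region filter {region_filter!r} is not chrom:start-end"
        ) from None


def read_haplotype_vcf(
    path: str | Path, region_filter: str | None = None
) -> HaplotypePanel:
    """Read phased biallelic SNPs from a VCF into a haplotype panel.

    One matrix row per haplotype (two per sample), columns in (chrom, pos)
    order. Multiallelic, non-SNP, unphased or incompletely called records
    are skipped with a logged count; MAF is recomputed from the matrix.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    want = _parse_region_filter(region_filter) if region_filter else None
    vcf = VCF(str(path))
    records: list[tuple[VariantRecord, np.ndarray]] = []
    n_skipped = 0
    for var in vcf:
        if want is not None:
            chrom, lo, hi = want
            if var.CHROM != chrom or not (lo <= var.POS <= hi):
                continue
        if (
            len(var.ALT) != 1
            or len(var.REF) != 1
            or len(var.ALT[0]) != 1
        ):
            n_skipped += 1
            continue
        gts = var.genotypes  # [allele_a, allele_b, phased]
        if any(g[0] < 0 or g[1] < 0 or not g[2] for g in gts):
            n_skipped += 1
            continue
        haps = np.array([[g[0], g[1]] for g in gts], dtype=np.uint8).reshape(-1)
        rec = VariantRecord(
            id=var.ID or f"{var.CHROM}:{var.POS}",
            chrom=var.CHROM,
            pos=var.POS,
            ref_allele=var.REF,
            alt_allele=var.ALT[0],
        )
        records.append((rec, haps))
    vcf.close()
    if n_skipped:
        logger.info("read_haplotype_vcf(%s): skipped %d records", path, n_skipped)
    if not records:
        raise EmptyPanelError(f"no phased biallelic SNPs in {path}")
    records.sort(key=lambda rv: (rv[0].chrom, rv[0].pos))
    variants = [rec for rec, _ in records]
    alleles = np.column_stack([haps for _, haps in records])
    panel = HaplotypePanel(variants, alleles)
    panel.n_skipped = n_skipped
    return panel


def write_haplotype_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a panel as a minimal phased VCF (two haplotypes per sample)."""
    if panel.n_haplotypes % 2:
        raise FormatError("panel has an odd haplotype count; cannot pair into samples")
    n_samples = panel.n_haplotypes // 2
    sample_names = [f"S{k}" for k in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(panel.chroms):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for k, v in enumerate(panel.variants):
            col = panel.alleles[:, k]
            gts = "\t".join(
                f"{col[2 * s]}|{col[2 * s + 1]}" for s in range(n_samples)
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Read a tab-delimited genetic map: chrom, pos (bp), rate (cM/Mb), cM.

    A header line is expected. Positions must be strictly increasing and the
    cumulative cM nondecreasing within each chromosome; violations raise a
    FormatError naming the offending line.
    """
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] != 4:
        raise FormatError(f"{path}: expected 4 columns, found {df.shape[1]}")
    df.columns = ["chrom", "pos", "rate", "cm"]
    anchors: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(dtype=float)
        cm = sub["cm"].to_numpy(dtype=float)
        bad_pos = np.nonzero(np.diff(pos) <= 0)[0]
        if bad_pos.size:
            line = sub.index[bad_pos[0] + 1] + 2  # +1 header, +1 one-based
            raise FormatError(
                f"{path} line {line}: position not strictly increasing on {chrom}"
            )
        bad_cm = np.nonzero(np.diff(cm) < 0)[0]
        if bad_cm.size:
            line = sub.index[bad_cm[0] + 1] + 2
            raise FormatError(f"{path} line {line}: cumulative cM decreases on {chrom}")
        anchors[str(chrom)] = np.column_stack(
            [pos, sub["rate"].to_numpy(dtype=float), cm]
        )
    return GeneticMap(anchors)


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\trate\tcm\n")
        for chrom in gmap.chromosomes():
            for pos, rate, cm in gmap.anchors[chrom]:
                fh.write(f"{chrom}\t{int(pos)}\t{rate:.10g}\t{cm:.10g}\n")


def read_summary_stats(path: str | Path, trait: str) -> SummaryStats:
    """Read tab-delimited summary statistics: id, chrom, pos, pvalue, eaf."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={"chrom": str})
    expected = ["id", "chrom", "pos", "pvalue", "eaf"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: header must be {expected}, found {list(df.columns)}")
    bad = df[(df["pvalue"] <= 0) | (df["pvalue"] > 1)]
    if not bad.empty:
        row = bad.index[0] + 2
        raise FormatError(
            f"{path} line {row} (variant {bad.iloc[0]['id']}): "
            f"p-value {bad.iloc[0]['pvalue']} outside (0, 1]"
        )
    records = [
        (str(r.id), str(r.chrom), int(r.pos), float(r.pvalue), float(r.eaf))
        for r in df.itertuples()
    ]
    return SummaryStats(trait=trait, records=records)


def write_summary_stats(stats: SummaryStats, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tchrom\tpos\tpvalue\teaf\n")
        for vid, chrom, pos, p, eaf in stats.records:
            fh.write(f"{vid}\t{chrom}\t{pos}\t{p:.10g}\t{eaf:.10g}\n")


def write_regions_bed(regions: list[Region], path: str | Path) -> None:
    """Write regions as BED: 0-based half-open, name = kind:index_ids:traits."""
    with open(path, "w") as fh:
        for r in regions:
            name = ":".join(
                [r.kind, ",".join(r.index_variants), ",".join(r.traits)]
            )
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\n")


def read_regions_bed(path: str | Path) -> list[Region]:
    """Read a BED written by :func:`write_regions_bed` back into regions."""
    out: list[Region] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name = line.rstrip("\n").split("\t")[:4]
            kind, ids, traits = (name.split(":") + ["", ""])[:3]
            out.append(
                Region(
                    chrom=chrom,
                    start=int(start) + 1,
                    end=int(end),
                    kind=kind if kind in ("SFM", "LFM") else "SFM",
                    index_variants=[x for x in ids.split(",") if x],
                    traits=[x for x in traits.split(",") if x],
                )
            )
    return out


def read_known_associations(path: str | Path) -> list[tuple[str, int]]:
    """Read a tab-delimited known-association list with columns chrom, pos."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={"chrom": str})
    if not {"chrom", "pos"} <= set(df.columns):
        raise FormatError(f"{path}: needs columns chrom, pos")
    return [(str(r.chrom), int(r.pos)) for r in df.itertuples()]


def read_gene_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read gene intervals from BED (0-based half-open → 1-based inclusive)."""
    genes = []
    with open(path) as fh:
        for k, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path} line {k}: fewer than 3 BED columns")
            name = parts[3] if len(parts) > 3 else f"gene{k}"
            genes.append((parts[0], int(parts[1]) + 1, int(parts[2]), name))
    return genes


def write_manifest(design: ArrayDesign, path: str | Path) -> None:
    """Write the array manifest CSV: one row per unique SNP with its tags."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["id", "chrom", "pos", "alleles", "categories", "traits", "aliases"]
        )
        for vid in sorted(
            design.entries, key=lambda x: (design.entries[x].variant.chrom,
                                           design.entries[x].variant.pos)
        ):
            entry = design.entries[vid]
            v = entry.variant
            cats = ";".join(sorted({c for c, _ in entry.tags}))
            traits = ";".join(sorted({t for _, t in entry.tags}))
            aliases = ";".join(design.aliases.get(vid, []))
            writer.writerow(
                [vid, v.chrom, v.pos, f"{v.ref_allele}/{v.alt_allele}", cats, traits, aliases]
            )
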