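"""Fine-mapping region construction.

A signal fine-mapping (SFM) region starts from the span of all SNPs in
strong LD (r² ≥ 0.5 by default) with an index SNP, then each boundary is
pushed outward to the inner edge of the nearest flanking recombination
hotspot; where no hotspot lies nearby, a small genetic-distance shoulder
(0.02 cM by default, ~20 kb at 1 cM/Mb) is applied instead. A locus
fine-mapping (LFM) region additionally absorbs every gene interval
overlapping it, to a fixed point. Overlapping regions across traits are
merged so each unique interval is genotyped once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import (
    ConfigError,
    GeneticMap,
    HaplotypePanel,
    HotspotInterval,
    MonomorphicVariantError,
    Region,
    VariantRecord,
)
from .ld import DEFAULT_LD_HORIZON_BP, r2_phased

DEFAULT_HOTSPOT_RATE = 10.0  # cM/Mb
DEFAULT_SHOULDER_CM = 0.02
DEFAULT_HOTSPOT_SEARCH_CM = 0.1


def interpolate_cm(gmap: GeneticMap, chrom: str, pos) -> float:
    """Piecewise-linear genetic position; constant beyond outermost anchors."""
    return gmap.interpolate_cm(chrom, pos)


def cm_to_bp(gmap: GeneticMap, chrom: str, cm) -> float:
    """Inverse of :func:`interpolate_cm` (leftmost bp on flat stretches)."""
    return gmap.cm_to_bp(chrom, cm)


def detect_hotspots(
    gmap: GeneticMap, rate_threshold: float = DEFAULT_HOTSPOT_RATE
) -> list[HotspotInterval]:
    """Maximal runs of inter-anchor intervals at local rate ≥ threshold.

    The local rate of an interval is (ΔcM/Δbp)·10⁶; adjacent qualifying
    intervals are merged and the run reported with its mean rate.
    """
    out: list[HotspotInterval] = []
    for chrom in gmap.chromosomes():
        arr = gmap.anchors[chrom]
        pos, cm = arr[:, 0], arr[:, 2]
        dbp = np.diff(pos)
        rate = np.diff(cm) / dbp * 1e6
        hot = rate >= rate_threshold
        k = 0
        while k < len(hot):
            if not hot[k]:
                k += 1
                continue
            j = k
            while j + 1 < len(hot) and hot[j + 1]:
                j += 1
            span_cm = cm[j + 1] - cm[k]
            span_bp = pos[j + 1] - pos[k]
            out.append(
                HotspotInterval(
                    chrom=chrom,
                    start=int(pos[k]),
                    end=int(pos[j + 1]),
                    mean_rate=float(span_cm / span_bp * 1e6),
                )
            )
            k = j + 1
    return out


def _nearest_hotspot_edge(
    hotspots: list[HotspotInterval],
    gmap: GeneticMap,
    chrom: str,
    boundary: int,
    side: str,
    search_cm: float,
) -> int | None:
    """Inner edge of the nearest hotspot strictly outward of ``boundary``.

    For the left boundary the inner edge is the hotspot's end; for the right
    boundary, its start. The edge must lie within ``search_cm`` of the
    boundary on the genetic map.
    """
    b_cm = gmap.interpolate_cm(chrom, boundary)
    best: int | None = None
    for hs in hotspots:
        if hs.chrom != chrom:
            continue
        if side == "left":
            edge = hs.end
            if edge > boundary:
                continue
            if b_cm - gmap.interpolate_cm(chrom, edge) > search_cm:
                continue
            if best is None or edge > best:
                best = edge
        else:
            edge = hs.start
            if edge < boundary:
                continue
            if gmap.interpolate_cm(chrom, edge) - b_cm > search_cm:
                continue
            if best is None or edge < best:
                best = edge
    return best


def build_sfm_region(
    panel: HaplotypePanel,
    gmap: GeneticMap,
    index_id: str,
    r2_seed: float = 0.5,
    shoulder_cm: float = DEFAULT_SHOULDER_CM,
    hotspot_rate: float = DEFAULT_HOTSPOT_RATE,
    hotspot_search_cm: float = DEFAULT_HOTSPOT_SEARCH_CM,
    ld_horizon_bp: int = DEFAULT_LD_HORIZON_BP,
    shoulder_mode: str = "fallback",
    trait: str | None = None,
) -> Region:
    """Construct the SFM region around an index SNP.

    Seed interval: min/max position over the index SNP and every SNP with
    r² ≥ ``r2_seed`` to it within the LD horizon. Each boundary then moves
    outward to the inner edge of the nearest hotspot within
    ``hotspot_search_cm``; absent one, it moves outward by ``shoulder_cm``
    on the genetic map (``shoulder_mode="always"`` applies the shoulder even
    when a hotspot was found, taking the outermost of the two). Every
    boundary decision is recorded in the region's provenance.
    """
    if shoulder_mode not in ("fallback", "always"):
        raise ConfigError("shoulder_mode must be 'fallback' or 'always'")
    idx = panel.index_of(index_id)
    chrom = panel.chroms[idx]
    ipos = int(panel.positions[idx])
    if panel.variants[idx].maf == 0:
        raise MonomorphicVariantError(f"index SNP {index_id} is monomorphic")
    partners = [ipos]
    for j in range(panel.n_variants):
        if j == idx or panel.chroms[j] != chrom:
            continue
        if abs(int(panel.positions[j]) - ipos) > ld_horizon_bp:
            continue
        try:
            if r2_phased(panel, idx, j) >= r2_seed:
                partners.append(int(panel.positions[j]))
        except MonomorphicVariantError:
            continue
    start, end = min(partners), max(partners)
    provenance = [
        f"seed: span [{start}, {end}] from {len(partners)} SNPs at r2>={r2_seed}"
    ]
    hotspots = detect_hotspots(gmap, hotspot_rate)
    new_bounds = {}
    for side, boundary in (("left", start), ("right", end)):
        sign = -1 if side == "left" else 1
        edge = _nearest_hotspot_edge(
            hotspots, gmap, chrom, boundary, side, hotspot_search_cm
        )
        b_cm = gmap.interpolate_cm(chrom, boundary)
        shoulder_bp = int(gmap.cm_to_bp(chrom, b_cm + sign * shoulder_cm))
        if edge is not None and shoulder_mode == "fallback":
            new_bounds[side] = edge
            provenance.append(f"{side}: hotspot inner edge at {edge}")
        elif edge is not None:  # shoulder_mode == "always"
            outermost = min(edge, shoulder_bp) if side == "left" else max(edge, shoulder_bp)
            new_bounds[side] = outermost
            provenance.append(
                f"{side}: outermost of hotspot edge {edge} and shoulder {shoulder_bp}"
            )
        else:
            new_bounds[side] = shoulder_bp
            provenance.append(
                f"{side}: no hotspot within {hotspot_search_cm} cM; "
                f"shoulder {shoulder_cm} cM -> {shoulder_bp}"
            )
    return Region(
        chrom=chrom,
        start=max(1, int(new_bounds["left"])),
        end=int(new_bounds["right"]),
        kind="SFM",
        index_variants=[index_id],
        traits=[trait] if trait else [],
        provenance=provenance,
    )


def build_lfm_region(
    sfm: Region, genes: list[tuple[str, int, int, str]]
) -> Region:
    """Extend an SFM region over all transitively overlapping gene intervals."""
    start, end = sfm.start, sfm.end
    provenance = list(sfm.provenance)
    absorbed: set[str] = set()
    changed = True
    while changed:
        changed = False
        for chrom, gs, ge, name in genes:
            if chrom != sfm.chrom or name in absorbed:
                continue
            if gs <= end and ge >= start:  # overlap
                if gs < start or ge > end:
                    provenance.append(
                        f"gene {name} [{gs}, {ge}] extends region to "
                        f"[{min(start, gs)}, {max(end, ge)}]"
                    )
                start, end = min(start, gs), max(end, ge)
                absorbed.add(name)
                changed = True
    return Region(
        chrom=sfm.chrom,
        start=start,
        end=end,
        kind="LFM",
        index_variants=list(sfm.index_variants),
        traits=list(sfm.traits),
        provenance=provenance,
    )


def merge_regions(regions: list[Region]) -> list[Region]:
    """Merge strictly overlapping same-chromosome regions into their union.

    Abutting regions (no shared bp) stay separate. Traits and index variants
    are concatenated without duplicates; a merged region is LFM if any input
    was. Output is disjoint and sorted; idempotent and order-insensitive.
    """
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    out: list[Region] = []
    for r in ordered:
        if out and out[-1].chrom == r.chrom and r.start <= out[-1].end:
            prev = out[-1]
            prev.end = max(prev.end, r.end)
            prev.kind = "LFM" if "LFM" in (prev.kind, r.kind) else "SFM"
            for x in r.index_variants:
                if x not in prev.index_variants:
                    prev.index_variants.append(x)
            for t in r.traits:
                if t not in prev.traits:
                    prev.traits.append(t)
            prev.provenance.append(f"merged with [{r.start}, {r.end}]")
        else:
            out.append(
                Region(
                    chrom=r.chrom,
                    start=r.start,
                    end=r.end,
                    kind=r.kind,
                    index_variants=list(r.index_variants),
                    traits=list(r.traits),
                    provenance=list(r.provenance),
                )
            )
    return out


def enumerate_finemapping_snps(
    catalog: list[VariantRecord], region: Region, require_designable: bool = False
) -> list[str]:
    """All catalog SNP ids inside the region, in position order."""
    hits = [
        v
        for v in catalog
        if region.contains(v.chrom, v.pos) and (v.designable or not require_designable)
    ]
    hits.sort(key=lambda v: (v.chrom, v.pos))
    return [v.id for v in hits]
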