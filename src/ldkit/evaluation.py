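"""Self-validation scenarios for the toolkit.

Each function builds a synthetic study with known ground truth, runs one
slice of the pipeline, and returns the measured quantities (oracle
disagreements, constraint violations, calibration statistics). They back
both the validation test suite and the reproduction script, so the numbers
reported are always recomputed from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import GeneticMap, GenotypeMatrix
from .design import SelectionConfig, assemble_design, select_replication_snps
from .ld import R2Source, ld_prune, r2_phased, r2_unphased_em
from .regions import build_lfm_region, build_sfm_region, merge_regions
from .simulate import (
    PanelSimConfig,
    PedigreeSpec,
    drop_pedigree,
    simulate_panel,
    simulate_stratified_cc,
    simulate_summary_stats,
)
from .stats import (
    grm,
    ibd_mom,
    lambda_gc,
    overlap_test,
    select_null_snps,
    select_structure_snps,
    trend_test_many,
)


def _sub_seeds(seed: int, n: int) -> list[int]:
    """n reproducible child seeds below 2**31."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _fixture_panel(seed: int, n_snps: int = 500, n_haplotypes: int = 200):
    cfg = PanelSimConfig(
        n_haplotypes=n_haplotypes,
        region_length=n_snps * 1000,
        n_founders=10,
        snp_density=1.0,
        background_rate=0.5,
        hotspot_positions=[
            (n_snps * 250, n_snps * 250 + 5000, 80.0),
            (n_snps * 600, n_snps * 600 + 5000, 80.0),
        ],
        seed=seed,
    )
    return simulate_panel(cfg)


def _bruteforce_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Independent oracle: r² from explicit 2×2 haplotype contingency counts."""
    counts = np.bincount(2 * a.astype(int) + b.astype(int), minlength=4)
    n = counts.sum()
    p_ab = counts[3] / n
    p_a = (counts[2] + counts[3]) / n
    p_b = (counts[1] + counts[3]) / n
    d = p_ab - p_a * p_b
    return d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))


def ld_oracle_max_diff(seed: int, n_pairs: int = 1000) -> tuple[float, int]:
    """Max |r2_phased − contingency-table oracle| over random polymorphic pairs."""
    panel, _ = _fixture_panel(seed)
    rng = np.random.default_rng(seed + 1)
    poly = np.nonzero(panel.maf > 0)[0]
    worst = 0.0
    for _ in range(n_pairs):
        i, j = rng.choice(poly, size=2, replace=False)
        oracle = _bruteforce_r2(panel.alleles[:, i], panel.alleles[:, j])
        worst = max(worst, abs(r2_phased(panel, int(i), int(j)) - oracle))
    return worst, n_pairs


def em_consistency_mean_diff(seed: int, n_pairs: int = 200) -> tuple[float, int]:
    """Mean |r2_unphased_em − r2_phased| on a collapsed 1,000-haplotype panel."""
    cfg = PanelSimConfig(
        n_haplotypes=1000, region_length=300_000, n_founders=20,
        snp_density=1.0, background_rate=0.5, seed=seed,
    )
    panel, _ = simulate_panel(cfg)
    dos = panel.alleles[0::2].astype(np.int8) + panel.alleles[1::2].astype(np.int8)
    geno = GenotypeMatrix(
        [f"S{k}" for k in range(dos.shape[0])], list(panel.variants), dos
    )
    rng = np.random.default_rng(seed + 1)
    poly = np.nonzero(panel.maf > 0.01)[0]
    diffs = []
    for _ in range(n_pairs):
        i, j = rng.choice(poly, size=2, replace=False)
        diffs.append(
            abs(r2_unphased_em(geno, int(i), int(j)) - r2_phased(panel, int(i), int(j)))
        )
    return float(np.mean(diffs)), n_pairs


def _count_pair_violations(panel, ids, r2_max, window_bp) -> tuple[int, int]:
    src = R2Source(panel, ld_horizon_bp=window_bp)
    idx = [panel.index_of(v) for v in ids]
    bad = 0
    checked = 0
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            if src.in_horizon(idx[a], idx[b]):
                checked += 1
                if src.r2(idx[a], idx[b]) > r2_max + 1e-12:
                    bad += 1
    return bad, checked


def selection_violations(seed: int) -> tuple[int, int]:
    """Exhaustive post-verification of every pruning/selection operation.

    Runs ld_prune, select_structure_snps, select_replication_snps and
    select_null_snps on a 500-SNP fixture and counts constraint violations
    (r² above threshold within window, or distance inside an exclusion zone).
    Returns (violations, pairs_checked).
    """
    panel, _ = _fixture_panel(seed)
    window = 150_000
    total_bad = 0
    total_checked = 0

    poly = [v.id for v in panel.variants if v.maf > 0]
    pruned = ld_prune(panel, poly, r2_max=0.3, window_bp=window)
    bad, checked = _count_pair_violations(panel, pruned, 0.3, window)
    total_bad += bad
    total_checked += checked

    structure = select_structure_snps(panel, maf_min=0.05, r2_max=0.3,
                                      window_bp=window)
    bad, checked = _count_pair_violations(panel, structure, 0.3, window)
    total_bad += sum(
        panel.variants[panel.index_of(v)].maf <= 0.05 for v in structure
    )
    total_bad += bad
    total_checked += checked

    common = [v for v in panel.variants if v.maf > 0.1]
    causal = [(common[len(common) // 3].id, 0.15),
              (common[2 * len(common) // 3].id, 0.15)]
    stats = simulate_summary_stats(panel, causal, n_study=20_000, trait="T2D",
                                   seed=seed + 2)
    exclude = [("1", int(panel.positions[panel.n_variants // 2]))]
    chosen = select_replication_snps(
        stats, panel,
        SelectionConfig(n_target=60, independence_r2=0.3,
                        independence_window_bp=window, exclusion_bp=50_000),
        exclude_loci=exclude,
    )
    bad, checked = _count_pair_violations(panel, chosen, 0.3, window)
    total_bad += bad
    total_checked += checked
    for vid in chosen:
        pos = int(panel.positions[panel.index_of(vid)])
        if any(c == "1" and abs(pos - p) <= 50_000 for c, p in exclude):
            total_bad += 1

    half = len(poly) // 2
    design = assemble_design(
        [("replication", "QT", poly[:half]), ("replication", "T2D", poly[half:])],
        panel.variants,
    )
    known = [("1", 100_000)]
    null = select_null_snps(design, "T2D", known, panel, exclusion_bp=40_000,
                            r2_max=0.3, window_bp=window)
    bad, checked = _count_pair_violations(panel, null.ids, 0.3, window)
    total_bad += bad
    total_checked += checked
    target_ids = set(poly[half:])
    for vid in null.ids:
        pos = int(panel.positions[panel.index_of(vid)])
        if any(c == "1" and abs(pos - p) <= 40_000 for c, p in known):
            total_bad += 1
        if vid in target_ids:
            total_bad += 1

    return total_bad, total_checked


@dataclass
class RegionRuleReport:
    shoulder_halfwidth_bp: float  # flat 1 cM/Mb map, 0.02 cM shoulder
    hotspot_boundary_bp_error: float
    lfm_contains_sfm: bool
    merge_idempotent: bool


def region_rule_checks(seed: int = 0) -> RegionRuleReport:
    """SFM/LFM boundary rules on constructed map/panel fixtures."""
    rng = np.random.default_rng(seed)
    from .containers import Region, VariantRecord
    from .containers import HaplotypePanel

    # shoulder: lone index SNP, flat 1 cM/Mb map -> +/- 20 kb
    cols = [rng.integers(0, 2, 400, dtype=np.uint8) for _ in range(9)]
    variants = [
        VariantRecord(id=f"v{k}", chrom="1", pos=3_000_000 + k * 10_000)
        for k in range(9)
    ]
    panel = HaplotypePanel(variants, np.column_stack(cols))
    flat = GeneticMap({"1": np.array([
        [1.0, 1.0, 0.0], [10_000_000.0, 0.0, 9.999999]
    ])})
    sfm = build_sfm_region(panel, flat, "v4", r2_seed=0.99)
    ipos = 3_040_000
    shoulder = max(abs(ipos - sfm.start), abs(sfm.end - ipos))

    # hotspot rule: LD block [1.20, 1.30] Mb flanked by hotspots
    block = rng.integers(0, 2, 300, dtype=np.uint8)
    flip = lambda: np.where(rng.uniform(size=300) < 0.05, 1 - block, block)
    hpanel = HaplotypePanel(
        [VariantRecord(id="l", chrom="1", pos=1_200_000),
         VariantRecord(id="idx", chrom="1", pos=1_250_000),
         VariantRecord(id="r", chrom="1", pos=1_300_000)],
        np.column_stack([flip(), block, flip()]).astype(np.uint8),
    )
    hmap = GeneticMap({"1": np.array([
        [1.0, 1.0, 0.0],
        [1_180_000.0, 100.0, 1.179],
        [1_190_000.0, 1.0, 2.179],
        [1_330_000.0, 100.0, 2.319],
        [1_340_000.0, 1.0, 3.319],
        [2_000_000.0, 0.0, 3.979],
    ])})
    hs = build_sfm_region(hpanel, hmap, "idx", hotspot_search_cm=0.5)
    hot_err = abs(hs.start - 1_190_000) + abs(hs.end - 1_330_000)

    lfm = build_lfm_region(hs, [("1", hs.start - 7_000, hs.start + 100, "G1"),
                                ("1", hs.end - 100, hs.end + 12_000, "G2")])
    contains = lfm.start <= hs.start and lfm.end >= hs.end

    regs = [Region(chrom="1", start=100, end=220, kind="SFM"),
            Region(chrom="1", start=200, end=400, kind="LFM"),
            Region(chrom="2", start=10, end=20, kind="SFM")]
    once = merge_regions(regs)
    twice = merge_regions(once)
    idem = [(r.chrom, r.start, r.end) for r in once] == [
        (r.chrom, r.start, r.end) for r in twice
    ]
    return RegionRuleReport(
        shoulder_halfwidth_bp=float(shoulder),
        hotspot_boundary_bp_error=float(hot_err),
        lfm_contains_sfm=contains,
        merge_idempotent=idem,
    )


def lambda_null_calibration(seed: int, n_seeds: int = 20,
                            n_snps: int = 10_000) -> list[float]:
    """λ_GC of balanced, unstructured case-control studies (one per seed)."""
    lams = []
    for s in _sub_seeds(seed, n_seeds):
        base = np.random.default_rng(s).uniform(0.1, 0.5, n_snps)
        geno, phen, _ = simulate_stratified_cc(
            base, 0.0, 500, 500, 0.5, 0.5, seed=s
        )
        stats = trend_test_many(geno, phen)
        lams.append(lambda_gc(stats[~np.isnan(stats)], "null").lam)
    return lams


def lambda_enrichment_ordering(
    seed: int, n_seeds: int = 20
) -> tuple[list[float], list[float]]:
    """λ_GC on trait-enriched vs null-set SNPs under stratified sampling.

    Each replicate study genotypes 1,000 differentiated SNPs standing in for
    the analysis trait's replication panel and 1,000 undifferentiated SNPs
    from an unrelated trait; cases oversample population 1 (70/30). Returns
    the per-seed λ of the enriched set and of the null set built by
    select_null_snps.
    """
    lam_enriched, lam_null = [], []
    for s in _sub_seeds(seed + 1, n_seeds):
        rng = np.random.default_rng(s)
        base = rng.uniform(0.1, 0.5, 2000)
        fst = np.where(np.arange(2000) < 1000, 0.005, 0.0)
        geno, phen, _ = simulate_stratified_cc(
            base, fst, 250, 250, 0.7, 0.3, seed=s
        )
        ids = [v.id for v in geno.variants]
        design = assemble_design(
            [("replication", "T2D", ids[:1000]),
             ("replication", "QT", ids[1000:])],
            geno.variants,
        )
        stats = trend_test_many(geno, phen)
        enr = stats[:1000]
        lam_enriched.append(lambda_gc(enr[~np.isnan(enr)], "enriched").lam)
        null = select_null_snps(design, "T2D", [], geno)
        idx = [geno.index_of(v) for v in null.ids]
        nul = stats[idx]
        lam_null.append(lambda_gc(nul[~np.isnan(nul)], "null set").lam)
    return lam_enriched, lam_null


def _kinship_study(s: int):
    cfg = PanelSimConfig(
        n_haplotypes=200, region_length=600_000, n_founders=200,
        snp_density=10_000 / 600, background_rate=2000.0, seed=s,
    )
    panel, gmap = simulate_panel(cfg)
    spec = PedigreeSpec(
        [("dad", None, None), ("mom", None, None), ("u1", None, None),
         ("kid", "dad", "mom")]
    )
    geno, _ = drop_pedigree(panel, gmap, spec, seed=s)
    freqs = panel.alt_freq
    keep = (freqs > 0.05) & (freqs < 0.95)
    sub = GenotypeMatrix(
        geno.samples,
        [v for v, k in zip(geno.variants, keep) if k],
        geno.dosages[:, keep],
    )
    return sub, freqs[keep]


def kinship_recovery(seed: int, n_seeds: int = 10) -> dict[str, float]:
    """Parent-offspring and unrelated-pair relatedness recovery.

    Returns mean π̂ and k0 for parent-offspring pairs, mean π̂ for unrelated
    founder pairs, and the mean |GRM − π̂| cross-consistency gap, over
    independent ~5,000-common-SNP studies.
    """
    po_pihat, po_k0, un_pihat, gap = [], [], [], []
    for s in _sub_seeds(seed + 2, n_seeds):
        sub, freqs = _kinship_study(s)
        po = ibd_mom(sub, "dad", "kid", freqs=freqs)
        un = ibd_mom(sub, "dad", "u1", freqs=freqs)
        g = grm(sub, freqs=freqs)
        po_pihat.append(po.pihat)
        po_k0.append(po.k0)
        un_pihat.append(un.pihat)
        gap.append(
            abs(g[sub.sample_index_of("dad"), sub.sample_index_of("kid")] - po.pihat)
        )
    return {
        "po_mean_pihat": float(np.mean(po_pihat)),
        "po_mean_k0": float(np.mean(po_k0)),
        "unrelated_mean_pihat": float(np.mean(un_pihat)),
        "grm_ibd_mean_abs_gap": float(np.mean(gap)),
        "n_seeds": n_seeds,
    }


def overlap_calibration(seed: int, n_trials: int = 1000) -> dict[str, float]:
    """Null calibration of the SNP-set overlap test.

    Reports the null-replicate mean against the hypergeometric expectation
    |A||B|/U, the type-I error rate at nominal 0.05 over independent null
    trials, and the p-value of a maximal (A = B) overlap.
    """
    universe = [f"u{k}" for k in range(1000)]
    a, b = universe[:50], universe[100:150]
    res = overlap_test(a, b, universe, n_sim=10_000, seed=seed)
    expected_exact = 50 * 50 / 1000

    # set sizes chosen so the discrete null has an attainable level near 0.05
    # (for Hypergeom(800; 150, 150) the largest tail prob <= .05 is .0459)
    frame = [f"f{k}" for k in range(800)]
    rng = np.random.default_rng(seed + 3)
    rejections = 0
    for t in range(n_trials):
        sa = list(rng.choice(frame, size=150, replace=False))
        sb = list(rng.choice(frame, size=150, replace=False))
        r = overlap_test(sa, sb, frame, n_sim=999, seed=seed + 10 + t)
        rejections += r.p_enrichment <= 0.05
    max_res = overlap_test(a, a, universe, n_sim=999, seed=seed)
    return {
        "null_mean": res.expected,
        "hypergeom_mean": expected_exact,
        "type1_rate": rejections / n_trials,
        "identical_sets_p": max_res.p_enrichment,
        "n_trials": n_trials,
    }


def determinism_mismatches(seed: int) -> int:
    """Run every stochastic operation twice with one seed; count mismatches."""
    bad = 0
    cfg = PanelSimConfig(
        n_haplotypes=80, region_length=150_000, n_founders=8,
        snp_density=0.5, hotspot_positions=[(70_000, 75_000, 60.0)], seed=seed,
    )
    p1, m1 = simulate_panel(cfg)
    p2, m2 = simulate_panel(cfg)
    bad += not np.array_equal(p1.alleles, p2.alleles)
    bad += not np.array_equal(m1.anchors["1"], m2.anchors["1"])

    spec = PedigreeSpec([("a", None, None), ("b", None, None), ("c", "a", "b")])
    g1, t1 = drop_pedigree(p1, m1, spec, seed=seed)
    g2, t2 = drop_pedigree(p2, m2, spec, seed=seed)
    bad += not np.array_equal(g1.dosages, g2.dosages)
    bad += t1 != t2

    base = np.random.default_rng(seed).uniform(0.1, 0.5, 200)
    cc1 = simulate_stratified_cc(base, 0.02, 50, 50, 0.7, 0.3, seed=seed)
    cc2 = simulate_stratified_cc(base, 0.02, 50, 50, 0.7, 0.3, seed=seed)
    bad += not np.array_equal(cc1[0].dosages, cc2[0].dosages)
    bad += not np.array_equal(cc1[1], cc2[1])

    cid = next(v.id for v in p1.variants if v.maf > 0.1)
    s1 = simulate_summary_stats(p1, [(cid, 0.2)], 5000, "t", seed=seed)
    s2 = simulate_summary_stats(p1, [(cid, 0.2)], 5000, "t", seed=seed)
    bad += s1.records != s2.records

    uni = [f"u{k}" for k in range(300)]
    o1 = overlap_test(uni[:30], uni[15:45], uni, n_sim=500, seed=seed)
    o2 = overlap_test(uni[:30], uni[15:45], uni, n_sim=500, seed=seed)
    bad += (o1.expected, o1.p_enrichment) != (o2.expected, o2.p_enrichment)
    return bad
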