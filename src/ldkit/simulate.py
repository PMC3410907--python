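"""Synthetic data with known ground truth.

Generators for (a) haplotype panels with block LD punctuated by recombination
hotspots, (b) pedigree genotypes with realized IBD truth, (c) stratified
case-control genotypes under the Balding–Nichols model, and (d) GWAS summary
statistics with planted causal signals propagated through LD. All generators
are deterministic given their seed.

The panel simulator is a founder-mosaic model, not a coalescent: descendant
haplotypes copy segments of a small founder pool, switching founders at
crossover points drawn from an inhomogeneous Poisson process whose intensity
follows the genetic map. That is enough to produce LD blocks separated by
hotspots, which is the structure the design and analysis algorithms consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .containers import (
    ConfigError,
    GeneticMap,
    GenotypeMatrix,
    HaplotypePanel,
    SummaryStats,
    VariantRecord,
)
from .ld import DEFAULT_LD_HORIZON_BP, signed_r_phased

P_FLOOR = 1e-300  # smallest reportable p-value; keeps p in (0, 1]


@dataclass
class PanelSimConfig:
    """Scenario for :func:`simulate_panel`.

    ``founder_maf_law`` is implicit: founder allele frequencies follow a
    density ∝ 1/x truncated to [1/n_haplotypes, 0.5], the neutral-like
    spectrum that makes rare alleles common in the panel.
    """

    n_haplotypes: int = 200
    region_length: int = 1_000_000
    n_founders: int = 8
    snp_density: float = 1.0  # SNPs per kb
    hotspot_positions: list[tuple[int, int, float]] = field(default_factory=list)
    # (start bp, end bp, intensity cM/Mb)
    background_rate: float = 1.0  # cM/Mb
    #: Effective depth of the founder mosaic: panel haplotypes carry the
    #: crossovers of this many generations, so LD has had time to decay at
    #: hotspots while cold blocks stay intact. Pedigree gene-dropping is
    #: unaffected (gametes are single meioses).
    mosaic_generations: float = 50.0
    chrom: str = "1"
    designable_fraction: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_haplotypes <= 0 or self.region_length <= 0:
            raise ConfigError("n_haplotypes and region_length must be positive")
        if self.n_founders > self.n_haplotypes:
            raise ConfigError("n_founders cannot exceed n_haplotypes")
        if self.background_rate < 0 or any(r < 0 for *_, r in self.hotspot_positions):
            raise ConfigError("recombination rates must be >= 0")
        for s, e, _ in self.hotspot_positions:
            if not (1 <= s < e <= self.region_length):
                raise ConfigError(f"hotspot [{s}, {e}] outside region")
        if self.mosaic_generations < 0:
            raise ConfigError("mosaic_generations must be >= 0")
        if not (0.0 <= self.designable_fraction <= 1.0):
            raise ConfigError("designable_fraction outside [0, 1]")


def _build_map(cfg: PanelSimConfig) -> GeneticMap:
    """Anchor the map at region ends and hotspot edges; rate is per-interval."""
    breaks = {1, cfg.region_length}
    for s, e, _ in cfg.hotspot_positions:
        breaks.update((s, e))
    pos = np.array(sorted(breaks), dtype=float)
    rate = np.full(len(pos), cfg.background_rate)
    for s, e, r in cfg.hotspot_positions:
        inside = (pos >= s) & (pos < e)
        rate[inside] = r
    cm = np.zeros(len(pos))
    for k in range(1, len(pos)):
        cm[k] = cm[k - 1] + rate[k - 1] * (pos[k] - pos[k - 1]) / 1e6
    rate[-1] = 0.0  # no interval to the right of the last anchor
    return GeneticMap({cfg.chrom: np.column_stack([pos, rate, cm])})


def _draw_crossovers(
    gmap: GeneticMap, chrom: str, rng: np.random.Generator, generations: float = 1.0
) -> np.ndarray:
    """Crossover bp positions: Poisson in cM (``generations`` meioses deep)."""
    arr = gmap.anchors[chrom]
    total_cm = arr[-1, 2] - arr[0, 2]
    n = rng.poisson(generations * total_cm / 100.0)
    if n == 0:
        return np.empty(0)
    cms = arr[0, 2] + rng.uniform(0.0, total_cm, size=n)
    bps = np.sort([gmap.cm_to_bp(chrom, c) for c in cms])
    return np.asarray(bps)


def simulate_panel(cfg: PanelSimConfig) -> tuple[HaplotypePanel, GeneticMap]:
    """Simulate a phased haplotype panel and its genetic map.

    Founder haplotypes are drawn site-wise from the 1/x frequency law; the
    remaining haplotypes are founder mosaics with crossovers following the
    map, so LD decays across hotspots and persists inside cold blocks.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    gmap = _build_map(cfg)
    n_snps = max(2, int(round(cfg.region_length / 1000.0 * cfg.snp_density)))
    positions = np.sort(
        rng.choice(np.arange(1, cfg.region_length + 1), size=n_snps, replace=False)
    )
    a = 1.0 / cfg.n_haplotypes
    u = rng.uniform(size=n_snps)
    freqs = a * (0.5 / a) ** u  # inverse CDF of density ∝ 1/x on [a, 0.5]
    founders = (rng.uniform(size=(cfg.n_founders, n_snps)) < freqs).astype(np.uint8)
    rows = [founders]
    for _ in range(cfg.n_haplotypes - cfg.n_founders):
        xovers = _draw_crossovers(gmap, cfg.chrom, rng, cfg.mosaic_generations)
        cuts = np.searchsorted(positions, xovers, side="right")
        cuts = np.unique(np.concatenate([[0], cuts, [n_snps]]))
        hap = np.empty(n_snps, dtype=np.uint8)
        cur = rng.integers(cfg.n_founders)
        for s, e in zip(cuts[:-1], cuts[1:]):
            hap[s:e] = founders[cur, s:e]
            if cfg.n_founders > 1:
                cur = (cur + 1 + rng.integers(cfg.n_founders - 1)) % cfg.n_founders
        rows.append(hap[None, :])
    alleles = np.vstack(rows)
    designable = rng.uniform(size=n_snps) < cfg.designable_fraction
    variants = [
        VariantRecord(
            id=f"snp{cfg.chrom}_{int(p)}",
            chrom=cfg.chrom,
            pos=int(p),
            designable=bool(d),
        )
        for p, d in zip(positions, designable)
    ]
    return HaplotypePanel(variants, alleles), gmap


@dataclass
class PedigreeSpec:
    """Ordered pedigree: parents must precede children; founders have no parents."""

    members: list[tuple[str, str | None, str | None]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for iid, dad, mom in self.members:
            if iid in seen:
                raise ConfigError(f"duplicate individual id {iid!r}")
            if (dad is None) != (mom is None):
                raise ConfigError(f"{iid!r}: either both parents or neither")
            for p in (dad, mom):
                if p is not None and p not in seen:
                    raise ConfigError(f"{iid!r}: parent {p!r} not defined earlier")
            seen.add(iid)

    @property
    def founders(self) -> list[str]:
        return [iid for iid, dad, _ in self.members if dad is None]


def _segments_to_alleles(
    segments: list[tuple[float, int]], panel: HaplotypePanel, region_end: float
) -> np.ndarray:
    """Fill per-site alleles from (start_bp, founder_hap_row) segments."""
    pos = panel.positions
    out = np.empty(panel.n_variants, dtype=np.uint8)
    starts = [s for s, _ in segments] + [region_end + 1]
    for k, (_, row) in enumerate(segments):
        lo = np.searchsorted(pos, starts[k], side="left")
        hi = np.searchsorted(pos, starts[k + 1], side="left")
        out[lo:hi] = panel.alleles[row, lo:hi]
    return out


def _meiosis(
    hap_a: list[tuple[float, int]],
    hap_b: list[tuple[float, int]],
    gmap: GeneticMap,
    chrom: str,
    rng: np.random.Generator,
) -> list[tuple[float, int]]:
    """Recombine two parental segment tracks into one gamete track."""
    xovers = _draw_crossovers(gmap, chrom, rng)
    tracks = [hap_a, hap_b]
    cur = int(rng.integers(2))
    out: list[tuple[float, int]] = []
    bounds = np.concatenate([[1.0], np.sort(xovers), [np.inf]])
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        if lo == hi:
            cur = 1 - cur
            continue
        track = tracks[cur]
        for idx, (s, row) in enumerate(track):
            e = track[idx + 1][0] if idx + 1 < len(track) else np.inf
            if e <= lo or s >= hi:
                continue
            seg_start = max(s, lo)
            if out and out[-1][1] == row:
                continue  # contiguous same founder haplotype: merge
            out.append((seg_start, row))
        cur = 1 - cur
    return out


def _pair_ibd(
    a: tuple[list[tuple[float, int]], list[tuple[float, int]]],
    b: tuple[list[tuple[float, int]], list[tuple[float, int]]],
    region_end: float,
) -> tuple[float, float, float]:
    """Length-weighted realized IBD state fractions between two individuals."""
    breaks = sorted(
        {1.0, region_end + 1.0}
        | {s for track in (*a, *b) for s, _ in track}
    )
    lens = np.diff(breaks)
    k_counts = np.zeros(3)

    def label_at(track: list[tuple[float, int]], x: float) -> int:
        lab = track[0][1]
        for s, row in track:
            if s <= x:
                lab = row
            else:
                break
        return lab

    for x, ln in zip(breaks[:-1], lens):
        a1, a2 = label_at(a[0], x), label_at(a[1], x)
        b1, b2 = label_at(b[0], x), label_at(b[1], x)
        if (a1 == b1 and a2 == b2) or (a1 == b2 and a2 == b1):
            ibd = 2
        elif a1 in (b1, b2) or a2 in (b1, b2):
            ibd = 1
        else:
            ibd = 0
        k_counts[ibd] += ln
    k = k_counts / k_counts.sum()
    return float(k[0]), float(k[1]), float(k[2])


def drop_pedigree(
    panel: HaplotypePanel,
    gmap: GeneticMap,
    spec: PedigreeSpec,
    seed: int = 0,
) -> tuple[GenotypeMatrix, dict[tuple[str, str], tuple[float, float, float]]]:
    """Gene-drop genotypes through a pedigree; return realized IBD truth.

    Founders draw haplotype pairs from the panel without replacement; children
    receive recombinant parental gametes with crossovers following the map.
    The truth dict maps each unordered sample pair to its realized genome-wide
    (k0, k1, k2), which sum to 1 exactly.
    """
    founders = spec.founders
    if panel.n_haplotypes < 2 * len(founders):
        raise ConfigError(
            f"panel has {panel.n_haplotypes} haplotypes; "
            f"{2 * len(founders)} needed for {len(founders)} founders"
        )
    rng = np.random.default_rng(seed)
    chrom = panel.variants[0].chrom
    region_end = float(panel.positions[-1])
    pool = rng.permutation(panel.n_haplotypes)
    tracks: dict[str, tuple[list[tuple[float, int]], list[tuple[float, int]]]] = {}
    next_hap = 0
    for iid, dad, mom in spec.members:
        if dad is None:
            h1, h2 = int(pool[next_hap]), int(pool[next_hap + 1])
            next_hap += 2
            tracks[iid] = ([(1.0, h1)], [(1.0, h2)])
        else:
            gam_p = _meiosis(*tracks[dad], gmap, chrom, rng)
            gam_m = _meiosis(*tracks[mom], gmap, chrom, rng)
            tracks[iid] = (gam_p, gam_m)
    sample_ids = [iid for iid, *_ in spec.members]
    dosages = np.empty((len(sample_ids), panel.n_variants), dtype=np.int8)
    for k, iid in enumerate(sample_ids):
        h1 = _segments_to_alleles(tracks[iid][0], panel, region_end)
        h2 = _segments_to_alleles(tracks[iid][1], panel, region_end)
        dosages[k] = h1 + h2
    geno = GenotypeMatrix(sample_ids, [v for v in panel.variants], dosages)
    truth = {
        (a, b): _pair_ibd(tracks[a], tracks[b], region_end)
        for a, b in combinations(sample_ids, 2)
    }
    return geno, truth


def simulate_stratified_cc(
    base_freqs: np.ndarray,
    fst: float | np.ndarray,
    n_cases: int,
    n_controls: int,
    case_pop1_fraction: float,
    control_pop1_fraction: float,
    seed: int = 0,
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Two-population case-control genotypes under the Balding–Nichols model.

    Each subpopulation frequency is Beta(p(1−F)/F, (1−p)(1−F)/F), giving mean
    p and variance F·p(1−p); genotypes are Binomial(2, subpop freq). The
    phenotype is independent of genotype given population, so any inflation
    in association statistics is pure stratification. ``fst`` may be a scalar
    or a per-SNP vector (vector form lets differentiated "trait-enriched"
    SNPs coexist with undifferentiated null SNPs in one study).

    Returns (genotypes, phenotype 0/1 vector, population labels 1/2).
    """
    base_freqs = np.asarray(base_freqs, dtype=float)
    fst_arr = np.broadcast_to(np.asarray(fst, dtype=float), base_freqs.shape).copy()
    if np.any((base_freqs <= 0.0) | (base_freqs >= 1.0)):
        raise ConfigError("base frequencies must lie strictly in (0, 1)")
    if np.any((fst_arr < 0.0) | (fst_arr >= 1.0)):
        raise ConfigError("fst must lie in [0, 1)")
    for frac in (case_pop1_fraction, control_pop1_fraction):
        if not (0.0 <= frac <= 1.0):
            raise ConfigError("population fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    m = base_freqs.size
    sub = np.empty((2, m))
    for popk in range(2):
        drift = fst_arr > 0
        sub[popk, ~drift] = base_freqs[~drift]
        if drift.any():
            p, f = base_freqs[drift], fst_arr[drift]
            sub[popk, drift] = rng.beta(p * (1 - f) / f, (1 - p) * (1 - f) / f)
    n = n_cases + n_controls
    phen = np.concatenate([np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)])
    pop = np.empty(n, dtype=int)
    pop[:n_cases] = np.where(rng.uniform(size=n_cases) < case_pop1_fraction, 1, 2)
    pop[n_cases:] = np.where(rng.uniform(size=n_controls) < control_pop1_fraction, 1, 2)
    dosages = rng.binomial(2, sub[pop - 1, :]).astype(np.int8)
    variants = [
        # far-apart positions: SNPs are simulated unlinked
        VariantRecord(id=f"cc{k}", chrom="1", pos=1 + k * 2_000_000)
        for k in range(m)
    ]
    geno = GenotypeMatrix([f"ind{k}" for k in range(n)], variants, dosages)
    return geno, phen, pop


def simulate_summary_stats(
    panel: HaplotypePanel,
    causal: list[tuple[str, float]],
    n_study: int,
    trait: str,
    seed: int = 0,
    ld_horizon_bp: int = DEFAULT_LD_HORIZON_BP,
) -> SummaryStats:
    """Analytic GWAS summary statistics with causal effects bled through LD.

    The marginal effect at SNP j is Σ_c r_jc·β_c over causal SNPs c within
    the LD horizon (r signed), its standard error 1/√(2·n_study·maf(1−maf)),
    and the Wald z gets a unit-normal noise draw, so unlinked null SNPs have
    uniform p-values. Orders of magnitude faster than simulating phenotypes;
    the selection algorithms only consume the p-value ranking.
    """
    rng = np.random.default_rng(seed)
    for cid, _ in causal:
        if cid not in panel:
            raise ConfigError(f"causal id {cid!r} not in panel")
    m = panel.n_variants
    effect = np.zeros(m)
    for cid, beta in causal:
        c = panel.index_of(cid)
        for j in range(m):
            if panel.chroms[j] != panel.chroms[c] or abs(
                int(panel.positions[j]) - int(panel.positions[c])
            ) > ld_horizon_bp:
                continue
            try:
                effect[j] += signed_r_phased(panel, j, c) * beta
            except Exception:
                continue  # monomorphic column: no effect propagates
    maf = panel.maf
    with np.errstate(divide="ignore"):
        se = 1.0 / np.sqrt(2.0 * n_study * maf * (1.0 - maf))
    z = np.where(maf > 0, effect / se, 0.0) + rng.standard_normal(m)
    p = np.clip(2.0 * sps.norm.sf(np.abs(z)), P_FLOOR, 1.0)
    records = [
        (v.id, v.chrom, v.pos, float(pj), float(fj))
        for v, pj, fj in zip(panel.variants, p, panel.alt_freq)
    ]
    return SummaryStats(trait=trait, records=records)
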