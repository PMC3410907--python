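"""Null-set selection, trend test, λ_GC, kinship and overlap testing."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from ldkit import (
    ConfigError,
    EmptyPanelError,
    GenotypeMatrix,
    InsufficientDataError,
    MonomorphicVariantError,
    VariantRecord,
    assemble_design,
    grm,
    ibd_mom,
    lambda_gc,
    overlap_test,
    select_null_snps,
    select_structure_snps,
    trend_test,
)
from ldkit.ld import R2Source
from ldkit.simulate import (
    PanelSimConfig,
    PedigreeSpec,
    drop_pedigree,
    simulate_panel,
    simulate_stratified_cc,
)
from ldkit.stats import trend_test_many

from .conftest import collapse_to_genotypes, make_panel


def geno_from_counts(case_counts, control_counts) -> tuple[GenotypeMatrix, np.ndarray]:
    """Build a one-variant genotype matrix from (aa, Aa, AA) count triples."""
    doses, phen = [], []
    for dose, n in enumerate(case_counts):
        doses += [dose] * n
        phen += [1] * n
    for dose, n in enumerate(control_counts):
        doses += [dose] * n
        phen += [0] * n
    variants = [VariantRecord(id="v", chrom="1", pos=1)]
    geno = GenotypeMatrix(
        [f"s{k}" for k in range(len(doses))], variants,
        np.array(doses, dtype=np.int8)[:, None],
    )
    return geno, np.array(phen)


def trend_oracle(doses: np.ndarray, phen: np.ndarray) -> float:
    """Independent oracle: the Armitage statistic equals N·corr(y, g)²."""
    r = np.corrcoef(doses.astype(float), phen.astype(float))[0, 1]
    return len(doses) * r * r


class TestTrendTest:
    def test_no_association_gives_zero(self):
        geno, phen = geno_from_counts((10, 20, 30), (10, 20, 30))
        assert trend_test(geno, phen, 0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_correlation_identity_oracle(self):
        geno, phen = geno_from_counts((10, 20, 30), (30, 20, 10))
        expected = trend_oracle(geno.dosages[:, 0], phen)
        assert trend_test(geno, phen, 0) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("case_counts,control_counts", [
        ((5, 15, 30), (25, 20, 5)),
        ((1, 2, 47), (40, 8, 2)),
        ((17, 3, 30), (12, 25, 13)),
    ])
    def test_identity_oracle_parametrized(self, case_counts, control_counts):
        geno, phen = geno_from_counts(case_counts, control_counts)
        expected = trend_oracle(geno.dosages[:, 0], phen)
        assert trend_test(geno, phen, 0) == pytest.approx(expected, rel=1e-10)

    def test_vectorized_agrees_with_scalar(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.1, 0.5, 50)
        geno, phen, _ = simulate_stratified_cc(base, 0.02, 100, 100, 0.5, 0.5, seed=1)
        many = trend_test_many(geno, phen)
        for k in range(geno.n_variants):
            if np.isnan(many[k]):
                continue
            assert many[k] == pytest.approx(trend_test(geno, phen, k), rel=1e-10)

    def test_null_statistics_chi2_distributed(self):
        # the chi-square limit needs a sizable study for a 10k-SNP KS check
        base = np.random.default_rng(2).uniform(0.15, 0.5, 10_000)
        geno, phen, _ = simulate_stratified_cc(base, 0.0, 1500, 1500, 0.5, 0.5, seed=3)
        stats = trend_test_many(geno, phen)
        stats = stats[~np.isnan(stats)]
        assert sps.kstest(stats, sps.chi2(df=1).cdf).pvalue > 0.01

    def test_single_class_and_monomorphic_rejected(self):
        geno, phen = geno_from_counts((10, 10, 10), (0, 0, 0))
        with pytest.raises(ConfigError):
            trend_test(geno, phen, 0)
        geno2, phen2 = geno_from_counts((0, 0, 30), (0, 0, 30))
        with pytest.raises(MonomorphicVariantError):
            trend_test(geno2, phen2, 0)


class TestLambdaGC:
    def test_definition_at_reference_median(self):
        stats = [0.1, 0.4549, 3.0]
        assert lambda_gc(stats).lam == pytest.approx(1.0)

    def test_scaling_property(self):
        draws = sps.chi2(df=1).rvs(size=10_000, random_state=5)
        lam = lambda_gc(2.0 * draws).lam
        assert lam == pytest.approx(2.0, abs=0.1)

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            lambda_gc([])


def _enriched_design_and_panel(seed=0):
    """A design with T2D-enriched SNPs plus QT (null) replication SNPs."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.1, 0.5, 400)
    fst = np.where(np.arange(400) < 200, 0.15, 0.0)  # T2D SNPs differentiated
    geno, phen, _ = simulate_stratified_cc(
        base, fst, 250, 250, case_pop1_fraction=0.85,
        control_pop1_fraction=0.15, seed=seed,
    )
    ids = [v.id for v in geno.variants]
    design = assemble_design(
        [("replication", "T2D", ids[:200]), ("replication", "QT", ids[200:])],
        geno.variants,
    )
    return design, geno, phen


class TestSelectNullSnps:
    def test_known_locus_exclusion_can_empty_the_set(self):
        col = np.array([0, 1] * 20)
        panel = make_panel({"only": col}, positions=[500_000])
        design = assemble_design(
            [("replication", "QT", ["only"])], panel.variants
        )
        with pytest.raises(EmptyPanelError):
            select_null_snps(design, "T2D", [("1", 400_000)], panel,
                             exclusion_bp=250_000)

    def test_unlinked_snps_all_retained_without_known_loci(self):
        design, geno, _ = _enriched_design_and_panel(seed=2)
        res = select_null_snps(design, "T2D", [], geno)
        assert set(res.ids) == set(design.ids_for("replication", "QT"))

    def test_bruteforce_postcheck(self, block_panel):
        panel, _ = block_panel
        poly = [v.id for v in panel.variants if v.maf > 0]
        design = assemble_design(
            [("replication", "QT", poly[: len(poly) // 2]),
             ("replication", "T2D", poly[len(poly) // 2:])],
            panel.variants,
        )
        known = [("1", 50_000)]
        res = select_null_snps(design, "T2D", known, panel,
                               exclusion_bp=30_000, r2_max=0.3, window_bp=100_000)
        src = R2Source(panel, ld_horizon_bp=100_000)
        idx = [panel.index_of(v) for v in res.ids]
        for i in idx:
            assert abs(int(panel.positions[i]) - 50_000) > 30_000
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if src.in_horizon(idx[a], idx[b]):
                    assert src.r2(idx[a], idx[b]) <= 0.3 + 1e-12
        # target-trait replication SNPs never enter the null set
        assert not set(res.ids) & set(poly[len(poly) // 2:])

    def test_lambda_ordering_enriched_vs_null_set(self):
        """Trait-enriched SNPs inflate λ_GC; the other-trait null set does not."""
        wins = 0
        for seed in range(10):
            design, geno, phen = _enriched_design_and_panel(seed=seed)
            stats = trend_test_many(geno, phen)
            lam_all = lambda_gc(stats[:200], "enriched").lam
            null = select_null_snps(design, "T2D", [], geno)
            null_idx = [geno.index_of(v) for v in null.ids]
            lam_null = lambda_gc(stats[null_idx], "null set").lam
            wins += lam_all > lam_null
        assert wins >= 9


class TestSelectStructureSnps:
    def test_all_rare_rejected(self):
        cols = {f"s{k}": np.array([1] + [0] * 99) for k in range(3)}
        panel = make_panel(cols)
        with pytest.raises(EmptyPanelError):
            select_structure_snps(panel, maf_min=0.05)

    def test_unlinked_common_retained_and_constraints_hold(self, block_panel):
        panel, _ = block_panel
        out = select_structure_snps(panel, maf_min=0.05, r2_max=0.3,
                                    window_bp=100_000)
        src = R2Source(panel, ld_horizon_bp=100_000)
        idx = [panel.index_of(v) for v in out]
        for i in idx:
            assert panel.variants[i].maf > 0.05
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if src.in_horizon(idx[a], idx[b]):
                    assert src.r2(idx[a], idx[b]) <= 0.3 + 1e-12


def unlinked_pedigree_geno(seed=0, n_snps=10_000):
    # founders-only pool large enough that in-sample frequency estimates
    # carry negligible -1/(n-1) bias into GRM/IBD estimates; ~half the 1/x-law
    # SNPs survive the MAF>0.05 filter, leaving ~n_snps/2 for estimation
    cfg = PanelSimConfig(
        n_haplotypes=200, region_length=600_000, n_founders=200,
        snp_density=n_snps / 600, background_rate=2000.0, seed=seed,
    )
    panel, gmap = simulate_panel(cfg)
    spec = PedigreeSpec(
        [("dad", None, None), ("mom", None, None), ("u1", None, None),
         ("kid", "dad", "mom")]
    )
    geno, truth = drop_pedigree(panel, gmap, spec, seed=seed)
    freqs = panel.alt_freq
    return geno, truth, freqs


class TestIbdMom:
    def test_duplicate_sample_pihat_one(self):
        geno, _, freqs = unlinked_pedigree_geno(seed=1)
        dup = GenotypeMatrix(
            ["a", "b"], geno.variants,
            np.vstack([geno.dosages[0], geno.dosages[0]]),
        )
        res = ibd_mom(dup, "a", "b", freqs=freqs)
        assert res.pihat == pytest.approx(1.0, abs=0.05)
        assert res.k2 > 0.9

    def test_parent_offspring_recovery(self):
        pihats, k0s = [], []
        for seed in range(15):
            geno, _, freqs = unlinked_pedigree_geno(seed=seed)
            keep = (freqs > 0.05) & (freqs < 0.95)
            sub = GenotypeMatrix(
                geno.samples,
                [v for v, k in zip(geno.variants, keep) if k],
                geno.dosages[:, keep],
            )
            res = ibd_mom(sub, "dad", "kid", freqs=freqs[keep])
            pihats.append(res.pihat)
            k0s.append(res.k0)
        assert 0.45 < np.mean(pihats) < 0.55
        assert np.mean(k0s) < 0.05

    def test_unrelated_founders_near_zero(self):
        pihats = []
        for seed in range(15):
            geno, _, freqs = unlinked_pedigree_geno(seed=100 + seed)
            keep = (freqs > 0.05) & (freqs < 0.95)
            sub = GenotypeMatrix(
                geno.samples,
                [v for v, k in zip(geno.variants, keep) if k],
                geno.dosages[:, keep],
            )
            pihats.append(ibd_mom(sub, "dad", "u1", freqs=freqs[keep]).pihat)
        assert np.mean(pihats) < 0.05

    def test_simplex_constraint_always_holds(self):
        for seed in range(5):
            geno, _, freqs = unlinked_pedigree_geno(seed=200 + seed)
            for i in range(geno.n_samples):
                for j in range(i + 1, geno.n_samples):
                    res = ibd_mom(geno, i, j, freqs=freqs)
                    assert res.k0 + res.k1 + res.k2 == pytest.approx(1.0, abs=1e-9)
                    assert min(res.k0, res.k1, res.k2) >= 0

    def test_too_few_snps_rejected(self):
        geno, _, freqs = unlinked_pedigree_geno(seed=3)
        sub = GenotypeMatrix(
            geno.samples, geno.variants[:50], geno.dosages[:, :50]
        )
        with pytest.raises(InsufficientDataError):
            ibd_mom(sub, "dad", "mom", freqs=freqs[:50])


class TestGrm:
    def test_duplicate_sample_offdiag_matches_diag(self):
        geno, _, freqs = unlinked_pedigree_geno(seed=4)
        dup = GenotypeMatrix(
            ["a", "b"], geno.variants,
            np.vstack([geno.dosages[0], geno.dosages[0]]),
        )
        g = grm(dup, freqs=freqs)
        assert g[0, 1] == pytest.approx(g[0, 0], abs=1e-9)

    def test_unrelated_offdiag_near_zero(self):
        vals = []
        for seed in range(10):
            geno, _, freqs = unlinked_pedigree_geno(seed=300 + seed, n_snps=5000)
            keep = (freqs > 0.05) & (freqs < 0.95)
            sub = GenotypeMatrix(
                geno.samples,
                [v for v, k in zip(geno.variants, keep) if k],
                geno.dosages[:, keep],
            )
            g = grm(sub, freqs=freqs[keep])
            vals.append(g[sub.sample_index_of("dad"), sub.sample_index_of("u1")])
        assert abs(np.mean(vals)) < 0.02

    def test_cross_consistency_with_ibd_for_parent_offspring(self):
        """GRM off-diagonal estimates π̂ = 2×kinship, ≈0.5 for parent-offspring."""
        diffs = []
        for seed in range(10):
            geno, _, freqs = unlinked_pedigree_geno(seed=400 + seed)
            keep = (freqs > 0.05) & (freqs < 0.95)
            sub = GenotypeMatrix(
                geno.samples,
                [v for v, k in zip(geno.variants, keep) if k],
                geno.dosages[:, keep],
            )
            g = grm(sub, freqs=freqs[keep])
            pihat = ibd_mom(sub, "dad", "kid", freqs=freqs[keep]).pihat
            off = g[sub.sample_index_of("dad"), sub.sample_index_of("kid")]
            diffs.append(abs(off - pihat))
        assert np.mean(diffs) < 0.1


class TestOverlapTest:
    def test_identical_sets_give_minimum_p(self):
        universe = [f"u{k}" for k in range(1000)]
        a = universe[:50]
        res = overlap_test(a, a, universe, n_sim=999, seed=1)
        assert res.prop_max == 1.0
        assert res.p_enrichment == pytest.approx(1 / 1000)

    def test_null_mean_matches_hypergeometric(self):
        universe = [f"u{k}" for k in range(1000)]
        a, b = universe[:50], universe[100:150]
        res = overlap_test(a, b, universe, n_sim=10_000, seed=2)
        assert res.expected == pytest.approx(50 * 50 / 1000, abs=0.1)

    def test_type_one_error_calibrated(self):
        # sizes give the discrete null an attainable level near 0.05
        rng = np.random.default_rng(3)
        universe = [f"u{k}" for k in range(800)]
        rejections = 0
        n_trials = 1000
        for t in range(n_trials):
            a = list(rng.choice(universe, size=150, replace=False))
            b = list(rng.choice(universe, size=150, replace=False))
            res = overlap_test(a, b, universe, n_sim=999, seed=t)
            rejections += res.p_enrichment <= 0.05
        assert 0.03 <= rejections / n_trials <= 0.07

    def test_seed_reproducibility(self):
        universe = [f"u{k}" for k in range(200)]
        a, b = universe[:30], universe[20:55]
        r1 = overlap_test(a, b, universe, n_sim=500, seed=9)
        r2 = overlap_test(a, b, universe, n_sim=500, seed=9)
        assert (r1.expected, r1.p_enrichment) == (r2.expected, r2.p_enrichment)

    def test_non_subset_rejected(self):
        with pytest.raises(ConfigError):
            overlap_test(["x"], ["y"], ["y"], n_sim=10)
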