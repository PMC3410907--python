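"""Shared fixtures: small deterministic panels, maps and genotype sets."""

from __future__ import annotations

import numpy as np
import pytest

from ldkit import GeneticMap, GenotypeMatrix, HaplotypePanel, VariantRecord
from ldkit.simulate import PanelSimConfig, simulate_panel


def make_panel(columns: dict[str, np.ndarray], chrom: str = "1",
               positions: list[int] | None = None) -> HaplotypePanel:
    """Build a panel from named allele columns at given (or spaced) positions."""
    ids = list(columns)
    pos = positions or [1000 * (k + 1) for k in range(len(ids))]
    variants = [VariantRecord(id=i, chrom=chrom, pos=p) for i, p in zip(ids, pos)]
    alleles = np.column_stack([np.asarray(columns[i], dtype=np.uint8) for i in ids])
    return HaplotypePanel(variants, alleles)


def flat_map(chrom: str = "1", length: int = 10_000_000,
             rate: float = 1.0) -> GeneticMap:
    """Uniform-rate map over [1, length]."""
    pos = np.array([1.0, float(length)])
    cm = np.array([0.0, rate * (length - 1) / 1e6])
    return GeneticMap({chrom: np.column_stack([pos, [rate, 0.0], cm])})


def collapse_to_genotypes(panel: HaplotypePanel) -> GenotypeMatrix:
    """Pair consecutive haplotypes into unphased diploid dosages."""
    assert panel.n_haplotypes % 2 == 0
    dos = panel.alleles[0::2].astype(np.int8) + panel.alleles[1::2].astype(np.int8)
    samples = [f"S{k}" for k in range(dos.shape[0])]
    return GenotypeMatrix(samples, list(panel.variants), dos)


@pytest.fixture(scope="session")
def block_panel():
    """A 200-haplotype panel with block LD and one strong central hotspot."""
    cfg = PanelSimConfig(
        n_haplotypes=200,
        region_length=500_000,
        n_founders=8,
        snp_density=0.6,
        hotspot_positions=[(240_000, 250_000, 100.0)],
        background_rate=0.5,
        seed=42,
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def iid_panel():
    """A founders-only panel (no LD): frequencies straight from the 1/x law."""
    cfg = PanelSimConfig(
        n_haplotypes=1000,
        region_length=1_000_000,
        n_founders=1000,
        snp_density=1.0,
        background_rate=1.0,
        seed=7,
    )
    return simulate_panel(cfg)
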