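import numpy as np
import pytest

from ordgen.popgen import maf_filter, vanraden_grm
from ordgen.synthetic_data import SimulationConfig, simulate_genotypes


@pytest.fixture(scope="session")
def two_pop_panel():
    """Structured panel: two germplasm clusters, moderate divergence."""
    cfg = SimulationConfig(
        n_individuals=120,
        n_chromosomes=2,
        n_snps_per_chrom=80,
        chromosome_length_bp=2_000_000,
        n_subpops=2,
        fst=0.2,
        copy_switch_rate=1e-5,
        seed=11,
    )
    return simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def filtered_panel(two_pop_panel):
    return maf_filter(two_pop_panel, 0.05)


@pytest.fixture(scope="session")
def unstructured_panel():
    """Single-population panel with effectively independent loci."""
    cfg = SimulationConfig(
        n_individuals=200,
        n_chromosomes=2,
        n_snps_per_chrom=150,
        chromosome_length_bp=50_000_000,
        n_subpops=1,
        fst=0.0,
        copy_switch_rate=1.0,  # switch at every locus: no LD beyond the founder pool
        seed=5,
    )
    return simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def small_grm(filtered_panel):
    return vanraden_grm(filtered_panel)
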