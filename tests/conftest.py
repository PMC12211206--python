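import numpy as np
import pandas as pd
import pytest

from mitonuc.simulate import SimulationConfig, simulate_counts, simulate_metadata
from mitonuc.variants import VariantMatrix


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def default_metadata(default_config):
    return simulate_metadata(default_config)


@pytest.fixture(scope="session")
def default_counts(default_config, default_metadata):
    counts, truth = simulate_counts(default_config, default_metadata)
    return counts, truth


def make_variant_matrix(
    genotypes: np.ndarray,
    site_qual: np.ndarray | None = None,
    depth: np.ndarray | None = None,
    contigs: list[str] | None = None,
    n_alleles: np.ndarray | None = None,
) -> VariantMatrix:
    """Hand-built VariantMatrix for unit tests."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_loci, n_ind = genotypes.shape
    loci = pd.DataFrame(
        {
            "contig": contigs if contigs is not None else [f"c{i}" for i in range(n_loci)],
            "pos": np.arange(1, n_loci + 1),
            "ref": ["A"] * n_loci,
            "alt": ["T"] * n_loci,
            "n_alleles": n_alleles if n_alleles is not None else np.full(n_loci, 2),
        }
    )
    return VariantMatrix(
        loci=loci,
        samples=[f"ind{j}" for j in range(n_ind)],
        genotypes=genotypes,
        site_qual=site_qual if site_qual is not None else np.full(n_loci, 50.0),
        depth=depth if depth is not None else np.full((n_loci, n_ind), 30, dtype=np.int32),
    )
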