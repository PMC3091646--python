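import numpy as np
import pytest

from pseudis.benchmark import run_benchmark
from pseudis.synthetic_genome import ISFamilySpec, SimConfig


def small_config(seed: int) -> SimConfig:
    """A ~40 kb genome with every planted feature class, fast enough for
    unit-level end-to-end runs."""
    return SimConfig(
        seed=seed,
        n_proteins=40,
        n_genes_placed=35,
        pseudo_fraction=8 / 35,
        is_families=(ISFamilySpec(n_complete=4, n_partial=1, n_defective=1),),
        n_is_split_genes=2,
        n_missplit_genes=3,
    )


@pytest.fixture(scope="session")
def small_bench():
    """One full pipeline run on a small synthetic genome, shared by tests.

    Yields (BenchmarkResult, SimResult, ReconciledAnnotation).
    """
    return run_benchmark(small_config(3))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)


AA20 = list("ACDEFGHIKLMNPQRSTVWY")


def random_protein(rng, n):
    return "M" + "".join(rng.choice(AA20, size=n - 1))


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
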