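import numpy as np
import pandas as pd
import pytest

from foxodep import IntensityMatrix, SimConfig, make_bundle


def matrix_from_values(values, genotypes, proteins=None, tissue="gut"):
    """Build an IntensityMatrix from a 2-D array and per-column genotypes."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    if len(genotypes) != m:
        raise ValueError("one genotype per column required")
    proteins = proteins or [f"P{i:05d}" for i in range(n)]
    counts: dict[str, int] = {}
    sample_ids = []
    reps = []
    for g in genotypes:
        counts[g] = counts.get(g, 0) + 1
        sample_ids.append(f"{tissue}_{g}{counts[g]}")
        reps.append(counts[g])
    samples = pd.DataFrame(
        {"genotype": list(genotypes), "tissue": tissue, "replicate": reps},
        index=pd.Index(sample_ids, name="sample"),
    )
    vdf = pd.DataFrame(values, index=pd.Index(proteins, name="protein"), columns=sample_ids)
    return IntensityMatrix(values=vdf, samples=samples)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic study reused across tests (fixed seed)."""
    return make_bundle(
        SimConfig(n_proteins=300, seed=11),
        n_modules=2,
        module_size=8,
        n_terms=12,
        dag_depth=2,
        term_size_range=(5, 20),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
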