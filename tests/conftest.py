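import numpy as np
import pandas as pd
import pytest

from phocycle import syndata
from phocycle.de import CountMatrix, GENOTYPES


@pytest.fixture(scope="session")
def small_genome():
    return syndata.make_toy_genome(
        n_chrom=2, chrom_len=20_000, n_genes=12, motif_plan={0: 4, 1: 3, 2: 2},
        seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_count_matrix(counts: np.ndarray, genotypes=None) -> CountMatrix:
    """Wrap a raw array as a CountMatrix with a default 4x2 factorial sheet."""
    n_samples = counts.shape[1]
    if genotypes is None:
        reps = n_samples // len(GENOTYPES)
        genotypes = [g for g in GENOTYPES for _ in range(reps)]
    sample_ids = [f"s{i}" for i in range(n_samples)]
    replicate = []
    seen: dict[str, int] = {}
    for g in genotypes:
        seen[g] = seen.get(g, 0) + 1
        replicate.append(seen[g])
    sheet = pd.DataFrame(
        {"sample_id": sample_ids, "genotype": genotypes, "replicate": replicate}
    )
    df = pd.DataFrame(
        counts, index=[f"g{i}" for i in range(counts.shape[0])], columns=sample_ids
    )
    return CountMatrix(df, sheet)
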