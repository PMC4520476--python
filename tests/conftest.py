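import numpy as np
import pandas as pd
import pytest

from igamap.io import GenotypeMatrix, MarkerMap, PhenotypeTable


def make_marker_map(n, chrom="1", spacing=10_000, prefix="m"):
    return MarkerMap(pd.DataFrame({
        "marker_id": [f"{prefix}{j:04d}" for j in range(n)],
        "chrom": chrom,
        "pos": [(j + 1) * spacing for j in range(n)],
        "allele_a": "A",
        "allele_b": "G",
    }))


def make_genotypes(rng, n_samples=10, n_markers=20, missing_rate=0.0,
                   ensure_polymorphic=True):
    """Random dosage matrix; optionally guarantees both alleles observed at
    every marker so PLINK-text round trips preserve the A/B coding."""
    while True:
        d = rng.integers(0, 3, size=(n_samples, n_markers)).astype(float)
        if not ensure_polymorphic:
            break
        has_a = ((d == 0) | (d == 1)).any(axis=0)
        has_b = ((d == 2) | (d == 1)).any(axis=0)
        if (has_a & has_b).all():
            break
    if missing_rate > 0:
        d[rng.random(d.shape) < missing_rate] = np.nan
    samples = [f"s{i:03d}" for i in range(n_samples)]
    return GenotypeMatrix(samples, make_marker_map(n_markers), d)


def make_phenotypes(rng, samples, iga=None):
    n = len(samples)
    return PhenotypeTable(pd.DataFrame({
        "sample_id": list(samples),
        "iga": rng.uniform(0.01, 1.4, n) if iga is None else iga,
        "age": rng.uniform(1, 12, n),
        "sex": rng.choice(["F", "M"], n),
    }))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
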