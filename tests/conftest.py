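import numpy as np
import pandas as pd
import pytest

from gerode.containers import GenotypeMatrix


def make_gm(
    genotypes,
    cohorts=None,
    impacts=None,
    depth=None,
    gq=None,
    sample_ids=None,
):
    """Build a small GenotypeMatrix from a (samples x sites) dosage array."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    if cohorts is None:
        cohorts = ["wild"] * n
    if impacts is None:
        impacts = ["LOW"] * m
    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, m + 1) * 1000,
            "anc": "A",
            "der": "T",
            "impact": impacts,
        }
    )
    return GenotypeMatrix(
        sample_ids=sample_ids,
        cohorts=np.array(cohorts, dtype=object),
        sites=sites,
        genotypes=genotypes,
        depth=None if depth is None else np.asarray(depth),
        gq=None if gq is None else np.asarray(gq),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
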