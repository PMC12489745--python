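import numpy as np
import pandas as pd
import pytest

from popgea.genio import GenotypeMatrix


def make_gm(dosages, pops=None, positions=None, chrom="chr1", qual=100.0, depth=8.0):
    """GenotypeMatrix from a raw dosage array (use -1 for missing)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, L = dosages.shape
    if positions is None:
        positions = np.arange(1, L + 1) * 1000
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "T",
            "qual": qual,
            "mean_depth": depth,
            "biallelic": True,
        }
    )
    if pops is None:
        pops = ["pop1"] * n
    individuals = pd.DataFrame(
        {
            "id": [f"ind{i:03d}" for i in range(n)],
            "region": pops,
            "subregion": "siteA",
            "lat": np.nan,
            "lon": np.nan,
        }
    )
    return GenotypeMatrix(dosages, sites, individuals)


@pytest.fixture
def two_pop_gm():
    """Deterministic 2-population matrix with moderate differentiation."""
    rng = np.random.default_rng(77)
    p1 = rng.uniform(0.1, 0.9, 300)
    p2 = np.clip(p1 + rng.normal(0, 0.25, 300), 0.02, 0.98)
    g = np.vstack(
        [rng.binomial(2, p1, (25, 300)), rng.binomial(2, p2, (25, 300))]
    )
    return make_gm(g, pops=["north"] * 25 + ["south"] * 25)
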