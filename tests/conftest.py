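import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import zmanova as zm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_snp_map() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rsid": [f"rs{i}" for i in range(5)],
            "chrom": ["1", "1", "2", "2", "3"],
            "pos": [100, 200, 50, 400, 10],
            "ref_allele": list("ATGCA"),
            "eff_allele": list("GGTAC"),
        }
    )


@pytest.fixture
def toy_zmatrix(toy_snp_map) -> zm.ZMatrix:
    rng = np.random.default_rng(0)
    z = pd.DataFrame(
        rng.standard_normal((5, 3)),
        index=pd.Index(toy_snp_map["rsid"], name="rsid"),
        columns=["t1", "t2", "t3"],
    )
    return zm.ZMatrix(z)


@pytest.fixture
def null_study():
    """A small pure-null cohort: genotypes, phenotypes and their OLS scan."""
    rng = np.random.default_rng(11)
    g, mafs = zm.simulate_genotypes(800, 300, (0.1, 0.5), rng)
    truth = zm.SimTruth(
        sigma=zm.equicorrelated(3, 0.5),
        causal_snps=np.array([], dtype=int),
        effect_matrix=np.zeros((0, 3)),
        mafs=mafs,
        seed=12,
    )
    y = zm.simulate_phenotypes(g, truth)
    scan = zm.univariate_gwas(g, y)
    return g, y, scan, truth
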