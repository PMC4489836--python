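import numpy as np
import pandas as pd
import pytest

import grs


@pytest.fixture(scope="session")
def panel():
    return grs.default_panel()


@pytest.fixture(scope="session")
def small_cohort(panel):
    """A modest complete-genotype prospective cohort shared across tests."""
    spec = grs.nphsii_scenario(seed=11, n=3000, missing_rate=0.0)
    geno, cohort = grs.simulate_cohort(spec)
    return geno, cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_genotypes(panel):
    """Three individuals with hand-set dosages at every panel SNP."""
    data = {rsid: [0.0, 1.0, 2.0] for rsid in panel.rsids}
    df = pd.DataFrame(data, index=pd.Index(["a", "b", "c"],
                                           name="individual_id"))
    return grs.GenotypeMatrix(df)
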