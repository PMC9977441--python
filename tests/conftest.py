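import numpy as np
import pandas as pd
import pytest

import methylcna as m


@pytest.fixture(scope="session")
def toy_genome():
    return m.GenomeModel.toy()


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort reused across read-only tests."""
    loci = m.default_loci(n_ancestry=5, n_germline=4, n_null=80)
    cfg = m.default_config(
        seed=7, loci=loci, n_tumor_group_a=60, n_tumor_group_b=60, n_normal=60
    )
    return m.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    return m.fit_mixture(small_cohort.segments, seed=7)


def make_track(values, sample_id="s1", chrom="chr1", bin_size=1000):
    values = np.asarray(values, float)
    n = len(values)
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "chrom": chrom,
            "start": np.arange(n) * bin_size,
            "end": (np.arange(n) + 1) * bin_size,
            "log2_ratio": values,
        }
    )
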