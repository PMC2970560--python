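import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20231107)


@pytest.fixture
def small_genotype_tables():
    """Two samples x two SNPs per arm, fully called, alleles A (risk) / G."""
    def rows(arm, genotypes):
        out = []
        for i, sample in enumerate(genotypes):
            for j, (a1, a2) in enumerate(sample):
                out.append((f"{arm}{i + 1}", arm, f"snp{j + 1}", a1, a2))
        return out

    case = rows("case", [[("A", "A"), ("A", "G")], [("A", "G"), ("G", "G")]])
    ctrl = rows("control", [[("G", "G"), ("A", "G")], [("A", "G"), ("G", "G")]])
    cols = ["sample_id", "arm", "snp_id", "allele1", "allele2"]
    return pd.DataFrame(case, columns=cols), pd.DataFrame(ctrl, columns=cols)
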