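import pandas as pd
import pytest

from lmsubtype import synthetic


@pytest.fixture(scope="session")
def subtype_cohort():
    """Moderate two-group expression cohort shared across read-only tests."""
    cfg = synthetic.SimConfig(seed=42, n_samples_per_group=(30, 30))
    return synthetic.gen_subtype_cohort(cfg)


@pytest.fixture(scope="session")
def mirna_cohort():
    cfg = synthetic.SimConfig(seed=5, n_samples_per_group=(20, 20))
    counts, gene_expr, db, mapping, truth = synthetic.gen_mirna_cohort(cfg)
    return counts, gene_expr, db, mapping, truth


@pytest.fixture(scope="session")
def cnv_cohort():
    cfg = synthetic.SimConfig(seed=7)
    return synthetic.gen_cnv_cohort(cfg)


@pytest.fixture()
def two_group_labels():
    def make(n_a: int, n_b: int, prefix: str = "P"):
        idx = [f"{prefix}{i:03d}" for i in range(1, n_a + n_b + 1)]
        return pd.Series(["h"] * n_a + ["o"] * n_b, index=idx, name="group")

    return make
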