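import numpy as np
import pandas as pd
import pytest

import pathassoc as pa


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_samples(n, rng, balanced=True, two_ethnicities=True):
    """Random sample table with the standard covariates."""
    status = rng.integers(0, 2, n) if not balanced else np.tile([0, 1], n // 2 + 1)[:n]
    eth = (rng.choice(["Caucasian", "African American"], n, p=[0.8, 0.2])
           if two_ethnicities else np.repeat("Caucasian", n))
    return pa.SampleTable(pd.DataFrame({
        "sample_id": [f"S{i:04d}" for i in range(n)],
        "status": status,
        "age": rng.normal(65.9, 8.4, n).clip(40, 90),
        "institution": rng.choice(["site_A", "site_B", "site_C"], n),
        "ethnicity": eth,
    }))


@pytest.fixture
def samples200(rng):
    return make_samples(200, rng)


@pytest.fixture(scope="session")
def small_cohort():
    """Simulated cohort on a 4-gene sub-panel (deterministic seed)."""
    ann = pa.packaged_annotation()
    keep = ann.table.gene.isin(["TLR1", "TLR6", "OAS1", "IL6R"]) | ann.table.is_aim
    sub = pa.SnpAnnotation(ann.table[keep].reset_index(drop=True))
    cfg = pa.SimConfig(n_cases=150, n_controls=170, annotation=sub, seed=20240915)
    gm, samples, a = pa.simulate_cohort(cfg)
    return gm, samples, a
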