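import numpy as np
import pandas as pd
import pytest

import sufucore as sc


@pytest.fixture(scope="session")
def table1():
    return sc.load_table1_fixture()


@pytest.fixture(scope="session")
def synth_default():
    """One strong-signal synthetic dataset with ground truth."""
    return sc.generate(sc.SynthConfig(seed=11))


@pytest.fixture(scope="session")
def recovery_criteria():
    """Screening setup of the planted-core recovery experiments: the
    promoter-only (positive-association) reading of the flavor screen,
    under which planted antagonists donate co-occurrence degree without
    qualifying as core."""
    return sc.ScreeningCriteria(flavor_sign="positive_only")


def make_abundance(values, days=None, replicates=None, mode="counts", genera=None):
    """Small helper to build an AbundanceTable from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    days = days if days is not None else [10 * (i + 1) for i in range(n)]
    replicates = replicates if replicates is not None else [1] * n
    genera = genera or [f"g{j}" for j in range(values.shape[1])]
    meta = [
        sc.SampleMeta(f"d{d}r{r}", d, r) for d, r in zip(days, replicates)
    ]
    df = pd.DataFrame(
        values, index=[m.sample_id for m in meta], columns=genera
    )
    return sc.AbundanceTable(meta=meta, values=df, mode=mode)
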