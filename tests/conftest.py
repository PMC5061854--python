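import numpy as np
import pandas as pd
import pytest

import benthonet as bn


@pytest.fixture(scope="session")
def small_dataset():
    """Deterministic 12-sample x 40-OTU community with 2 planted modules."""
    table, meta, taxonomy, truth, design = bn.fixture_small()
    return {"table": table, "meta": meta, "taxonomy": taxonomy,
            "truth": truth, "design": design}


@pytest.fixture()
def tiny_table():
    df = pd.DataFrame(
        [[4, 0, 1], [2, 3, 5], [0, 0, 7], [1, 1, 1]],
        index=["otuA", "otuB", "otuC", "otuD"],
        columns=["s1", "s2", "s3"],
    )
    return bn.AbundanceTable(df)


@pytest.fixture()
def pah_profile():
    return {c: 1.0 for c in bn.PAH_COMPOUNDS}


def random_table(rng: np.random.Generator, n_otus: int, n_samples: int,
                 lam: float = 5.0) -> bn.AbundanceTable:
    counts = rng.poisson(lam, size=(n_otus, n_samples))
    return bn.AbundanceTable(pd.DataFrame(
        counts,
        index=[f"otu{i}" for i in range(n_otus)],
        columns=[f"s{j}" for j in range(n_samples)],
    ))
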