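import numpy as np
import pandas as pd
import pytest

from graftmicrobe import (
    CountMatrix,
    SampleMetadata,
    SyntheticConfig,
    TaxonomyTable,
    generate_dataset,
)
from graftmicrobe.data_model import RANKS


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_matrix():
    """2 samples x 2 features with known cells."""
    return CountMatrix(
        pd.DataFrame([[5, 0], [3, 500]], index=["s1", "s2"], columns=["f1", "f2"])
    )


@pytest.fixture
def random_matrix(rng):
    """20 samples x 50 features of Poisson counts with uneven totals."""
    depth = rng.integers(200, 5000, size=20)
    counts = rng.poisson(depth[:, None] * rng.dirichlet(np.ones(50)), size=(20, 50))
    return CountMatrix(
        pd.DataFrame(
            counts,
            index=[f"s{i:02d}" for i in range(20)],
            columns=[f"f{j:02d}" for j in range(50)],
        )
    )


@pytest.fixture
def balanced_metadata():
    """9 varieties x 15 locations, one sample per cell (135 samples)."""
    rows = []
    varieties = ["ungrafted"] + [f"rootstock_{k:02d}" for k in range(1, 9)]
    sid = 0
    for l in range(15):
        for v in varieties:
            sid += 1
            rows.append(
                {
                    "sample_id": f"S{sid:03d}",
                    "variety": v,
                    "location": f"set_{l + 1:02d}",
                    "line": f"line_{l // 5 + 1}",
                }
            )
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture
def simple_taxonomy():
    """Taxonomy for f00..f49: 10 genera in 3 orders, last 5 OTUs unassigned
    at genus."""
    rows = {}
    for j in range(50):
        genus = j % 10
        order = genus % 3
        lineage = [
            "Fungi",
            f"Phylum_{order + 1}",
            f"Class_{order + 1}",
            f"Order_{order + 1}",
            f"Family_{genus + 1}",
            f"Genus_{genus + 1:02d}" if j < 45 else "unidentified",
        ]
        rows[f"f{j:02d}"] = lineage
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)))


@pytest.fixture(scope="session")
def small_synthetic():
    """One small synthetic dataset for pipeline-level tests."""
    config = SyntheticConfig(n_taxa=40, seed=11)
    return generate_dataset(config)
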