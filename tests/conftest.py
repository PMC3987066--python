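import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from replivar import GeneExpressionTable

settings.register_profile(
    "default",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_table(values_by_column: dict, gene_ids=None, samples=None) -> GeneExpressionTable:
    """Build a table from {(sample, replicate): values}."""
    first = next(iter(values_by_column.values()))
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(len(first))]
    df = pd.DataFrame(
        {k: np.asarray(v, float) for k, v in values_by_column.items()},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["sample", "replicate"])
    return GeneExpressionTable(df, samples or {})


@pytest.fixture
def two_sample_table():
    """3 genes x 2 samples x 2 replicates, all passing a 0.5 floor."""
    return make_table({
        ("A", "R1"): [3.0, 7.3, 1.0],
        ("A", "R2"): [1.0, 7.3, 3.0],
        ("B", "R1"): [2.0, 4.0, 8.0],
        ("B", "R2"): [2.0, 4.0, 8.0],
    })


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Deterministic on-disk bundle shared by the pipeline tests."""
    from replivar import make_fixture_bundle

    out = tmp_path_factory.mktemp("bundle")
    manifest = make_fixture_bundle(out, seed=7)
    return out, manifest
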