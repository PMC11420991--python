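import numpy as np
import pytest

from myconet.io import CountTable, SampleMetadata, SampleRecord, TaxonomyTable, ENV_VARS
from myconet.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture
def small_table() -> CountTable:
    counts = np.array(
        [
            [5, 0, 3, 2],
            [1, 4, 0, 5],
            [2, 2, 2, 2],
        ]
    )
    return CountTable(["s1", "s2", "s3"], ["o1", "o2", "o3", "o4"], counts)


@pytest.fixture
def small_taxonomy() -> TaxonomyTable:
    return TaxonomyTable(
        {
            "o1": {"kingdom": "Fungi", "phylum": "Ascomycota", "genus": "Fusarium"},
            "o2": {"kingdom": "Fungi", "phylum": "Glomeromycota", "genus": "Glomus"},
            "o3": {"kingdom": "Fungi", "phylum": "Basidiomycota"},
            "o4": {"kingdom": "Fungi", "phylum": ""},
        }
    )


@pytest.fixture
def small_metadata(small_table) -> SampleMetadata:
    records = {}
    for i, sid in enumerate(small_table.sample_ids):
        env = {v: float(10 + i) for v in ENV_VARS}
        records[sid] = SampleRecord(sid, "DG", "Apr", i + 1, env)
    return SampleMetadata(records)


@pytest.fixture(scope="session")
def default_dataset():
    """The 54-sample study-design dataset at seed 1 (generated once)."""
    return generate_dataset(SyntheticSpec(seed=1))
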