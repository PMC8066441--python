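import numpy as np
import pandas as pd
import pytest

from ecoassembly.tables_io import CountTable, SampleFrame


@pytest.fixture
def small_table() -> CountTable:
    df = pd.DataFrame(
        [[5, 0, 3, 1], [2, 2, 2, 2], [0, 7, 1, 0]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3", "t4"],
    )
    return CountTable(df)


@pytest.fixture
def random_table() -> CountTable:
    rng = np.random.default_rng(42)
    df = pd.DataFrame(
        rng.integers(0, 50, size=(6, 12)),
        index=[f"s{i}" for i in range(6)],
        columns=[f"t{j}" for j in range(12)],
    )
    return CountTable(df)


@pytest.fixture
def lineage_table() -> CountTable:
    df = pd.DataFrame(
        [[10, 5, 1, 4], [0, 3, 2, 1]],
        index=["s1", "s2"],
        columns=["t1", "t2", "t3", "t4"],
    )
    lin = pd.Series(
        {
            "t1": "Bacteria;Proteobacteria;Gamma",
            "t2": "Bacteria;Bacteroidota;Bact",
            "t3": "Archaea;Euryarchaeota;Methano",
            # t4 deliberately unannotated
        }
    )
    return CountTable(df, lineages=lin)


@pytest.fixture
def meta_frame() -> SampleFrame:
    df = pd.DataFrame(
        {
            "group": ["river", "river", "lake"],
            "lat": [42.0, 42.1, 42.2],
            "lon": [86.0, 86.0, 86.1],
            "TDS": [0.5, 0.6, 1.2],
            "WT": [14.0, 15.0, 18.0],
        },
        index=["s1", "s2", "s3"],
    )
    return SampleFrame(df)
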