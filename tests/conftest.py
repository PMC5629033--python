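import pandas as pd
import pytest

from protpipe import (
    ProteinRecord,
    SpectralCountTable,
    TMTExperiment,
)


@pytest.fixture
def small_counts() -> SpectralCountTable:
    return SpectralCountTable.from_records(
        [
            ("P0001", 10, 0, 2),
            ("P0002", 40, 10, 3),
            ("P0003", 9, 0, 2),
        ]
    )


@pytest.fixture
def small_meta() -> list[ProteinRecord]:
    return [
        ProteinRecord("P0001", "GeneA", 500, "nuclear", 10.0),
        ProteinRecord("P0002", "GeneB", 200, "unknown", 100.0),
        ProteinRecord("P0003", "GeneC", 300, "other", None),
    ]


@pytest.fixture
def tiny_tmt() -> TMTExperiment:
    mat = pd.DataFrame(
        {
            "c1": [100.0, 200.0, 50.0, 10.0],
            "c2": [110.0, 190.0, 55.0, 9.0],
            "m1": [150.0, 100.0, 50.0, 20.0],
            "m2": [140.0, 110.0, 52.0, 19.0],
        },
        index=pd.Index(["P0001", "P0002", "P0003", "P0004"], name="accession"),
    )
    return TMTExperiment(
        mat,
        {
            "c1": ("control", 1),
            "c2": ("control", 2),
            "m1": ("mutant", 1),
            "m2": ("mutant", 2),
        },
    )
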