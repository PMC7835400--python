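import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # printed_tables

from germcore import (
    PhenotypeTable,
    SimulationConfig,
    TraitSchema,
    TraitSpec,
    generate_germplasm,
)


@pytest.fixture
def mixed_schema() -> TraitSchema:
    return TraitSchema(
        (
            TraitSpec("height", "quantitative", units="cm"),
            TraitSpec("color", "qualitative", levels=("green", "purple")),
        )
    )


@pytest.fixture
def small_table(mixed_schema) -> PhenotypeTable:
    frame = pd.DataFrame(
        {
            "height": [10.0, 12.5, np.nan],
            "color": ["green", None, "purple"],
        },
        index=pd.Index(["a1", "a2", "a3"], name="accession"),
    )
    return PhenotypeTable(frame, mixed_schema)


def make_clustered_table(
    seed: int,
    n: int = 90,
    n_quant: int = 3,
    n_qual: int = 2,
    k: int = 3,
    separation: float = 5.0,
    missing_rate: float = 0.0,
):
    cfg = SimulationConfig(
        n_accessions=n,
        n_quant=n_quant,
        n_qual=n_qual,
        n_clusters=k,
        cluster_separation=separation,
        missing_rate=missing_rate,
        n_redundant_pairs=0,
        seed=seed,
    )
    return generate_germplasm(cfg)


@pytest.fixture
def clustered_table():
    return make_clustered_table(seed=7)
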