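import logging

import numpy as np
import pandas as pd
import pytest

from microtriad.pipeline import run_pipeline
from microtriad.preprocess import PipelineConfig
from microtriad.simulate import generate_cohort, standard_fixture_spec
from microtriad.tables import AbundanceTable, MetadataTable

logging.getLogger("microtriad").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def standard_cohort():
    """Synthetic 57-sample cohort with one planted fatigue motif (|rho|=0.5)."""
    spec = standard_fixture_spec()
    taxa, modules, meta, truth = generate_cohort(spec)
    return {"spec": spec, "taxa": taxa, "modules": modules, "meta": meta, "truth": truth}


@pytest.fixture(scope="session")
def fixture_config():
    # the QC cut is expressed against the emulated 59-genus prevalent tables
    return PipelineConfig(qc_min_features=15, seed=1)


@pytest.fixture(scope="session")
def standard_run(standard_cohort, fixture_config):
    """The full pipeline result on the standard cohort."""
    return run_pipeline(
        fixture_config,
        standard_cohort["taxa"],
        standard_cohort["modules"],
        standard_cohort["meta"],
    )


@pytest.fixture
def tiny_counts():
    """A 5-sample x 4-feature count table with a hand-checkable zero pattern."""
    data = pd.DataFrame(
        {
            "f1": [10.0, 5.0, 8.0, 2.0, 1.0],   # present in 5 samples
            "f2": [0.0, 3.0, 0.0, 1.0, 0.0],    # present in 2
            "f3": [4.0, 0.0, 0.0, 0.0, 0.0],    # present in 1
            "f4": [1.0, 1.0, 1.0, 1.0, 0.0],    # present in 4
        },
        index=[f"s{i}" for i in range(1, 6)],
    )
    return AbundanceTable(data, modality="taxon", unit="count")


@pytest.fixture
def small_metadata():
    """Six samples, complete covariates, hand-checkable."""
    rng = np.random.default_rng(42)
    n = 6
    frame = pd.DataFrame(
        {
            "age": [30, 45, 50, 28, 60, 39],
            "sex": [0, 1, 1, 0, 1, 0],
            "diagnosis": ["CD", "UC", "CD", "CD", "UC", "CD"],
            "crp": [5.0, 20.0, 1.0, 8.0, 30.0, 2.0],
            "fcal": [100.0, np.nan, 250.0, 90.0, 400.0, 120.0],
            "steroid": [0, 1, 0, 0, 1, 0],
            "mesalamine": [1, 0, 0, 1, 0, 0],
            "immunosuppressant": [0, 0, 1, 0, 0, 0],
            "contraceptive": [0, 1, 0, 0, 0, 0],
            "antidepressant": [0, 0, 0, 0, 1, 0],
            "ppi": [1, 0, 0, 0, 0, 1],
            "hads_d": [4, 12, 7, 2, 15, 9],
            "weimus": [20, 45, 33, 10, 60, 27],
        },
        index=pd.Index([f"s{i}" for i in range(1, 7)], name="sample"),
    )
    return MetadataTable(frame)
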