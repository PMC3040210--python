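import numpy as np
import pandas as pd
import pytest

from equiscreen import PeakTable, SimulationConfig, StudyDesign, generate_study


@pytest.fixture(scope="session")
def small_config():
    """A reduced study: 1 transgenic, 3 reference cultivars, 120 peaks."""
    return SimulationConfig(
        n_transgenic=1, n_reference=3, n_stages=2, n_replicates=6,
        peaks_per_platform={"GC-MS": 50, "LC-MS": 40, "CE-MS": 30},
        n_shared_metabolites=12, n_gm_peaks=8, seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture
def tiny_table():
    """4 samples x 3 peaks, strictly positive, one missing cell."""
    data = pd.DataFrame(
        {"p1": [10.0, 20.0, 15.0, 12.0],
         "p2": [100.0, np.nan, 120.0, 90.0],
         "p3": [1.0, 2.0, 4.0, 8.0]},
        index=["s1", "s2", "s3", "s4"],
    )
    return PeakTable(data, platform="GC-MS")


def make_design(genotype_roles, stages=("g",), treatments=("t",), replicates=2,
                seed=0):
    """Build a StudyDesign from {genotype: role} with full crossing."""
    rng = np.random.default_rng(seed)
    rows = []
    for geno, role in genotype_roles.items():
        for stage in stages:
            for trt in treatments:
                for rep in range(1, replicates + 1):
                    rows.append({"sample_id": f"{geno}_{stage}_{trt}_{rep}",
                                 "genotype": geno, "role": role, "stage": stage,
                                 "treatment": trt, "replicate": rep})
    df = pd.DataFrame(rows).set_index("sample_id")
    df["harvest_order"] = rng.permutation(len(df)) + 1
    return StudyDesign(df)
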