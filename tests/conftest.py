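import pandas as pd
import pytest

from gvprotcomm.simulate import (
    SimulationConfig,
    simulate_annotation_bundle,
    simulate_psm_tables,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_proteins=60, frac_shared=0.4, frac_differential=0.5, seed=7)


@pytest.fixture(scope="session")
def small_sim(small_config):
    """(tables, truth) for a small seeded run shared across tests."""
    return simulate_psm_tables(small_config)


@pytest.fixture(scope="session")
def small_bundle(small_config, small_sim):
    _, truth = small_sim
    return simulate_annotation_bundle(small_config, truth)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, small_config):
    """Full synthetic input directory written to disk once."""
    from gvprotcomm.simulate import write_simulation

    outdir = tmp_path_factory.mktemp("bundle")
    write_simulation(small_config, outdir)
    return outdir


def make_psm_frame(rows):
    """Build a PSM DataFrame from (sample, rep, frac, pep, z, xcorr, dcn, rsp, acc, decoy)."""
    from gvprotcomm.io import PSM_COLUMNS

    return pd.DataFrame(rows, columns=list(PSM_COLUMNS)).astype(
        {"replicate": "int64", "fraction": "int64", "charge": "int64",
         "xcorr": "float64", "deltacn": "float64", "rsp": "int64", "is_decoy": "bool"}
    )
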