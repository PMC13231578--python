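import numpy as np
import pandas as pd
import pytest

from pd1rev import simdata


@pytest.fixture(scope="session")
def design_one_group():
    return simdata.make_design(3, groups=("NI",))


@pytest.fixture(scope="session")
def design_two_groups():
    return simdata.make_design(3, groups=("NI", "RA"))


@pytest.fixture(scope="session")
def null_truth(design_one_group):
    return simdata.make_truth(
        design_one_group, n_genes=600, seed=11, frac_tnf_de=0.0,
        n_responsive=0, sigma_donor=0.0, mean_library_size=5e5,
    )


@pytest.fixture(scope="session")
def signal_truth(design_two_groups):
    return simdata.make_truth(
        design_two_groups, n_genes=1000, seed=7, frac_tnf_de=0.15,
        n_responsive=60, spd1_lfc=1.5, mean_library_size=5e5,
    )


@pytest.fixture(scope="session")
def signal_counts(signal_truth, design_two_groups):
    return simdata.simulate_bulk_counts(signal_truth, design_two_groups)


@pytest.fixture()
def toy_counts():
    rng = np.random.default_rng(0)
    counts = rng.poisson(50, (200, 6))
    return pd.DataFrame(
        counts,
        index=[f"G{i:03d}" for i in range(200)],
        columns=[f"S{j}" for j in range(6)],
    )
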