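import numpy as np
import pytest

from genaccount import (
    MacroParams,
    SyntheticConfig,
    calibrate,
    generate_profiles,
    sum_taxes,
    sum_transfers,
)
from genaccount.synthetic import DEFAULT_TARGET_PV_TAXES, DEFAULT_TARGET_PV_TRANSFERS


@pytest.fixture(scope="session")
def base_params():
    return MacroParams()


@pytest.fixture(scope="session")
def default_profiles(base_params):
    """Shipped default synthetic profiles, calibrated to the lifetime totals."""
    transfers, taxes = generate_profiles(SyntheticConfig(seed=1))
    transfers, taxes, report = calibrate(
        transfers,
        taxes,
        DEFAULT_TARGET_PV_TAXES,
        DEFAULT_TARGET_PV_TRANSFERS,
        base_params,
    )
    return transfers, taxes, report


@pytest.fixture(scope="session")
def default_flows(default_profiles):
    transfers, taxes, _ = default_profiles
    return sum_taxes(taxes), sum_transfers(transfers)


@pytest.fixture()
def rng():
    return np.random.default_rng(20060101)
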