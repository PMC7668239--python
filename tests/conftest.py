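import pandas as pd
import pytest

from pbroutes import datasets, franz


@pytest.fixture(scope="session")
def study_doses() -> pd.DataFrame:
    return datasets.load_skin_doses()


@pytest.fixture(scope="session")
def study_workers() -> pd.DataFrame:
    return datasets.load_workers()


@pytest.fixture(scope="session")
def franz_balance() -> pd.DataFrame:
    return franz.balance_from_means(datasets.load_franz_amounts())


@pytest.fixture(scope="session")
def study_hand_sums(study_doses):
    from pbroutes.wipes import hand_sums

    return hand_sums(study_doses)
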