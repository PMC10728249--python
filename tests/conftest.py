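import pandas as pd
import pytest

from patterntiming.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset() -> pd.DataFrame:
    """Three simulated participants at the default truth, full 264-trial sessions."""
    table, _ = simulate_dataset(SimulationConfig(master_seed=42, n_participants=3))
    return table


@pytest.fixture(scope="session")
def one_participant(small_dataset) -> pd.DataFrame:
    return small_dataset.loc[small_dataset["participant_id"] == "P01"].copy()
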