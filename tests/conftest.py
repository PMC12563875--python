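import numpy as np
import pandas as pd
import pytest

from p300sttc.containers import TARGET, EpochSet
from p300sttc.preprocess import preprocess_cohort
from p300sttc.simulate import ParadigmConfig, SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cfg():
    """2+2 subjects, 5 trials per subject — fast end-to-end fixture."""
    return SimulationConfig(
        n_subjects_per_group=2,
        paradigm=ParadigmConfig(runs=1, blocks_per_run=1, trials_per_block=5),
        seed=99,
    )


@pytest.fixture(scope="session")
def tiny_epochs(tiny_cfg):
    """Preprocessed target epochs for the tiny cohort (session-cached)."""
    return preprocess_cohort(simulate_cohort(tiny_cfg), codes={TARGET})


@pytest.fixture(scope="session")
def noiseless_cfg():
    return SimulationConfig(n_subjects_per_group=1).noiseless()


def make_epochs(data, sfreq=250.0, t0=-100.0, channels=None, subject_ids=None,
                groups=None, code=TARGET):
    """Construct an EpochSet directly from an array (test helper)."""
    data = np.asarray(data, dtype=float)
    n, c, t = data.shape
    channels = channels or [f"ch{i}" for i in range(c)]
    t_axis = t0 + np.arange(t) * 1000.0 / sfreq
    meta = pd.DataFrame({
        "subject_id": subject_ids if subject_ids is not None else [f"s{i}" for i in range(n)],
        "group": groups if groups is not None else ["HC"] * n,
        "stimulus_code": [code] * n,
        "trial_index": np.arange(n),
    })
    return EpochSet(data=data, channels=channels, sfreq=sfreq, t_axis=t_axis, meta=meta)
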