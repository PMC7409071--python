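import numpy as np
import pandas as pd
import pytest

from circarest import synthio

START = pd.Timestamp("2024-03-04 12:00:00")


@pytest.fixture(scope="session")
def robust_record():
    prof = synthio.default_profile("rob0", "patient", "robust", seed=20240304)
    return synthio.generate_subject(prof, 7)


@pytest.fixture(scope="session")
def disrupted_record():
    prof = synthio.default_profile("dis0", "patient", "disrupted", seed=20240305)
    return synthio.generate_subject(prof, 7)


@pytest.fixture(scope="session")
def robust_subject_dir(robust_record, tmp_path_factory):
    d = tmp_path_factory.mktemp("subjects") / "rob0"
    synthio.write_subject_dir(robust_record, d)
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
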