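import numpy as np
import pytest

from aesignal import ArmSummary


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_summary(n=100, mean=0.0, sd=1.0, skewness=0.0) -> ArmSummary:
    return ArmSummary(n=n, mean=mean, sd=sd, skewness=skewness)


@pytest.fixture
def small_trial_csv(tmp_path):
    """4-row lab file: 2 subjects x 2 outcomes, 1 visit."""
    path = tmp_path / "labs.csv"
    path.write_text(
        "subject_id,arm,visit_week,outcome,value,site\n"
        "S1,treatment,24,potassium,4.1,A\n"
        "S1,treatment,24,sodium,140,A\n"
        "S2,control,24,potassium,3.9,B\n"
        "S2,control,24,sodium,138,B\n"
    )
    return path
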