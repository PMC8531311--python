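import numpy as np
import pytest

from riskrl.models import ParameterVector, get_model
from riskrl.simulate import simulate_subject
from riskrl.task import GAIN, LOSS, build_schedule


@pytest.fixture(scope="session")
def hybrid():
    return get_model("hybrid")


@pytest.fixture(scope="session")
def hybrid_params(hybrid):
    return ParameterVector.from_natural(
        hybrid, dict(alpha_p=0.4, alpha_n=0.3, beta=3.0, kappa=0.8)
    )


@pytest.fixture(scope="session")
def schedules():
    return (build_schedule(GAIN, 11), build_schedule(LOSS, 12))


@pytest.fixture(scope="session")
def hybrid_dataset(hybrid, hybrid_params, schedules):
    return simulate_subject(hybrid_params, hybrid, schedules, seed=99)


def simulate_many(model, params, n, seed0=0, block="gain-first"):
    """Simulate n agents with fresh schedules; returns list of datasets."""
    out = []
    for i in range(n):
        sch = (
            build_schedule(GAIN, seed0 + 2 * i),
            build_schedule(LOSS, seed0 + 2 * i + 1),
        )
        out.append(
            simulate_subject(
                params, model, sch, block, seed=seed0 + 10_000 + i,
                subject_id=f"a{i:03d}",
            )
        )
    return out
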