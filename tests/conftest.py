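import pytest
from hypothesis import settings

from gradpump import build_program, paper_tp_spec, paper_ts_spec

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

SAMPLING_MINUTES = (1, 2, 4, 6, 8, 10, 15, 20, 25, 30, 35, 40, 45, 50)


@pytest.fixture(scope="session")
def tp_spec():
    """Time-Point worked configuration (0→0.4 M/50 min, 14×1 mL samples)."""
    return paper_tp_spec()


@pytest.fixture(scope="session")
def ts_spec():
    """Time-Series worked configuration (Pump 2 at 0.1 mL/min, 40 phases)."""
    return paper_ts_spec()


@pytest.fixture(scope="session")
def tp_disc(tp_spec):
    return tp_spec.profile.discretized(tp_spec.experiment)


@pytest.fixture(scope="session")
def ts_disc(ts_spec):
    return ts_spec.profile.discretized(ts_spec.experiment)


@pytest.fixture(scope="session")
def tp_program(tp_spec, tp_disc):
    return build_program(tp_spec.experiment, tp_disc)


@pytest.fixture(scope="session")
def ts_program(ts_spec, ts_disc):
    return build_program(ts_spec.experiment, ts_disc)
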