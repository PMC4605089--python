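from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from htltea import datasets

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def feed():
    """The bundled yeast feedstock composition."""
    return datasets.yeast_feedstock()


@pytest.fixture()
def reference_records():
    """Fresh copies of the four bundled reference runs."""
    return datasets.reference_experiments()
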