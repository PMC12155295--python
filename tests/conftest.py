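import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from phylostage import AgeMap, StagedExpression

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_ages() -> AgeMap:
    return AgeMap({"g1": 1, "g2": 3, "g3": 6, "g4": 14})


@pytest.fixture
def small_expression() -> StagedExpression:
    """4 genes x 6 samples, one sample per tumor stage plus two NAT."""
    values = pd.DataFrame(
        np.array(
            [
                [5.0, 1.0, 2.0, 4.0, 3.0, 3.0],
                [1.0, 4.0, 3.0, 1.0, 2.0, 2.0],
                [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
                [3.0, 0.0, 1.0, 5.0, 1.0, 1.0],
            ]
        ),
        index=["g1", "g2", "g3", "g4"],
        columns=["s1", "s2", "s3", "s4", "n1", "n2"],
    )
    stages = pd.Series(
        {"s1": "I", "s2": "II", "s3": "III", "s4": "IV", "n1": "NAT", "n2": "NAT"}
    )
    return StagedExpression(values, stages)
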