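import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spdq import COURSE_PATTERNS, SENSORY_ITEMS, QuestionnaireRecord

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_complete_records(rng: np.random.Generator, n: int) -> list[QuestionnaireRecord]:
    """Uniformly random complete records (all nine scored items present)."""
    grades = rng.integers(0, 6, size=(n, len(SENSORY_ITEMS)))
    courses = rng.integers(0, 4, size=n)
    radiating = rng.integers(0, 2, size=n).astype(bool)
    return [
        QuestionnaireRecord(
            **{item: int(grades[i, j]) for j, item in enumerate(SENSORY_ITEMS)},
            course_pattern=COURSE_PATTERNS[courses[i]],
            radiating=bool(radiating[i]),
        )
        for i in range(n)
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
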