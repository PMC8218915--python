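import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_labelled_matrix():
    """3 genes x 4 samples where only gene B separates the classes."""
    from frl import ExpressionMatrix

    values = np.array([
        [5.0, 5.1, 4.9, 5.0],   # A: flat
        [2.0, 2.1, 8.0, 8.2],   # B: clean class split
        [3.0, 7.0, 3.1, 7.1],   # C: varies within both classes
    ])
    return ExpressionMatrix(["A", "B", "C"], ["s1", "s2", "s3", "s4"],
                            values, labels=np.array([0, 0, 1, 1]),
                            scale="log2")
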