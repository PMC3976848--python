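import pytest

from overcover import DetectionParams, karate_fixture, run_pipeline


@pytest.fixture(scope="session")
def karate():
    return karate_fixture()


@pytest.fixture(scope="session")
def karate_result(karate):
    """Full pipeline run with the documented root sequence ("1", "15").

    Session-scoped: tests must not mutate the result's cover (use
    ``result.cover.copy()`` when a mutable cover is needed).
    """
    return run_pipeline(karate, DetectionParams(seed=1), roots=["1", "15"])
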