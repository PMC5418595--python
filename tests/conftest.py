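import pytest

from combilib import build_reference_db, demo_decoys, demo_design

# Test-scale geometry: region lengths are 0.15x the full-size demo design so
# the O(n*m) oracle aligner stays fast; the classification rules under test
# are scale-free.  MIN_SCORE sits well above the random local-alignment noise
# floor (~19 for this scoring) and well below genuine full-region scores.
TEST_SCALE = 0.15
TEST_MIN_SCORE = 25


@pytest.fixture(scope="session")
def min_score():
    return TEST_MIN_SCORE


@pytest.fixture(scope="session")
def design():
    return demo_design(seed=7, scale=TEST_SCALE)


@pytest.fixture(scope="session")
def decoys():
    return demo_decoys(seed=11, scale=TEST_SCALE)


@pytest.fixture(scope="session")
def reference_db(design, decoys):
    return build_reference_db(design, decoys)


@pytest.fixture(scope="session")
def full_scale_design():
    return demo_design(seed=7, scale=1.0)
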