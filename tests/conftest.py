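import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import insulreg as ir
from insulreg.simulate import GenerativeSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_matrix():
    """Default synthetic chromosome: 200 bins, 8 borders + 2 facilitators."""
    spec = ir.default_fixture_spec(seed=3)
    m, truth = ir.generate_matrix(spec)
    return m, truth


@pytest.fixture(scope="session")
def fixture_fit(fixture_matrix):
    m, truth = fixture_matrix
    return ir.run_sim(m, seed=1789), truth


@pytest.fixture()
def small_matrix():
    """Tiny random symmetric matrix with decaying means, no planted effects."""
    spec = GenerativeSpec(p=20, resolution=10_000, effects={}, seed=5, depth_gap1=50)
    m, _ = ir.generate_matrix(spec)
    return m


def recovery_score(fit, truth_effects):
    """(#borders hit +-1 bin, #facilitators hit, #false positives)."""
    selb = set(np.flatnonzero(fit.beta < 0).tolist())
    self_ = set(np.flatnonzero(fit.beta > 0).tolist())
    tb = {k for k, v in truth_effects.items() if v < 0}
    tf = {k for k, v in truth_effects.items() if v > 0}
    hit_b = sum(1 for k in tb if selb & {k - 1, k, k + 1})
    hit_f = sum(1 for k in tf if self_ & {k - 1, k, k + 1})
    near = set()
    for k in truth_effects:
        near |= {k - 1, k, k + 1}
    fp = sum(1 for s in selb | self_ if s not in near)
    return hit_b, hit_f, fp
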