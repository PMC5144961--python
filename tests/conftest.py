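import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hemivar as hv

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_params():
    """Default (study-condition) lifespan variance parameters."""
    return hv.default_lifespan_params()


@pytest.fixture(scope="session")
def small_design():
    """Desk-scale design: fewer lines and flies, full factorial structure."""
    return hv.DesignConfig(n_lines_per_type=12, n_flies_per_vial=10)


@pytest.fixture(scope="session")
def small_records(small_design, study_params):
    return hv.simulate_lifespans(small_design, study_params, seed=101)


@pytest.fixture(scope="session")
def a_full_records(study_params):
    """Full-design A-line data at study-condition parameters."""
    design = hv.DesignConfig(chromosome_types=("A",))
    return hv.simulate_lifespans(design, {"A": study_params["A"]}, seed=103)


@pytest.fixture(scope="session")
def quick_chain(small_records):
    """A short lifespan chain on the small A-line dataset."""
    from hemivar.mixed_model import ChainConfig, ModelSpec, PriorSpec, run_gibbs
    sub = small_records[small_records.chromosome_type == "A"]
    cfg = ChainConfig(iterations=4000, burn_in=1000, thin=5, seed=7)
    return run_gibbs(ModelSpec(), PriorSpec(), cfg, sub)


@pytest.fixture(scope="session")
def quick_chain_x(small_records):
    from hemivar.mixed_model import ChainConfig, ModelSpec, PriorSpec, run_gibbs
    sub = small_records[small_records.chromosome_type == "X"]
    cfg = ChainConfig(iterations=4000, burn_in=1000, thin=5, seed=8)
    return run_gibbs(ModelSpec(), PriorSpec(), cfg, sub)
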