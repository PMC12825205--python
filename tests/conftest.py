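"""Shared fixtures.

Heavy artifacts (networks, observation tables, the reduced-budget recovery
fits) are session-scoped so that unit tests and the acceptance tests share
one computation.
"""

import numpy as np
import pytest
from hypothesis import settings

import prljag as pj

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from prljag.fitting import ObservationSet, default_stage_specs, two_stage_fit
from prljag.network import load_default_initials, load_default_parameters
from prljag.synth import SyntheticDesign, generate_observations

VARIED_INITIALS = ("RJ", "PPX", "S3c", "S3n")


def make_anchor():
    """Initial-guess anchor vector: kinetic constants plus the four varied
    initial conditions."""
    ic = load_default_initials()
    anchor = dict(load_default_parameters())
    anchor |= {k: ic[k] for k in VARIED_INITIALS}
    return anchor


@pytest.fixture(scope="session")
def net():
    return pj.build_network()


@pytest.fixture(scope="session")
def anchor():
    return make_anchor()


@pytest.fixture(scope="session")
def fitted():
    return pj.load_fitted_parameters()


@pytest.fixture(scope="session")
def phenom_obs():
    """Default phenomenological Data-S1-shaped observations."""
    frame = generate_observations(SyntheticDesign(seed=0))
    return ObservationSet.from_frame(frame)


@pytest.fixture(scope="session")
def noiseless_model_obs(net):
    """Model-based observations generated noiselessly from the default
    (ground-truth) parameters."""
    frame = generate_observations(
        SyntheticDesign(seed=0, noise_sd=0.0, mode="model-based"),
        network=net)
    return ObservationSet.from_frame(frame)


@pytest.fixture(scope="session")
def recovery_fit_noiseless(net, anchor, noiseless_model_obs):
    """Reduced-budget (500 + 1500) two-stage fit on noiseless synthetic
    observations whose ground truth is the anchor itself."""
    s1, s2 = default_stage_specs(anchor, seed=11, budget_scale=0.05)
    return two_stage_fit(noiseless_model_obs, net, s1, s2)


@pytest.fixture(scope="session")
def sensitivity_rows(net, fitted):
    from prljag.analysis import knockout_sensitivity
    return knockout_sensitivity(net, fitted)


@pytest.fixture(scope="session")
def ensembles(net, fitted):
    """Robustness ensembles at the four tolerance levels, n = 1000."""
    from prljag.analysis import robustness_ensemble
    return robustness_ensemble(net, fitted, n=1000, seed=17)


@pytest.fixture(scope="session")
def recovery_fit_noisy(net, anchor):
    """Reduced-budget fit on 5%-noise synthetic observations."""
    frame = generate_observations(
        SyntheticDesign(seed=3, noise_sd=0.05, mode="model-based"),
        network=net)
    obs = ObservationSet.from_frame(frame)
    s1, s2 = default_stage_specs(anchor, seed=12, budget_scale=0.05)
    return two_stage_fit(obs, net, s1, s2), obs
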