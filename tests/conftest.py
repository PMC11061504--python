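import numpy as np
import pytest

from hillmc import limb_model as lm
from hillmc import reference_gen as rg
from hillmc.hill_mtu import MTUParameters


@pytest.fixture
def baseline_params() -> MTUParameters:
    return MTUParameters(
        name="test_mtu", f_max=2500.0, l_opt=0.12, alpha_opt=0.15,
        v_max=1.2, k_tendon=35.0, l_tendon_slack=0.16, volume_fraction=0.2)


@pytest.fixture(scope="session")
def default_model() -> lm.LimbModel:
    return lm.build_default_model(seed=0)


@pytest.fixture(scope="session")
def scenario() -> dict:
    """Desk-scale recovery scenario shared across OCP/campaign tests."""
    return rg.recovery_scenario()


@pytest.fixture(scope="session")
def small_model(scenario) -> lm.LimbModel:
    return scenario["model"]


def make_single_mtu_model(params: MTUParameters, arm: float = 0.04,
                          l_tilde_start: float = 1.1) -> lm.LimbModel:
    """One knee-spanning MTU with a constant moment arm, for toy problems."""
    h = params.l_opt * np.sin(params.alpha_opt)
    l_fib = l_tilde_start * params.l_opt
    l_ref = params.l_tendon_slack + np.sqrt(max(l_fib**2 - h**2, 1e-12))
    kin = lm.MTUKinematicsPoly(constant=l_ref, coords={"knee": np.array([0.0, -arm])})
    mtu = lm.MTU(params=params, kinematics=kin, volume_cm3=100.0)
    model = lm.LimbModel(coordinates=["knee"], mtus=[mtu],
                         default_pose={"knee": 0.0})
    lm.classify_muscle_groups(model)
    return model
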