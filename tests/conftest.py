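import numpy as np
import pytest

import multicause as mc


@pytest.fixture(scope="session")
def theta_typical():
    return dict(mc.TYPICAL_THETA)


@pytest.fixture(scope="session")
def theta_const(theta_typical):
    th = dict(theta_typical)
    th["w_vest"] = 0.0
    th["w_vis"] = 0.0
    return th


@pytest.fixture(scope="session")
def grid_small():
    """Coarse grid for fast likelihood evaluations in unit tests."""
    return mc.GridSpec(n_x=101, n_s=101, gl_order=4)


@pytest.fixture(scope="session")
def grid_med():
    return mc.GridSpec(n_x=201, n_s=151)


@pytest.fixture(scope="session")
def unity_bay_spec():
    return mc.ModelSpec(explicit="Bay", noise="C", prior="I", tasks=("unity",))


@pytest.fixture(scope="session")
def unity_bay_theta(unity_bay_spec, theta_const):
    names = mc.build_parameter_space(unity_bay_spec).names
    return {k: theta_const[k] for k in names}


@pytest.fixture(scope="session")
def unity_bay_data(unity_bay_spec, unity_bay_theta):
    design = mc.DesignSpec(n_unisensory=0, n_unity=900, n_inertial=0, seed=11)
    return mc.simulate_observer(mc.generate_design(design), unity_bay_spec,
                                unity_bay_theta, seed=12)


@pytest.fixture(scope="session")
def probe_conditions():
    """Small deterministic probe set of bisensory conditions."""
    triples = [(-10.0, 10.0, "low"), (5.0, 15.0, "med"), (2.5, -2.5, "high")]
    return {
        task: [mc.StimulusCondition(task=task, s_vis=sv, s_vest=se, c_vis=c)
               for sv, se, c in triples]
        for task in ("unity", "inertial")
    }


def make_joint_theta(spec, base):
    names = mc.build_parameter_space(spec).names
    return {k: base[k] for k in names}


@pytest.fixture(scope="session")
def joint_theta_factory(theta_typical, theta_const):
    def factory(spec):
        base = theta_const if spec.noise == "C" else theta_typical
        return make_joint_theta(spec, base)
    return factory
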