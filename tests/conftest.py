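import numpy as np
import pytest

from posekin import synthetic


@pytest.fixture(scope="session")
def small_system():
    """3-state reference system at reduced size, with hidden ground truth."""
    spec = synthetic.default_system_spec(seed=11, n_traj=10, n_steps=2000)
    hidden = synthetic.simulate_hidden_chain(spec)
    trajs = synthetic.emit_features(hidden, spec)
    return spec, hidden, trajs


@pytest.fixture(scope="session")
def two_state_loop_ensemble():
    """Coordinate ensemble from two loop templates 12 A apart, 0.5 A jitter."""
    sspec = synthetic.default_structure_spec(n_states=2, loop_rmsd=12.0,
                                             jitter_sd=0.5, seed=3)
    hidden = [np.array([0] * 140 + [1] * 60)]
    ens = synthetic.emit_coordinates(hidden, sspec)
    return sspec, ens
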