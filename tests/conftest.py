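import numpy as np
import pytest

from spikeglm import GroundTruth, TrialSpec, WindowScheme, simulate_ensemble


@pytest.fixture(scope="session")
def scheme3():
    return WindowScheme.from_list([[1, 3], [4, 6], [7, 9]])


@pytest.fixture(scope="session")
def scheme2():
    return WindowScheme.from_list([[1, 2], [3, 4]])


def full_trial_spec(n_trials, **kw):
    """Trial spec whose single epoch spans the whole trial."""
    kw.setdefault("epoch_boundaries", {"all": (0.0, 3.0)})
    return TrialSpec(n_trials=n_trials, **kw)


@pytest.fixture(scope="session")
def coupled_pair_ensemble(scheme3):
    """Two cells with one planted excitatory coupling 0 -> 1 (first window)."""
    gt = GroundTruth(
        n_cells=2,
        cell_types=["RS", "RS"],
        baseline_log_rates=np.log([15.0, 15.0]),
        coupling={(1, 0, 0): 0.5},
        window_scheme=scheme3,
        seed=7,
    )
    ens = simulate_ensemble(gt, full_trial_spec(60))
    return gt, ens
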