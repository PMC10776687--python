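import numpy as np
import pytest

from occlusim import synthetic as sw


@pytest.fixture(scope="session")
def small_5ht_ensemble():
    """Short 5HT-profile ensemble shared by featurization tests."""
    profile = sw.default_profile("5HT")
    return profile, sw.make_ligand_ensemble(
        profile, n_replicas=3, n_steps=800, seed=42, dt=0.5, substeps=50)


@pytest.fixture(scope="session")
def three_state_chain():
    """A known 3-state chain and a long sampled trajectory."""
    T = np.array([[0.90, 0.08, 0.02],
                  [0.10, 0.85, 0.05],
                  [0.05, 0.10, 0.85]])
    traj = sw.simulate_discrete_chain(T, 100_000, seed=7)
    evals, evecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(evals - 1.0)))
    pi = np.real(evecs[:, i])
    pi = np.abs(pi) / np.abs(pi).sum()
    return T, pi, traj
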