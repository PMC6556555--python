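import numpy as np
import pytest

from dmriharm import sh
from dmriharm.io import DWIStack, GradientScheme


@pytest.fixture(scope="session")
def dirs30():
    return sh.hemisphere_directions(30, seed=1)


@pytest.fixture(scope="session")
def shell_scheme(dirs30):
    """One b=0 volume plus a 30-direction b=1200 shell."""
    bvals = np.r_[0.0, np.full(30, 1200.0)]
    bvecs = np.vstack([np.zeros(3), dirs30])
    return GradientScheme(bvals=bvals, bvecs=bvecs)


def make_stack(data, scheme, affine=None):
    return DWIStack(
        data=data, affine=np.eye(4) if affine is None else affine, scheme=scheme
    )


@pytest.fixture
def tensor_stack(shell_scheme):
    """Noise-free single-tensor stack factory on a small grid."""
    from dmriharm import dti

    def build(D6, shape=(3, 3, 3), s0=1000.0):
        A = dti.design_matrix(shell_scheme.bvals, shell_scheme.bvecs)
        signal = np.exp(A @ np.r_[np.log(s0), np.asarray(D6)])
        data = np.broadcast_to(signal, shape + (len(shell_scheme),)).copy()
        return make_stack(data, shell_scheme)

    return build


@pytest.fixture(scope="session")
def small_cohort():
    """Two-scanner cohort of 4 subjects, shared across slow tests."""
    from dmriharm import phantom

    return phantom.simulate_cohort(seed=11, n_subjects=4)
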