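import numpy as np
import pytest

from delics.forward_model import AcquisitionModel, CoilMaps
from delics.mrf_signal import SequenceParams, SubspaceBasis
from delics.sampling import Trajectory


def random_small_model(K=2, C=2, T=4, M=16, N=8, seed=1, engine="direct"):
    """A tiny acquisition model with a random orthonormal basis and random coils."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((T, K)) + 1j * rng.standard_normal((T, K)))
    basis = SubspaceBasis(phi=q, singular_values=np.ones(min(T, K)))
    coords = rng.uniform(-N / 2, N / 2 * 0.98, (T, M, 3))
    traj = Trajectory(coords=coords, group_index=np.zeros(T, dtype=int), n_groups=1, matrix_size=N)
    maps = rng.standard_normal((C, N, N, N)) + 1j * rng.standard_normal((C, N, N, N))
    return AcquisitionModel(basis=basis, coil_maps=CoilMaps(maps=maps), traj=traj, engine=engine)


@pytest.fixture
def small_model():
    return random_small_model()


@pytest.fixture(scope="session")
def desk_setup():
    """Shared desk-scale sequence/dictionary/basis (reduced grids, rank 3)."""
    from delics.experiments import desk_dictionary_basis

    seq, dictionary, basis = desk_dictionary_basis(n_tr=240, K=3)
    return seq, dictionary, basis
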