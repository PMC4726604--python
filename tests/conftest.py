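import numpy as np
import pytest

from dtiprog.synthetic import PhantomSpec, TissueDistribution


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_phantom_spec():
    """Desk-scale phantom lattice for fast voxel-level tests."""
    return PhantomSpec(shape=(32, 32, 32))


@pytest.fixture
def static_phantom_spec():
    """Phantom with all drifts zeroed (no progression)."""
    tissues = {
        name: TissueDistribution(d.fa_loc, d.fa_scale, d.md_loc, d.md_scale)
        for name, d in PhantomSpec().tissues.items()
    }
    return PhantomSpec(shape=(32, 32, 32), tissues=tissues)


def random_psd_tensors(rng, n, scale=1e-3):
    """Random positive semi-definite 3x3 tensors, (n, 3, 3)."""
    A = rng.normal(0.0, scale, (n, 3, 3))
    return A @ np.transpose(A, (0, 2, 1))


def random_rotations(rng, n):
    """Random proper rotation matrices via QR of Gaussian matrices."""
    A = rng.standard_normal((n, 3, 3))
    Q, R = np.linalg.qr(A)
    sign = np.sign(np.einsum("nii->ni", R))
    Q = Q * sign[:, None, :]
    det = np.linalg.det(Q)
    Q[det < 0, :, 0] *= -1
    return Q
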