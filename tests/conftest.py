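import numpy as np
import pytest

import gliomodel as g


@pytest.fixture(scope="session")
def iso_field():
    return g.make_synthetic_dti("isotropic", shape=(16, 16), spacing=1.0)


@pytest.fixture(scope="session")
def bundle_field():
    return g.make_synthetic_dti(
        "single_bundle", shape=(16, 16), spacing=1.0, anisotropy_ratio=9.0
    )


@pytest.fixture(scope="session")
def diag41_field():
    t = np.zeros((12, 12, 3, 3))
    t[..., 0, 0] = 4.0
    t[..., 1, 1] = 1.0
    t[..., 2, 2] = 1.0
    return g.DiffusionTensorField(
        origin=np.zeros(2),
        spacing=np.ones(2),
        tensors=t,
        mask=np.ones((12, 12), bool),
    )


@pytest.fixture(scope="session")
def base_params():
    return g.ModelParams()


@pytest.fixture(scope="session")
def small_scenario():
    """A coarse brain-slice-like scenario for quick macroscopic runs."""
    field = g.make_brain_slice_field(shape=(48, 48), spacing=1.0, seed=0)
    env = g.environment_from_field(field)
    return field, env


def constant_coeffs(
    shape, dx, d=1.0, drift=None, mu0=0.0, K_M=1.0, A=1.0, origin=(0.0, 0.0)
):
    """Hand-built constant-coefficient macroscopic setup for solver tests."""
    ny, nx = shape
    D = np.zeros((ny, nx, 2, 2))
    if np.ndim(d) == 0:
        D[..., 0, 0] = D[..., 1, 1] = d
    else:
        D[:] = np.asarray(d)
    dr = np.zeros((ny, nx, 2))
    if drift is not None:
        dr[:] = np.asarray(drift)
    return g.MacroCoefficients(
        D_eff=D,
        drift=dr,
        A=np.full((ny, nx), A),
        mask=np.ones((ny, nx), bool),
        spacing=(dx, dx),
        origin=origin,
        mu0=mu0,
        K_M=K_M,
    )
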