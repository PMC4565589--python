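import numpy as np
import pytest

from fdgen.builtin_models import (
    diffusion_model,
    diffusion_relation,
    fhn_model,
    fhn_relation,
    membrane_model,
    membrane_relation,
)
from fdgen.schemes import builtin_scheme


@pytest.fixture(scope="session")
def membrane():
    return membrane_model()


@pytest.fixture(scope="session")
def ftcs1():
    return builtin_scheme("FTCS", 1)


@pytest.fixture(scope="session")
def btcs1():
    return builtin_scheme("BTCS", 1)


@pytest.fixture(scope="session")
def cn1():
    return builtin_scheme("CN", 1)


@pytest.fixture(scope="session")
def ftcs2():
    return builtin_scheme("FTCS", 2)


def reference_fhn_ftcs(side, steps, dt=0.001, D=200.0, dx=1.0, clamp=-1.0):
    """Independent hand-written FTCS simulator for the FHN model on a padded
    square mesh with zero-flux (ghost-copy) boundaries and a centre V clamp.

    Written directly against the update formulas with vectorized numpy — it
    shares no code with the generator and serves as the oracle for generated
    programs.
    """
    from fdgen.builtin_models import FHN_BETA, FHN_EPS, FHN_GAMMA, fhn_rest_state

    v0, w0 = fhn_rest_state()
    N = side + 2
    V = np.full((N, N), v0)
    W = np.full((N, N), w0)
    c = 1 + side // 2
    V[c, c] = clamp
    inner = slice(1, N - 1)
    for _ in range(steps):
        # Neumann ghost copies at level n (one-sided zero flux)
        V[0, inner] = V[1, inner]
        V[N - 1, inner] = V[N - 2, inner]
        V[inner, 0] = V[inner, 1]
        V[inner, N - 1] = V[inner, N - 2]
        Vi = V[inner, inner]
        lap = (
            (V[2:, inner] - 2 * Vi + V[:-2, inner]) / dx**2
            + (V[inner, 2:] - 2 * Vi + V[inner, :-2]) / dx**2
        )
        Vn = Vi + dt * (Vi - Vi**3 / 3 - W[inner, inner] + 0.0 + D * lap)
        Wn = W[inner, inner] + dt * FHN_EPS * (Vi + FHN_BETA - FHN_GAMMA * W[inner, inner])
        V[inner, inner] = Vn
        W[inner, inner] = Wn
        V[c, c] = clamp
    return V, W
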