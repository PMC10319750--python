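import numpy as np
import pytest

from tautodyn import ChannelParams, InitialState, TwoQubitDensityMatrix


@pytest.fixture
def bell_state() -> InitialState:
    return InitialState.bell()


@pytest.fixture
def bell_rho() -> TwoQubitDensityMatrix:
    return TwoQubitDensityMatrix.pure([1.0, 0.0, 0.0, 1.0])


@pytest.fixture
def product_rho() -> TwoQubitDensityMatrix:
    return TwoQubitDensityMatrix.pure([1.0, 0.0, 0.0, 0.0])


@pytest.fixture
def equal_channels():
    ch = ChannelParams(delta=1.0, gamma=np.log(2.0))
    return ch, ch


def mode_density_integral_oracle(t: float) -> float:
    """Brute-force value of int_0^inf D(w, t) dw, independent of scipy.quad.

    Dense Simpson sum on [0, A], plus the analytic tail: with
    D = (1/(pi t)) (1 - cos(w t)) / w^2,

        int_A^inf D dw = (1/(pi t)) (1/A + sin(A t)/(t A^2)) + O(1/(t^3 A^3)),

    by two integrations by parts of the cosine term.  Accurate well below
    1e-7 for A = 2000/t.
    """
    from scipy.integrate import simpson

    from tautodyn import mode_density

    A = 2000.0 / t
    w = np.linspace(0.0, A, 400_001)
    head = simpson(mode_density(w, t), x=w)
    tail = (1.0 / (np.pi * t)) * (1.0 / A + np.sin(A * t) / (t * A**2))
    return head + tail


def random_parameter_draw(rng):
    """One random (state, channel, channel) triple for property tests."""
    theta = rng.uniform(0.05, np.pi / 2 - 0.05)
    state = InitialState.from_angle(theta)
    ch1 = ChannelParams(delta=rng.uniform(0.0, 5.0), gamma=rng.uniform(0.0, 2.0))
    ch2 = ChannelParams(delta=rng.uniform(0.0, 5.0), gamma=rng.uniform(0.0, 2.0))
    return state, ch1, ch2
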