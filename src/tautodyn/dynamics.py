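"""Time evolution of the entangled two-qubit system.

Starting from alpha|00> + beta|11> with both reservoirs in the vacuum, the
second-order perturbative propagator leaves the reduced density matrix in
X form in the product basis {|00>, |01>, |10>, |11>}:

    rho_S(t) = [[L11, 0,   0,   L14],
                [0,   L22, 0,   0  ],
                [0,   0,   L33, 0  ],
                [L41, 0,   0,   L44]]

with

    L14 = alpha*beta * exp(-(G1+G2) t / 2) * exp(+i (D1+D2) t)
    L22 = beta^2 * (1 - exp(-G1 t)) * exp(-G2 t)
    L33 = beta^2 * exp(-G1 t) * (1 - exp(-G2 t))
    L44 = beta^2 * exp(-(G1+G2) t)

where G_i, D_i are the decay rate and tunnel splitting of channel i.  The
doubly excited population decays through each channel independently while
the coherence L14 decays at half the total rate and precesses at the summed
splitting — the two-channel analogue of single-qubit amplitude damping.

Two conventions are supported for L11.  ``mode="paper"`` keeps
L11 = alpha^2 fixed, which reproduces the source closed forms verbatim but
lets the trace leak to alpha^2 + beta^2 (e^{-G1 t} + e^{-G2 t} -
e^{-(G1+G2) t}).  ``mode="trace_preserving"`` (default) routes the decayed
population into |00>, adding beta^2 (1-e^{-G1 t})(1-e^{-G2 t}) to L11, which
restores trace one and positivity.  The concurrence is identical in both
conventions (the branch it could affect is never the active one).

The survival probability of the initial entangled state is the closed form

    P(t) = alpha^4 + beta^4 e^{-(G1+G2) t}
           + 2 alpha^2 beta^2 e^{-(G1+G2) t / 2} cos((D1+D2) t).
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np

from .spectra import OhmicSpectrum, principal_value_shift
from .units import ChannelParams, InitialState

__all__ = [
    "MODES",
    "PropagatorElements",
    "LambdaElements",
    "TwoQubitDensityMatrix",
    "parity_allowed",
    "propagator_elements",
    "lambda_elements",
    "reduced_density_matrix",
    "survival_probability",
]

MODES = ("paper", "trace_preserving")


def _check_mode(mode: str) -> str:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    return mode


def parity_allowed(m: int, n: int, operator: str) -> bool:
    """Selection rule for matrix elements of the perturbative propagator.

    The vacuum-preserving part (``operator="vac"``) contains an even number
    of bath-coupling insertions, so it connects system levels of equal
    parity: <m|u_vac|n> vanishes unless m - n is even.  The one-boson part
    (``operator="alpha"``) carries a single insertion and flips parity:
    <m|u_alpha|n> vanishes unless m - n is odd.
    """
    if m not in (0, 1) or n not in (0, 1):
        raise ValueError(f"level indices must be 0 or 1, got ({m}, {n})")
    even = (m - n) % 2 == 0
    if operator == "vac":
        return even
    if operator == "alpha":
        return not even
    raise ValueError(f"operator must be 'vac' or 'alpha', got {operator!r}")


@dataclass(frozen=True)
class PropagatorElements:
    """Non-vanishing matrix elements of one channel's dressed propagator.

    ``u_vac_00`` / ``u_vac_11`` are the pure phases picked up by the ground
    and excited system level while the reservoir stays in vacuum:

        u_vac_00 = exp[-(i/hbar_tilde) (t dE0 - |f10|^2 F_plus(t))]
        u_vac_11 = exp[-(i/hbar_tilde) (t dE1 - |f01|^2 F_minus(t))]

    with F_pm the principal-value shifts of the bath spectrum.  The
    one-boson amplitude into mode omega is available through
    :meth:`u_alpha_01`; parity-forbidden elements are identically zero.
    """

    t: float
    hbar_tilde: float
    u_vac_00: complex
    u_vac_11: complex
    F_plus: float
    F_minus: float
    delta_E0: float
    delta_E1: float
    channel: ChannelParams
    spectrum: OhmicSpectrum

    def u_alpha_01(self, omega: float) -> complex:
        """One-boson emission amplitude <0|u_alpha|1> for bath mode omega.

            (2 pi i / sqrt(2 hbar_tilde)) * gamma_bar(omega) * f01 * (1/pi)
            * sin((omega + Delta) t / 2) / (omega + Delta)
            * exp(i (omega + Delta) t / 2)

        <1|u_alpha|0> is its complex conjugate.
        """
        if self.t == 0.0:
            return 0.0 + 0.0j
        x = omega + self.channel.delta
        gbar = self.spectrum.gamma_bar(omega, self.t)
        if x == 0.0:
            osc = self.t / 2.0  # sin(x t/2)/x -> t/2
        else:
            osc = math.sin(x * self.t / 2.0) / x
        return (
            2.0j
            * math.pi
            / math.sqrt(2.0 * self.hbar_tilde)
            * gbar
            * self.spectrum.f01
            * (1.0 / math.pi)
            * osc
            * cmath.exp(1.0j * x * self.t / 2.0)
        )

    def u_alpha_10(self, omega: float) -> complex:
        return np.conj(self.u_alpha_01(omega))


def propagator_elements(
    ch: ChannelParams,
    spec: OhmicSpectrum,
    t: float,
    hbar_tilde: float = 1.0,
    *,
    delta_E0: float = 0.0,
    delta_E1: float = 0.0,
) -> PropagatorElements:
    """Evaluate the dressed propagator elements of one channel at time t.

    The second-order energy shifts dE0, dE1 have no closed form at this
    level of the model and default to zero; they contribute only a global
    phase per level and drop out of every reduced-state observable.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    F_plus = principal_value_shift(spec, ch.delta, t, +1)
    F_minus = principal_value_shift(spec, ch.delta, t, -1)
    phase00 = -(t * delta_E0 - abs(spec.f10) ** 2 * F_plus) / hbar_tilde
    phase11 = -(t * delta_E1 - abs(spec.f01) ** 2 * F_minus) / hbar_tilde
    return PropagatorElements(
        t=t,
        hbar_tilde=hbar_tilde,
        u_vac_00=cmath.exp(1.0j * phase00),
        u_vac_11=cmath.exp(1.0j * phase11),
        F_plus=F_plus,
        F_minus=F_minus,
        delta_E0=delta_E0,
        delta_E1=delta_E1,
        channel=ch,
        spectrum=spec,
    )


@dataclass(frozen=True)
class LambdaElements:
    """The eight potentially nonzero entries of the X-form reduced state."""

    l11: float
    l14: complex
    l22: float
    l33: float
    l44: float
    mode: str
    l23: complex = 0.0 + 0.0j
    l32: complex = 0.0 + 0.0j

    @property
    def l41(self) -> complex:
        return np.conj(self.l14)

    @property
    def trace(self) -> float:
        return self.l11 + self.l22 + self.l33 + self.l44


def lambda_elements(
    state: InitialState,
    ch1: ChannelParams,
    ch2: ChannelParams,
    t: float,
    mode: str = "trace_preserving",
) -> LambdaElements:
    """Closed-form reduced-density-matrix elements at time t (see module docs)."""
    _check_mode(mode)
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    a, b = state.alpha, state.beta
    e1 = math.exp(-ch1.gamma * t)
    e2 = math.exp(-ch2.gamma * t)
    l22 = b**2 * (1.0 - e1) * e2
    l33 = b**2 * e1 * (1.0 - e2)
    l44 = b**2 * e1 * e2
    l14 = (
        a
        * b
        * math.sqrt(e1 * e2)
        * cmath.exp(1.0j * (ch1.delta + ch2.delta) * t)
    )
    l11 = a**2
    if mode == "trace_preserving":
        l11 += b**2 * (1.0 - e1) * (1.0 - e2)
    return LambdaElements(l11=l11, l14=l14, l22=l22, l33=l33, l44=l44, mode=mode)


@dataclass(frozen=True)
class TwoQubitDensityMatrix:
    """A 4x4 reduced density matrix in the {|00>, |01>, |10>, |11>} basis.

    ``mode`` records which L11 convention produced it; in
    "trace_preserving" mode the matrix is a bona fide density operator
    (unit trace, PSD), in "paper" mode the trace may fall below one.
    """

    matrix: np.ndarray
    mode: str = "trace_preserving"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=complex)
        if m.shape != (4, 4):
            raise ValueError(f"expected a 4x4 matrix, got shape {m.shape}")
        object.__setattr__(self, "matrix", m)
        _check_mode(self.mode)

    @property
    def trace(self) -> float:
        return float(np.real(np.trace(self.matrix)))

    def validate(self, atol: float = 1e-12) -> None:
        """Raise ValueError if Hermiticity/positivity/trace invariants fail."""
        m = self.matrix
        if np.linalg.norm(m - m.conj().T) >= atol:
            raise ValueError("density matrix is not Hermitian")
        diag = np.real(np.diag(m))
        if np.any(diag < -atol):
            raise ValueError(f"negative population on the diagonal: {diag}")
        tr = self.trace
        if self.mode == "trace_preserving":
            if abs(tr - 1.0) >= atol:
                raise ValueError(f"trace = {tr!r}, expected 1")
            if np.linalg.eigvalsh(m).min() < -atol:
                raise ValueError("density matrix has a negative eigenvalue")
        else:
            if not (0.0 < tr <= 1.0 + atol):
                raise ValueError(f"trace = {tr!r} outside (0, 1]")

    @classmethod
    def from_lambda(cls, lam: LambdaElements) -> "TwoQubitDensityMatrix":
        m = np.zeros((4, 4), dtype=complex)
        m[0, 0] = lam.l11
        m[0, 3] = lam.l14
        m[3, 0] = lam.l41
        m[1, 1] = lam.l22
        m[1, 2] = lam.l23
        m[2, 1] = lam.l32
        m[2, 2] = lam.l33
        m[3, 3] = lam.l44
        return cls(matrix=m, mode=lam.mode)

    @classmethod
    def pure(cls, amplitudes, mode: str = "trace_preserving") -> "TwoQubitDensityMatrix":
        """Projector onto a pure two-qubit state given by 4 amplitudes."""
        v = np.asarray(amplitudes, dtype=complex).reshape(4)
        v = v / np.linalg.norm(v)
        return cls(matrix=np.outer(v, v.conj()), mode=mode)


def reduced_density_matrix(
    state: InitialState,
    ch1: ChannelParams,
    ch2: ChannelParams,
    t: float,
    mode: str = "trace_preserving",
) -> TwoQubitDensityMatrix:
    """Assemble rho_S(t) from the closed-form X-state elements."""
    return TwoQubitDensityMatrix.from_lambda(
        lambda_elements(state, ch1, ch2, t, mode=mode)
    )


def survival_probability(
    state: InitialState,
    ch1: ChannelParams,
    ch2: ChannelParams,
    t,
):
    """Probability of finding the pair still in its initial entangled state.

    ``P(t) = alpha^4 + beta^4 e^{-(G1+G2) t}
    + 2 alpha^2 beta^2 e^{-(G1+G2) t/2} cos((D1+D2) t)``; equivalently
    ``|alpha^2 + beta^2 e^{-(G1+G2)t/2} e^{i (D1+D2) t}|^2``, hence always
    in [0, 1].  Vectorized over ``t``.
    """
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("t must be >= 0")
    a2, b2 = state.alpha**2, state.beta**2
    g = ch1.gamma + ch2.gamma
    d = ch1.delta + ch2.delta
    p = (
        a2**2
        + b2**2 * np.exp(-g * tt)
        + 2.0 * a2 * b2 * np.exp(-g * tt / 2.0) * np.cos(d * tt)
    )
    return p if p.ndim else float(p)
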