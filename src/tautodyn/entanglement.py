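"""Entanglement measures for the decohering two-qubit pair.

Two routes to the concurrence are implemented and cross-checked:

* the general Wootters procedure — eigenvalues of the non-Hermitian matrix
  ``R = rho (sigma_y x sigma_y) rho* (sigma_y x sigma_y)``, sorted
  descending, giving ``C = max(0, sqrt(l1) - sqrt(l2) - sqrt(l3) - sqrt(l4))``;
* the closed form specialized to the model's X state,

      C(t) = max(0, 2 alpha beta e^{-(G1+G2) t/2}
                    - 2 beta^2 e^{-(G1+G2) t/2}
                      sqrt((1 - e^{-G1 t})(1 - e^{-G2 t}))).

The first term is the surviving |00><11| coherence, the second the
geometric mean of the single-excitation populations fed by the decay.  When
beta > alpha the bracket crosses zero at a finite time t* — entanglement
sudden death — found here by bracketed root solving; for alpha >= beta the
concurrence decays asymptotically without ever vanishing.

The entanglement of formation follows from the concurrence through the
binary entropy: ``E(C) = h((1 + sqrt(1 - C^2)) / 2)``.

The biological reading of the state uses the rotated single-qubit basis
|0> = (|cor> - |er>)/sqrt(2), |1> = (|cor> + |er>)/sqrt(2), where "er"
marks the incorporation error made by the DNA polymerase (first qubit) or
the RNA polymerase (second qubit); :func:`error_basis_populations` returns
the joint error/correct probabilities in that frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import xlogy

from .dynamics import (
    LambdaElements,
    TwoQubitDensityMatrix,
    lambda_elements,
    reduced_density_matrix,
    survival_probability,
)
from .units import ChannelParams, InitialState

__all__ = [
    "EntanglementResult",
    "wootters_concurrence",
    "xstate_eigenvalues",
    "concurrence_closed_form",
    "binary_entropy",
    "entanglement_of_formation",
    "sudden_death_time",
    "error_basis_populations",
    "evolve_entanglement",
]

_SIGMA_Y = np.array([[0.0, -1.0j], [1.0j, 0.0]])
_SPIN_FLIP = np.kron(_SIGMA_Y, _SIGMA_Y)

# single-qubit change of basis: columns are |cor>, |er> expressed in {|0>,|1>}
_W = np.array([[1.0, -1.0], [1.0, 1.0]]) / math.sqrt(2.0)


def _as_matrix(rho) -> np.ndarray:
    if isinstance(rho, TwoQubitDensityMatrix):
        return rho.matrix
    m = np.asarray(rho, dtype=complex)
    if m.shape != (4, 4):
        raise ValueError(f"expected a 4x4 density matrix, got shape {m.shape}")
    return m


def wootters_concurrence(rho, *, normalize: bool = True, atol: float = 1e-10) -> float:
    """Concurrence of an arbitrary two-qubit density matrix.

    Forms ``R = rho (sy x sy) rho* (sy x sy)``, takes its eigenvalues
    (real and nonnegative up to round-off; tiny negatives above -1e-12 are
    clamped), sorts them descending and returns
    ``max(0, sqrt(l1) - sqrt(l2) - sqrt(l3) - sqrt(l4))``.

    With ``normalize=True`` (default) the input is divided by its trace
    first, as the measure presumes a unit-trace density operator; passing
    ``normalize=False`` evaluates the same functional on the raw matrix,
    which is the convention under which the model's closed form lives in
    its trace-leaking variant.
    """
    m = _as_matrix(rho)
    if np.linalg.norm(m - m.conj().T) > atol:
        raise ValueError("input is not Hermitian to tolerance")
    tr = float(np.real(np.trace(m)))
    if normalize:
        if tr <= 0:
            raise ValueError(f"trace must be positive to normalize, got {tr!r}")
        m = m / tr
    r = m @ _SPIN_FLIP @ m.conj() @ _SPIN_FLIP
    lam = np.linalg.eigvals(r).real
    if lam.min() < -1e-12:
        raise ValueError(f"spin-flip spectrum has a large negative eigenvalue: {lam.min()}")
    lam = np.sort(np.clip(lam, 0.0, None))[::-1]
    roots = np.sqrt(lam)
    return float(max(0.0, roots[0] - roots[1] - roots[2] - roots[3]))


def xstate_eigenvalues(lam: LambdaElements) -> tuple[float, float, float, float]:
    """Spin-flip spectrum of the model's X state, in closed form.

    For the X pattern with vanishing inner coherences (L23 = L32 = 0) the
    eigenvalues of ``rho (sy x sy) rho* (sy x sy)`` are

        l1 = l2 = L22 * L33,
        l3 = (sqrt(L11 L44) - |L14|)**2,
        l4 = (sqrt(L11 L44) + |L14|)**2,

    matching the direct numerical eigendecomposition.  Returned unsorted in
    the order (l1, l2, l3, l4).
    """
    if lam.l11 < 0 or lam.l22 < 0 or lam.l33 < 0 or lam.l44 < 0:
        raise ValueError("diagonal elements must be nonnegative")
    l12 = lam.l22 * lam.l33
    g = math.sqrt(lam.l11 * lam.l44)
    c = abs(lam.l14)
    return (l12, l12, (g - c) ** 2, (g + c) ** 2)


def concurrence_closed_form(
    state: InitialState,
    ch1: ChannelParams,
    ch2: ChannelParams,
    t,
    *,
    clamp: bool = True,
):
    """Closed-form concurrence of the decohering pair (vectorized over t).

    ``clamp=False`` returns the raw bracket, which goes negative past the
    sudden-death time when beta > alpha; the physical measure is the
    clamped value.
    """
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("t must be >= 0")
    a, b = state.alpha, state.beta
    env = np.exp(-(ch1.gamma + ch2.gamma) * tt / 2.0)
    feed = np.sqrt((1.0 - np.exp(-ch1.gamma * tt)) * (1.0 - np.exp(-ch2.gamma * tt)))
    c = 2.0 * a * b * env - 2.0 * b**2 * env * feed
    if clamp:
        c = np.maximum(c, 0.0)
    return c if c.ndim else float(c)


def binary_entropy(x) -> float:
    """Shannon entropy of a bit, ``h(x) = -x log2 x - (1-x) log2 (1-x)``."""
    xx = np.asarray(x, dtype=float)
    if np.any((xx < 0) | (xx > 1)):
        raise ValueError("binary_entropy requires x in [0, 1]")
    h = -(xlogy(xx, xx) + xlogy(1.0 - xx, 1.0 - xx)) / math.log(2.0)
    h = np.maximum(h, 0.0)  # avoid -0.0 at the endpoints
    return h if h.ndim else float(h)


def entanglement_of_formation(C) -> float:
    """Entanglement of formation from the concurrence.

    ``E(C) = h((1 + sqrt(1 - C^2)) / 2)`` in bits; monotone increasing,
    E(0) = 0, E(1) = 1.
    """
    cc = np.asarray(C, dtype=float)
    if np.any((cc < 0) | (cc > 1)):
        raise ValueError("concurrence must lie in [0, 1]")
    e = binary_entropy((1.0 + np.sqrt(1.0 - cc**2)) / 2.0)
    return e if isinstance(e, np.ndarray) else float(e)


def sudden_death_time(
    state: InitialState,
    ch1: ChannelParams,
    ch2: ChannelParams,
    t_max: float = 1e3,
    *,
    xtol: float = 1e-10,
) -> Optional[float]:
    """First time at which the concurrence reaches exactly zero, if any.

    Solves ``alpha beta = beta^2 sqrt((1 - e^{-G1 t})(1 - e^{-G2 t}))``.
    The right side grows monotonically from 0 to beta^2, so a root exists
    iff alpha < beta (and both rates are positive); returns None otherwise,
    or when the root lies beyond ``t_max``.
    """
    if ch1.gamma <= 0 or ch2.gamma <= 0:
        return None
    a, b = state.alpha, state.beta
    if b == 0 or a >= b:
        return None

    target = a / b

    def gap(t: float) -> float:
        return (
            math.sqrt((1.0 - math.exp(-ch1.gamma * t)) * (1.0 - math.exp(-ch2.gamma * t)))
            - target
        )

    if gap(t_max) <= 0:
        return None
    lo = 0.0
    hi = min(t_max, 1.0 / min(ch1.gamma, ch2.gamma))
    while gap(hi) <= 0:
        hi = min(2.0 * hi, t_max)
        if hi == t_max:
            break
    return float(brentq(gap, lo, hi, xtol=xtol))


def error_basis_populations(rho) -> np.ndarray:
    """Joint replication/transcription-error probabilities.

    Rotates each qubit from the energy eigenbasis {|0>, |1>} to the
    biological basis {|cor>, |er>} and returns the diagonal, normalized by
    the trace, ordered (P_cor_cor, P_cor_er, P_er_cor, P_er_er).  For the
    maximally entangled state the lone-error probabilities vanish: an
    incorporation error on the DNA strand is perfectly correlated with the
    same error on the mRNA.
    """
    m = _as_matrix(rho)
    tr = float(np.real(np.trace(m)))
    if tr <= 0:
        raise ValueError(f"trace must be positive, got {tr!r}")
    w2 = np.kron(_W, _W)
    probs = np.real(np.diag(w2.conj().T @ m @ w2)) / tr
    return probs


@dataclass(frozen=True)
class EntanglementResult:
    """Time series of the entanglement measures with their provenance."""

    times: np.ndarray
    concurrence_closed: np.ndarray
    concurrence_numeric: np.ndarray
    eof: np.ndarray
    survival: np.ndarray
    sudden_death: Optional[float]
    params: dict = field(default_factory=dict)


def evolve_entanglement(
    state: InitialState,
    ch1: ChannelParams,
    ch2: ChannelParams,
    times,
    mode: str = "trace_preserving",
) -> EntanglementResult:
    """Evaluate concurrence (both routes), EoF and survival on a time grid.

    The numeric route runs the Wootters eigenvalue procedure on the
    assembled rho_S(t); in "paper" mode the raw (un-normalized) functional
    is used, matching the convention of the closed form.
    """
    tt = np.asarray(times, dtype=float)
    closed = np.atleast_1d(concurrence_closed_form(state, ch1, ch2, tt))
    numeric = np.array(
        [
            wootters_concurrence(
                reduced_density_matrix(state, ch1, ch2, float(t), mode=mode),
                normalize=(mode == "trace_preserving"),
            )
            for t in tt
        ]
    )
    return EntanglementResult(
        times=tt,
        concurrence_closed=closed,
        concurrence_numeric=numeric,
        eof=np.atleast_1d(entanglement_of_formation(closed)),
        survival=np.atleast_1d(survival_probability(state, ch1, ch2, tt)),
        sudden_death=sudden_death_time(state, ch1, ch2, t_max=float(tt.max(initial=0.0)) or 1.0),
        params={
            "alpha": state.alpha,
            "beta": state.beta,
            "delta1": ch1.delta,
            "delta2": ch2.delta,
            "gamma1": ch1.gamma,
            "gamma2": ch2.gamma,
            "mode": mode,
        },
    )
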