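"""Bath spectral functions and the quadrature engines built on them.

Each qubit couples linearly to its own reservoir of bosonic modes, which
starts in the vacuum.  At second order in the coupling the reservoir enters
the reduced dynamics only through three scalar functions:

* the time-dependent mode density
  ``D(omega, t) = (1/(2 pi t)) * (sin(omega t / 2) / (omega / 2))**2``,
  a nascent-delta profile that integrates to 1/2 over omega in [0, inf)
  for every t > 0;
* the spectral density of the (s, omega_c, eta) Ohmic family,
  ``J(omega) = eta * omega * (omega/omega_c)**(s-1) * exp(-omega/omega_c)``
  (s = 1 Ohmic, s < 1 sub-Ohmic, s > 1 super-Ohmic);
* the principal-value phase shifts
  ``F_pm(t) = -(1/pi) PV int_0^inf J(w) sin((w +- Delta) t) / (w +- Delta)**2 dw``
  that dress the diagonal propagator phases, where the minus branch has a
  Cauchy singularity at omega = Delta handled by symmetric-window
  subtraction.

The decay rate of a channel follows from the Ohmic spectrum as

    Gamma(t) = (1/(pi*hbar_tilde)) * |f01|**2 * eta
               * int_0^inf (w/w_c)**(s-1) * w * exp(-w/w_c)
                 * (1/t) * (sin(w t/2)/(w/2))**2 dw,

equivalently ``(2 |f01|**2 / hbar_tilde) * int J(w) D(w, t) dw``.  The
closed-form two-qubit dynamics uses a constant Gamma per channel; Gamma(t)
profiles are a diagnostic for how that constant emerges (Gamma(t) grows
from 0 and saturates once t >> 1/omega_c).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
from scipy import integrate

__all__ = [
    "OhmicSpectrum",
    "QuadratureError",
    "mode_density",
    "principal_value_shift",
    "decay_rate",
]


class QuadratureError(RuntimeError):
    """Raised when an adaptive quadrature fails to reach its tolerance."""

    def __init__(self, message: str, achieved: float):
        super().__init__(f"{message} (achieved error estimate {achieved:.3e})")
        self.achieved = achieved


@dataclass(frozen=True)
class OhmicSpectrum:
    """An (s, omega_c, eta) spectral-density family with transition coupling.

    Parameters
    ----------
    s : float
        Ohmicity exponent (> 0); s = 1 Ohmic, s < 1 sub-Ohmic,
        s > 1 super-Ohmic.
    omega_c : float
        Exponential cutoff frequency (> 0, dimensionless units).
    eta : float
        Dimensionless system-bath coupling strength (>= 0).
    f01 : complex
        Transition matrix element of the coupling function between the two
        system levels; ``f10 = conj(f01)``.
    """

    s: float = 1.0
    omega_c: float = 1.0
    eta: float = 1.0
    f01: complex = 1.0 + 0.0j

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise ValueError(f"s must be > 0, got {self.s}")
        if not self.omega_c > 0:
            raise ValueError(f"omega_c must be > 0, got {self.omega_c}")
        if self.eta < 0:
            raise ValueError(f"eta must be >= 0, got {self.eta}")

    @property
    def f10(self) -> complex:
        return np.conj(self.f01)

    def spectral_density(self, omega):
        """J(omega) = eta * omega * (omega/omega_c)**(s-1) * exp(-omega/omega_c).

        Vectorized; J(0) = 0 for s >= 0 (the s < 1 power-law divergence at
        the origin is tamed by the linear factor for all s > 0).
        """
        w = np.asarray(omega, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            j = self.eta * w * (w / self.omega_c) ** (self.s - 1.0) * np.exp(
                -w / self.omega_c
            )
        j = np.where(w == 0.0, 0.0, j)
        return j if j.ndim else float(j)

    def gamma_bar(self, omega, t: float):
        """Diagnostic coupling profile ``sqrt(2 J(omega) / (pi D(omega, t)))``.

        Only the combination J = (pi/2) * gamma_bar**2 * D enters the
        dynamics; this inversion is exposed for inspection of the implied
        per-mode coupling and is undefined at zeros of D.
        """
        return np.sqrt(2.0 * self.spectral_density(omega) / (np.pi * mode_density(omega, t)))


def mode_density(omega, t: float):
    """Nascent-delta frequency distribution of the reservoir oscillators.

    ``D(omega, t) = (1/(2 pi t)) * (sin(omega t/2) / (omega/2))**2``, with
    the removable singularity at omega = 0 filled by its limit
    ``t / (2 pi)``.  For every t > 0, ``int_0^inf D(omega, t) domega = 1/2``.
    """
    if t <= 0:
        raise ValueError(f"t must be > 0, got {t}")
    w = np.asarray(omega, dtype=float)
    # sin(wt/2)/(w/2) = t * sinc(wt/(2 pi)) handles w = 0 exactly
    kernel = t * np.sinc(w * t / (2.0 * np.pi))
    d = kernel**2 / (2.0 * np.pi * t)
    return d if d.ndim else float(d)


SpectralDensity = Union[OhmicSpectrum, Callable[[np.ndarray], np.ndarray]]


def _as_density(spec: SpectralDensity) -> Callable:
    if isinstance(spec, OhmicSpectrum):
        return spec.spectral_density
    if callable(spec):
        return spec
    raise TypeError(f"spec must be an OhmicSpectrum or a callable, got {type(spec)!r}")


def _default_omega_max(spec: SpectralDensity, omega_max: float | None) -> float:
    if omega_max is not None:
        return float(omega_max)
    if isinstance(spec, OhmicSpectrum):
        # exp(-w/w_c) tail beyond 50 w_c contributes < 1e-20 of the integral
        return 50.0 * spec.omega_c
    raise ValueError("omega_max is required for a bare callable spectral density")


def _quad(func, a, b, *, epsabs, what, points=None, limit=400):
    value, err = integrate.quad(
        func, a, b, epsabs=epsabs, epsrel=1e-10, limit=limit, points=points
    )
    if err > max(100 * epsabs, 1e-8 * abs(value)):
        raise QuadratureError(f"quadrature for {what} did not converge", err)
    return value


def principal_value_shift(
    spec: SpectralDensity,
    delta: float,
    t: float,
    sign: int,
    *,
    omega_max: float | None = None,
    epsabs: float = 1e-10,
) -> float:
    """Principal-value phase shift F_+ (sign=+1) or F_- (sign=-1).

    ``F_pm(t) = -(1/pi) PV int_0^inf J(w) sin((w pm Delta) t)/(w pm Delta)**2 dw``.

    For sign=+1 and Delta > 0 the integrand is regular on (0, inf).  For
    sign=-1 the factor 1/(w - Delta) is Cauchy-singular at w = Delta; the
    integral is evaluated by splitting off a symmetric window
    [Delta - h, Delta + h] on which the odd part cancels exactly:

        int_{Delta-h}^{Delta+h} g(w) dw
            = int_0^h (J(Delta+u) - J(Delta-u)) * sin(u t)/u**2 du,

    a regular integrand, plus ordinary adaptive quadrature on the tails.
    Returns 0 exactly for t = 0.  Raises :class:`QuadratureError` if the
    adaptive scheme cannot certify the requested absolute tolerance.
    """
    if sign not in (+1, -1):
        raise ValueError(f"sign must be +1 or -1, got {sign}")
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    if t == 0.0:
        return 0.0

    J = _as_density(spec)
    upper = _default_omega_max(spec, omega_max)
    if isinstance(spec, OhmicSpectrum) and spec.eta == 0.0:
        return 0.0

    shift = sign * delta

    def regular(w):
        x = w + shift
        # sin(xt)/x^2 = t^2 * sinc(xt/pi)^2 * x / ... ; only used away from x=0
        return J(w) * math.sin(x * t) / x**2

    if sign == +1 or delta == 0.0 or delta >= upper:
        # integrand has at worst an integrable endpoint feature at w=0
        pts = [delta] if 0 < delta < upper else None
        value = _quad(regular, 0.0, upper, epsabs=epsabs, what="F_shift", points=pts)
        return -value / math.pi

    # sign = -1 with 0 < delta < upper: symmetric-window PV at w = delta
    h = min(delta, upper - delta) / 2.0

    def window(u):
        if u == 0.0:
            return 0.0  # limit is 2 J'(delta) * t * ... ; integrand continuous, 0 weight point
        return (J(delta + u) - J(delta - u)) * math.sin(u * t) / u**2

    value = _quad(window, 0.0, h, epsabs=epsabs, what="F_minus window")
    value += _quad(regular, 0.0, delta - h, epsabs=epsabs, what="F_minus left tail")
    value += _quad(regular, delta + h, upper, epsabs=epsabs, what="F_minus right tail")
    return -value / math.pi


def decay_rate(spec: OhmicSpectrum, t: float, hbar_tilde: float = 1.0) -> float:
    """Channel decay rate Gamma(t) induced by an Ohmic reservoir.

    Evaluates

        Gamma(t) = (1/(pi hbar_tilde)) |f01|^2 eta
                   int_0^inf (w/w_c)^(s-1) w exp(-w/w_c)
                             (1/t) (sin(w t/2)/(w/2))^2 dw

    by adaptive quadrature on [0, 50 omega_c] (the exponential cutoff makes
    the truncated tail negligible).  Nonnegative for all inputs; linear in
    eta and in |f01|^2.
    """
    if t <= 0:
        raise ValueError(f"t must be > 0, got {t}")
    if not hbar_tilde > 0:
        raise ValueError(f"hbar_tilde must be > 0, got {hbar_tilde}")
    amp = abs(spec.f01) ** 2 * spec.eta
    if amp == 0.0:
        return 0.0

    s, wc = spec.s, spec.omega_c

    def integrand(w):
        if w == 0.0:
            return 0.0  # integrand ~ w**s * t -> 0 for all s > 0
        kernel = math.sin(w * t / 2.0) / (w / 2.0)
        return (w / wc) ** (s - 1.0) * w * math.exp(-w / wc) * kernel**2 / t

    value = _quad(
        integrand,
        0.0,
        50.0 * wc,
        epsabs=1e-12,
        what="Gamma(t)",
        limit=800,
    )
    return amp * value / (math.pi * hbar_tilde)
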