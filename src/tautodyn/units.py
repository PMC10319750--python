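"""Parameter containers, unit scales and the dimensionless Planck constant.

The model describes each biomolecule (daughter DNA, mRNA) as a two-level
system arising from proton tautomery in a double-well potential.  All
dynamical quantities are made dimensionless by choosing a characteristic
length ``R0`` (well separation), a characteristic energy ``U0`` (barrier
scale) and the tunneling time ``tau0 = R0*sqrt(M/U0)``.  In these units the
role of Planck's constant is played by the dimensionless combination

    hbar_tilde = hbar / (U0 * tau0) = hbar / (P0 * R0)
               = sqrt( (hbar**2 / (M * R0**2)) / U0 ),

which measures how quantum a near-macroscopic two-level system can behave
(``hbar_tilde << 1`` is the quasi-classical limit).

Also provided: the Zurek-style decoherence-time estimate
``t_D = t_R * lambda_T / delta_x`` for a mass in a spatial superposition,
with the thermal de Broglie wavelength in its standard form
``lambda_T = hbar / sqrt(2 m k_B T)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "HBAR",
    "K_B",
    "UnitsSystem",
    "InitialState",
    "ChannelParams",
    "DecoherenceEstimate",
    "hbar_tilde",
    "thermal_de_broglie",
    "zurek_decoherence_time",
]

# CODATA 2018 values, SI units
HBAR = 1.054571817e-34  # J s
K_B = 1.380649e-23  # J / K


def _require_positive(**fields: float) -> None:
    for name, value in fields.items():
        if not (value > 0) or not math.isfinite(value):
            raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class UnitsSystem:
    """Characteristic scales of the double-well two-level system.

    Parameters
    ----------
    mass : float
        Effective tunneling mass ``M`` (arbitrary mass unit).
    characteristic_length : float
        Well separation scale ``R0`` (length unit).
    characteristic_energy : float
        Barrier energy scale ``U0`` (energy unit).
    hbar_physical : float
        Planck's reduced constant expressed in the same unit system
        (action = energy * time).  Defaults to 1 for model units.
    """

    mass: float = 1.0
    characteristic_length: float = 1.0
    characteristic_energy: float = 1.0
    hbar_physical: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(
            mass=self.mass,
            characteristic_length=self.characteristic_length,
            characteristic_energy=self.characteristic_energy,
            hbar_physical=self.hbar_physical,
        )

    @property
    def momentum_scale(self) -> float:
        """Momentum unit ``P0 = sqrt(M * U0)``."""
        return math.sqrt(self.mass * self.characteristic_energy)

    @property
    def time_scale(self) -> float:
        """Tunneling time ``tau0 = R0 * sqrt(M / U0)``."""
        return self.characteristic_length * math.sqrt(
            self.mass / self.characteristic_energy
        )

    @property
    def hbar_tilde(self) -> float:
        """Dimensionless Planck constant ``hbar / (U0 * tau0)``."""
        return self.hbar_physical / (self.characteristic_energy * self.time_scale)

    def hbar_tilde_forms(self) -> tuple[float, float, float]:
        """The three algebraically equivalent expressions for ``hbar_tilde``.

        Returned as (energy-time form, momentum-length form, square-root
        form); they agree to floating-point accuracy and are exposed for
        validation.
        """
        h, m = self.hbar_physical, self.mass
        r0, u0 = self.characteristic_length, self.characteristic_energy
        return (
            h / (u0 * self.time_scale),
            h / (self.momentum_scale * r0),
            math.sqrt((h**2 / (m * r0**2)) / u0),
        )


def hbar_tilde(units: UnitsSystem) -> float:
    """Dimensionless Planck constant of a :class:`UnitsSystem`."""
    return units.hbar_tilde


@dataclass(frozen=True)
class InitialState:
    """Amplitudes of the initial entangled state alpha|00> + beta|11>.

    ``alpha`` is the weight of the doubly "correct-geometry" branch |00>,
    ``beta`` of the doubly tautomeric branch |11>.  Complex inputs are
    reduced to their moduli: every observable of the model (survival
    probability, populations, concurrence) depends only on alpha**2,
    beta**2 and alpha*beta, so phases of the amplitudes are unobservable.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", abs(self.alpha))
        object.__setattr__(self, "beta", abs(self.beta))
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError(
                f"amplitudes must lie in [0, 1], got alpha={self.alpha}, beta={self.beta}"
            )
        norm = self.alpha**2 + self.beta**2
        if abs(norm - 1.0) > 1e-12:
            raise ValueError(
                f"state not normalized: alpha^2 + beta^2 = {norm!r} (tolerance 1e-12)"
            )

    @classmethod
    def from_angle(cls, theta: float) -> "InitialState":
        """Build cos(theta)|00> + sin(theta)|11> for theta in [0, pi/2]."""
        return cls(math.cos(theta), math.sin(theta))

    @classmethod
    def bell(cls) -> "InitialState":
        """The equally weighted, maximally entangled state (|00>+|11>)/sqrt(2)."""
        return cls.from_angle(math.pi / 4)


@dataclass(frozen=True)
class ChannelParams:
    """One system-bath channel: tunnel splitting and decay rate.

    delta : dimensionless tunnel splitting (E1 - E0)/hbar_tilde of the
        double-well ground doublet, >= 0.
    gamma : dimensionless decay rate of the channel's coherence, >= 0.
        May be supplied directly or computed from an Ohmic spectrum via
        :func:`tautodyn.spectra.decay_rate`.
    """

    delta: float
    gamma: float

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")


def thermal_de_broglie(
    m: float,
    T: float,
    convention: str = "standard",
    *,
    hbar: float = HBAR,
    k_B: float = K_B,
) -> float:
    """Thermal de Broglie wavelength of a mass ``m`` at temperature ``T``.

    convention="standard" returns ``hbar / sqrt(2 m k_B T)`` (a length,
    the form the decoherence-time formula requires).  convention="as_printed"
    returns ``hbar * sqrt(2 m k_B T)``, a variant that appears in parts of
    the literature; it is dimensionally a momentum-scaled action, not a
    length, and is retained only for fidelity comparisons.
    """
    _require_positive(m=m, T=T)
    thermal_momentum = math.sqrt(2.0 * m * k_B * T)
    if convention == "standard":
        return hbar / thermal_momentum
    if convention == "as_printed":
        return hbar * thermal_momentum
    raise ValueError(f"unknown convention {convention!r}")


@dataclass(frozen=True)
class DecoherenceEstimate:
    """Inputs for the position-superposition decoherence-time estimate.

    mass [kg], temperature [K], separation delta_x [m] between the two
    superposed proton positions, and the thermal relaxation time t_R [s].
    """

    mass: float
    temperature: float
    delta_x: float
    relaxation_time: float
    convention: str = "standard"
    hbar: float = HBAR
    k_B: float = K_B

    def __post_init__(self) -> None:
        _require_positive(
            mass=self.mass,
            temperature=self.temperature,
            relaxation_time=self.relaxation_time,
        )
        if self.delta_x < 0 or not math.isfinite(self.delta_x):
            raise ValueError(f"delta_x must be >= 0 and finite, got {self.delta_x}")

    @property
    def lambda_T(self) -> float:
        return thermal_de_broglie(
            self.mass,
            self.temperature,
            self.convention,
            hbar=self.hbar,
            k_B=self.k_B,
        )

    @property
    def t_D(self) -> float:
        return zurek_decoherence_time(self)


def zurek_decoherence_time(est: DecoherenceEstimate) -> float:
    """Decoherence time ``t_D = t_R * lambda_T / delta_x``.

    A mass in superposition across ``delta_x`` loses coherence faster than
    it thermalizes by the ratio of the thermal de Broglie wavelength to the
    separation; for delta_x >> lambda_T decoherence is essentially
    instantaneous on the relaxation timescale.
    """
    if est.delta_x == 0:
        raise ZeroDivisionError(
            "delta_x = 0: decoherence time undefined for coincident positions"
        )
    return est.relaxation_time * est.lambda_T / est.delta_x
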