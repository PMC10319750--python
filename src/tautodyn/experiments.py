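"""Parameter sweeps over the decoherence scenarios, fixtures, and output.

The scenarios mirror the qualitative studies of the model: survival
probability of the entangled state under ordered decay rates, concurrence
and entanglement of formation when each channel's rate is tied to its
tunnel splitting by a single ratio kappa (Gamma_i = kappa * Delta_i), and
asymmetric-channel comparisons.  Only orderings are asserted by the tests
(faster decay for stronger coupling; faster entanglement loss for larger
kappa); the sweep grids are documented defaults, not fitted values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import survival_probability
from .entanglement import (
    concurrence_closed_form,
    entanglement_of_formation,
)
from .units import ChannelParams, InitialState

__all__ = [
    "SCENARIOS",
    "SweepSpec",
    "RandomStateFixture",
    "run_sweep",
    "generate_random_states",
    "write_results",
]

SCENARIOS = ("fig2a", "fig2b", "fig2c", "fig3", "fig4")

_DEFAULT_KAPPAS = (0.05, 0.1, 0.3)
_DEFAULT_DELTAS = (0.2, 1.0, 5.0)


def _default_times() -> np.ndarray:
    return np.linspace(0.0, 20.0, 400)


@dataclass(frozen=True)
class SweepSpec:
    """One sweep scenario with its parameter grids.

    scenario:
        "fig2a"  — survival probability at Delta1 = Delta2 = 1 for an
                   increasing ladder of decay rates;
        "fig2b"  — symmetric (D1 = D2, G1 = G2) vs moderately asymmetric
                   (D1 > D2, G1 > G2) channels;
        "fig2c"  — as fig2b with strongly asymmetric channels;
        "fig3"   — concurrence with G_i = kappa * D_i over the kappa and
                   Delta grids;
        "fig4"   — entanglement of formation on the same grids as fig3.
    kappa: rate-to-splitting ratios Gamma_i / Delta_i (> 0 each).
    deltas: tunnel-splitting grid.
    gammas: explicit decay-rate ladder for the fig2a scenario.
    """

    scenario: str
    alpha: float = np.cos(np.pi / 4)
    beta: float = np.sin(np.pi / 4)
    kappa: Sequence[float] = _DEFAULT_KAPPAS
    deltas: Sequence[float] = _DEFAULT_DELTAS
    gammas: Sequence[float] = (0.05, 0.1, 0.3)
    times: np.ndarray = field(default_factory=_default_times)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if len(self.kappa) == 0 or len(self.deltas) == 0 or len(self.gammas) == 0:
            raise ValueError("parameter grids must be non-empty")
        if any(k <= 0 for k in self.kappa):
            raise ValueError("kappa values must be > 0")


def _rows(state, ch1, ch2, times, scenario, label):
    p = survival_probability(state, ch1, ch2, times)
    c = concurrence_closed_form(state, ch1, ch2, times)
    return pd.DataFrame(
        {
            "scenario": scenario,
            "label": label,
            "delta1": ch1.delta,
            "delta2": ch2.delta,
            "gamma1": ch1.gamma,
            "gamma2": ch2.gamma,
            "t": times,
            "P_survival": p,
            "C": c,
            "EoF": entanglement_of_formation(c),
        }
    )


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run the full factorial sweep of one scenario into a tidy table."""
    state = InitialState(spec.alpha, spec.beta)
    t = np.asarray(spec.times, dtype=float)
    frames: list[pd.DataFrame] = []

    if spec.scenario == "fig2a":
        for g in spec.gammas:
            ch = ChannelParams(delta=1.0, gamma=g)
            frames.append(_rows(state, ch, ch, t, spec.scenario, f"gamma={g}"))
    elif spec.scenario in ("fig2b", "fig2c"):
        ratio = 2.0 if spec.scenario == "fig2b" else 20.0
        g0 = spec.gammas[len(spec.gammas) // 2]
        sym = ChannelParams(delta=1.0, gamma=g0)
        frames.append(_rows(state, sym, sym, t, spec.scenario, "symmetric"))
        ch1 = ChannelParams(delta=1.0 * ratio, gamma=g0 * ratio)
        ch2 = ChannelParams(delta=1.0, gamma=g0)
        frames.append(_rows(state, ch1, ch2, t, spec.scenario, f"asymmetric x{ratio}"))
    else:  # fig3 / fig4: Gamma_i = kappa * Delta_i
        for kappa in spec.kappa:
            for d in spec.deltas:
                ch = ChannelParams(delta=d, gamma=kappa * d)
                frames.append(
                    _rows(state, ch, ch, t, spec.scenario, f"kappa={kappa},delta={d}")
                )

    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class RandomStateFixture:
    """Reproducible random two-qubit density matrices for cross-checks.

    Construction: draw a complex 4x4 matrix A with independent standard
    normal real and imaginary parts and normalize A A^dagger by its trace —
    Hermitian, positive semidefinite, unit trace by construction.
    """

    seed: int
    n_states: int

    def __post_init__(self) -> None:
        if self.n_states <= 0:
            raise ValueError(f"n_states must be > 0, got {self.n_states}")


def generate_random_states(fixture: RandomStateFixture) -> np.ndarray:
    """Generate the fixture's density matrices, shape (n_states, 4, 4)."""
    rng = np.random.default_rng(fixture.seed)
    out = np.empty((fixture.n_states, 4, 4), dtype=complex)
    for i in range(fixture.n_states):
        a = rng.standard_normal((4, 4)) + 1j * rng.standard_normal((4, 4))
        rho = a @ a.conj().T
        out[i] = rho / np.trace(rho).real
    return out


def write_results(
    table: pd.DataFrame,
    path,
    format: str = "csv",
    *,
    metadata: dict | None = None,
) -> Path:
    """Write a sweep table to CSV or JSON; round-trips losslessly.

    CSV: comma-separated, '.' decimal, header row, no index column.
    JSON: {"metadata": {...}, "columns": [...], "data": [[...], ...]}.
    Raises ValueError on an empty table before touching the filesystem.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty results table")
    path = Path(path)
    if format == "csv":
        # %.17g round-trips IEEE doubles exactly
        table.to_csv(path, index=False, float_format="%.17g")
    elif format == "json":
        payload = {
            "metadata": dict(metadata or {}),
            "columns": list(table.columns),
            "data": table.to_numpy().tolist(),
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"format must be 'csv' or 'json', got {format!r}")
    return path
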