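"""Deterministic generators of tiny test assets.

Everything the test suite needs — a 12-cell toy dome, single-cell analytic
decay problems and explicit reference trajectories of the full model — is
regenerated from seeds at run time, so there are no stored binary fixtures
and no hand-entered "expected" concentrations: the reference integrator is
a plain explicit RK4 at small step size, independent of the production
IMEX scheme.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import MeristemGeometry, build_dome_geometry
from .integrator import graph_laplacian
from .model import ModelParameters, ScenarioParameters, reaction_rhs

__all__ = [
    "toy_dome",
    "single_cell_geometry",
    "DecayProblem",
    "single_cell_decay_problem",
    "rk4_reference",
    "generate_fixtures",
]


def toy_dome(seed: int = 0) -> MeristemGeometry:
    """Fixed 12-cell, 3-layer dome (6/4/2 cells) for oracle tests."""
    return build_dome_geometry(n_layers=3, cells_per_layer_profile=(6, 4, 2),
                               competent_depth=2, seed=seed)


def single_cell_geometry(competent: bool = True,
                         anchoring: float = 0.0) -> MeristemGeometry:
    """One isolated cell: the smallest system the kinetics run on."""
    return MeristemGeometry(
        cell_ids=np.array([0]),
        centres=np.zeros((1, 2)),
        edges=np.empty((0, 2), dtype=int),
        layer=np.array([0]),
        competent=np.array([competent]),
        boundary=np.array([True]),
        anchoring=np.array([float(anchoring)]),
        tip_cell=0,
    )


@dataclass(frozen=True)
class DecayProblem:
    """Analytic reference for pure linear decay ``du/dt = -rate * u``."""

    rate: float
    u0: float

    def exact(self, t):
        return self.u0 * np.exp(-self.rate * np.asarray(t, dtype=float))


def single_cell_decay_problem(rate: float, u0: float) -> DecayProblem:
    if rate < 0:
        raise ValueError("decay rate must be nonnegative")
    return DecayProblem(rate=rate, u0=u0)


def rk4_reference(state0: np.ndarray,
                  duration: float,
                  dt: float,
                  params: ModelParameters,
                  scenario: ScenarioParameters,
                  geometry: MeristemGeometry,
                  noise: np.ndarray) -> np.ndarray:
    """Classical explicit RK4 on the full (reaction + diffusion) system.

    Used as the independent accuracy oracle for the IMEX scheme; runs at a
    much smaller step than production simulations and never clips, so it
    must only be applied on horizons where the dynamics stay nonnegative.
    """
    lap = graph_laplacian(geometry)
    drates = params.diffusion_rates()

    def f(u):
        rhs = reaction_rhs(np.clip(u, 0.0, None), params, scenario,
                           geometry, noise)
        for i, d in enumerate(drates):
            if d:
                rhs[i] += d * (lap @ u[i])
        return rhs

    n_steps = int(round(duration / dt))
    u = state0.astype(float).copy()
    for _ in range(n_steps):
        k1 = f(u)
        k2 = f(u + 0.5 * dt * k1)
        k3 = f(u + 0.5 * dt * k2)
        k4 = f(u + dt * k3)
        u = u + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return u


def generate_fixtures(directory: str | Path, seed: int = 0) -> None:
    """Materialize the standard fixtures as plain-text files."""
    from .geometry import save_geometry
    directory = Path(directory)
    save_geometry(toy_dome(seed), directory / "toy_dome")
    save_geometry(build_dome_geometry(seed=seed), directory / "default_dome")
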