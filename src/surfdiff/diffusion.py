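"""Surface-dependent diffusion coefficients and Brownian step generation.

The central data structure is :class:`DiffusionTable`: a default diffusion
coefficient per (species, state) plus optional per-surface overrides. A
molecule's step is always drawn with the coefficient of the surface its panel
belongs to at the *start* of the step; if the step carries it onto another
surface, the new coefficient takes effect from the next step. This start-panel
rule is an Itô-like discretisation with no drift correction, and it is what
produces net accumulation of molecules on slow-diffusion surfaces.

Units: D in µm² s⁻¹, timestep in s, displacements in µm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import SurfaceMesh, SurfacePosition, propagate

__all__ = [
    "DEFAULT_STATE",
    "DiffusionTable",
    "StepSampler",
    "lookup_difc",
    "sample_step",
    "diffuse_molecule",
]

DEFAULT_STATE = "surface"


@dataclass
class DiffusionTable:
    """Default per-(species, state) coefficients plus per-surface exceptions.

    ``defaults[(species, state)] = D`` declares a species; ``overrides[(species,
    state, surface)] = D`` adds an exception for one surface. Lookup returns
    the override when present and the default otherwise, so a table with no
    overrides reduces exactly to a species-indexed table.
    """

    defaults: dict[tuple[str, str], float] = field(default_factory=dict)
    overrides: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def set_default(self, species: str, D: float, state: str = DEFAULT_STATE) -> None:
        if D < 0:
            raise ValueError(f"negative diffusion coefficient for {species}: {D}")
        self.defaults[(species, state)] = float(D)

    def set_override(
        self, surface: str, species: str, D: float, state: str = DEFAULT_STATE
    ) -> None:
        if D < 0:
            raise ValueError(f"negative diffusion coefficient for {species}: {D}")
        if (species, state) not in self.defaults:
            raise KeyError(
                f"surface override for undeclared species/state {species}({state})"
            )
        self.overrides[(species, state, surface)] = float(D)

    def lookup(self, species: str, state: str, surface: str) -> float:
        key = (species, state, surface)
        if key in self.overrides:
            return self.overrides[key]
        try:
            return self.defaults[(species, state)]
        except KeyError:
            raise KeyError(f"undeclared species/state {species}({state})") from None

    def species_states(self) -> list[tuple[str, str]]:
        return sorted(self.defaults)


def lookup_difc(
    table: DiffusionTable, species: str, state: str, surface: str
) -> float:
    """Diffusion coefficient for a species/state on a given surface (µm² s⁻¹)."""
    return table.lookup(species, state, surface)


@dataclass
class StepSampler:
    """Seeded Gaussian step generator at a fixed timestep.

    The same seed and call sequence reproduce the same displacement sequence
    bit for bit; simulations share one sampler consumed in a fixed molecule
    order to make whole runs seed-reproducible.
    """

    seed: int
    dt: float
    rng: np.random.Generator = field(init=False)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.rng = np.random.default_rng(self.seed)

    def sigma(self, D: float) -> float:
        """Per-axis standard deviation sqrt(2·D·dt) of one tangent-plane step."""
        if D < 0:
            raise ValueError("negative diffusion coefficient")
        return math.sqrt(2.0 * D * self.dt)

    def step(self, D: float) -> np.ndarray:
        """One 2-D tangent-plane displacement for coefficient ``D``."""
        s = self.sigma(D)
        z = self.rng.standard_normal(2)
        return z * s

    def steps(self, sigmas: np.ndarray) -> np.ndarray:
        """A batch of displacements, one row per entry of ``sigmas``."""
        z = self.rng.standard_normal((len(sigmas), 2))
        return z * np.asarray(sigmas)[:, None]


def sample_step(sampler: StepSampler, D: float) -> np.ndarray:
    """Draw one Brownian tangent-plane step: N(0, 2·D·dt) per component."""
    return sampler.step(D)


def diffuse_molecule(
    pos: SurfacePosition,
    species: str,
    state: str,
    table: DiffusionTable,
    mesh: SurfaceMesh,
    sampler: StepSampler,
    allow_cross: bool = True,
    max_crossings: int = 1000,
) -> SurfacePosition:
    """Advance one molecule by one timestep.

    D is looked up for the surface of the panel occupied at the step start;
    the step is then carried across the mesh by geodesic unfolding. A surface
    change only affects D from the next step on.
    """
    D = table.lookup(species, state, mesh.surface_of(pos.panel))
    disp = sampler.step(D)
    new_pos, _ = propagate(
        pos, disp, mesh, max_crossings=max_crossings, allow_cross=allow_cross
    )
    return new_pos
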