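"""Built-in scenario generators.

Each generator returns a :class:`~surfdiff.config.Config` for one of the three
validation systems:

* ``two_triangle`` — a flat square split along its diagonal into a "fast" and
  a "slow" triangular surface with a hundredfold diffusion contrast; used for
  single-molecule paths, MSD/anomalous-diffusion analysis and steady-state
  occupancy.
* ``pip`` — PIP2 phosphorylation by membrane-anchored PI3K on the same
  two-triangle plane (3 kinases and 500 PIP2 per triangle); kinases never
  cross between the triangles, substrate crossing is switchable.
* ``spine`` — a parametric spherical spine head with a PSD cap (~10% of the
  head area) and the remainder extrasynaptic membrane; 66 AMPAR with
  D_ESM = 0.45 µm² s⁻¹, optionally 132 immobile scaffold molecules in the PSD
  with a reversible AMPAR–scaffold binding reaction.

Kinetic constants that the underlying studies only cite (PIP2/PI3K catalysis,
scaffold binding) are exposed as parameters with documented defaults; the
scientific claims made about these scenarios are qualitative orderings, not
values of k.
"""

from __future__ import annotations

import math

import numpy as np

from .config import Config, parse, serialize
from .diffusion import DEFAULT_STATE
from .reactions import ReactionDef

__all__ = [
    "scenario_two_triangle",
    "scenario_pip",
    "scenario_spine",
    "make_scenario",
    "SCENARIOS",
]


def _square_triangles(side: float) -> tuple[tuple, tuple]:
    """Two coplanar triangles forming a [0, side]² square split by its diagonal."""
    fast = (0.0, 0.0, 0.0, side, 0.0, 0.0, side, side, 0.0)
    slow = (0.0, 0.0, 0.0, side, side, 0.0, 0.0, side, 0.0)
    return fast, slow


def scenario_two_triangle(
    D_fast: float = 0.45,
    D_slow: float | None = None,
    n_molecules: int = 1,
    crossing: bool = True,
    side: float = 1.0,
    time_stop: float = 100.0,
    time_step: float = 1e-3,
    output_interval: int = 100,
    seed: int = 0,
    start_surface: str = "fast",
) -> Config:
    """Tracer diffusion on the heterogeneous two-triangle plane.

    ``D_slow`` defaults to ``D_fast / 100`` (the hundredfold contrast). With
    ``crossing=False`` the tracer is confined, making the shared diagonal a
    reflective edge for it. ``start_surface`` may be ``fast``, ``slow`` or
    ``split`` (half on each).
    """
    if D_slow is None:
        D_slow = D_fast / 100.0
    fast, slow = _square_triangles(side)
    placements: list[tuple[int, str, str]] = []
    if start_surface == "split":
        placements.append((n_molecules // 2, "T", "fast"))
        placements.append((n_molecules - n_molecules // 2, "T", "slow"))
    elif start_surface in ("fast", "slow"):
        placements.append((n_molecules, "T", start_surface))
    else:
        raise ValueError("start_surface must be 'fast', 'slow' or 'split'")
    return Config(
        species=("T",),
        difc=(("T", DEFAULT_STATE, D_fast),),
        surface_difc=(("slow", "T", DEFAULT_STATE, D_slow),),
        surfaces=(("fast", (fast,)), ("slow", (slow,))),
        placements=tuple(placements),
        confined=() if crossing else ("T",),
        time_stop=time_stop,
        time_step=time_step,
        random_seed=seed,
        output_interval=output_interval,
        outputs=(("counts", "counts.tsv"), ("trajectory", "T", "traj.tsv")),
    )


def scenario_pip(
    k_cat: float = 0.01,
    crossing: bool = False,
    D_fast: float = 0.01,
    D_slow: float | None = None,
    D_kinase: float = 0.0,
    n_pip2: int = 500,
    n_kinase: int = 3,
    side: float = 1.0,
    time_stop: float = 30.0,
    time_step: float = 1e-3,
    output_interval: int = 100,
    seed: int = 0,
) -> Config:
    """Surface phosphorylation PIP2 + PI3K → PIP3 + PI3K on the split plane.

    ``k_cat`` (µm² s⁻¹) is the macroscopic bimolecular rate; the default
    places the reaction in the diffusion-influenced regime on the slow
    triangle (where the 2-D diffusion-limited ceiling bites) while staying
    reaction-limited on the fast one, which is the regime in which the fast
    surface out-produces the slow one. Kinases are always confined to their
    triangle; with ``crossing=False`` the phosphoinositides are confined too.
    """
    if D_slow is None:
        D_slow = D_fast / 100.0
    fast, slow = _square_triangles(side)
    confined = ["PI3K"] if crossing else ["PI3K", "PIP2", "PIP3"]
    return Config(
        species=("PIP2", "PIP3", "PI3K"),
        difc=(
            ("PIP2", DEFAULT_STATE, D_fast),
            ("PIP3", DEFAULT_STATE, D_fast),
            ("PI3K", DEFAULT_STATE, D_kinase),
        ),
        surface_difc=(
            ("slow", "PIP2", DEFAULT_STATE, D_slow),
            ("slow", "PIP3", DEFAULT_STATE, D_slow),
        ),
        surfaces=(("fast", (fast,)), ("slow", (slow,))),
        reactions=(
            ReactionDef(
                "phos",
                2,
                [("PIP2", DEFAULT_STATE), ("PI3K", DEFAULT_STATE)],
                [("PIP3", DEFAULT_STATE), ("PI3K", DEFAULT_STATE)],
                k_cat,
            ),
        ),
        placements=(
            (n_pip2, "PIP2", "fast"),
            (n_pip2, "PIP2", "slow"),
            (n_kinase, "PI3K", "fast"),
            (n_kinase, "PI3K", "slow"),
        ),
        confined=tuple(confined),
        time_stop=time_stop,
        time_step=time_step,
        random_seed=seed,
        output_interval=output_interval,
        outputs=(("counts", "counts.tsv"),),
    )


def _spine_head_triangles(
    radius: float,
    theta_neck_deg: float,
    theta_psd_deg: float,
    n_theta: int,
    n_phi: int,
) -> tuple[list, list[str]]:
    """Lat–long triangulation of a spherical cap head with a PSD polar cap.

    The head is the sphere surface with polar angle θ in [0, θ_neck]; the rim
    at θ_neck is the (open, reflective) neck. Panels whose centroid has
    θ < θ_psd are labelled ``psd``, the rest ``esm``. Shared vertices are
    computed once so edge adjacency matches exactly.
    """
    th_neck = math.radians(theta_neck_deg)
    th_psd = math.radians(theta_psd_deg)
    thetas = np.linspace(0.0, th_neck, n_theta + 1)
    phis = np.linspace(0.0, 2.0 * math.pi, n_phi, endpoint=False)

    def vert(th: float, ph: float) -> tuple[float, float, float]:
        return (
            radius * math.sin(th) * math.cos(ph),
            radius * math.sin(th) * math.sin(ph),
            radius * math.cos(th),
        )

    grid = [[vert(th, ph) for ph in phis] for th in thetas]
    pole = (0.0, 0.0, radius)
    tris: list = []
    labels: list[str] = []

    def add(a, b, c):
        th_c = math.acos(
            min(max((a[2] + b[2] + c[2]) / (3.0 * radius), -1.0), 1.0)
        )
        tris.append([a, b, c])
        labels.append("psd" if th_c < th_psd else "esm")

    for j in range(n_phi):
        j2 = (j + 1) % n_phi
        add(pole, grid[1][j], grid[1][j2])
    for i in range(1, n_theta):
        for j in range(n_phi):
            j2 = (j + 1) % n_phi
            a, b = grid[i][j], grid[i][j2]
            c, d = grid[i + 1][j], grid[i + 1][j2]
            add(a, c, b)
            add(b, c, d)
    return tris, labels


def scenario_spine(
    D_psd: float = 0.45,
    with_scaffold: bool = False,
    D_esm: float = 0.45,
    n_ampar: int = 66,
    n_scaffold: int = 132,
    k_on: float = 0.02,
    k_off: float = 0.01,
    pgem: float = 0.2,
    radius: float = 0.5,
    theta_neck_deg: float = 150.0,
    theta_psd_deg: float = 35.0,
    n_theta: int = 10,
    n_phi: int = 14,
    time_stop: float = 20.0,
    time_step: float = 1e-3,
    output_interval: int = 100,
    seed: int = 0,
) -> Config:
    """AMPAR on a spherical spine head with a PSD cap.

    The default geometry (head radius 0.5 µm, neck opening at 150° polar
    angle, PSD cap at 35°) puts the PSD at roughly 10% of the head area.
    Without scaffolds, trapping is purely diffusive via the ``surface_difc``
    override at the PSD. With scaffolds, 132 immobile scaffold molecules are
    scattered in the PSD and AMPAR binds them reversibly
    (AMPAR + Scaffold ⇌ AMPAR_Scaffold, on-rate ``k_on`` µm² s⁻¹, off-rate
    ``k_off`` s⁻¹, geminate-recombination probability ``pgem``); the bound
    complex is immobile.
    """
    tris, labels = _spine_head_triangles(
        radius, theta_neck_deg, theta_psd_deg, n_theta, n_phi
    )
    psd_tris = tuple(
        tuple(v for p in t for v in p) for t, l in zip(tris, labels) if l == "psd"
    )
    esm_tris = tuple(
        tuple(v for p in t for v in p) for t, l in zip(tris, labels) if l == "esm"
    )
    species = ["AMPAR"]
    difc: list[tuple[str, str, float]] = [("AMPAR", DEFAULT_STATE, D_esm)]
    reactions: list[ReactionDef] = []
    reversible: tuple = ()
    placements: list[tuple[int, str, str]] = [(n_ampar, "AMPAR", "esm")]
    if with_scaffold:
        species += ["Scaffold", "AMPAR_Scaffold"]
        difc += [
            ("Scaffold", DEFAULT_STATE, 0.0),
            ("AMPAR_Scaffold", DEFAULT_STATE, 0.0),
        ]
        reactions = [
            ReactionDef(
                "bind",
                2,
                [("AMPAR", DEFAULT_STATE), ("Scaffold", DEFAULT_STATE)],
                [("AMPAR_Scaffold", DEFAULT_STATE)],
                k_on,
            ),
            ReactionDef(
                "unbind",
                1,
                [("AMPAR_Scaffold", DEFAULT_STATE)],
                [("AMPAR", DEFAULT_STATE), ("Scaffold", DEFAULT_STATE)],
                k_off,
                reversible_partner="bind",
                pgem=pgem,
            ),
        ]
        reversible = (("bind", "unbind", pgem),)
        placements.append((n_scaffold, "Scaffold", "psd"))
    return Config(
        species=tuple(species),
        difc=tuple(difc),
        surface_difc=(("psd", "AMPAR", DEFAULT_STATE, D_psd),),
        surfaces=(("psd", psd_tris), ("esm", esm_tris)),
        reactions=tuple(reactions),
        reversible=reversible,
        placements=tuple(placements),
        time_stop=time_stop,
        time_step=time_step,
        random_seed=seed,
        output_interval=output_interval,
        outputs=(("counts", "counts.tsv"), ("trajectory", "AMPAR", "traj.tsv")),
    )


SCENARIOS = {
    "two_triangle": scenario_two_triangle,
    "pip": scenario_pip,
    "spine": scenario_spine,
}


def make_scenario(name: str, **params) -> Config:
    """Dispatch by scenario name with keyword parameters (used by the CLI)."""
    try:
        fn = SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        ) from None
    return fn(**params)
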