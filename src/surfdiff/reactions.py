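"""Surface reactions and the calibration of their microscopic parameters.

Bimolecular reactions are executed Smoluchowski-style: at each timestep every
reactant pair closer than a *binding radius* σ_b reacts. σ_b is calibrated so
that the simulated well-mixed rate reproduces a requested macroscopic rate
constant k (µm² s⁻¹ for reactions between surface-bound species). The
calibration uses a deterministic radially symmetric propagation of the pair
separation distribution: each step convolves the radial density with the 2-D
Gaussian step kernel, absorbs everything inside σ_b, and holds an outer
reservoir at the bulk density; the steady-state absorbed flux is the effective
rate, and σ_b is found by root finding.

Because both reactants may sit on surfaces with different diffusion
coefficients, the mutual diffusion coefficient — and hence σ_b — is computed
per surface (and per ordered surface pair for reactants straddling an edge).
This per-surface derivation of reaction parameters is the point of the whole
exercise: a slow surface needs a larger binding radius to realise the same k.

In two dimensions the diffusion-limited rate is bounded (it grows only
logarithmically with the capture radius), so a requested k can be unachievable
at a given (D, dt); :func:`binding_radius_from_rate` then raises and reports
the achievable maximum, and table construction clamps to it with a warning.

Reversible reactions place their dissociation products an *unbinding radius*
σ_u apart, calibrated with the same radial machinery so that the probability
of geminate recombination (re-entering σ_b before escaping past a documented
cutoff radius) equals a requested ``pgem``.

All radial calculations are done in reduced units of the per-axis rms mutual
step s = sqrt(2·D_mutual·dt); the reduced binding radius depends only on the
reduced rate κ = k/(2·D_mutual), which makes caching effective.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from scipy.special import ive

from .diffusion import DEFAULT_STATE, DiffusionTable
from .geometry import SurfaceMesh, SurfacePosition, from_world, propagate, to_world

__all__ = [
    "CalibrationError",
    "UnachievableRateError",
    "CalibrationSettings",
    "ReactionDef",
    "ReactionTable",
    "unimolecular_prob",
    "binding_radius_from_rate",
    "unbinding_radius_from_pgem",
    "compute_reaction_tables",
    "apply_bimolecular",
    "place_products_apart",
]


class CalibrationError(RuntimeError):
    """Radial calibration failed to converge or the target is out of range."""


class UnachievableRateError(CalibrationError):
    """Requested rate exceeds the diffusion-limited maximum at this (D, dt)."""

    def __init__(self, k: float, k_max: float):
        super().__init__(
            f"rate {k:g} µm²/s is unachievable at this D and dt; "
            f"maximum achievable is {k_max:g} µm²/s"
        )
        self.k = k
        self.k_max = k_max


@dataclass(frozen=True)
class CalibrationSettings:
    """Numerical settings of the radial propagation, in reduced units of s.

    ``r_max`` is the outer cutoff: the bulk reservoir sits in the outermost
    ``reservoir`` band for rate calibration, and separations beyond ``r_max``
    count as escaped for geminate recombination. Grid sizes trade accuracy for
    the cost of one dense linear solve per evaluation.
    """

    r_max: float = 16.0
    reservoir: float = 3.0
    n_inner: int = 64
    n_mid: int = 560
    n_outer: int = 256
    rho_tol: float = 1e-5


_DEFAULT_SETTINGS = CalibrationSettings()


def _radial_grid(rho: float, st: CalibrationSettings) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quadrature grid split at the capture radius, where the density jumps.

    The node at ``rho`` is duplicated — once as the last absorber node, once
    as the first free node — so the trapezoid rule never integrates across
    the discontinuity. Returns ``(r, weights, absorber_mask)``.
    """
    lo = max(rho, 1e-9)
    mid_hi = min(lo + 5.0, st.r_max - st.reservoir)
    r_abs = np.linspace(0.0, lo, st.n_inner + 1)
    r_free = np.concatenate(
        [
            np.linspace(lo, mid_hi, st.n_mid, endpoint=False),
            np.linspace(mid_hi, st.r_max, st.n_outer + 1),
        ]
    )
    r = np.concatenate([r_abs, r_free])
    w = np.concatenate([_trapezoid_weights(r_abs), _trapezoid_weights(r_free)])
    absorber = np.zeros(len(r), dtype=bool)
    absorber[: len(r_abs)] = True
    return r, w, absorber


def _trapezoid_weights(r: np.ndarray) -> np.ndarray:
    w = np.zeros_like(r)
    w[1:] += 0.5 * np.diff(r)
    w[:-1] += 0.5 * np.diff(r)
    return w


def _step_kernel(r: np.ndarray) -> np.ndarray:
    """K[i, j] = T(r_i | r_j): radial density after one unit-variance 2-D step.

    T(r|r') = r · exp(-(r-r')²/2) · ive(0, r·r'); integrates to 1 over r.
    """
    ri = r[:, None]
    rj = r[None, :]
    return ri * np.exp(-0.5 * (ri - rj) ** 2) * ive(0, ri * rj)


def _reduced_rate(rho: float, st: CalibrationSettings) -> float:
    """Steady-state absorbed flux per step for a capture disk of radius ``rho``.

    Bulk density is 1 per unit area, held fixed in the outer reservoir band;
    the returned flux equals k·dt/s² for the physical problem.
    """
    r, w, absorber = _radial_grid(rho, st)
    K = _step_kernel(r) * w[None, :]
    res = ~absorber & (r >= st.r_max - st.reservoir)
    free = ~(absorber | res)
    h_res = 2.0 * math.pi * r[res]
    A = K[np.ix_(free, free)]
    b = K[np.ix_(free, res)] @ h_res
    h_free = np.linalg.solve(np.eye(A.shape[0]) - A, b)
    h_in = K[np.ix_(absorber, free)] @ h_free + K[np.ix_(absorber, res)] @ h_res
    return float(h_in @ w[absorber])


@lru_cache(maxsize=512)
def _rho_from_kappa(kappa: float, st: CalibrationSettings = _DEFAULT_SETTINGS) -> float:
    """Reduced binding radius with reduced rate ``kappa`` = k/(2·D_mutual)."""
    if kappa <= 0.0:
        return 0.0
    rho_hi = st.r_max - st.reservoir - 1.0
    kappa_max = _reduced_rate(rho_hi, st)
    if kappa > kappa_max:
        raise UnachievableRateError(kappa, kappa_max)
    # πρ² is exact in the reaction-limited regime; a safe lower bracket.
    rho_lo = min(0.5 * math.sqrt(kappa / math.pi), rho_hi)
    while rho_lo > 1e-12 and _reduced_rate(rho_lo, st) > kappa:
        rho_lo *= 0.5
    return float(
        brentq(
            lambda rho: _reduced_rate(rho, st) - kappa,
            rho_lo,
            rho_hi,
            xtol=st.rho_tol,
            rtol=1e-6,
            maxiter=200,
        )
    )


@lru_cache(maxsize=256)
def _capture_profile(
    rho_b: float, st: CalibrationSettings = _DEFAULT_SETTINGS
):
    """Probability of eventual capture (before escaping past r_max) vs start radius.

    Solves the discrete backward equation c(r') = a(r') + ∫ T(r|r') c(r) dr on
    the free region in one dense solve; returns (radii, capture probability)
    for interpolation.
    """
    r, w, absorber = _radial_grid(rho_b, st)
    T = _step_kernel(r)  # T[i, j] = T(r_i | r_j)
    free = ~absorber
    a = (w[absorber] @ T[np.ix_(absorber, free)]).ravel()
    B = (T[np.ix_(free, free)] * w[free, None]).T
    c = np.linalg.solve(np.eye(B.shape[0]) - B, a)
    return r[free], np.clip(c, 0.0, 1.0)


def unimolecular_prob(k: float, dt: float) -> float:
    """Per-step reaction probability 1 − exp(−k·dt) for a first-order channel."""
    if k < 0:
        raise ValueError("rate constant must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return -math.expm1(-k * dt)


def binding_radius_from_rate(
    k: float,
    D_mutual: float,
    dt: float,
    settings: CalibrationSettings = _DEFAULT_SETTINGS,
) -> float:
    """Binding radius σ_b (µm) reproducing macroscopic rate k (µm² s⁻¹).

    Raises :class:`UnachievableRateError` when k exceeds the diffusion-limited
    maximum at this (D_mutual, dt); the exception carries the achievable value.
    """
    if k < 0:
        raise ValueError("rate constant must be non-negative")
    if k == 0.0:
        return 0.0
    if D_mutual <= 0:
        raise ValueError("D_mutual must be positive for a nonzero rate")
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = math.sqrt(2.0 * D_mutual * dt)
    kappa = k / (2.0 * D_mutual)
    try:
        rho = _rho_from_kappa(kappa, settings)
    except UnachievableRateError as err:
        raise UnachievableRateError(k, err.k_max * 2.0 * D_mutual) from None
    return rho * s


def max_achievable_rate(
    D_mutual: float, dt: float, settings: CalibrationSettings = _DEFAULT_SETTINGS
) -> tuple[float, float]:
    """(k_max, σ_b at k_max) for the diffusion-limited ceiling at this (D, dt)."""
    s = math.sqrt(2.0 * D_mutual * dt)
    rho_hi = settings.r_max - settings.reservoir - 1.0
    kappa_max = _reduced_rate(rho_hi, settings)
    return kappa_max * 2.0 * D_mutual, rho_hi * s


def unbinding_radius_from_pgem(
    pgem: float,
    sigma_b: float,
    D_mutual: float,
    dt: float,
    settings: CalibrationSettings = _DEFAULT_SETTINGS,
) -> float:
    """Unbinding radius σ_u (µm) with geminate-recombination probability pgem.

    A product pair released at separation σ_u re-enters σ_b (before escaping
    past the cutoff radius of ``settings``) with probability pgem, as computed
    by the same deterministic radial propagation used for σ_b.
    """
    if not 0.0 <= pgem < 1.0:
        raise ValueError("pgem must lie in [0, 1)")
    if sigma_b <= 0:
        raise ValueError("sigma_b must be positive")
    if D_mutual <= 0 or dt <= 0:
        raise ValueError("D_mutual and dt must be positive")
    s = math.sqrt(2.0 * D_mutual * dt)
    rho_b = sigma_b / s
    radii, cap = _capture_profile(rho_b, settings)
    usable = radii >= rho_b
    radii, cap = radii[usable], cap[usable]
    if pgem >= cap[0]:
        # more recombination than contact itself yields: release at contact
        return sigma_b
    if pgem < cap[-1]:
        raise CalibrationError(
            f"pgem={pgem:g} below the minimum {cap[-1]:.3g} reachable inside "
            f"the escape cutoff r_max={settings.r_max:g} reduced units"
        )
    # capture probability is monotone decreasing in the start radius
    idx = np.searchsorted(-cap, -pgem)
    i0 = max(idx - 1, 0)
    i1 = min(idx, len(cap) - 1)
    if cap[i0] == cap[i1]:
        rho_u = radii[i1]
    else:
        f = (pgem - cap[i0]) / (cap[i1] - cap[i0])
        rho_u = radii[i0] + f * (radii[i1] - radii[i0])
    return float(max(rho_u, rho_b)) * s


# -- reaction definitions and per-surface tables ------------------------------


@dataclass
class ReactionDef:
    """One reaction channel.

    ``order`` 0 creates products at rate k (µm⁻² s⁻¹) per unit area; order 1
    converts its single reactant at rate k (s⁻¹); order 2 fires on reactant
    pairs within the calibrated binding radius, with k in µm² s⁻¹. A reverse
    channel of a reversible pair names its forward partner, whose binding
    radius anchors the unbinding radius via ``pgem`` (default 0.2).
    """

    name: str
    order: int
    reactants: list[tuple[str, str]]
    products: list[tuple[str, str]]
    rate: float
    reversible_partner: str | None = None
    pgem: float | None = None

    def __post_init__(self) -> None:
        if self.order not in (0, 1, 2):
            raise ValueError(f"reaction {self.name}: order must be 0, 1 or 2")
        if self.rate < 0:
            raise ValueError(f"reaction {self.name}: negative rate")
        if len(self.reactants) != self.order and self.order < 2:
            raise ValueError(f"reaction {self.name}: wrong reactant count")
        if self.order == 2 and len(self.reactants) != 2:
            raise ValueError(f"reaction {self.name}: order 2 needs two reactants")


DEFAULT_PGEM = 0.2


@dataclass
class ReactionTable:
    """Per-reaction, per-surface runtime parameters derived from the rates."""

    dt: float
    binding_radius: dict[tuple[str, str, str], float] = field(default_factory=dict)
    unbinding_radius: dict[tuple[str, str], float] = field(default_factory=dict)
    prob: dict[str, float] = field(default_factory=dict)
    zeroth_mean: dict[tuple[str, str], float] = field(default_factory=dict)
    max_binding_radius: dict[str, float] = field(default_factory=dict)

    def sigma_b(self, reaction: str, surf1: str, surf2: str) -> float:
        return self.binding_radius[(reaction, surf1, surf2)]


def _mutual_D(
    table: DiffusionTable,
    r1: tuple[str, str],
    r2: tuple[str, str],
    surf1: str,
    surf2: str,
) -> float:
    return table.lookup(r1[0], r1[1], surf1) + table.lookup(r2[0], r2[1], surf2)


def compute_reaction_tables(
    reactions: list[ReactionDef],
    diffusion_table: DiffusionTable,
    mesh: SurfaceMesh,
    dt: float,
    settings: CalibrationSettings = _DEFAULT_SETTINGS,
) -> ReactionTable:
    """Derive σ_b / σ_u / probabilities for every reaction on every surface.

    For an order-2 reaction the mutual diffusion coefficient on each ordered
    surface pair is the sum of the reactants' per-surface coefficients, so the
    binding radius differs between surfaces whenever an override does. A rate
    above the 2-D diffusion-limited ceiling is clamped to the achievable
    radius with a warning rather than rejected: the effective on-rate then
    degrades, which is the physically expected behaviour of a (nearly) frozen
    reactant.
    """
    out = ReactionTable(dt=dt)
    surfaces = mesh.surface_names
    by_name = {r.name: r for r in reactions}
    for rxn in reactions:
        if rxn.order == 0:
            for s in surfaces:
                out.zeroth_mean[(rxn.name, s)] = rxn.rate * mesh.surface_area[s] * dt
        elif rxn.order == 1:
            out.prob[rxn.name] = unimolecular_prob(rxn.rate, dt)
        else:
            r1, r2 = rxn.reactants
            smax = 0.0
            for s1 in surfaces:
                for s2 in surfaces:
                    Dm = _mutual_D(diffusion_table, r1, r2, s1, s2)
                    if rxn.rate == 0.0 or Dm <= 0.0:
                        sb = 0.0
                        if rxn.rate > 0.0 and Dm <= 0.0:
                            warnings.warn(
                                f"reaction {rxn.name}: both reactants immobile on "
                                f"({s1}, {s2}); no binding possible"
                            )
                    else:
                        try:
                            sb = binding_radius_from_rate(rxn.rate, Dm, dt, settings)
                        except UnachievableRateError as err:
                            k_max, sb = max_achievable_rate(Dm, dt, settings)
                            warnings.warn(
                                f"reaction {rxn.name} on ({s1}, {s2}): requested "
                                f"k={rxn.rate:g} exceeds achievable {k_max:g} "
                                f"µm²/s; binding radius clamped"
                            )
                    out.binding_radius[(rxn.name, s1, s2)] = sb
                    smax = max(smax, sb)
            out.max_binding_radius[rxn.name] = smax
    # Unbinding radii for reverse channels, anchored to the forward σ_b.
    for rxn in reactions:
        if rxn.reversible_partner is None:
            continue
        fwd = by_name.get(rxn.reversible_partner)
        if fwd is None or fwd.order != 2:
            raise ValueError(
                f"reaction {rxn.name}: reversible partner "
                f"{rxn.reversible_partner!r} is not a declared order-2 reaction"
            )
        pgem = rxn.pgem if rxn.pgem is not None else DEFAULT_PGEM
        r1, r2 = fwd.reactants
        for s in surfaces:
            sb = out.binding_radius[(fwd.name, s, s)]
            Dm = _mutual_D(diffusion_table, r1, r2, s, s)
            if sb <= 0.0 or Dm <= 0.0:
                out.unbinding_radius[(rxn.name, s)] = 0.0
            else:
                out.unbinding_radius[(rxn.name, s)] = unbinding_radius_from_pgem(
                    pgem, sb, Dm, dt, settings
                )
    return out


# -- pair execution -----------------------------------------------------------


def _project_to_panel(point: np.ndarray, panel: int, mesh: SurfaceMesh) -> SurfacePosition:
    """Project a 3-D point onto a panel's plane and clamp it into the triangle."""
    pos = from_world(point, panel, mesh)
    xy = np.array(pos.xy)
    if mesh.contains_local(panel, xy):
        return pos
    # barycentric clamp
    a, b, c = mesh.local[panel]
    T = np.column_stack([b - a, c - a])
    lam = np.linalg.solve(T, xy - a)
    l1, l2 = float(lam[0]), float(lam[1])
    l0 = 1.0 - l1 - l2
    lam3 = np.clip([l0, l1, l2], 0.0, None)
    lam3 = lam3 / lam3.sum()
    xy = lam3[0] * a + lam3[1] * b + lam3[2] * c
    return SurfacePosition(panel, (float(xy[0]), float(xy[1])))


def place_products_apart(
    pos: SurfacePosition,
    sigma_u: float,
    mesh: SurfaceMesh,
    rng: np.random.Generator,
    allow_cross: bool = True,
) -> tuple[SurfacePosition, SurfacePosition]:
    """Positions for a dissociating pair, σ_u apart along a random tangent axis."""
    theta = rng.random() * 2.0 * math.pi
    d = np.array([math.cos(theta), math.sin(theta)]) * (0.5 * sigma_u)
    p1, _ = propagate(pos, d, mesh, allow_cross=allow_cross)
    p2, _ = propagate(pos, -d, mesh, allow_cross=allow_cross)
    return p1, p2


def apply_bimolecular(store, reaction: ReactionDef, table: ReactionTable,
                      mesh: SurfaceMesh, rng: np.random.Generator) -> int:
    """Fire one order-2 channel on all eligible pairs; returns the event count.

    Candidate pairs are those whose 3-D separation is within the binding
    radius of their (ordered) surface pair. Pairs are processed in ascending
    separation (ties by molecule ids); a molecule consumed by an earlier event
    is skipped, so each molecule reacts at most once per step.
    """
    sp1, st1 = reaction.reactants[0]
    sp2, st2 = reaction.reactants[1]
    smax = table.max_binding_radius.get(reaction.name, 0.0)
    if smax <= 0.0:
        return 0
    idx1 = store.indices_of(sp1, st1)
    idx2 = store.indices_of(sp2, st2)
    if idx1.size == 0 or idx2.size == 0:
        return 0
    pos1 = store.world_positions(idx1)
    same = (sp1, st1) == (sp2, st2)
    if same:
        tree = cKDTree(pos1)
        raw = tree.query_pairs(smax, output_type="ndarray")
        cand = np.column_stack([idx1[raw[:, 0]], idx1[raw[:, 1]]])
    else:
        pos2 = store.world_positions(idx2)
        raw = cKDTree(pos1).query_ball_tree(cKDTree(pos2), smax)
        pairs = [(i, j) for i, row in enumerate(raw) for j in row]
        if not pairs:
            return 0
        raw = np.asarray(pairs, dtype=np.int64)
        cand = np.column_stack([idx1[raw[:, 0]], idx2[raw[:, 1]]])
    if cand.shape[0] == 0:
        return 0
    pa = store.world_positions(cand[:, 0])
    pb = store.world_positions(cand[:, 1])
    dist = np.linalg.norm(pa - pb, axis=1)
    ids_a = store.ids[cand[:, 0]]
    ids_b = store.ids[cand[:, 1]]
    order = np.lexsort((ids_b, ids_a, dist))
    events = 0
    surf_names = mesh.surface_names
    for n in order:
        i, j = int(cand[n, 0]), int(cand[n, 1])
        if not (store.alive[i] and store.alive[j]):
            continue
        s1 = surf_names[mesh.surface_of_panel[store.panel[i]]]
        s2 = surf_names[mesh.surface_of_panel[store.panel[j]]]
        if dist[n] > table.binding_radius[(reaction.name, s1, s2)]:
            continue
        _fire_pair(store, reaction, table, mesh, rng, i, j, pa[n], pb[n])
        events += 1
    return events


def _fire_pair(store, reaction, table, mesh, rng, i, j, xa, xb) -> None:
    store.kill(i)
    store.kill(j)
    if not reaction.products:
        return
    mid = 0.5 * (xa + xb)
    anchor = _project_to_panel(mid, int(store.panel[i]), mesh)
    if len(reaction.products) == 1:
        sp, stt = reaction.products[0]
        store.add(sp, stt, anchor)
    else:
        sigma_u = table.unbinding_radius.get((reaction.name, ""), 0.0)
        positions = [anchor, _project_to_panel(mid, int(store.panel[j]), mesh)]
        if sigma_u > 0.0:
            positions = list(place_products_apart(anchor, sigma_u, mesh, rng))
        for (sp, stt), p in zip(reaction.products, positions):
            store.add(sp, stt, p)
        for extra in reaction.products[2:]:
            store.add(extra[0], extra[1], anchor)
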