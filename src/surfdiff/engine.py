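"""Fixed-timestep simulation loop with seeded determinism.

Each step executes, in this fixed order: zeroth-order creations, first-order
conversions, diffusion of every molecule in ascending-id order, bimolecular
reactions, then observers when due. A single seeded generator is consumed in
exactly this order, so two runs with equal configuration and seed produce
byte-identical output files. Molecules created earlier in a step do diffuse in
the same step's diffusion phase. Simulated time is accumulated by step count
(``t = t0 + n·dt``), never by floating-point addition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .diffusion import DEFAULT_STATE, DiffusionTable
from .geometry import (
    SurfaceMesh,
    SurfacePosition,
    PropagationError,
    _kernel,
    _NO_REC,
)
from .reactions import (
    CalibrationSettings,
    ReactionDef,
    ReactionTable,
    apply_bimolecular,
    compute_reaction_tables,
    place_products_apart,
)

__all__ = [
    "Molecule",
    "MoleculeStore",
    "CountSeries",
    "TrajectoryRecord",
    "Simulation",
]


@dataclass(frozen=True)
class Molecule:
    """Snapshot view of one molecule (ids are unique and never reused)."""

    id: int
    species: str
    state: str
    position: SurfacePosition


class MoleculeStore:
    """Array-of-columns store for the live molecule population.

    Rows are append-only within a run; removal marks ``alive`` False and the
    arrays are compacted periodically. Row order is ascending creation id,
    which fixes the iteration (and RNG-consumption) order everywhere.
    """

    _CHUNK = 1024

    def __init__(self, mesh: SurfaceMesh):
        self.mesh = mesh
        self._n = 0
        self._next_id = 0
        cap = self._CHUNK
        self.ids = np.zeros(cap, dtype=np.int64)
        self.species = np.zeros(cap, dtype=np.int32)
        self.state = np.zeros(cap, dtype=np.int32)
        self.panel = np.zeros(cap, dtype=np.int64)
        self.x = np.zeros(cap)
        self.y = np.zeros(cap)
        self.alive = np.zeros(cap, dtype=bool)
        self._species_names: list[str] = []
        self._state_names: list[str] = []
        self._species_idx: dict[str, int] = {}
        self._state_idx: dict[str, int] = {}

    # -- registry ------------------------------------------------------------

    def species_code(self, name: str) -> int:
        if name not in self._species_idx:
            self._species_idx[name] = len(self._species_names)
            self._species_names.append(name)
        return self._species_idx[name]

    def state_code(self, name: str) -> int:
        if name not in self._state_idx:
            self._state_idx[name] = len(self._state_names)
            self._state_names.append(name)
        return self._state_idx[name]

    @property
    def species_names(self) -> list[str]:
        return list(self._species_names)

    # -- mutation ------------------------------------------------------------

    def _grow(self) -> None:
        cap = len(self.ids)
        if self._n < cap:
            return
        new = max(cap * 2, self._CHUNK)
        for name in ("ids", "species", "state", "panel", "x", "y", "alive"):
            arr = getattr(self, name)
            ext = np.zeros(new, dtype=arr.dtype)
            ext[:cap] = arr
            setattr(self, name, ext)

    def add(self, species: str, state: str, pos: SurfacePosition) -> int:
        self._grow()
        i = self._n
        self.ids[i] = self._next_id
        self.species[i] = self.species_code(species)
        self.state[i] = self.state_code(state)
        self.panel[i] = pos.panel
        self.x[i] = pos.xy[0]
        self.y[i] = pos.xy[1]
        self.alive[i] = True
        self._n += 1
        self._next_id += 1
        return int(self.ids[i])

    def kill(self, row: int) -> None:
        self.alive[row] = False

    def compact(self) -> None:
        keep = np.flatnonzero(self.alive[: self._n])
        n = keep.size
        for name in ("ids", "species", "state", "panel", "x", "y", "alive"):
            arr = getattr(self, name)
            arr[:n] = arr[keep]
            setattr(self, name, arr)
        self._n = n

    # -- queries -------------------------------------------------------------

    def live_rows(self) -> np.ndarray:
        return np.flatnonzero(self.alive[: self._n])

    def indices_of(self, species: str, state: str | None = None) -> np.ndarray:
        sel = self.alive[: self._n] & (
            self.species[: self._n] == self._species_idx.get(species, -1)
        )
        if state is not None:
            sel &= self.state[: self._n] == self._state_idx.get(state, -1)
        return np.flatnonzero(sel)

    def world_positions(self, rows) -> np.ndarray:
        rows = np.asarray(rows)
        p = self.panel[rows]
        m = self.mesh
        return (
            m.origin[p]
            + self.x[rows, None] * m.e1[p]
            + self.y[rows, None] * m.e2[p]
        )

    def n_alive(self) -> int:
        return int(self.alive[: self._n].sum())

    def molecule(self, row: int) -> Molecule:
        return Molecule(
            id=int(self.ids[row]),
            species=self._species_names[self.species[row]],
            state=self._state_names[self.state[row]],
            position=SurfacePosition(
                int(self.panel[row]), (float(self.x[row]), float(self.y[row]))
            ),
        )


# -- observers ----------------------------------------------------------------


class CountSeries:
    """Per-surface molecule counts sampled on the observer cadence."""

    def __init__(self) -> None:
        self.rows: list[tuple[float, str, str, int]] = []

    def record(self, time: float, store: MoleculeStore) -> None:
        mesh = store.mesh
        live = store.live_rows()
        surf = mesh.surface_of_panel[store.panel[live]]
        spec = store.species[live]
        n_s = len(store.species_names)
        n_f = len(mesh.surface_names)
        counts = np.zeros((n_s, n_f), dtype=np.int64)
        np.add.at(counts, (spec, surf), 1)
        for si, sname in enumerate(store.species_names):
            for fi, fname in enumerate(mesh.surface_names):
                self.rows.append((time, sname, fname, int(counts[si, fi])))

    def frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows, columns=["time", "species", "surface", "count"])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("time\tspecies\tsurface\tcount\n")
            for t, sp, sf, c in self.rows:
                fh.write(f"{t:.9g}\t{sp}\t{sf}\t{c}\n")


class TrajectoryRecord:
    """3-D positions of selected molecules sampled on the observer cadence."""

    def __init__(self, species: str | None = None, molecule_id: int | None = None):
        self.species = species
        self.molecule_id = molecule_id
        self.rows: list[tuple[float, int, float, float, float, int, str]] = []

    def record(self, time: float, store: MoleculeStore) -> None:
        if self.molecule_id is not None:
            rows = store.live_rows()
            rows = rows[store.ids[rows] == self.molecule_id]
        elif self.species is not None:
            rows = store.indices_of(self.species)
        else:
            rows = store.live_rows()
        if rows.size == 0:
            return
        pts = store.world_positions(rows)
        mesh = store.mesh
        for r, pt in zip(rows, pts):
            self.rows.append(
                (
                    time,
                    int(store.ids[r]),
                    float(pt[0]),
                    float(pt[1]),
                    float(pt[2]),
                    int(store.panel[r]),
                    mesh.surface_of(int(store.panel[r])),
                )
            )

    def frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.rows,
            columns=["time", "id", "x", "y", "z", "panel", "surface"],
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("time\tid\tx\ty\tz\tpanel\tsurface\n")
            for t, i, x, y, z, p, s in self.rows:
                fh.write(
                    f"{t:.9g}\t{i}\t{x:.9g}\t{y:.9g}\t{z:.9g}\t{p}\t{s}\n"
                )


# -- the simulation -----------------------------------------------------------


@dataclass
class _Placement:
    n: int
    species: str
    state: str
    surface: str


class Simulation:
    """One reaction–diffusion run on a fixed mesh.

    Parameters mirror the configuration file: the mesh, the diffusion table
    (defaults plus surface overrides), reaction definitions, timestep and
    simulated time span, the RNG seed, and the set of species confined to
    their current surface (for which shared edges act as reflective
    boundaries).
    """

    def __init__(
        self,
        mesh: SurfaceMesh,
        diffusion_table: DiffusionTable,
        reactions: list[ReactionDef] | None = None,
        *,
        dt: float,
        seed: int,
        time_start: float = 0.0,
        time_stop: float,
        confined_species: set[str] | None = None,
        output_interval: int = 1,
        max_crossings: int = 1000,
        calibration: CalibrationSettings | None = None,
    ):
        if dt <= 0:
            raise ValueError("time_step must be positive")
        if time_stop < time_start:
            raise ValueError("time_stop must be >= time_start")
        self.mesh = mesh
        self.diffusion_table = diffusion_table
        self.reactions = list(reactions or [])
        self.dt = float(dt)
        self.seed = int(seed)
        self.time_start = float(time_start)
        self.time_stop = float(time_stop)
        self.confined = set(confined_species or ())
        self.output_interval = max(int(output_interval), 1)
        self.max_crossings = int(max_crossings)
        self.rng = np.random.default_rng(self.seed)
        self.store = MoleculeStore(mesh)
        # register every declared species/state up front so count series
        # include zero-count species and codes are configuration-stable
        for sp, st in diffusion_table.species_states():
            self.store.species_code(sp)
            self.store.state_code(st)
        self.step_index = 0
        self.event_counts: dict[str, int] = {r.name: 0 for r in self.reactions}
        self.observers: list[CountSeries | TrajectoryRecord] = []
        self._placements: list[_Placement] = []
        kwargs = {} if calibration is None else {"settings": calibration}
        self.reaction_table: ReactionTable = compute_reaction_tables(
            self.reactions, diffusion_table, mesh, self.dt, **kwargs
        )
        self._order0 = [r for r in self.reactions if r.order == 0]
        self._order1 = [r for r in self.reactions if r.order == 1]
        self._order2 = [r for r in self.reactions if r.order == 2]
        self._sigma_cache: np.ndarray | None = None

    # -- setup ---------------------------------------------------------------

    @property
    def time(self) -> float:
        return self.time_start + self.step_index * self.dt

    @property
    def n_steps(self) -> int:
        return int(round((self.time_stop - self.time_start) / self.dt))

    def place(
        self, n: int, species: str, surface: str, state: str = DEFAULT_STATE
    ) -> None:
        """Queue ``n`` molecules placed uniformly at random on a surface."""
        self.diffusion_table.lookup(species, state, surface)  # declared?
        self._placements.append(_Placement(n, species, state, surface))

    def add_molecule(
        self, species: str, pos: SurfacePosition, state: str = DEFAULT_STATE
    ) -> int:
        return self.store.add(species, state, pos)

    def add_observer(self, obs) -> None:
        self.observers.append(obs)

    def _apply_placements(self) -> None:
        for pl in self._placements:
            for _ in range(pl.n):
                pos = self.mesh.sample_uniform(pl.surface, self.rng)
                self.store.add(pl.species, pl.state, pos)
        self._placements = []

    def _sigma_matrix(self) -> np.ndarray:
        """sqrt(2·D·dt) per (species, state) code pair and surface — the n·m table."""
        st = self.store
        n_pairs = len(st._species_names) * max(len(st._state_names), 1)
        n_surf = len(self.mesh.surface_names)
        sig = np.zeros((max(n_pairs, 1), n_surf))
        for sp, si in st._species_idx.items():
            for stt, ti in st._state_idx.items():
                for fname, fi in self.mesh._surface_index.items():
                    try:
                        D = self.diffusion_table.lookup(sp, stt, fname)
                    except KeyError:
                        D = 0.0
                    sig[si * len(st._state_names) + ti, fi] = math.sqrt(
                        2.0 * D * self.dt
                    )
        return sig

    # -- stepping ------------------------------------------------------------

    def step(self) -> None:
        """Advance one timestep through the fixed phase order."""
        rng = self.rng
        store = self.store
        mesh = self.mesh
        # (1) zeroth-order creations
        for rxn in self._order0:
            for sname in mesh.surface_names:
                mean = self.reaction_table.zeroth_mean[(rxn.name, sname)]
                n = int(rng.poisson(mean)) if mean > 0 else 0
                for _ in range(n):
                    pos = mesh.sample_uniform(sname, rng)
                    for sp, stt in rxn.products:
                        store.add(sp, stt, pos)
                self.event_counts[rxn.name] += n
        # (2) first-order conversions
        if self._order1:
            self._first_order_phase()
        # (3) diffusion, ascending id order
        self._diffusion_phase()
        # (4) bimolecular reactions
        for rxn in self._order2:
            self.event_counts[rxn.name] += apply_bimolecular(
                store, rxn, self.reaction_table, mesh, rng
            )
        store.compact()
        self.step_index += 1

    def _first_order_phase(self) -> None:
        rng = self.rng
        store = self.store
        by_reactant: dict[tuple[str, str], list[ReactionDef]] = {}
        for rxn in self._order1:
            by_reactant.setdefault(rxn.reactants[0], []).append(rxn)
        for (sp, stt), channels in by_reactant.items():
            rows = store.indices_of(sp, stt)
            if rows.size == 0:
                continue
            k_tot = sum(r.rate for r in channels)
            if k_tot <= 0:
                continue
            p = -math.expm1(-k_tot * self.dt)
            u = rng.random(rows.size)
            firing = rows[u < p]
            if firing.size == 0:
                continue
            if len(channels) > 1:
                pick = rng.random(firing.size)
            cum = np.cumsum([r.rate for r in channels]) / k_tot
            for n, row in enumerate(firing):
                ci = 0
                if len(channels) > 1:
                    ci = int(np.searchsorted(cum, pick[n], side="right"))
                    ci = min(ci, len(channels) - 1)
                self._fire_first_order(int(row), channels[ci])

    def _fire_first_order(self, row: int, rxn: ReactionDef) -> None:
        store = self.store
        pos = SurfacePosition(
            int(store.panel[row]), (float(store.x[row]), float(store.y[row]))
        )
        surface = self.mesh.surface_of(pos.panel)
        store.kill(row)
        self.event_counts[rxn.name] += 1
        if not rxn.products:
            return
        if len(rxn.products) == 1:
            sp, stt = rxn.products[0]
            store.add(sp, stt, pos)
            return
        sigma_u = self.reaction_table.unbinding_radius.get((rxn.name, surface), 0.0)
        cross_ok = [p[0] not in self.confined for p in rxn.products]
        if sigma_u > 0.0:
            p1, p2 = place_products_apart(
                pos, sigma_u, self.mesh, self.rng,
                allow_cross=cross_ok[0] and cross_ok[1],
            )
        else:
            p1 = p2 = pos
        positions = [p1, p2] + [pos] * max(len(rxn.products) - 2, 0)
        for (sp, stt), p in zip(rxn.products, positions):
            store.add(sp, stt, p)

    def _diffusion_phase(self) -> None:
        store = self.store
        mesh = self.mesh
        rows = store.live_rows()
        if rows.size == 0:
            _ = self.rng.standard_normal((0, 2))
            return
        sig = self._sigma_matrix()
        n_states = max(len(store._state_names), 1)
        pair_code = store.species[rows] * n_states + store.state[rows]
        surf = mesh.surface_of_panel[store.panel[rows]]
        sigma = sig[pair_code, surf]
        z = self.rng.standard_normal((rows.size, 2))
        disp = z * sigma[:, None]
        moving = sigma > 0.0
        if not np.any(moving):
            return
        mrows = rows[moving]
        mdisp = disp[moving]
        panels = store.panel[mrows]
        xy = np.column_stack([store.x[mrows], store.y[mrows]])
        target = xy + mdisp
        d = target[:, None, :] - mesh.edge_anchor[panels]
        s = np.einsum("nek,nek->ne", d, mesh.edge_normal[panels])
        inside = np.all(s <= 0.0, axis=1)
        # fast path: endpoint strictly inside the start panel
        easy = mrows[inside]
        store.x[easy] = target[inside, 0]
        store.y[easy] = target[inside, 1]
        # slow path: walk the step across edges
        hard = np.flatnonzero(~inside)
        if hard.size == 0:
            return
        confined_codes = {
            store._species_idx[sp]
            for sp in self.confined
            if sp in store._species_idx
        }
        for h in hard:
            row = int(mrows[h])
            allow = int(store.species[row]) not in confined_codes
            panel, px, py, _, status = _kernel(
                int(panels[h]), float(xy[h, 0]), float(xy[h, 1]),
                float(mdisp[h, 0]), float(mdisp[h, 1]),
                mesh.edge_anchor, mesh.edge_normal, mesh.edge_dir,
                mesh.neighbor_panel, mesh.xfer_anchor, mesh.xfer_dir,
                mesh.xfer_normal_in, allow, self.max_crossings, _NO_REC,
            )
            if status != 0:
                raise PropagationError(
                    f"molecule id {int(store.ids[row])}: step exceeded "
                    f"{self.max_crossings} edge events"
                )
            store.panel[row] = panel
            store.x[row] = px
            store.y[row] = py

    # -- driving -------------------------------------------------------------

    def run(self) -> dict:
        """Execute all steps; returns a summary of totals and event counts."""
        self._apply_placements()
        for obs in self.observers:
            obs.record(self.time, self.store)
        n = self.n_steps
        for _ in range(n):
            self.step()
            if (
                self.step_index % self.output_interval == 0
                or self.step_index == n
            ):
                for obs in self.observers:
                    obs.record(self.time, self.store)
        return {
            "steps": n,
            "time": self.time,
            "n_molecules": self.store.n_alive(),
            "events": dict(self.event_counts),
        }
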