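import math
import warnings

import numpy as np
import pytest

from surfdiff.config import Config, build_simulation
from surfdiff.diffusion import DEFAULT_STATE as S
from surfdiff.diffusion import DiffusionTable
from surfdiff.engine import MoleculeStore
from surfdiff.geometry import SurfacePosition, build_mesh
from surfdiff.reactions import (
    ReactionDef,
    UnachievableRateError,
    apply_bimolecular,
    binding_radius_from_rate,
    compute_reaction_tables,
    unbinding_radius_from_pgem,
    unimolecular_prob,
)


class TestUnimolecularProb:
    def test_zero_rate(self):
        assert unimolecular_prob(0.0, 1e-3) == 0.0

    def test_half_life_closed_form(self):
        assert unimolecular_prob(math.log(2), 1.0) == pytest.approx(0.5)

    def test_monotone_saturation(self):
        ps = [unimolecular_prob(k, 1.0) for k in (0.1, 1, 10, 100)]
        assert ps == sorted(ps)
        assert ps[-1] == pytest.approx(1.0, abs=1e-10)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            unimolecular_prob(-1.0, 1e-3)


class TestBindingRadius:
    def test_zero_rate_zero_radius(self):
        assert binding_radius_from_rate(0.0, 1.0, 1e-3) == 0.0

    def test_strictly_increasing_in_rate(self):
        sbs = [binding_radius_from_rate(k, 2.0, 1e-3) for k in (0.1, 0.5, 2.0)]
        assert sbs[0] < sbs[1] < sbs[2]

    def test_reaction_limited_asymptote(self):
        # for k << D the per-step capture is geometric: sigma_b -> sqrt(k dt / pi)
        k, dt = 1e-3, 1e-3
        sb = binding_radius_from_rate(k, 1.0, dt)
        assert sb == pytest.approx(math.sqrt(k * dt / math.pi), rel=0.10)

    def test_unachievable_rate_reports_maximum(self):
        with pytest.raises(UnachievableRateError) as err:
            binding_radius_from_rate(10.0, 1e-4, 1e-3)
        assert 0.0 < err.value.k_max < 10.0


class TestUnbindingRadius:
    # a diffusion-influenced anchor case: kappa = 1
    D_m, dt, k = 1.0, 1e-3, 2.0

    def test_at_least_binding_radius(self):
        sb = binding_radius_from_rate(self.k, self.D_m, self.dt)
        su = unbinding_radius_from_pgem(0.3, sb, self.D_m, self.dt)
        assert su >= sb

    def test_monotone_decreasing_in_pgem(self):
        sb = binding_radius_from_rate(self.k, self.D_m, self.dt)
        sus = [
            unbinding_radius_from_pgem(p, sb, self.D_m, self.dt)
            for p in (0.4, 0.25, 0.12)
        ]
        assert sus[0] < sus[1] < sus[2]

    def test_recombination_fraction_matches_pgem(self):
        """Pairs released at sigma_u recombine with probability pgem (MC check)."""
        pgem = 0.2
        sb = binding_radius_from_rate(self.k, self.D_m, self.dt)
        su = unbinding_radius_from_pgem(pgem, sb, self.D_m, self.dt)
        rng = np.random.default_rng(42)
        n = 6000
        s = math.sqrt(2 * self.D_m * self.dt)
        X = np.column_stack([np.full(n, su), np.zeros(n)])
        alive = np.ones(n, bool)
        captured = 0
        r_escape = 16.0 * s
        for _ in range(6000):
            idx = np.flatnonzero(alive)
            if idx.size == 0:
                break
            X[idx] += rng.normal(0, s, (idx.size, 2))
            r = np.linalg.norm(X[idx], axis=1)
            cap = r <= sb
            captured += int(cap.sum())
            alive[idx[cap | (r >= r_escape)]] = False
        se = math.sqrt(pgem * (1 - pgem) / n)
        assert abs(captured / n - pgem) < 3 * se


class TestReactionTables:
    @staticmethod
    def _mesh():
        tris = [
            [(0, 0, 0), (1, 0, 0), (1, 1, 0)],
            [(0, 0, 0), (1, 1, 0), (0, 1, 0)],
        ]
        return build_mesh(tris, ["fast", "slow"])

    def test_slow_surface_needs_larger_radius(self):
        # diffusion-influenced regime: a 100x slower surface must compensate
        # the rarer encounters with a strictly larger binding radius
        mesh = self._mesh()
        table = DiffusionTable()
        table.set_default("A", 0.05)
        table.set_override("slow", "A", 0.0005)
        table.set_default("E", 0.0)
        rxn = ReactionDef("r", 2, [("A", S), ("E", S)], [("A", S)], 0.005)
        out = compute_reaction_tables([rxn], table, mesh, 1e-3)
        assert (
            out.sigma_b("r", "slow", "slow") > out.sigma_b("r", "fast", "fast")
        )

    def test_uniform_D_reduces_to_surface_agnostic(self):
        mesh = self._mesh()
        table = DiffusionTable()
        table.set_default("A", 0.5)
        table.set_default("B", 0.5)
        rxn = ReactionDef("r", 2, [("A", S), ("B", S)], [], 0.2)
        out = compute_reaction_tables([rxn], table, mesh, 1e-3)
        radii = {out.sigma_b("r", s1, s2) for s1 in ("fast", "slow")
                 for s2 in ("fast", "slow")}
        assert len(radii) == 1
        assert radii.pop() == pytest.approx(
            binding_radius_from_rate(0.2, 1.0, 1e-3)
        )

    def test_zero_rate_no_pair_checks(self):
        mesh = self._mesh()
        table = DiffusionTable()
        table.set_default("A", 0.5)
        rxn = ReactionDef("r", 2, [("A", S), ("A", S)], [], 0.0)
        out = compute_reaction_tables([rxn], table, mesh, 1e-3)
        assert out.max_binding_radius["r"] == 0.0

    def test_unachievable_rate_clamped_with_warning(self):
        mesh = self._mesh()
        table = DiffusionTable()
        table.set_default("A", 1e-5)
        table.set_default("E", 0.0)
        rxn = ReactionDef("r", 2, [("A", S), ("E", S)], [], 1.0)
        with pytest.warns(UserWarning, match="exceeds achievable"):
            out = compute_reaction_tables([rxn], table, mesh, 1e-3)
        assert out.sigma_b("r", "fast", "fast") > 0.0

    def test_zeroth_order_expected_counts(self):
        mesh = self._mesh()
        table = DiffusionTable()
        rxn = ReactionDef("src", 0, [], [("A", S)], 10.0)
        table.set_default("A", 0.0)
        out = compute_reaction_tables([rxn], table, mesh, 1e-3)
        assert out.zeroth_mean[("src", "fast")] == pytest.approx(10.0 * 0.5 * 1e-3)


class TestApplyBimolecular:
    @staticmethod
    def _setup(k=0.5):
        tris = [
            [(0, 0, 0), (1, 0, 0), (1, 1, 0)],
            [(0, 0, 0), (1, 1, 0), (0, 1, 0)],
        ]
        mesh = build_mesh(tris, ["p", "p"])
        table = DiffusionTable()
        for sp in ("A", "B", "C"):
            table.set_default(sp, 0.5)
        rxn = ReactionDef("bind", 2, [("A", S), ("B", S)], [("C", S)], k)
        rt = compute_reaction_tables([rxn], table, mesh, 1e-3)
        store = MoleculeStore(mesh)
        return mesh, rxn, rt, store

    def test_distant_pair_does_not_react(self):
        mesh, rxn, rt, store = self._setup()
        store.add("A", S, SurfacePosition(0, (0.2, 0.05)))
        store.add("B", S, SurfacePosition(0, (0.8, 0.05)))
        n = apply_bimolecular(store, rxn, rt, mesh, np.random.default_rng(0))
        assert n == 0
        assert store.n_alive() == 2

    def test_close_pair_reacts_with_stoichiometry(self):
        mesh, rxn, rt, store = self._setup()
        sb = rt.sigma_b("bind", "p", "p")
        store.add("A", S, SurfacePosition(0, (0.5, 0.1)))
        store.add("B", S, SurfacePosition(0, (0.5 + 0.5 * sb, 0.1)))
        n = apply_bimolecular(store, rxn, rt, mesh, np.random.default_rng(0))
        assert n == 1
        assert store.indices_of("A").size == 0
        assert store.indices_of("B").size == 0
        c_rows = store.indices_of("C")
        assert c_rows.size == 1
        # product at the pair midpoint
        assert store.x[c_rows[0]] == pytest.approx(0.5 + 0.25 * sb)
        assert store.y[c_rows[0]] == pytest.approx(0.1)

    def test_molecule_reacts_at_most_once_per_step(self):
        mesh, rxn, rt, store = self._setup()
        sb = rt.sigma_b("bind", "p", "p")
        store.add("A", S, SurfacePosition(0, (0.5, 0.1)))
        store.add("B", S, SurfacePosition(0, (0.5 + 0.4 * sb, 0.1)))
        store.add("B", S, SurfacePosition(0, (0.5 - 0.4 * sb, 0.1)))
        n = apply_bimolecular(store, rxn, rt, mesh, np.random.default_rng(0))
        assert n == 1
        assert store.indices_of("B").size == 1


class TestKinetics:
    def test_first_order_decay_survival(self):
        """Survivors of A -> 0 at t = 1/k sit within 3 SD of N·e⁻¹."""
        sq = (
            (0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 1.0, 1.0, 0.0),
            (0.0, 0.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0),
        )
        conf = Config(
            species=("A",),
            difc=(("A", S, 0.0),),
            surfaces=(("plane", sq),),
            reactions=(ReactionDef("decay", 1, [("A", S)], [], 1.0),),
            placements=((4000, "A", "plane"),),
            time_stop=1.0,
            time_step=1e-3,
            random_seed=3,
        )
        sim, _ = build_simulation(conf)
        sim.run()
        expected = 4000 * math.exp(-1)
        assert abs(sim.store.n_alive() - expected) < 3 * math.sqrt(expected)

    def test_well_mixed_decay_matches_mass_action_ode(self):
        """A + B -> C over one half-life tracks 1/n − 1/n₀ = k·t/Area within 10%."""
        side = 3.0
        sq = (
            (0, 0, 0, side, 0, 0, side, side, 0),
            (0, 0, 0, side, side, 0, 0, side, 0),
        )
        conf = Config(
            species=("A", "B", "C"),
            difc=(("A", S, 1.0), ("B", S, 1.0), ("C", S, 0.0)),
            surfaces=(("plane", sq),),
            reactions=(
                ReactionDef("bind", 2, [("A", S), ("B", S)], [("C", S)], 0.02),
            ),
            placements=((500, "A", "plane"), (500, "B", "plane")),
            time_stop=1.0,
            time_step=1e-3,
            random_seed=1,
        )
        sim, _ = build_simulation(conf)
        sim.run()
        ode = 500 / (1 + 0.02 * 500 * 1.0 / side**2)
        n_a = sim.store.indices_of("A").size
        assert n_a == pytest.approx(ode, rel=0.10)
        # exact stoichiometric bookkeeping
        assert sim.store.indices_of("B").size == n_a
        assert sim.store.indices_of("C").size == 500 - n_a
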