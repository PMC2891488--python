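"""Force terms: Hooke's law, steric ramp, hydrogen bonding, boundaries."""

import numpy as np
import pytest

from crowdfold.forces import (boundary_forces, harmonic_force, hb_force,
                              total_force, vdw_force, vdw_forces)
from crowdfold.model_core import (ParticleSystem, Role, build_chain,
                                  make_system)
from crowdfold.synthesis_crowding import Scene

from helpers_oracles import finite_difference_force


class TestHarmonic:
    def test_equilibrium_gives_zero(self):
        f_i, f_j = harmonic_force([0, 0, 0], [2.0, 0, 0], k=1.0, L0=2.0)
        assert np.allclose(f_i, 0) and np.allclose(f_j, 0)

    def test_hookes_law_at_double_rest_length(self):
        L0 = 1.7
        f_i, f_j = harmonic_force([0, 0, 0], [2 * L0, 0, 0], k=1.0, L0=L0)
        assert np.linalg.norm(f_i) == pytest.approx(L0)
        assert f_i[0] > 0  # attractive: i pulled toward j
        assert np.allclose(f_i, -f_j)

    def test_matches_finite_difference_gradient(self, rng):
        k, L0 = 0.7, 2.9
        for _ in range(20):
            xi = rng.uniform(-3, 3, 3)
            xj = rng.uniform(-3, 3, 3)
            if np.linalg.norm(xj - xi) < 0.2:
                continue
            f_i, _ = harmonic_force(xi, xj, k, L0)

            def U(x):
                return 0.5 * k * (np.linalg.norm(xj - x) - L0) ** 2

            ref = finite_difference_force(U, xi)
            assert np.allclose(f_i, ref, rtol=1e-6, atol=1e-8)

    def test_coincident_points_return_zero(self):
        f_i, f_j = harmonic_force([1, 1, 1], [1, 1, 1], k=1.0, L0=2.0)
        assert np.allclose(f_i, 0) and np.allclose(f_j, 0)


class TestVdw:
    TABLE = {("a", "a"): (4.0, 2.0)}

    def test_zero_beyond_contact(self):
        f_i, f_j = vdw_force("a", "a", [0, 0, 0], [4.0, 0, 0], self.TABLE)
        assert np.allclose(f_i, 0) and np.allclose(f_j, 0)

    def test_linear_ramp_midpoint(self):
        f_i, _ = vdw_force("a", "a", [0, 0, 0], [2.0, 0, 0], self.TABLE)
        assert np.linalg.norm(f_i) == pytest.approx(1.0)  # max_rep / 2
        assert f_i[0] < 0  # repulsive

    def test_matches_finite_difference_gradient(self, rng):
        contact, max_rep = self.TABLE[("a", "a")]
        for _ in range(20):
            xi = rng.uniform(-2, 2, 3)
            xj = rng.uniform(-2, 2, 3)
            d = np.linalg.norm(xj - xi)
            if d < 0.3 or abs(d - contact) < 0.05:
                continue
            f_i, _ = vdw_force("a", "a", xi, xj, self.TABLE)

            def U(x):
                dd = np.linalg.norm(xj - x)
                if dd >= contact:
                    return 0.0
                # integral of the linear ramp from dd to contact
                return max_rep * (contact / 2 - dd + dd**2 / (2 * contact))

            ref = finite_difference_force(U, xi)
            assert np.allclose(f_i, ref, rtol=1e-6, atol=1e-8)

    def test_tabulated_profile_interpolation(self):
        profile = np.array([[0.0, 3.0], [1.0, 2.0], [2.0, 1.5],
                            [3.0, 0.5], [4.0, 0.0]])
        table = {("a", "a"): profile}
        for d, expected in [(0.5, 2.5), (1.5, 1.75), (2.5, 1.0),
                            (3.5, 0.25), (4.5, 0.0)]:
            f_i, _ = vdw_force("a", "a", [0, 0, 0], [d, 0, 0], table)
            assert np.linalg.norm(f_i) == pytest.approx(expected)

    def test_missing_pair_falls_back_to_radii_sum(self):
        radii = {"a": 1.0, "b": 2.5}
        f_i, _ = vdw_force("a", "b", [0, 0, 0], [3.6, 0, 0], {}, radii)
        assert np.allclose(f_i, 0)  # beyond 3.5 contact
        f_i, _ = vdw_force("a", "b", [0, 0, 0], [1.75, 0, 0], {}, radii)
        assert np.linalg.norm(f_i) == pytest.approx(0.5)


class TestHydrogenBonding:
    def _chain_on(self, positions, length, ff):
        chain = build_chain("A" * length, "E" * length, ff)
        system = make_system(chain, ff=ff)
        for i, (bb, sc) in enumerate(chain.particle_ids):
            system.pos[bb] = positions[i]
            if sc is not None:
                system.pos[sc] = positions[i] + [0, 5.0, 0]
        return chain, system

    def test_distant_pairs_contribute_nothing(self, params):
        ff, _ = params
        pos = np.array([[i * 3.8, 0, 0] for i in range(6)], float)
        chain, system = self._chain_on(pos, 6, ff)
        out = hb_force(chain, system.pos, ff)
        assert np.allclose(out, 0)

    def test_minimum_separation_gate(self, params):
        ff, _ = params
        # residues 1 and 3 are close but |i-j| = 2 < hb_min_separation
        pos = np.array([[0, 0, 0], [3.0, 2.0, 0], [0.5, 3.5, 0],
                        [-2.5, 1.5, 0]], float)
        chain, system = self._chain_on(pos, 4, ff)
        out = hb_force(chain, system.pos, ff)
        assert np.allclose(out, 0)

    def test_close_pair_attracts_antisymmetrically(self, params):
        ff, _ = params
        # two antiparallel pleated strands; the zig-zag makes the local
        # bisectors (and hence the virtual H/O sites) point between the
        # strands
        top = [[i * 3.6, 4.6 + 0.9 * (-1.0) ** i, 0] for i in range(5)]
        bot = [[(4 - i) * 3.6, -0.9 * (-1.0) ** i, 0] for i in range(5)]
        pos = np.array(top + bot, float)
        chain, system = self._chain_on(pos, 10, ff)
        out = hb_force(chain, system.pos, ff)
        assert np.allclose(out.sum(axis=0), 0, atol=1e-12)
        bb = chain.backbone_ids
        moved = [i for i in bb if np.linalg.norm(out[i]) > 0]
        assert moved, "expected at least one bonded pair"
        # attraction: force on a top-strand residue points toward the
        # bottom strand (negative y)
        assert any(out[i][1] < 0 for i in bb[:5] if np.linalg.norm(out[i]) > 0)


class TestBoundary:
    def _one_particle_system(self, pos, radius=2.0, role=Role.CROWDER):
        sys = ParticleSystem(
            pos=np.array([pos], float), vel=np.zeros((1, 3)),
            mass=np.ones(1), solvent_radius=np.array([radius]),
            role=np.array([int(role)], dtype=np.int8),
            residue_index=np.full(1, -1, dtype=np.int32),
            hydrophobic=np.zeros(1, bool), movable=np.ones(1, bool),
            active=np.ones(1, bool))
        return sys

    def test_interior_particle_feels_nothing(self, params):
        ff, _ = params
        scene = Scene()
        sys = self._one_particle_system([0, 0, 20], radius=2.0)
        assert np.allclose(boundary_forces(sys, scene, ff), 0)

    def test_container_overrun_spring_law(self, params):
        ff, _ = params
        scene = Scene()
        r, delta = 2.0, 3.0
        sys = self._one_particle_system([0, 0, scene.container_radius + delta],
                                        radius=r)
        f = boundary_forces(sys, scene, ff)[0]
        assert np.linalg.norm(f) == pytest.approx(ff.k_boundary * (delta + r))
        assert f[2] < 0  # inward

    def test_just_clear_of_ribosome_is_zero(self, params):
        ff, _ = params
        scene = Scene()
        r = 2.0
        z = scene.ribosome_center[2] + scene.ribosome_radius + r + 0.01
        sys = self._one_particle_system([0, 0, z], radius=r)
        # also outside container; isolate the ribosome term by moving
        # the container far away
        scene.container_radius = np.inf
        assert np.allclose(boundary_forces(sys, scene, ff), 0)

    def test_ribosome_penetration_repels_outward(self, params):
        ff, _ = params
        scene = Scene()
        scene.container_radius = np.inf
        r = 2.0
        z = scene.ribosome_center[2] + scene.ribosome_radius + r - 1.0
        sys = self._one_particle_system([0, 0, z], radius=r)
        f = boundary_forces(sys, scene, ff)[0]
        assert f[2] > 0
        assert np.linalg.norm(f) == pytest.approx(ff.k_boundary * 1.0)


class TestTotalForce:
    def test_empty_system(self, params):
        ff, _ = params
        sys = ParticleSystem(
            pos=np.zeros((0, 3)), vel=np.zeros((0, 3)), mass=np.zeros(0),
            solvent_radius=np.zeros(0), role=np.zeros(0, np.int8),
            residue_index=np.zeros(0, np.int32), hydrophobic=np.zeros(0, bool),
            movable=np.zeros(0, bool), active=np.zeros(0, bool))
        rep = total_force(sys, None, None, ff)
        assert rep.total.shape == (0, 3)

    def _random_chain_system(self, rng, ff, length=8):
        chain = build_chain("ALSKVEDF"[:length], "HHCCEEHC"[:length], ff)
        system = make_system(chain, ff=ff)
        system.pos += rng.normal(0, 1.5, system.pos.shape)
        return chain, system

    def test_newtons_third_law_for_internal_terms(self, params, rng):
        ff, _ = params
        chain, system = self._random_chain_system(rng, ff)
        rep = total_force(system, chain, None, ff)
        for term in ("cov", "bb", "sc", "vdw", "hb"):
            assert np.allclose(rep.terms[term].sum(axis=0), 0, atol=1e-9), term

    def test_breakdown_sums_to_total(self, params, rng):
        ff, _ = params
        chain, system = self._random_chain_system(rng, ff)
        rep = total_force(system, chain, Scene(), ff)
        assert np.allclose(sum(rep.terms.values()), rep.total, atol=1e-12)

    def test_total_equals_independent_term_evaluation(self, params, rng):
        ff, _ = params
        chain, system = self._random_chain_system(rng, ff)
        rep = total_force(system, chain, None, ff)
        from crowdfold.forces import spring_forces
        terms = spring_forces(system.pos, chain.springs, system.active,
                              system.n)
        exclude = {(min(s.i, s.j), max(s.i, s.j)) for s in chain.springs
                   if s.category == "cov"}
        vdw = vdw_forces(system, ff, exclude)
        hb = hb_force(chain, system.pos, ff)
        expected = (terms.get("cov", 0) + terms.get("bb", 0)
                    + terms.get("sc", 0) + vdw + hb)
        assert np.allclose(rep.total, expected, atol=1e-12)

    def test_translation_invariance_of_internal_forces(self, params, rng):
        ff, _ = params
        chain, system = self._random_chain_system(rng, ff)
        rep1 = total_force(system, chain, None, ff)
        system.pos += np.array([11.0, -5.0, 3.0])
        rep2 = total_force(system, chain, None, ff)
        assert np.allclose(rep1.total, rep2.total, atol=1e-9)
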