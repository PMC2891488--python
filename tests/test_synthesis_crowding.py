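"""Cell geometry, crowder placement, synthesis schedule."""

import math

import numpy as np
import pytest

from crowdfold.integrator import compile_state, run
from crowdfold.model_core import Role
from crowdfold.synthesis_crowding import (Scene, SynthesisHook,
                                          available_volume, build_cell,
                                          close_packing_fraction,
                                          crowder_count, place_crowders,
                                          realised_fraction,
                                          run_crowding_simulation,
                                          sampling_plan,
                                          sphere_overlap_volume)

from helpers_oracles import montecarlo_available_volume


class TestVolumes:
    def test_close_packing_bound(self):
        assert close_packing_fraction() == pytest.approx(math.pi
                                                         / math.sqrt(18))
        assert close_packing_fraction() == pytest.approx(0.7405, abs=5e-4)

    def test_ribosome_outside_container_full_volume(self):
        scene = Scene(ribosome_center=np.array([0, 0, -1000.0]))
        assert available_volume(scene) == pytest.approx(
            4 / 3 * math.pi * scene.container_radius ** 3)

    def test_concentric_equal_spheres_no_volume(self):
        scene = Scene(ribosome_radius=50.0,
                      ribosome_center=np.zeros(3))
        assert available_volume(scene) == pytest.approx(0.0, abs=1e-9)

    def test_overlap_volume_degenerate_cases(self):
        assert sphere_overlap_volume(3, 4, 10) == 0.0
        assert sphere_overlap_volume(3, 10, 1) == pytest.approx(
            4 / 3 * math.pi * 27)

    def test_default_geometry_matches_monte_carlo(self):
        scene = Scene()
        mc = montecarlo_available_volume(scene, 200_000, seed=1)
        assert available_volume(scene) == pytest.approx(mc, rel=0.01)

    def test_whole_container_denominator_option(self):
        scene = Scene(volume_denominator="container")
        assert available_volume(scene) == pytest.approx(
            4 / 3 * math.pi * 50 ** 3)


class TestCrowderCount:
    def test_zero_fraction(self):
        assert crowder_count(0.0, Scene()) == 0

    def test_single_crowder_fraction(self):
        scene = Scene()
        f = scene.crowder_volume / available_volume(scene)
        assert crowder_count(f, scene) == 1

    @pytest.mark.parametrize("fraction", [0.1, 0.25, 0.4, 0.5])
    def test_rounding_bound(self, fraction):
        scene = Scene()
        n = crowder_count(fraction, scene)
        unit = scene.crowder_volume / available_volume(scene)
        assert abs(realised_fraction(n, scene) - fraction) <= 0.5 * unit + 1e-12

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError, match="close packing"):
            crowder_count(0.8, Scene())

    def test_accounting_identity(self):
        scene = Scene()
        n = crowder_count(0.3, scene)
        assert realised_fraction(n, scene) == pytest.approx(
            n * scene.crowder_volume / available_volume(scene), rel=1e-12)


class TestPlacement:
    def _check(self, pts, scene):
        from scipy.spatial.distance import pdist
        r = scene.crowder_radius
        assert np.all(np.linalg.norm(pts - scene.container_center, axis=1)
                      <= scene.container_radius - r + 1e-9)
        assert np.all(np.linalg.norm(pts - scene.ribosome_center, axis=1)
                      >= scene.ribosome_radius - 1e-9)
        if len(pts) > 1:
            assert pdist(pts).min() >= 2 * r - 1e-9

    def test_zero_crowders(self, rng):
        assert place_crowders(0, Scene(), rng).shape == (0, 3)

    @pytest.mark.parametrize("fraction", [0.15, 0.35, 0.5])
    def test_constraints_hold_across_fractions(self, fraction, rng):
        scene = Scene(target_fraction=fraction)
        n = crowder_count(fraction, scene)
        pts = place_crowders(n, scene, rng)
        assert len(pts) == n
        self._check(pts, scene)

    def test_infeasible_count_raises(self, rng):
        with pytest.raises(RuntimeError, match="lower the target"):
            place_crowders(100, Scene(), rng)


class TestSynthesis:
    def test_schedule_and_tether_uniqueness(self, params):
        ff, lp = params
        seq, ss = "ALSKVE", "CCCCCC"
        system, chain, scene = build_cell(seq, ss, 0.0, 3, ff=ff, lp=lp)
        compiled = compile_state(system, chain, scene, ff)
        hook = SynthesisHook(chain, scene, rate=10)
        l = len(seq)
        for it in range(0, l * 10 + 1):
            nxt = hook.next_event(it)
            if nxt == it:
                hook.apply(it, system, chain, compiled)
            expected = min(it // 10 + 1, l)
            assert chain.synthesized_count == expected
            tethers = [compiled.sp_active[row]
                       for row in compiled.tether_rows.values()]
            if it < l * 10:
                assert sum(tethers) == 1, f"iteration {it}"
            else:
                assert sum(tethers) == 0  # complete and untethered
        # activated particles sit outside the ribosome sphere
        active_protein = (system.active
                          & np.isin(system.role, [int(Role.BACKBONE),
                                                  int(Role.SIDECHAIN)]))
        d = np.linalg.norm(system.pos[active_protein]
                           - scene.ribosome_center, axis=1)
        assert np.all(d >= scene.ribosome_radius)

    def test_requires_unsynthesized_chain(self, params):
        ff, lp = params
        system, chain, scene = build_cell("AL", "CC", 0.0, 0, ff=ff, lp=lp)
        chain.synthesized_count = 1
        with pytest.raises(ValueError, match="unsynthesized"):
            SynthesisHook(chain, scene)


class TestCrowdingRuns:
    def test_dry_run_sampling_plan(self):
        plan = run_crowding_simulation("A" * 50, "C" * 50, 0.3, 0,
                                       dry_run=True)
        assert plan["samples_per_replicate"] == 1000
        assert plan["total_iterations"] == 50 * 1000 + 1_000_000
        assert plan["synthesis_iterations"] == 50_000

    def test_study_scale_bookkeeping(self):
        plan = sampling_plan()
        assert plan["samples_per_protein_per_level"] == 100_000
        assert plan["total_conformations_per_level"] == 1_200_000

    def test_zero_fraction_cell_has_no_crowders(self, params):
        ff, lp = params
        system, chain, scene = build_cell("ALSK", "CCCC", 0.0, 1, ff=ff,
                                          lp=lp)
        assert scene.crowder_ids == []
        assert not np.any(system.role == int(Role.CROWDER))

    def test_short_crowded_run_respects_containment(self, params):
        ff, lp = params
        lp.exposure_interval = 4
        seq = "LSLSLSLSLS"
        traj = run_crowding_simulation(seq, "C" * 10, 0.3, 5, ff=ff, lp=lp,
                                       post_iterations=5000,
                                       sample_interval=1000,
                                       synthesis_rate=200,
                                       pre_equilibration=1000)
        assert traj.n_samples == 7
        assert np.all(np.isfinite(traj.coords))
        scene = Scene()
        # recorded protein beads stay within the containment restraint
        d = np.linalg.norm(traj.coords.reshape(-1, 3)
                           - scene.container_center, axis=1)
        active = d > 0  # unsynthesized beads are parked at the origin
        assert np.all(d[active] <= scene.container_radius + 2.0)
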