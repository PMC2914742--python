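import math

import numpy as np
import pytest

from crowdfold import thermo
from crowdfold.dmd import Simulation
from crowdfold.model import ProteinModel
from crowdfold.simulate import (
    CrowdedSystemSpec,
    PackingError,
    block_standard_error,
    build_system,
    estimate_distribution,
    estimate_f_native,
    integrated_autocorr_time,
    make_simulation,
    place_initial,
    pool_estimates,
    run_cell,
)


class TestSpecValidation:
    def test_phi_range(self):
        with pytest.raises(ValueError):
            CrowdedSystemSpec(c_urea=1.0, phi=0.6)
        with pytest.raises(ValueError):
            CrowdedSystemSpec(c_urea=1.0, phi=-0.1)

    def test_full_box_must_exceed_twice_outer_wall(self):
        with pytest.raises(ValueError, match="2 \\* b6"):
            CrowdedSystemSpec(c_urea=1.0, R_c=0.7, phi=0.2, box=200.0)

    def test_reduced_box_floor(self):
        with pytest.raises(ValueError, match="reduced box"):
            CrowdedSystemSpec(c_urea=1.0, R_c=0.7, phi=0.2, box=120.0, reduced_box=True)

    def test_negative_urea(self):
        with pytest.raises(ValueError):
            CrowdedSystemSpec(c_urea=-1.0)

    def test_crowder_count_formula(self):
        spec = CrowdedSystemSpec(c_urea=1.0, R_c=0.7, phi=0.3, box=150.0, reduced_box=True)
        v_c = (4 * math.pi / 3) * 9.1**3
        assert spec.n_crowders == round(0.3 * 150.0**3 / v_c)
        assert abs(spec.achieved_phi - 0.3) <= 0.01 * 0.3

    def test_phi_zero_two_particles(self, rng):
        state = place_initial(CrowdedSystemSpec(c_urea=1.0, phi=0.0), rng)
        assert state.n == 2

    def test_start_separation_validated(self, rng):
        with pytest.raises(ValueError, match="accessible"):
            place_initial(
                CrowdedSystemSpec(c_urea=1.0, phi=0.0, start_separation=20.0), rng
            )


class TestBuildSystem:
    def test_same_seed_bit_identical(self):
        spec = CrowdedSystemSpec(
            c_urea=2.0, R_c=0.7, phi=0.2, box=150.0, reduced_box=True, relax_tu=5.0
        )
        s1, _ = build_system(spec, np.random.default_rng(42))
        s2, _ = build_system(spec, np.random.default_rng(42))
        np.testing.assert_array_equal(s1.pos, s2.pos)
        np.testing.assert_array_equal(s1.vel, s2.vel)

    @pytest.mark.parametrize("R_c,phi,box", [(0.7, 0.3, 150.0), (1.4, 0.4, 190.0)])
    def test_zero_overlaps_after_build(self, rng, R_c, phi, box):
        spec = CrowdedSystemSpec(
            c_urea=2.0, R_c=R_c, phi=phi, box=box, reduced_box=True, relax_tu=5.0
        )
        state, inter = build_system(spec, rng)
        sim = Simulation(state, inter, q=0.2, rng=rng)  # init audits overlaps
        assert sim.audit_overlaps(raise_on_violation=False) <= 1e-6

    def test_native_start_separation(self, rng):
        spec = CrowdedSystemSpec(c_urea=1.0, phi=0.0)
        state = place_initial(spec, rng)
        assert 26.0 < state.pair_distance(0, 1, unwrapped=True) < 28.6

    def test_packing_error_when_too_dense(self, rng):
        spec = CrowdedSystemSpec(
            c_urea=1.0, R_c=0.7, phi=0.5, box=150.0, reduced_box=True, relax_tu=0.0
        )
        with pytest.raises(PackingError):
            place_initial(spec, rng)

    def test_velocities_are_thermal(self, rng):
        spec = CrowdedSystemSpec(
            c_urea=2.0, R_c=0.7, phi=0.3, box=150.0, reduced_box=True, relax_tu=0.0
        )
        state = place_initial(spec, rng)
        ke_per_dof = state.kinetic_energy() / (3 * state.n)
        assert ke_per_dof == pytest.approx(0.5, rel=0.15)


class TestEstimateFNative:
    def test_direct_count(self):
        est = estimate_f_native(np.array([27.0, 30.0, 27.0, 50.0]), 28.6)
        assert est.value == pytest.approx(0.5)

    def test_all_native(self):
        est = estimate_f_native(np.full(100, 26.5), 28.6)
        assert est.value == 1.0 and est.stderr == 0.0

    def test_boundary_inclusive(self):
        # r_g <= b1/2, i.e. r <= b1, counts as native
        assert estimate_f_native(np.array([28.6]), 28.6).value == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_f_native(np.array([]), 28.6)

    def test_block_se_iid(self, rng):
        x = (rng.random(20_000) < 0.3).astype(float)
        se, tau = block_standard_error(x)
        naive = math.sqrt(0.3 * 0.7 / len(x))
        assert 0.5 * naive < se < 2.0 * naive
        assert tau < 2.0

    def test_block_se_correlated(self, rng):
        k = 25
        x = np.repeat((rng.random(800) < 0.5).astype(float), k)
        se, tau = block_standard_error(x)
        naive = math.sqrt(0.25 / len(x))
        assert se > 2.5 * naive  # correlation inflates the error
        assert tau > k / 2

    def test_autocorr_time_constant_series(self):
        assert integrated_autocorr_time(np.ones(100)) == 1.0

    def test_pooling_includes_between_seed_variance(self):
        from crowdfold.simulate import EstimateResult

        a = EstimateResult(0.2, 0.01, 1000)
        b = EstimateResult(0.8, 0.01, 1000)
        pooled = pool_estimates([a, b])
        assert pooled.value == pytest.approx(0.5)
        assert pooled.stderr > 0.2  # dominated by seed disagreement


class TestReweighting:
    def test_same_concentration_is_identity(self, model, rng):
        from crowdfold.simulate import reweight_f_native

        r = rng.uniform(26.0, 104.0, 2000)
        direct = estimate_f_native(r, model.edges[1])
        rew = reweight_f_native(r, model, 3.0, 3.0)
        assert rew.value == pytest.approx(direct.value, abs=1e-12)

    def test_reweighted_dilute_matches_theory(self, model):
        from crowdfold.simulate import reweight_f_native

        # sample at fast-mixing c = 4, reweight down to c = 3
        spec = CrowdedSystemSpec(
            c_urea=4.0, phi=0.0, relax_tu=500.0, production_tu=60_000.0, q=0.2
        )
        _, samples = run_cell(spec, np.random.SeedSequence(21), n_seeds=2)
        ests = [reweight_f_native(s, model, 4.0, 3.0) for s in samples]
        pooled = pool_estimates(ests)
        expect = thermo.fraction_native(model, 3.0)
        assert abs(pooled.value - expect) < 3 * max(pooled.stderr, 0.01)

    def test_weights_direction(self, model):
        from crowdfold.simulate import reweight_f_native

        r = np.array([27.0] * 10 + [50.0] * 90, dtype=float)
        low = reweight_f_native(r, model, 4.0, 2.0)
        assert low.value > 0.9  # native samples upweighted by e^{6.6}


class TestEstimateDistribution:
    def test_normalised(self, model, rng):
        r = rng.uniform(26.0, 104.0, 5000)
        est = estimate_distribution(r, model)
        assert est.bin_fractions.sum() == pytest.approx(1.0)

    def test_low_occupancy_flagged(self, model):
        r = np.concatenate([np.full(10_000, 50.0), [27.0]])
        est = estimate_distribution(r, model)
        assert est.unreliable[0] and not est.unreliable[2]

    def test_bin_convention_matches_model(self, model):
        est = estimate_distribution(np.array([28.6, 26.0, 104.0]), model)
        # 28.6 -> bin 2, 26 -> bin 1, 104 -> bin 6 (closed)
        np.testing.assert_allclose(
            est.bin_fractions, np.array([1, 1, 0, 0, 0, 1]) / 3.0
        )

    def test_flat_potential_run_matches_shell_weights(self, flat_model, rng):
        # Jacobian oracle: walls-only dynamics sample P(r) ~ r^2
        spec = CrowdedSystemSpec(c_urea=0.0, phi=0.0, model=flat_model, relax_tu=0.0)
        state, inter = build_system(spec, rng, relax=False)
        sim = make_simulation(state, inter, spec, rng, fast=True)
        sim.run(500.0)
        s = sim.run(30_000.0, sample_interval=1.0)
        est = estimate_distribution(s.r, flat_model)
        edges = np.array(flat_model.edges)
        shells = edges[1:] ** 3 - edges[:-1] ** 3
        want = shells / shells.sum()
        n_eff = len(s.r) / 30.0
        for got, w in zip(est.bin_fractions, want):
            assert abs(got - w) < 4 * math.sqrt(w * (1 - w) / n_eff) + 0.01

    def test_high_urea_bin1_below_bin3(self, model, rng):
        spec = CrowdedSystemSpec(c_urea=4.0, phi=0.0, relax_tu=0.0)
        state, inter = build_system(spec, rng, relax=False)
        sim = make_simulation(state, inter, spec, rng, fast=True)
        sim.run(300.0)
        s = sim.run(8000.0, sample_interval=1.0)
        est = estimate_distribution(s.r, model)
        assert est.bin_fractions[0] < est.bin_fractions[2]


class TestRunCell:
    def test_sampling_interval_invariance(self, model):
        # same physics sampled at 1 vs 5 t_u: estimates agree within errors
        ests = []
        for interval in (1.0, 5.0):
            spec = CrowdedSystemSpec(
                c_urea=3.5,
                phi=0.0,
                relax_tu=50.0,
                production_tu=15_000.0,
                sample_interval=interval,
                q=0.5,
            )
            est, _ = run_cell(spec, np.random.SeedSequence(11), n_seeds=2)
            ests.append(est)
        diff = abs(ests[0].value - ests[1].value)
        se = math.sqrt(ests[0].stderr**2 + ests[1].stderr**2)
        assert diff < 4 * max(se, 0.01)

    def test_dilute_production_matches_theory(self, model):
        # scaled-down analytic oracle check at fast-mixing urea
        spec = CrowdedSystemSpec(
            c_urea=3.5, phi=0.0, relax_tu=100.0, production_tu=40_000.0, q=0.5
        )
        est, samples = run_cell(spec, np.random.SeedSequence(7), n_seeds=2)
        expect = thermo.fraction_native(model, 3.5)
        assert abs(est.value - expect) < 3 * max(est.stderr, 0.01)
        assert len(samples) == 2

    def test_crowder_only_control_uniform_density(self, rng):
        # no protein: crowder fluid equilibrates to uniform density
        from crowdfold.dmd import Interactions, StepPairPotential, SystemState

        L, r_c, n = 80.0, 9.1, 35
        grid = (np.arange(4) + 0.5) * (L / 4)
        sites = np.array(np.meshgrid(grid, grid, grid, indexing="ij")).reshape(3, -1).T
        pos = sites[rng.choice(len(sites), n, replace=False)]
        state = SystemState(
            pos=pos, vel=rng.normal(size=(n, 3)), box=L, kinds=np.ones(n, dtype=int)
        )
        inter = Interactions(
            kind_potentials={(1, 1): StepPairPotential.hard_sphere(2 * r_c)}, n_kinds=2
        )
        sim = Simulation(state, inter, q=0.3, rng=rng, t_table=5.0)
        sim.run(200.0)
        s = sim.run(2000.0, sample_interval=5.0, record_positions=True)
        # mean occupancy of each half along x stays near n/2
        wrapped = np.mod(s.positions[..., 0], L)
        frac_left = (wrapped < L / 2).mean()
        assert abs(frac_left - 0.5) < 0.05


def test_run_experiment_grid_smoke(tmp_path):
    import yaml

    from crowdfold.io import load_config
    from crowdfold.simulate import run_experiment_grid

    cfg = {
        "grid": {"R_c": [1.0], "phi": [0.0, 0.2], "c_urea": [3.0, 4.0]},
        "simulation": {
            "box_edge_angstrom": 165.0,
            "reduced_box": True,
            "duration_tu": 800.0,
            "relax_tu": 20.0,
            "n_seeds": 1,
        },
        "seed": 3,
    }
    p = tmp_path / "cfg.yaml"
    p.write_text(yaml.safe_dump(cfg))
    results = run_experiment_grid(load_config(p))
    curves, c50 = results["curves"], results["c50"]
    assert set(curves["source"]) == {"theory", "dmd"}
    assert len(curves) == 2 * 2 * 2  # 2 cells x 2 urea x 2 sources
    assert (c50["method"] == "theory").sum() == 2
    assert curves["f_native"].notna().all()
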