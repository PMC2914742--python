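import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from crowdfold.dmd import (
    EventOrderingError,
    Interactions,
    Simulation,
    StepPairPotential,
    SystemState,
    collision_time,
    predict_pair_event,
    resolve_event,
)
from crowdfold.dmd.fast import HAVE_NUMBA, FastSimulation
from crowdfold.model import ProteinModel
from crowdfold.simulate import (
    CrowdedSystemSpec,
    build_system,
    estimate_distribution,
    estimate_f_native,
)
from crowdfold import thermo


def pair_state(r0=27.0, v=None, box=210.0, rng=None):
    """Two bonded subunits at separation r0 along x, at the box centre."""
    c = box / 2.0
    pos = np.array([[c - r0 / 2, c, c], [c + r0 / 2, c, c]])
    if v is None:
        v = rng.normal(size=(2, 3)) if rng is not None else np.zeros((2, 3))
    return SystemState(pos=pos, vel=np.asarray(v, float), box=box, kinds=np.array([0, 0]))


def protein_interactions(c_urea=2.5, model=None):
    model = model or ProteinModel()
    bond = StepPairPotential.from_histogram(model.build_potential(c_urea))
    return Interactions(bonds={(0, 1): bond}, n_kinds=1)


class TestStepPairPotential:
    def test_hard_sphere(self):
        p = StepPairPotential.hard_sphere(5.0)
        assert p.is_plain_hard_sphere and p.n_shells == 1 and p.levels == (0.0,)

    def test_from_histogram(self, model):
        p = StepPairPotential.from_histogram(model.build_potential(0.0))
        assert p.outer_wall and p.n_shells == 6
        assert p.boundaries[0] == 26.0 and p.boundaries[-1] == 104.0

    def test_shell_lookup(self, model):
        p = StepPairPotential.from_histogram(model.build_potential(0.0))
        assert p.shell_of(27.0) == 0
        assert p.shell_of(50.0) == 2
        # exactly on a boundary: receding pair belongs to the outer shell
        assert p.shell_of(28.6, v_r=1.0) == 1
        assert p.shell_of(28.6, v_r=-1.0) == 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            StepPairPotential((5.0, 4.0), (0.0, 1.0))
        with pytest.raises(ValueError):
            StepPairPotential((5.0,), (0.0, 1.0))
        with pytest.raises(ValueError):
            StepPairPotential.from_histogram(ProteinModel().build_potential(0.0)).shell_of(10.0)

    def test_pending_boundaries(self, model):
        p = StepPairPotential.from_histogram(model.build_potential(0.0))
        pend = list(p.pending_boundaries(0))
        assert pend[0] == (0, 26.0, True, 0.0)  # hard core
        idx, sig, hard, du = pend[1]
        assert (idx, sig, hard) == (1, 28.6, False)
        assert du == pytest.approx(4.0 - (-10.8))


class TestPredictPairEvent:
    def test_head_on_approach(self):
        # gap g = 3, closing speed 2 -> t = 1.5
        t = collision_time(np.array([8.0, 0, 0]), np.array([-2.0, 0, 0]), 5.0)
        assert t == pytest.approx(1.5)

    def test_receding_inner_boundary_none(self):
        assert collision_time(np.array([8.0, 0, 0]), np.array([2.0, 0, 0]), 5.0) is None

    def test_miss_returns_none(self):
        # passing by with impact parameter > sigma
        assert collision_time(np.array([10.0, 6.0, 0]), np.array([-1.0, 0, 0]), 5.0) is None

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10_000))
    def test_root_substitution_oracle(self, seed):
        r = np.random.default_rng(seed)
        dr = r.uniform(-20, 20, 3)
        dv = r.uniform(-3, 3, 3)
        sigma = r.uniform(0.5, 25.0)
        t = collision_time(dr, dv, sigma)
        if t is not None:
            assert np.linalg.norm(dr + dv * t) == pytest.approx(sigma, abs=1e-9)

    def test_minimum_image_used(self):
        # particles near opposite faces approach through the boundary
        st_ = SystemState(
            pos=np.array([[1.0, 5.0, 5.0], [99.0, 5.0, 5.0]]),
            vel=np.array([[-1.0, 0, 0], [1.0, 0, 0]]),
            box=100.0,
            kinds=np.array([0, 0]),
        )
        t = predict_pair_event(st_, (0, 1), 1.0)
        assert t == pytest.approx(0.5)  # image gap 2 - sigma 1, closing speed 2


class TestResolveEvent:
    def make_pair_at(self, sigma, vi, vj):
        pos = np.array([[0.0, 0, 0], [sigma, 0, 0]])
        return SystemState(
            pos=pos, vel=np.array([vi, vj], float), box=500.0, kinds=np.array([0, 0])
        )

    def test_hard_core_reflection(self):
        s = self.make_pair_at(5.0, [1.0, 0.3, 0], [-1.0, -0.3, 0])
        ke0 = s.kinetic_energy()
        p0 = s.total_momentum().copy()
        crossed = resolve_event(s, (0, 1), 5.0, hard=True)
        assert not crossed
        assert s.kinetic_energy() == pytest.approx(ke0, rel=1e-12)
        np.testing.assert_allclose(s.total_momentum(), p0, atol=1e-12)
        # normal relative velocity negated, tangential untouched
        assert s.vel[1][0] - s.vel[0][0] == pytest.approx(2.0)
        assert s.vel[1][1] - s.vel[0][1] == pytest.approx(-0.6)

    def test_attractive_capture_gains_radial_ke(self):
        eps = 2.0  # falling into a well of depth 2 kT: d_u = -2
        s = self.make_pair_at(30.0, [0.5, 0, 0], [-0.5, 0, 0])
        ke0 = s.kinetic_energy()
        crossed = resolve_event(s, (0, 1), 30.0, d_u=-eps)
        assert crossed
        assert s.kinetic_energy() - ke0 == pytest.approx(eps, rel=1e-12)

    def test_insufficient_radial_ke_reflects(self):
        # closing speed 1 -> radial KE = mu vn^2 / 2 = 0.25 < d_u = 5
        s = self.make_pair_at(30.0, [0.5, 0, 0], [-0.5, 0, 0])
        ke0 = s.kinetic_energy()
        crossed = resolve_event(s, (0, 1), 30.0, d_u=5.0)
        assert not crossed
        assert s.kinetic_energy() == pytest.approx(ke0, rel=1e-12)
        assert s.vel[0][0] == pytest.approx(-0.5)  # bounced back

    def test_off_boundary_raises(self):
        s = self.make_pair_at(30.0, [0.5, 0, 0], [-0.5, 0, 0])
        with pytest.raises(EventOrderingError):
            resolve_event(s, (0, 1), 29.0)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10_000))
    def test_conservation_oracle(self, seed):
        r = np.random.default_rng(seed)
        sigma = r.uniform(1.0, 40.0)
        s = self.make_pair_at(sigma, r.normal(size=3), r.normal(size=3))
        d_u = r.uniform(-4.0, 4.0)
        ke0 = s.kinetic_energy()
        p0 = s.total_momentum().copy()
        v_tan0 = (s.vel[1] - s.vel[0])[1:].copy()  # tangential = y, z here
        crossed = resolve_event(s, (0, 1), sigma, d_u=d_u)
        np.testing.assert_allclose(s.total_momentum(), p0, atol=1e-10)
        d_ke = s.kinetic_energy() - ke0
        if crossed:
            assert d_ke == pytest.approx(-d_u, abs=1e-9)
        else:
            assert d_ke == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose((s.vel[1] - s.vel[0])[1:], v_tan0, atol=1e-10)


class TestThermostat:
    def test_thermostat_step_operation(self, rng):
        from crowdfold.dmd import thermostat_step

        n, q, T = 8, 0.5, 1.0
        state = SystemState(
            pos=rng.uniform(0, 50, (n, 3)),
            vel=np.zeros((n, 3)),
            box=50.0,
            kinds=np.zeros(n, dtype=int),
        )
        waits, comps = [], []
        t_prev = state.time
        for _ in range(4000):
            a = thermostat_step(state, q, T, rng)
            assert 0 <= a < n
            waits.append(state.time - t_prev)
            t_prev = state.time
            comps.extend(state.vel[a])
        res = stats.kstest(np.asarray(waits), "expon", args=(0, 1.0 / (q * n)))
        assert res.pvalue > 0.01
        res = stats.kstest(np.asarray(comps), "norm", args=(0, math.sqrt(T)))
        assert res.pvalue > 0.01
        with pytest.raises(ValueError):
            thermostat_step(state, 0.0, T, rng)

    def test_intercollision_times_exponential(self, rng):
        # generator property of the Poisson schedule
        times = rng.exponential(1.0 / 3.0, size=100_000)
        stat = stats.kstest(times, "expon", args=(0, 1.0 / 3.0))
        assert stat.pvalue > 0.01

    def test_event_count_matches_poisson_rate(self, rng):
        n, q, duration = 20, 0.5, 400.0
        state = SystemState(
            pos=rng.uniform(0, 100, (n, 3)),
            vel=rng.normal(size=(n, 3)),
            box=100.0,
            kinds=np.zeros(n, dtype=int),
        )
        sim = Simulation(state, Interactions(n_kinds=1), q=q, rng=rng)
        s = sim.run(duration)
        lam = n * q * duration
        assert abs(s.n_thermostat - lam) < 4 * math.sqrt(lam)

    def test_maxwell_boltzmann_speeds(self, rng):
        # ideal gas (no interactions): long-run speeds follow Maxwell at T
        n, T = 10, 1.0
        state = SystemState(
            pos=rng.uniform(0, 100, (n, 3)),
            vel=rng.normal(0, math.sqrt(T), size=(n, 3)),
            box=100.0,
            kinds=np.zeros(n, dtype=int),
        )
        sim = Simulation(state, Interactions(n_kinds=1), T=T, q=1.0, rng=rng)
        s = sim.run(1500.0, sample_interval=1.0, record_velocities=True)
        speeds = np.linalg.norm(s.velocities.reshape(-1, 3), axis=1)
        res = stats.kstest(speeds[::7], stats.maxwell(scale=math.sqrt(T)).cdf)
        assert res.pvalue > 0.01

    def test_q_zero_is_microcanonical(self, rng):
        state, inter = build_system(
            CrowdedSystemSpec(c_urea=2.0, phi=0.0, relax_tu=0.0), rng, relax=False
        )
        sim = Simulation(state, inter, q=0.0)
        e0 = sim.total_energy()
        s = sim.run(5000.0)
        assert s.n_thermostat == 0
        assert abs(sim.total_energy() - e0) / max(s.n_events, 1) < 1e-9


class TestRun:
    def test_bonded_pair_energy_conservation(self, rng):
        state = pair_state(rng=rng)
        sim = Simulation(state, protein_interactions(c_urea=4.0), q=0.0)
        e0 = sim.total_energy()
        s = sim.run(20_000.0)
        assert s.n_events > 3000
        assert abs(sim.total_energy() - e0) / s.n_events < 1e-9

    def test_momentum_conserved_without_thermostat(self, rng):
        spec = CrowdedSystemSpec(
            c_urea=2.0, R_c=1.0, phi=0.1, box=165.0, reduced_box=True, relax_tu=0.0
        )
        state, inter = build_system(spec, rng, relax=False)
        sim = Simulation(state, inter, q=0.0, t_table=5.0)
        p0 = state.total_momentum().copy()
        s = sim.run(150.0)
        assert s.n_events > 100
        np.testing.assert_allclose(state.total_momentum(), p0, atol=1e-8)

    def test_no_hard_core_violations_during_run(self, rng):
        spec = CrowdedSystemSpec(
            c_urea=2.0, R_c=0.7, phi=0.2, box=150.0, reduced_box=True, relax_tu=10.0
        )
        state, inter = build_system(spec, rng)
        sim = Simulation(state, inter, q=0.2, rng=rng, overlap_check_interval=10.0)
        sim.run(60.0, sample_interval=1.0)
        assert sim.audit_overlaps(raise_on_violation=False) <= 1e-6

    def test_overlapping_initial_state_rejected(self):
        state = SystemState(
            pos=np.array([[0.0, 0, 0], [3.0, 0, 0]]),
            vel=np.zeros((2, 3)),
            box=100.0,
            kinds=np.array([0, 0]),
        )
        inter = Interactions(kind_potentials={(0, 0): StepPairPotential.hard_sphere(5.0)})
        with pytest.raises(EventOrderingError):
            Simulation(state, inter)

    def test_equilibrium_distribution_oracle(self, rng, model):
        # thermostatted isolated pair at high urea (fast mixing) reproduces
        # the analytic P(r); scaled-down cousin of the acceptance check
        state = pair_state(rng=rng)
        sim = Simulation(state, protein_interactions(c_urea=4.0), q=0.5, rng=rng)
        sim.run(500.0)
        s = sim.run(20_000.0, sample_interval=1.0)
        est = estimate_distribution(s.r, model)
        expected = thermo.closed_form_bin_fractions(model.build_potential(4.0))
        # loose per-bin agreement for a short run
        n_eff = len(s.r) / 40.0
        for got, want in zip(est.bin_fractions, expected):
            se = math.sqrt(max(want * (1 - want), 1e-4) / n_eff)
            assert abs(got - want) < 5 * se

    def test_detailed_balance_between_adjacent_bins(self, rng, model):
        # occupancy ratio of bins 3 and 4 ~ exp(-dU) * shell-weight ratio
        state = pair_state(r0=49.0, rng=rng)
        sim = Simulation(state, protein_interactions(c_urea=4.0), q=0.5, rng=rng)
        sim.run(500.0)
        s = sim.run(20_000.0, sample_interval=1.0)
        est = estimate_distribution(s.r, model)
        edges = np.array(model.edges)
        shells = edges[1:] ** 3 - edges[:-1] ** 3
        want = math.exp(-(1.0 - 0.0)) * shells[3] / shells[2]
        got = est.bin_fractions[3] / est.bin_fractions[2]
        assert got == pytest.approx(want, rel=0.25)

    def test_t_table_statistical_invariance(self, model):
        # scheduling horizon must not change the physics
        fs = []
        for t_table in (2.0, 20.0):
            r = np.random.default_rng(99)
            state = pair_state(rng=r)
            sim = Simulation(state, protein_interactions(c_urea=4.0), q=0.5, rng=r, t_table=t_table)
            sim.run(300.0)
            s = sim.run(8000.0, sample_interval=1.0)
            fs.append(estimate_f_native(s.r, model.edges[1]))
        diff = abs(fs[0].value - fs[1].value)
        se = math.sqrt(fs[0].stderr**2 + fs[1].stderr**2)
        assert diff < 4 * max(se, 0.01)


@pytest.mark.skipif(not HAVE_NUMBA, reason="numba unavailable")
class TestFastEngineEquivalence:
    def test_identical_trajectory_microcanonical_pair(self, rng):
        state = pair_state(rng=rng)
        ref = Simulation(state.copy(), protein_interactions(2.5), q=0.0)
        fast = FastSimulation(state.copy(), protein_interactions(2.5), q=0.0)
        s_ref = ref.run(800.0, sample_interval=1.0)
        s_fast = fast.run(800.0, sample_interval=1.0)
        assert s_ref.n_events == s_fast.n_events
        np.testing.assert_allclose(s_ref.r, s_fast.r, atol=1e-8)

    def test_identical_trajectory_microcanonical_crowded(self, rng):
        spec = CrowdedSystemSpec(
            c_urea=2.5, R_c=1.0, phi=0.15, box=160.0, reduced_box=True, relax_tu=0.0
        )
        state, inter = build_system(spec, rng, relax=False)
        ref = Simulation(state.copy(), inter, q=0.0, t_table=5.0)
        fast = FastSimulation(state.copy(), inter, q=0.0, t_table=5.0)
        s_ref = ref.run(40.0, sample_interval=0.5)
        s_fast = fast.run(40.0, sample_interval=0.5)
        assert s_ref.n_events == s_fast.n_events
        np.testing.assert_allclose(s_ref.r, s_fast.r, atol=1e-7)
        np.testing.assert_allclose(ref.state.pos, fast.state.pos, atol=1e-7)

    def test_thermostatted_distributions_agree(self, model):
        # different RNG streams, same physics: compare native fractions
        ests = []
        for cls in (Simulation, FastSimulation):
            r = np.random.default_rng(5)
            state = pair_state(rng=r)
            sim = cls(state, protein_interactions(3.5), q=0.5, rng=r)
            sim.run(500.0)
            s = sim.run(15_000.0, sample_interval=1.0)
            ests.append(estimate_f_native(s.r, model.edges[1]))
        diff = abs(ests[0].value - ests[1].value)
        se = math.sqrt(ests[0].stderr**2 + ests[1].stderr**2)
        assert diff < 4 * max(se, 0.01)
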