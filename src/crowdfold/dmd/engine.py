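"""Event queue, kinematics and main loop of the discontinuous MD engine.

Between events every particle moves ballistically, r_i(t) = r_i0 + v_i t.
The time at which a pair may reach an interaction distance sigma is the
smallest positive root of |dr + dv t|^2 = sigma^2, a quadratic with
discriminant b^2 - v^2 (r^2 - sigma^2), b = dr . dv.  Predicted events are
kept in a priority queue and invalidated lazily via per-particle collision
counters; after each resolved event only predictions involving the two
affected particles are recomputed.  The full table is regenerated whenever
the simulation clock reaches the scheduling horizon ``t_table`` (predictions
are only trusted up to the horizon so that the periodic minimum image used
at prediction time cannot go stale; keep ``t_table`` well below
``(L/2 - sigma_max) / v_typ``).

Pairs interact either through per-kind potentials (plain hard spheres on the
vectorised fast path, arbitrary step potentials on the scalar path) or
through explicit *bonds* between named particle pairs, whose separation is
evaluated without the minimum image (the bonded pair never interacts with
periodic images of itself).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from crowdfold.dmd.potentials import StepPairPotential

__all__ = [
    "DMDError",
    "EventOrderingError",
    "SystemState",
    "Interactions",
    "Simulation",
    "TrajectorySamples",
    "collision_time",
    "predict_pair_event",
    "resolve_event",
    "thermostat_step",
]

#: Positions must never violate a hard core by more than this [A].
CORE_TOL = 1e-6

#: A pair being resolved must sit at its boundary within this distance [A].
EVENT_TOL = 1e-6

#: Small negative predicted times (round-off at a boundary) clamped to zero.
TIME_EPS = 1e-9


class DMDError(RuntimeError):
    pass


class EventOrderingError(DMDError):
    """A particle pair was found in an impossible configuration — an event
    was missed or processed out of order."""


def collision_time(dr, dv, sigma: float) -> float | None:
    """Smallest non-negative root of |dr + dv t|^2 = sigma^2, or None.

    Times in (-TIME_EPS, 0) caused by a pair sitting exactly on the
    boundary are clamped to zero.
    """
    dr = np.asarray(dr, dtype=float)
    dv = np.asarray(dv, dtype=float)
    v2 = float(dv @ dv)
    if v2 == 0.0:
        return None
    b = float(dr @ dv)
    d2 = float(dr @ dr)
    disc = b * b - v2 * (d2 - sigma * sigma)
    if disc < 0.0:
        return None
    sq = math.sqrt(disc)
    for t in ((-b - sq) / v2, (-b + sq) / v2):
        if t > -TIME_EPS:
            return max(t, 0.0)
    return None


@dataclass
class SystemState:
    """Positions and velocities of N particles in a cubic periodic box.

    Positions are stored unwrapped; the minimum image convention is applied
    in every pair computation, so coordinates may drift outside [0, L).
    All particles share one mass.
    """

    pos: np.ndarray
    vel: np.ndarray
    box: float
    kinds: np.ndarray
    mass: float = 1.0
    time: float = 0.0

    def __post_init__(self):
        self.pos = np.ascontiguousarray(self.pos, dtype=float)
        self.vel = np.ascontiguousarray(self.vel, dtype=float)
        self.kinds = np.asarray(self.kinds, dtype=np.int64)
        if self.pos.shape != self.vel.shape or self.pos.ndim != 2 or self.pos.shape[1] != 3:
            raise ValueError("pos and vel must both have shape (N, 3)")
        if len(self.kinds) != len(self.pos):
            raise ValueError("one kind per particle required")
        if self.box <= 0:
            raise ValueError("box edge must be positive")
        if not np.all(np.isfinite(self.vel)):
            raise ValueError("velocities must be finite")

    @property
    def n(self) -> int:
        return len(self.pos)

    def minimum_image(self, dr: np.ndarray) -> np.ndarray:
        return dr - self.box * np.round(dr / self.box)

    def pair_displacement(self, i: int, j: int, unwrapped: bool = False) -> np.ndarray:
        """Displacement r_j - r_i (minimum image unless ``unwrapped``)."""
        dr = self.pos[j] - self.pos[i]
        return dr if unwrapped else self.minimum_image(dr)

    def pair_distance(self, i: int, j: int, unwrapped: bool = False) -> float:
        dr = self.pair_displacement(i, j, unwrapped)
        return float(np.sqrt(dr @ dr))

    def kinetic_energy(self) -> float:
        return 0.5 * self.mass * float(np.sum(self.vel * self.vel))

    def total_momentum(self) -> np.ndarray:
        return self.mass * self.vel.sum(axis=0)

    def advance(self, dt: float) -> None:
        if dt < 0:
            raise ValueError(f"cannot advance backwards (dt = {dt})")
        if dt > 0:
            self.pos += self.vel * dt
        self.time += dt

    def copy(self) -> "SystemState":
        return SystemState(
            self.pos.copy(), self.vel.copy(), self.box, self.kinds.copy(), self.mass, self.time
        )


class Interactions:
    """Pair interaction table: per-kind potentials plus explicit bonds.

    Parameters
    ----------
    kind_potentials
        Mapping ``(kind_a, kind_b) -> StepPairPotential`` (unordered keys).
        Plain hard spheres take the vectorised prediction path.
    bonds
        Mapping ``(i, j) -> StepPairPotential`` for specific particle pairs,
        evaluated with unwrapped separations; overrides the kind potential
        for that pair.
    """

    def __init__(self, kind_potentials=None, bonds=None, n_kinds: int | None = None):
        self.kind_potentials: dict[tuple[int, int], StepPairPotential] = {}
        for (a, b), pot in (kind_potentials or {}).items():
            self.kind_potentials[(min(a, b), max(a, b))] = pot
        self.bonds: dict[tuple[int, int], StepPairPotential] = {}
        for (i, j), pot in (bonds or {}).items():
            if i == j:
                raise ValueError("bond endpoints must differ")
            self.bonds[(min(i, j), max(i, j))] = pot
        kinds_seen = [k for key in self.kind_potentials for k in key]
        self.n_kinds = n_kinds if n_kinds is not None else (max(kinds_seen) + 1 if kinds_seen else 1)
        # hard-sphere sigma matrix for the fast path; NaN = no simple interaction
        self.sigma = np.full((self.n_kinds, self.n_kinds), np.nan)
        self._scalar_kind_pairs = set()
        for (a, b), pot in self.kind_potentials.items():
            if pot.is_plain_hard_sphere:
                self.sigma[a, b] = self.sigma[b, a] = pot.hard_core
            else:
                self._scalar_kind_pairs.add((a, b))

    def bonded(self, i: int, j: int) -> StepPairPotential | None:
        return self.bonds.get((min(i, j), max(i, j)))

    def kind_potential(self, ka: int, kb: int) -> StepPairPotential | None:
        return self.kind_potentials.get((min(ka, kb), max(ka, kb)))

    def potential_for(self, state: SystemState, i: int, j: int):
        """Resolve the potential governing pair (i, j) -> (pot, unwrapped) or None."""
        pot = self.bonded(i, j)
        if pot is not None:
            return pot, True
        pot = self.kind_potential(state.kinds[i], state.kinds[j])
        return (pot, False) if pot is not None else None

    def max_range(self) -> float:
        ranges = [p.max_range for p in self.kind_potentials.values()]
        return max(ranges) if ranges else 0.0


def predict_pair_event(
    state: SystemState, pair: tuple[int, int], sigma: float, unwrapped: bool = False
) -> float | None:
    """Time from now until pair reaches distance ``sigma``, or None."""
    i, j = pair
    dr = state.pair_displacement(i, j, unwrapped)
    dv = state.vel[j] - state.vel[i]
    return collision_time(dr, dv, sigma)


def resolve_event(
    state: SystemState,
    pair: tuple[int, int],
    sigma: float,
    d_u: float = 0.0,
    hard: bool = False,
    unwrapped: bool = False,
) -> bool:
    """Apply the impulsive velocity change for a pair sitting at ``sigma``.

    Velocity changes act along the line of centres only and conserve
    momentum exactly.  Outcomes: hard boundary -> the normal relative
    velocity reverses; step with sufficient radial kinetic energy -> the
    pair crosses and total energy changes by exactly ``-d_u``; otherwise ->
    elastic reflection off the step.

    Returns True if the boundary was crossed, False if reflected.

    Raises
    ------
    EventOrderingError
        If the pair is not at the boundary within tolerance.
    """
    i, j = pair
    dr = state.pair_displacement(i, j, unwrapped)
    d = math.sqrt(float(dr @ dr))
    if abs(d - sigma) > EVENT_TOL:
        raise EventOrderingError(
            f"pair ({i}, {j}) resolved at distance {d!r}, expected boundary {sigma!r}"
        )
    nhat = dr / d
    dv = state.vel[j] - state.vel[i]
    vn = float(dv @ nhat)
    crossed = False
    if hard:
        vn_new = -vn
    else:
        mu = state.mass / 2.0
        arg = vn * vn - 2.0 * d_u / mu
        if arg > 0.0:
            vn_new = math.copysign(math.sqrt(arg), vn)
            crossed = True
        else:
            vn_new = -vn
    w = 0.5 * (vn_new - vn)
    state.vel[i] -= w * nhat
    state.vel[j] += w * nhat
    return crossed


def thermostat_step(
    state: SystemState, q: float, T: float, rng: np.random.Generator
) -> int:
    """Apply one Andersen ghost collision to ``state`` and return the index
    of the struck particle.

    The waiting time is exponential with total rate ``q * N`` (rate ``q``
    per particle); the system is advanced ballistically to the collision
    instant and the struck particle's momentum is redrawn from the
    Boltzmann (Maxwell) distribution at temperature ``T``.
    """
    if q <= 0:
        raise ValueError("thermostat rate q must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    state.advance(rng.exponential(1.0 / (q * state.n)))
    a = int(rng.integers(state.n))
    state.vel[a] = rng.normal(0.0, math.sqrt(T / state.mass), 3)
    return a


@dataclass
class TrajectorySamples:
    """Samples collected at fixed intervals during a run."""

    times: np.ndarray
    r: np.ndarray | None = None
    velocities: np.ndarray | None = None
    positions: np.ndarray | None = None
    n_events: int = 0
    n_thermostat: int = 0
    n_reflections: int = 0


class Simulation:
    """Event-driven simulation of one :class:`SystemState`.

    Parameters
    ----------
    state
        Initial configuration (mutated in place as the run advances).
    interactions
        Pair potential table.
    T
        Thermostat temperature (reduced units).
    q
        Andersen ghost-collision rate per particle per time unit; 0 disables
        the thermostat (microcanonical dynamics).
    t_table
        Scheduling horizon: predictions are trusted for at most this long,
        after which the full event table is rebuilt.
    rng
        numpy Generator; required when q > 0.
    tracked_pair
        Pair whose separation is recorded at sample times (defaults to the
        first bond, if any).
    overlap_check_interval
        Period [t_u] of full hard-core overlap audits (None disables).
    """

    def __init__(
        self,
        state: SystemState,
        interactions: Interactions,
        T: float = 1.0,
        q: float = 0.0,
        t_table: float = 10.0,
        rng: np.random.Generator | None = None,
        tracked_pair: tuple[int, int] | None = None,
        overlap_check_interval: float | None = 50.0,
    ):
        if q < 0:
            raise ValueError("thermostat rate q must be >= 0")
        if q > 0 and rng is None:
            raise ValueError("a numpy Generator is required when the thermostat is on")
        if T <= 0:
            raise ValueError("temperature must be positive")
        if t_table <= 0:
            raise ValueError("t_table must be positive")
        self.state = state
        self.inter = interactions
        self.T = float(T)
        self.q = float(q)
        self.t_table = float(t_table)
        self.rng = rng
        self.overlap_check_interval = overlap_check_interval
        self.n_events = 0
        self.n_thermostat = 0
        self.n_reflections = 0

        if tracked_pair is None and interactions.bonds:
            tracked_pair = next(iter(interactions.bonds))
        self.tracked_pair = tracked_pair

        n = state.n
        self._counts: list[int] = [0] * n  # plain list: fast scalar indexing in the hot loop
        self._heap: list[tuple] = []
        self._seq = 0
        self._horizon = state.time
        self._next_thermo = math.inf
        self._others = [np.delete(np.arange(n), a) for a in range(n)]
        self._bonds_of: dict[int, list[tuple[int, int]]] = {}
        for (i, j) in interactions.bonds:
            self._bonds_of.setdefault(i, []).append((i, j))
            self._bonds_of.setdefault(j, []).append((i, j))
        if interactions._scalar_kind_pairs:
            raise NotImplementedError(
                "multi-step potentials between particle kinds are supported only "
                "as explicit bonds; register the pair as a bond instead"
            )
        self._check_initial_overlaps()
        self._schedule_thermostat()
        self._rebuild()

    # ------------------------------------------------------------------ setup

    def _check_initial_overlaps(self):
        self.audit_overlaps(raise_on_violation=True)

    def _schedule_thermostat(self):
        if self.q > 0:
            rate = self.q * self.state.n
            self._next_thermo = self.state.time + self.rng.exponential(1.0 / rate)
        else:
            self._next_thermo = math.inf

    # ------------------------------------------------------------- prediction

    def _push(self, t_abs, i, j, sigma, hard, d_u):
        self._seq += 1
        heapq.heappush(
            self._heap,
            (t_abs, self._seq, i, j, sigma, hard, d_u, self._counts[i], self._counts[j]),
        )

    def _predict_bond(self, key):
        i, j = key
        pot = self.inter.bonds[key]
        st = self.state
        dr = st.pair_displacement(i, j, unwrapped=True)
        dv = st.vel[j] - st.vel[i]
        d2 = float(dr @ dr)
        d = math.sqrt(d2)
        b = float(dr @ dv)
        v2 = float(dv @ dv)
        if v2 == 0.0:
            return
        shell = pot.shell_of(d, v_r=b / d if d > 0 else 0.0)
        limit = self._horizon - st.time
        for b_idx, sigma, hard, d_u in pot.pending_boundaries(shell):
            s2 = sigma * sigma
            if b_idx == shell:  # inner boundary: only reachable while approaching
                if b >= 0.0:
                    continue
                disc = b * b - v2 * (d2 - s2)
                if disc <= 0.0:
                    continue
                t = (-b - math.sqrt(disc)) / v2
            else:  # outer boundary: always reachable while moving
                disc = b * b - v2 * (d2 - s2)
                if disc <= 0.0:
                    continue
                t = (-b + math.sqrt(disc)) / v2
            if -TIME_EPS < t <= limit:
                self._push(st.time + max(t, 0.0), i, j, sigma, hard, d_u)

    def _predict_hard(self, a: int, js: np.ndarray):
        """Vectorised hard-sphere approach prediction of particle a vs js."""
        st = self.state
        sig = self.inter.sigma[st.kinds[a], st.kinds[js]]
        valid = ~np.isnan(sig)
        # bonds override the kind potential
        for key in self._bonds_of.get(a, ()):
            other = key[0] if key[1] == a else key[1]
            valid &= js != other
        if not valid.any():
            return
        js = js[valid]
        sig = sig[valid]
        dr = st.minimum_image(st.pos[js] - st.pos[a])
        dv = st.vel[js] - st.vel[a]
        b = np.einsum("ij,ij->i", dr, dv)
        v2 = np.einsum("ij,ij->i", dv, dv)
        d2 = np.einsum("ij,ij->i", dr, dr)
        disc = b * b - v2 * (d2 - sig * sig)
        ok = (b < 0.0) & (disc > 0.0) & (v2 > 0.0)
        if not ok.any():
            return
        with np.errstate(invalid="ignore", divide="ignore"):
            t = (-b - np.sqrt(np.where(ok, disc, 0.0))) / np.where(v2 > 0, v2, 1.0)
        limit = self._horizon - st.time
        ok &= (t > -TIME_EPS) & (t <= limit)
        now = st.time
        for j, tj, sj in zip(js[ok], t[ok], sig[ok]):
            self._push(now + max(float(tj), 0.0), a, int(j), float(sj), True, 0.0)

    def _predict_particle(self, a: int, exclude: int | None = None):
        for key in self._bonds_of.get(a, ()):
            other = key[0] if key[1] == a else key[1]
            if other != exclude:
                self._predict_bond(key)
        js = self._others[a]
        if exclude is not None:
            js = js[js != exclude]
        self._predict_hard(a, js)

    def _rebuild(self):
        self._heap.clear()
        self._horizon = self.state.time + self.t_table
        for key in self.inter.bonds:
            self._predict_bond(key)
        n = self.state.n
        for a in range(n - 1):
            self._predict_hard(a, np.arange(a + 1, n))

    # ------------------------------------------------------------- resolution

    def _handle_pair_event(self, ev):
        t, _, i, j, sigma, hard, d_u, ci, cj = ev
        st = self.state
        unwrapped = self.inter.bonded(i, j) is not None
        dr = st.pair_displacement(i, j, unwrapped)
        d = math.sqrt(float(dr @ dr))
        if abs(d - sigma) > EVENT_TOL:
            raise EventOrderingError(
                f"event at t = {t}: pair ({i}, {j}) at distance {d}, "
                f"expected boundary {sigma} (missed or stale event)"
            )
        nhat = dr / d
        dv = st.vel[j] - st.vel[i]
        vn = float(dv @ nhat)
        if hard:
            vn_new = -vn
        else:
            mu = st.mass / 2.0
            arg = vn * vn - 2.0 * d_u / mu
            if arg > 0.0:
                vn_new = math.copysign(math.sqrt(arg), vn)
            else:
                vn_new = -vn
                self.n_reflections += 1
        w = 0.5 * (vn_new - vn)
        st.vel[i] -= w * nhat
        st.vel[j] += w * nhat
        self._counts[i] += 1
        self._counts[j] += 1
        self.n_events += 1
        self._predict_particle(i)
        self._predict_particle(j, exclude=i)

    def _handle_thermostat(self):
        st = self.state
        a = int(self.rng.integers(st.n))
        st.vel[a] = self.rng.normal(0.0, math.sqrt(self.T / st.mass), 3)
        self._counts[a] += 1
        self.n_thermostat += 1
        self._predict_particle(a)
        self._schedule_thermostat()

    # ------------------------------------------------------------------ audit

    def audit_overlaps(self, raise_on_violation: bool = True) -> float:
        """Worst hard-core violation [A] over all pairs (negative = none)."""
        st = self.state
        worst = -math.inf
        n = st.n
        for a in range(n - 1):
            js = np.arange(a + 1, n)
            sig = self.inter.sigma[st.kinds[a], st.kinds[js]]
            for key in self._bonds_of.get(a, ()):
                other = key[0] if key[1] == a else key[1]
                sig = np.where(js == other, np.nan, sig)
            valid = ~np.isnan(sig)
            if valid.any():
                dr = st.minimum_image(st.pos[js[valid]] - st.pos[a])
                d = np.sqrt(np.einsum("ij,ij->i", dr, dr))
                viol = sig[valid] - d
                if viol.size:
                    worst = max(worst, float(viol.max()))
        for (i, j), pot in self.inter.bonds.items():
            d = st.pair_distance(i, j, unwrapped=True)
            worst = max(worst, pot.hard_core - d)
            if pot.outer_wall:
                worst = max(worst, d - pot.boundaries[-1])
        if raise_on_violation and worst > CORE_TOL:
            raise EventOrderingError(f"hard-core violation of {worst} A detected")
        return worst

    def potential_energy(self) -> float:
        """Current total potential energy [kT] (bonds only; hard spheres are 0)."""
        pe = 0.0
        st = self.state
        for (i, j), pot in self.inter.bonds.items():
            d = st.pair_distance(i, j, unwrapped=True)
            dr = st.pair_displacement(i, j, unwrapped=True)
            dv = st.vel[j] - st.vel[i]
            vr = float(dr @ dv) / d if d > 0 else 0.0
            pe += pot.energy(pot.shell_of(d, v_r=vr))
        return pe

    def total_energy(self) -> float:
        return self.state.kinetic_energy() + self.potential_energy()

    # -------------------------------------------------------------------- run

    def run(
        self,
        duration: float,
        sample_interval: float | None = None,
        record_velocities: bool = False,
        record_positions: bool = False,
        max_events: int | None = None,
    ) -> TrajectorySamples:
        """Advance the system by ``duration`` time units, sampling on the way.

        Samples are taken every ``sample_interval`` t_u starting one interval
        after the current time.  Returns the collected samples; the state is
        left at the final time.
        """
        st = self.state
        t_end = st.time + duration
        next_sample = st.time + sample_interval if sample_interval else math.inf
        next_check = (
            st.time + self.overlap_check_interval
            if self.overlap_check_interval
            else math.inf
        )
        ev0, th0, rf0 = self.n_events, self.n_thermostat, self.n_reflections
        times, rs, vels, poss = [], [], [], []
        heap = self._heap
        counts = self._counts
        while True:
            # drop stale events from the top of the queue
            while heap and (
                heap[0][7] != counts[heap[0][2]] or heap[0][8] != counts[heap[0][3]]
            ):
                heapq.heappop(heap)
            t_pair = heap[0][0] if heap else math.inf
            t_next = min(t_pair, self._next_thermo, self._horizon, next_sample, next_check, t_end)
            st.advance(t_next - st.time)
            if t_pair == t_next:
                self._handle_pair_event(heapq.heappop(heap))
                if max_events is not None and self.n_events - ev0 >= max_events:
                    break
            elif self._next_thermo == t_next:
                self._handle_thermostat()
            elif next_sample == t_next:
                times.append(st.time)
                if self.tracked_pair is not None:
                    i, j = self.tracked_pair
                    unw = self.inter.bonded(i, j) is not None
                    rs.append(st.pair_distance(i, j, unwrapped=unw))
                if record_velocities:
                    vels.append(st.vel.copy())
                if record_positions:
                    poss.append(st.pos.copy())
                next_sample += sample_interval
            elif next_check == t_next:
                self.audit_overlaps(raise_on_violation=True)
                next_check += self.overlap_check_interval
            elif t_next < t_end:  # horizon reached: rebuild the table
                self._rebuild()
            else:
                break  # t_end reached
        return TrajectorySamples(
            times=np.asarray(times),
            r=np.asarray(rs) if rs else None,
            velocities=np.asarray(vels) if vels else None,
            positions=np.asarray(poss) if poss else None,
            n_events=self.n_events - ev0,
            n_thermostat=self.n_thermostat - th0,
            n_reflections=self.n_reflections - rf0,
        )
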