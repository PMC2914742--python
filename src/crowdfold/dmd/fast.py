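"""Numba-accelerated event loop for the protein + hard-sphere-crowder system.

Covers the system class simulated in production: one optional bonded pair
(particles 0 and 1, arbitrary walled step potential, unwrapped separation)
plus hard-sphere interactions by particle kind under the minimum image.
Behaviour matches :class:`crowdfold.dmd.engine.Simulation`; with the
thermostat off the two engines follow bit-for-bit identical trajectories
(verified by an equivalence test), so the fast path is a drop-in
acceleration, not a different algorithm.

Positions are updated lazily (per-particle timestamps); the event queue is
a binary heap on parallel arrays with lazy invalidation via per-particle
collision counters, exactly as in the reference engine.
"""

from __future__ import annotations

import math

import numpy as np

from crowdfold.dmd.engine import (
    CORE_TOL,
    EVENT_TOL,
    TIME_EPS,
    EventOrderingError,
    Interactions,
    SystemState,
    TrajectorySamples,
)

try:  # pragma: no cover - exercised implicitly
    import numba
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


__all__ = ["HAVE_NUMBA", "FastSimulation"]

_STATUS_OK = 0
_STATUS_HEAP_OVERFLOW = 1
_STATUS_MISSED_EVENT = 2


@njit(cache=True, inline="always")
def _heap_swap(ht, hseq, hi, hj, hsig, hdu, hhard, hci, hcj, a, b):
    ht[a], ht[b] = ht[b], ht[a]
    hseq[a], hseq[b] = hseq[b], hseq[a]
    hi[a], hi[b] = hi[b], hi[a]
    hj[a], hj[b] = hj[b], hj[a]
    hsig[a], hsig[b] = hsig[b], hsig[a]
    hdu[a], hdu[b] = hdu[b], hdu[a]
    hhard[a], hhard[b] = hhard[b], hhard[a]
    hci[a], hci[b] = hci[b], hci[a]
    hcj[a], hcj[b] = hcj[b], hcj[a]


@njit(cache=True, inline="always")
def _heap_push(ht, hseq, hi, hj, hsig, hdu, hhard, hci, hcj, n_heap, t, seq, i, j, sig, du, hard, ci, cj):
    k = n_heap
    ht[k] = t
    hseq[k] = seq
    hi[k] = i
    hj[k] = j
    hsig[k] = sig
    hdu[k] = du
    hhard[k] = hard
    hci[k] = ci
    hcj[k] = cj
    while k > 0:
        p = (k - 1) >> 1
        if ht[p] > ht[k] or (ht[p] == ht[k] and hseq[p] > hseq[k]):
            _heap_swap(ht, hseq, hi, hj, hsig, hdu, hhard, hci, hcj, p, k)
            k = p
        else:
            break
    return n_heap + 1


@njit(cache=True, inline="always")
def _heap_pop(ht, hseq, hi, hj, hsig, hdu, hhard, hci, hcj, n_heap):
    last = n_heap - 1
    if last > 0:
        _heap_swap(ht, hseq, hi, hj, hsig, hdu, hhard, hci, hcj, 0, last)
    k = 0
    while True:
        l = 2 * k + 1
        if l >= last:
            break
        m = l
        r = l + 1
        if r < last and (ht[r] < ht[l] or (ht[r] == ht[l] and hseq[r] < hseq[l])):
            m = r
        if ht[m] < ht[k] or (ht[m] == ht[k] and hseq[m] < hseq[k]):
            _heap_swap(ht, hseq, hi, hj, hsig, hdu, hhard, hci, hcj, k, m)
            k = m
        else:
            break
    return last


@njit(cache=True)
def _run_core(
    pos,
    vel,
    tp,
    kinds,
    box,
    sigma_kk,
    bond_b,
    bond_lv,
    has_bond,
    T,
    q,
    t_table,
    t_start,
    duration,
    sample_interval,
    counts,
    seq0,
    r_out,
    stats,
):
    """Advance the system by ``duration`` from ``t_start``.

    ``stats`` (int64[6]) returns: n_samples, n_events, n_thermostat,
    n_reflections, status, seq.  The numba internal RNG must be seeded by
    the caller (inside another njit function or via np.random.seed).

    A Verlet neighbour list is rebuilt together with the event table at
    every scheduling horizon; its skin covers the maximum relative approach
    2 v_cap t_table, and any velocity exceeding v_cap (thermostat redraw or
    energy gained at a well boundary) forces an immediate rebuild, so the
    culling is exact: trajectories are identical to the all-pairs engine.
    """
    n = pos.shape[0]
    nb = bond_b.shape[0]
    cap = 64 * n + 4096
    ht = np.empty(cap)
    hseq = np.empty(cap, np.int64)
    hi = np.empty(cap, np.int32)
    hj = np.empty(cap, np.int32)
    hsig = np.empty(cap)
    hdu = np.empty(cap)
    hhard = np.empty(cap, np.uint8)
    hci = np.empty(cap, np.int64)
    hcj = np.empty(cap, np.int64)
    n_heap = 0
    seq = seq0

    sigma_max = 0.0
    for a in range(sigma_kk.shape[0]):
        for b_ in range(sigma_kk.shape[1]):
            if sigma_kk[a, b_] > sigma_max:
                sigma_max = sigma_kk[a, b_]
    nbr_cap = 128
    nbr = np.empty((n, nbr_cap), np.int32)
    nbr_cnt = np.zeros(n, np.int64)

    t = t_start
    t_end = t_start + duration
    horizon = t
    next_thermo = np.inf
    if q > 0.0:
        next_thermo = t + np.random.exponential(1.0 / (q * n))
    next_sample = t + sample_interval if sample_interval > 0 else np.inf
    n_samples = 0
    n_events = 0
    n_thermo = 0
    n_refl = 0
    status = _STATUS_OK
    mu = 0.5  # reduced mass, unit particle masses
    sqT = math.sqrt(T)
    v2cap = 0.0

    need_rebuild = True
    while True:
        if need_rebuild:
            n_heap = 0
            horizon = t + t_table
            limit = t_table
            # advance everyone to t and size the velocity cap
            v2max = 0.0
            for p in range(n):
                dt = t - tp[p]
                pos[p, 0] += vel[p, 0] * dt
                pos[p, 1] += vel[p, 1] * dt
                pos[p, 2] += vel[p, 2] * dt
                tp[p] = t
                v2 = vel[p, 0] ** 2 + vel[p, 1] ** 2 + vel[p, 2] ** 2
                if v2 > v2max:
                    v2max = v2
            vcap = math.sqrt(v2max)
            floor = 5.0 * sqT
            if vcap < floor:
                vcap = floor
            v2cap = vcap * vcap
            cutoff = sigma_max + 2.0 * vcap * t_table
            cut2 = cutoff * cutoff
            for p in range(n):
                nbr_cnt[p] = 0
            for a in range(n - 1):
                for j in range(a + 1, n):
                    if has_bond and a == 0 and j == 1:
                        continue
                    if sigma_kk[kinds[a], kinds[j]] <= 0.0:
                        continue
                    dx = pos[j, 0] - pos[a, 0]
                    dy = pos[j, 1] - pos[a, 1]
                    dz = pos[j, 2] - pos[a, 2]
                    dx -= box * math.floor(dx / box + 0.5)
                    dy -= box * math.floor(dy / box + 0.5)
                    dz -= box * math.floor(dz / box + 0.5)
                    if dx * dx + dy * dy + dz * dz < cut2:
                        if nbr_cnt[a] >= nbr_cap or nbr_cnt[j] >= nbr_cap:
                            status = _STATUS_HEAP_OVERFLOW
                            break
                        nbr[a, nbr_cnt[a]] = j
                        nbr_cnt[a] += 1
                        nbr[j, nbr_cnt[j]] = a
                        nbr_cnt[j] += 1
                if status != _STATUS_OK:
                    break
            if status != _STATUS_OK:
                break
            if has_bond:
                seq, n_heap = _predict_bond(
                    pos, vel, tp, bond_b, bond_lv, t, limit, counts, seq,
                    ht, hseq, hi, hj, hsig, hdu, hhard, hci, hcj, n_heap,
                )
            for a in range(n):
                seq, n_heap, ok = _predict_hard(
                    pos, vel, tp, kinds, box, sigma_kk, a, nbr, nbr_cnt, True, -1,
                    t, limit, counts, seq,
                    ht, hseq, hi, hj, hsig, hdu, hhard, hci, hcj, n_heap, cap,
                )
                if not ok:
                    status = _STATUS_HEAP_OVERFLOW
                    break
            if status != _STATUS_OK:
                break
            need_rebuild = False

        # drop stale heap tops
        while n_heap > 0 and (hci[0] != counts[hi[0]] or hcj[0] != counts[hj[0]]):
            n_heap = _heap_pop(ht, hseq, hi, hj, hsig, hdu, hhard, hci, hcj, n_heap)
        t_pair = ht[0] if n_heap > 0 else np.inf

        t_next = t_pair
        if next_thermo < t_next:
            t_next = next_thermo
        if horizon < t_next:
            t_next = horizon
        if next_sample < t_next:
            t_next = next_sample
        if t_end < t_next:
            t_next = t_end

        if t_pair == t_next:
            t = t_pair
            i = hi[0]
            j = hj[0]
            sig = hsig[0]
            du = hdu[0]
            hard = hhard[0]
            n_heap = _heap_pop(ht, hseq, hi, hj, hsig, hdu, hhard, hci, hcj, n_heap)
            # advance the two participants
            for p in (i, j):
                dt = t - tp[p]
                pos[p, 0] += vel[p, 0] * dt
                pos[p, 1] += vel[p, 1] * dt
                pos[p, 2] += vel[p, 2] * dt
                tp[p] = t
            bonded = has_bond and ((i == 0 and j == 1) or (i == 1 and j == 0))
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            if not bonded:
                dx -= box * math.floor(dx / box + 0.5)
                dy -= box * math.floor(dy / box + 0.5)
                dz -= box * math.floor(dz / box + 0.5)
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            if abs(d - sig) > EVENT_TOL:
                status = _STATUS_MISSED_EVENT
                break
            nx = dx / d
            ny = dy / d
            nz = dz / d
            vn = (
                (vel[j, 0] - vel[i, 0]) * nx
                + (vel[j, 1] - vel[i, 1]) * ny
                + (vel[j, 2] - vel[i, 2]) * nz
            )
            if hard == 1:
                vn_new = -vn
            else:
                arg = vn * vn - 2.0 * du / mu
                if arg > 0.0:
                    vn_new = math.sqrt(arg) if vn > 0 else -math.sqrt(arg)
                else:
                    vn_new = -vn
                    n_refl += 1
            w = 0.5 * (vn_new - vn)
            vel[i, 0] -= w * nx
            vel[i, 1] -= w * ny
            vel[i, 2] -= w * nz
            vel[j, 0] += w * nx
            vel[j, 1] += w * ny
            vel[j, 2] += w * nz
            counts[i] += 1
            counts[j] += 1
            n_events += 1
            # a well crossing may push a speed beyond the neighbour-list cap
            for p in (i, j):
                if vel[p, 0] ** 2 + vel[p, 1] ** 2 + vel[p, 2] ** 2 > v2cap:
                    need_rebuild = True
            if need_rebuild:
                continue
            limit = horizon - t
            for idx in range(2):
                a = i if idx == 0 else j
                excl = -1 if idx == 0 else i
                if has_bond and a < 2:
                    other = 1 - a
                    if other != excl:
                        seq, n_heap = _predict_bond(
                            pos, vel, tp, bond_b, bond_lv, t, limit, counts, seq,
                            ht, hseq, hi, hj, hsig, hdu, hhard, hci, hcj, n_heap,
                        )
                seq, n_heap, ok = _predict_hard(
                    pos, vel, tp, kinds, box, sigma_kk, a, nbr, nbr_cnt, False, excl,
                    t, limit, counts, seq,
                    ht, hseq, hi, hj, hsig, hdu, hhard, hci, hcj, n_heap, cap,
                )
                if not ok:
                    need_rebuild = True
                    break
            continue

        if next_thermo == t_next:
            t = next_thermo
            a = np.random.randint(0, n)
            dt = t - tp[a]
            pos[a, 0] += vel[a, 0] * dt
            pos[a, 1] += vel[a, 1] * dt
            pos[a, 2] += vel[a, 2] * dt
            tp[a] = t
            vel[a, 0] = np.random.normal(0.0, sqT)
            vel[a, 1] = np.random.normal(0.0, sqT)
            vel[a, 2] = np.random.normal(0.0, sqT)
            counts[a] += 1
            n_thermo += 1
            next_thermo = t + np.random.exponential(1.0 / (q * n))
            if vel[a, 0] ** 2 + vel[a, 1] ** 2 + vel[a, 2] ** 2 > v2cap:
                need_rebuild = True
                continue
            limit = horizon - t
            if has_bond and a < 2:
                seq, n_heap = _predict_bond(
                    pos, vel, tp, bond_b, bond_lv, t, limit, counts, seq,
                    ht, hseq, hi, hj, hsig, hdu, hhard, hci, hcj, n_heap,
                )
            seq, n_heap, ok = _predict_hard(
                pos, vel, tp, kinds, box, sigma_kk, a, nbr, nbr_cnt, False, -1,
                t, limit, counts, seq,
                ht, hseq, hi, hj, hsig, hdu, hhard, hci, hcj, n_heap, cap,
            )
            if not ok:
                need_rebuild = True
            continue

        if next_sample == t_next:
            t = next_sample
            if has_bond:
                dx = (pos[1, 0] + vel[1, 0] * (t - tp[1])) - (pos[0, 0] + vel[0, 0] * (t - tp[0]))
                dy = (pos[1, 1] + vel[1, 1] * (t - tp[1])) - (pos[0, 1] + vel[0, 1] * (t - tp[0]))
                dz = (pos[1, 2] + vel[1, 2] * (t - tp[1])) - (pos[0, 2] + vel[0, 2] * (t - tp[0]))
                r_out[n_samples] = math.sqrt(dx * dx + dy * dy + dz * dz)
                n_samples += 1
            next_sample += sample_interval
            continue

        if horizon == t_next and horizon < t_end:
            t = horizon
            need_rebuild = True
            continue

        t = t_end
        break

    # bring all particles to the final time
    for p in range(n):
        dt = t - tp[p]
        pos[p, 0] += vel[p, 0] * dt
        pos[p, 1] += vel[p, 1] * dt
        pos[p, 2] += vel[p, 2] * dt
        tp[p] = t

    stats[0] = n_samples
    stats[1] = n_events
    stats[2] = n_thermo
    stats[3] = n_refl
    stats[4] = status
    stats[5] = seq
    return t


@njit(cache=True, inline="always")
def _predict_bond(
    pos, vel, tp, bond_b, bond_lv, t, limit, counts, seq,
    ht, hseq, hi, hj, hsig, hdu, hhard, hci, hcj, n_heap,
):
    nb = bond_b.shape[0]
    dx = (pos[1, 0] + vel[1, 0] * (t - tp[1])) - (pos[0, 0] + vel[0, 0] * (t - tp[0]))
    dy = (pos[1, 1] + vel[1, 1] * (t - tp[1])) - (pos[0, 1] + vel[0, 1] * (t - tp[0]))
    dz = (pos[1, 2] + vel[1, 2] * (t - tp[1])) - (pos[0, 2] + vel[0, 2] * (t - tp[0]))
    dvx = vel[1, 0] - vel[0, 0]
    dvy = vel[1, 1] - vel[0, 1]
    dvz = vel[1, 2] - vel[0, 2]
    d2 = dx * dx + dy * dy + dz * dz
    d = math.sqrt(d2)
    b = dx * dvx + dy * dvy + dz * dvz
    v2 = dvx * dvx + dvy * dvy + dvz * dvz
    if v2 == 0.0:
        return seq, n_heap
    # locate the shell (boundary snap resolved by the sign of b)
    shell = 0
    for k in range(nb):
        if abs(d - bond_b[k]) <= 1e-9:
            shell = k if b > 0 else k - 1
            break
        if d > bond_b[k]:
            shell = k
        else:
            break
    if shell < 0:
        shell = 0  # at the hard core moving inward: treat as inside shell 0
    n_shells = nb - 1  # outer wall potential
    if shell > n_shells - 1:
        shell = n_shells - 1
    # inner boundary
    if b < 0.0:
        sig = bond_b[shell]
        disc = b * b - v2 * (d2 - sig * sig)
        if disc > 0.0:
            tt = (-b - math.sqrt(disc)) / v2
            if -TIME_EPS < tt <= limit:
                if tt < 0.0:
                    tt = 0.0
                if shell == 0:
                    hard = np.uint8(1)
                    du = 0.0
                else:
                    hard = np.uint8(0)
                    du = bond_lv[shell - 1] - bond_lv[shell]
                seq += 1
                n_heap = _heap_push(
                    ht, hseq, hi, hj, hsig, hdu, hhard, hci, hcj, n_heap,
                    t + tt, seq, np.int32(0), np.int32(1), sig, du, hard,
                    counts[0], counts[1],
                )
    # outer boundary
    outer = shell + 1
    if outer < nb:
        sig = bond_b[outer]
        disc = b * b - v2 * (d2 - sig * sig)
        if disc > 0.0:
            tt = (-b + math.sqrt(disc)) / v2
            if -TIME_EPS < tt <= limit:
                if tt < 0.0:
                    tt = 0.0
                if outer == nb - 1:
                    hard = np.uint8(1)
                    du = 0.0
                else:
                    hard = np.uint8(0)
                    du = bond_lv[shell + 1] - bond_lv[shell]
                seq += 1
                n_heap = _heap_push(
                    ht, hseq, hi, hj, hsig, hdu, hhard, hci, hcj, n_heap,
                    t + tt, seq, np.int32(0), np.int32(1), sig, du, hard,
                    counts[0], counts[1],
                )
    return seq, n_heap


@njit(cache=True, inline="always")
def _predict_hard(
    pos, vel, tp, kinds, box, sigma_kk, a, nbr, nbr_cnt, only_greater, excl,
    t, limit, counts, seq,
    ht, hseq, hi, hj, hsig, hdu, hhard, hci, hcj, n_heap, cap,
):
    ax = pos[a, 0] + vel[a, 0] * (t - tp[a])
    ay = pos[a, 1] + vel[a, 1] * (t - tp[a])
    az = pos[a, 2] + vel[a, 2] * (t - tp[a])
    ka = kinds[a]
    for k in range(nbr_cnt[a]):
        j = nbr[a, k]
        if j == excl or (only_greater and j < a):
            continue
        sig = sigma_kk[ka, kinds[j]]
        if sig <= 0.0:
            continue
        dtj = t - tp[j]
        dx = (pos[j, 0] + vel[j, 0] * dtj) - ax
        dy = (pos[j, 1] + vel[j, 1] * dtj) - ay
        dz = (pos[j, 2] + vel[j, 2] * dtj) - az
        dx -= box * math.floor(dx / box + 0.5)
        dy -= box * math.floor(dy / box + 0.5)
        dz -= box * math.floor(dz / box + 0.5)
        dvx = vel[j, 0] - vel[a, 0]
        dvy = vel[j, 1] - vel[a, 1]
        dvz = vel[j, 2] - vel[a, 2]
        b = dx * dvx + dy * dvy + dz * dvz
        if b >= 0.0:
            continue
        v2 = dvx * dvx + dvy * dvy + dvz * dvz
        d2 = dx * dx + dy * dy + dz * dz
        disc = b * b - v2 * (d2 - sig * sig)
        if disc <= 0.0:
            continue
        tt = (-b - math.sqrt(disc)) / v2
        if tt <= -TIME_EPS or tt > limit:
            continue
        if tt < 0.0:
            tt = 0.0
        if n_heap >= cap:
            return seq, n_heap, False
        seq += 1
        lo = a if a < j else j
        hi_ = j if a < j else a
        n_heap = _heap_push(
            ht, hseq, hi, hj, hsig, hdu, hhard, hci, hcj, n_heap,
            t + tt, seq, np.int32(lo), np.int32(hi_), sig, 0.0, np.uint8(1),
            counts[lo], counts[hi_],
        )
    return seq, n_heap, True


@njit(cache=True)
def _seed_numba(seed):
    np.random.seed(seed)


class FastSimulation:
    """Drop-in production runner mirroring :class:`Simulation` for the
    protein-plus-crowders system class (bond on particles 0-1, hard spheres
    otherwise).  Overlap audits run between chunks in numpy."""

    def __init__(
        self,
        state: SystemState,
        interactions: Interactions,
        T: float = 1.0,
        q: float = 0.0,
        t_table: float = 10.0,
        rng: np.random.Generator | None = None,
        overlap_check_interval: float | None = 200.0,
    ):
        if not HAVE_NUMBA:
            raise RuntimeError("numba is not available; use dmd.Simulation instead")
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

        bond = interactions.bonded(0, 1) if state.n >= 2 else None
        for key in interactions.bonds:
            if key != (0, 1):
                raise NotImplementedError("fast engine supports a single bond on (0, 1)")
        if bond is not None and not bond.outer_wall:
            raise NotImplementedError("fast engine expects a walled bond potential")
        self._bond_b = (
            np.asarray(bond.boundaries) if bond is not None else np.zeros(0)
        )
        self._bond_lv = np.asarray(bond.levels) if bond is not None else np.zeros(0)
        self._has_bond = bond is not None
        k = interactions.sigma.shape[0]
        self._sigma_kk = np.nan_to_num(interactions.sigma, nan=0.0)
        self._counts = np.zeros(state.n, dtype=np.int64)
        self._seq = 0
        self._tp = np.full(state.n, state.time)
        self._audit()

    def _audit(self):
        st = self.state
        n = st.n
        worst = -math.inf
        sig = self._sigma_kk
        for a in range(n - 1):
            js = np.arange(a + 1, n)
            if self._has_bond and a == 0:
                js = js[js != 1]
            s = sig[st.kinds[a], st.kinds[js]]
            dr = st.minimum_image(st.pos[js] - st.pos[a])
            d = np.sqrt(np.einsum("ij,ij->i", dr, dr))
            viol = s - d
            viol = viol[s > 0]
            if viol.size:
                worst = max(worst, float(viol.max()))
        if self._has_bond:
            d = st.pair_distance(0, 1, unwrapped=True)
            worst = max(worst, self._bond_b[0] - d, d - self._bond_b[-1])
        if worst > CORE_TOL:
            raise EventOrderingError(f"hard-core violation of {worst} A detected")

    def run(self, duration: float, sample_interval: float | None = None) -> TrajectorySamples:
        st = self.state
        interval = sample_interval if sample_interval else 0.0
        chunk = self.overlap_check_interval or duration
        n_total = int(duration / interval) + 2 if interval else 2
        r_all = []
        ev0, th0, rf0 = self.n_events, self.n_thermostat, self.n_reflections
        stats = np.zeros(6, dtype=np.int64)
        remaining = duration
        if self.rng is not None:
            _seed_numba(int(self.rng.integers(0, 2**31 - 1)))
        elif self.q > 0:
            raise ValueError("a numpy Generator is required when the thermostat is on")
        while remaining > 1e-12:
            step = min(chunk, remaining)
            n_cap = (int(step / interval) + 2) if interval else 2
            r_out = np.empty(n_cap)
            t_new = _run_core(
                st.pos, st.vel, self._tp, st.kinds, st.box, self._sigma_kk,
                self._bond_b, self._bond_lv, self._has_bond,
                self.T, self.q, self.t_table, st.time, step, interval,
                self._counts, self._seq, r_out, stats,
            )
            st.time = t_new
            self._seq = int(stats[5])
            self.n_events += int(stats[1])
            self.n_thermostat += int(stats[2])
            self.n_reflections += int(stats[3])
            if stats[4] == _STATUS_HEAP_OVERFLOW:
                raise EventOrderingError("event heap overflow (system too dense)")
            if stats[4] == _STATUS_MISSED_EVENT:
                raise EventOrderingError("missed event detected (pair off its boundary)")
            if stats[0]:
                r_all.append(r_out[: stats[0]].copy())
            remaining -= step
            self._audit()
        r = np.concatenate(r_all) if r_all else None
        times = (
            st.time - duration + interval * (1 + np.arange(len(r)))
            if r is not None
            else np.zeros(0)
        )
        return TrajectorySamples(
            times=np.asarray(times),
            r=r,
            n_events=self.n_events - ev0,
            n_thermostat=self.n_thermostat - th0,
            n_reflections=self.n_reflections - rf0,
        )

    def audit_overlaps(self, raise_on_violation: bool = True) -> float:
        self._audit()
        return 0.0
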