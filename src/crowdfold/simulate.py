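"""Assembly and production runs of the protein + explicit-crowder systems.

A system is the two bonded subunit spheres plus N hard-sphere crowders in a
cubic periodic box.  The crowder-subunit contact distance is
``a_sub + r_c`` and the crowder-crowder contact ``2 r_c``.  The subunit pair
interacts through the histogram potential evaluated on the *unwrapped*
separation (the pair never sees periodic images of itself); this enables a
reduced-box mode with ``L >= b6 + r_i`` in which the box is kept just large
enough that depletion between in-box images of the subunits cannot occur.

Crowders are introduced on a jittered cubic lattice that is overlap-free by
construction (sites clashing with the protein are discarded), then melted by
a thermostatted relaxation run before production sampling; only equilibrium
averages are reported, so any overlap-free, equilibrium-preserving
preparation is acceptable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from crowdfold.dmd import Interactions, Simulation, StepPairPotential, SystemState
from crowdfold.dmd.fast import HAVE_NUMBA, FastSimulation
from crowdfold.model import ProteinModel
from crowdfold.spt import CrowderFluid, crowding_pmf
from crowdfold.thermo import DenaturationCurve, c50_from_curve, fraction_native, solve_c50

__all__ = [
    "PackingError",
    "CrowdedSystemSpec",
    "EstimateResult",
    "DistributionEstimate",
    "build_system",
    "make_simulation",
    "place_initial",
    "estimate_f_native",
    "reweight_f_native",
    "reweighted_c50",
    "estimate_distribution",
    "pool_estimates",
    "run_cell",
    "run_experiment_grid",
    "block_standard_error",
    "integrated_autocorr_time",
]

log = logging.getLogger(__name__)

SUBUNIT, CROWDER = 0, 1


class PackingError(RuntimeError):
    """The requested crowder volume fraction could not be packed."""


@dataclass(frozen=True)
class CrowdedSystemSpec:
    """One simulation cell: urea concentration, crowder fluid and run settings.

    ``reduced_box`` permits a box smaller than twice the outer wall: safe
    because the subunit bond uses unwrapped separations, provided
    ``box >= b6 + 2(a_sub + r_c)`` so in-box subunit images cannot generate
    spurious depletion.  The full-size mode requires ``box > 2 b6``.
    """

    c_urea: float
    R_c: float = 1.0
    phi: float = 0.0
    box: float = 210.0
    reduced_box: bool = False
    relax_tu: float = 200.0
    production_tu: float = 10_000.0
    burn_in_fraction: float = 0.1
    sample_interval: float = 1.0
    q: float = 0.2
    #: scheduling horizon [t_u]; affects performance only (see dmd docs)
    t_table: float = 2.0
    temperature: float = 1.0
    model: ProteinModel = field(default_factory=ProteinModel)
    overlap_check_interval: float = 100.0
    #: initial subunit separation [A]; None = middle of the native bin
    start_separation: float | None = None

    def __post_init__(self):
        if self.c_urea < 0:
            raise ValueError("c_urea must be >= 0")
        if not 0.0 <= self.phi <= 0.5:
            raise ValueError(f"phi must lie in [0, 0.5], got {self.phi}")
        if self.phi > 0 and self.R_c <= 0:
            raise ValueError("R_c must be positive")
        b6 = self.model.edges[-1]
        if self.phi > 0:
            if self.reduced_box:
                needed = b6 + 2.0 * (self.model.subunit_radius + self.r_c)
                if self.box < needed:
                    raise ValueError(
                        f"reduced box must be >= b6 + 2(a_sub + r_c) = {needed:.1f} A, "
                        f"got {self.box}"
                    )
            elif self.box <= 2.0 * b6:
                raise ValueError(
                    f"full-size box must exceed 2 * b6 = {2 * b6} A, got {self.box}"
                )
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must lie in [0, 1)")

    @property
    def r_c(self) -> float:
        return self.R_c * self.model.subunit_radius

    @property
    def crowder_volume(self) -> float:
        return (4.0 * math.pi / 3.0) * self.r_c**3

    @property
    def n_crowders(self) -> int:
        if self.phi == 0:
            return 0
        return int(round(self.phi * self.box**3 / self.crowder_volume))

    @property
    def achieved_phi(self) -> float:
        return self.n_crowders * self.crowder_volume / self.box**3

    def validate_phi(self) -> None:
        if self.phi > 0 and abs(self.achieved_phi - self.phi) > 0.01 * self.phi:
            raise PackingError(
                f"achieved volume fraction {self.achieved_phi:.4f} deviates more than "
                f"1% from requested {self.phi} (box too small for this crowder size)"
            )

    def interactions(self) -> Interactions:
        a = self.model.subunit_radius
        bond = StepPairPotential.from_histogram(self.model.build_potential(self.c_urea))
        kind_pots = {}
        if self.phi > 0:
            kind_pots[(SUBUNIT, CROWDER)] = StepPairPotential.hard_sphere(a + self.r_c)
            kind_pots[(CROWDER, CROWDER)] = StepPairPotential.hard_sphere(2.0 * self.r_c)
        return Interactions(kind_potentials=kind_pots, bonds={(0, 1): bond}, n_kinds=2)


def _lattice_sites(spec: CrowdedSystemSpec, sub_pos: np.ndarray, rng) -> np.ndarray:
    """Jittered cubic-lattice crowder positions with zero overlaps.

    Raises :class:`PackingError` when no lattice spacing can host the
    requested count at this crowder size.
    """
    n_target = spec.n_crowders
    L, r_c = spec.box, spec.r_c
    a = spec.model.subunit_radius
    d_cc = 2.0 * r_c  # crowder-crowder contact
    n_side_max = int(L / (d_cc * (1.0 + 1e-9)))
    n_side = max(1, int(math.ceil(n_target ** (1.0 / 3.0))))
    while n_side <= n_side_max:
        spacing = L / n_side
        jitter = 0.45 * (spacing - d_cc) / math.sqrt(3.0)
        grid = (np.arange(n_side) + 0.5) * spacing
        sites = np.array(np.meshgrid(grid, grid, grid, indexing="ij")).reshape(3, -1).T
        if jitter > 0:
            sites = sites + rng.uniform(-jitter, jitter, size=sites.shape)
        # discard sites clashing with either subunit (with jitter safety margin)
        keep = np.ones(len(sites), dtype=bool)
        for p in sub_pos:
            dr = sites - p
            dr -= L * np.round(dr / L)
            keep &= np.einsum("ij,ij->i", dr, dr) > (a + r_c + 1e-6) ** 2
        usable = sites[keep]
        if len(usable) >= n_target:
            idx = rng.choice(len(usable), size=n_target, replace=False)
            return usable[idx]
        n_side += 1
    raise PackingError(
        f"cannot place {n_target} crowders of radius {r_c} A in a {L} A box "
        f"(phi = {spec.phi} too high for this geometry)"
    )


def place_initial(spec: CrowdedSystemSpec, rng: np.random.Generator) -> SystemState:
    """Deterministically assemble the un-relaxed system for a given RNG state.

    The subunit pair is placed at the box centre at a native (bin-1)
    separation along a random axis; crowders go on the jittered lattice.
    Velocities are Maxwell-Boltzmann at the spec temperature.
    """
    spec.validate_phi()
    L = spec.box
    b0, b1 = spec.model.edges[0], spec.model.edges[1]
    if spec.start_separation is None:
        r0 = 0.5 * (b0 + b1)
    else:
        r0 = float(spec.start_separation)
        if not b0 < r0 < spec.model.edges[-1]:
            raise ValueError(f"start separation {r0} outside the accessible range")
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    centre = np.full(3, L / 2.0)
    sub_pos = np.array([centre - 0.5 * r0 * axis, centre + 0.5 * r0 * axis])
    n_c = spec.n_crowders
    if n_c:
        crowders = _lattice_sites(spec, sub_pos, rng)
        pos = np.vstack([sub_pos, crowders])
    else:
        pos = sub_pos
    kinds = np.array([SUBUNIT, SUBUNIT] + [CROWDER] * n_c)
    vel = rng.normal(0.0, math.sqrt(spec.temperature), size=pos.shape)
    return SystemState(pos=pos, vel=vel, box=L, kinds=kinds)


def make_simulation(
    state: SystemState,
    inter: Interactions,
    spec: CrowdedSystemSpec,
    rng: np.random.Generator,
    fast: bool | None = None,
):
    """Reference or numba-accelerated simulation, whichever is available.

    The fast engine is a verified drop-in for this system class (see
    :mod:`crowdfold.dmd.fast`); set ``fast=False`` to force the reference
    engine.
    """
    if fast is None:
        fast = HAVE_NUMBA
    cls = FastSimulation if fast else Simulation
    return cls(
        state,
        inter,
        T=spec.temperature,
        q=spec.q,
        t_table=spec.t_table,
        rng=rng,
        overlap_check_interval=spec.overlap_check_interval,
    )


def build_system(
    spec: CrowdedSystemSpec,
    rng: np.random.Generator,
    relax: bool = True,
    fast: bool | None = None,
) -> tuple[SystemState, Interactions]:
    """Assemble and (optionally) relax a crowded system, ready for production.

    Returns the relaxed state and its interaction table; guaranteed free of
    hard-core overlaps.  Identical RNG state yields a bit-identical system.
    """
    state = place_initial(spec, rng)
    inter = spec.interactions()
    if relax and spec.relax_tu > 0:
        relax_spec = replace(spec, q=max(spec.q, 0.1))
        sim = make_simulation(state, inter, relax_spec, rng, fast=fast)
        sim.run(spec.relax_tu)
        sim.audit_overlaps(raise_on_violation=True)
    return state, inter


# --------------------------------------------------------------- estimation


def integrated_autocorr_time(x: np.ndarray, c: float = 6.0) -> float:
    """Integrated autocorrelation time via FFT with Sokal's windowing."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        return 1.0
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0:
        return 1.0
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acf = np.fft.irfft(f * np.conjugate(f), m)[:n].real
    acf /= acf[0]
    tau = 1.0
    for window in range(1, n):
        tau = 1.0 + 2.0 * float(acf[1 : window + 1].sum())
        if window >= c * tau:
            break
    return max(tau, 1.0)


def block_standard_error(x: np.ndarray) -> tuple[float, float]:
    """(standard error of the mean, tau) using autocorrelation-sized blocks."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 or np.all(x == x[0]):
        return 0.0, 1.0
    tau = integrated_autocorr_time(x)
    b = max(1, int(math.ceil(5.0 * tau)))
    nb = n // b
    if nb < 4:  # too few blocks: fall back to the tau-corrected naive estimate
        se = float(np.std(x, ddof=1)) * math.sqrt(tau / n)
        return se, tau
    means = x[: nb * b].reshape(nb, b).mean(axis=1)
    return float(np.std(means, ddof=1) / math.sqrt(nb)), tau


@dataclass(frozen=True)
class EstimateResult:
    value: float
    stderr: float
    n_samples: int
    tau: float = 1.0


def estimate_f_native(r_samples: np.ndarray, b1: float) -> EstimateResult:
    """Native fraction from separation samples: fraction with r <= b1.

    (Equivalently r_g <= b1/2.)  The standard error comes from block
    averaging over autocorrelation-decorrelated blocks.
    """
    r = np.asarray(r_samples, dtype=float)
    if r.size == 0:
        raise ValueError("need at least one sample")
    ind = (r <= b1).astype(float)
    se, tau = block_standard_error(ind)
    return EstimateResult(float(ind.mean()), se, len(r), tau)


def pool_estimates(estimates) -> EstimateResult:
    """Pool per-seed estimates; the quoted error includes the between-seed
    variance on top of the mean within-seed block error."""
    vals = np.array([e.value for e in estimates])
    ses = np.array([e.stderr for e in estimates])
    k = len(vals)
    if k == 1:
        return estimates[0]
    between = float(np.var(vals, ddof=1)) / k
    within = float(np.mean(ses**2)) / k
    return EstimateResult(
        float(vals.mean()),
        math.sqrt(within + between),
        int(sum(e.n_samples for e in estimates)),
        float(np.mean([e.tau for e in estimates])),
    )


def reweight_f_native(
    r_samples: np.ndarray,
    model: ProteinModel,
    c_from: float,
    c_to: float,
) -> EstimateResult:
    """Native fraction at urea ``c_to`` from samples generated at ``c_from``.

    Only the native-bin energy depends on urea (by ``slope * (c_to -
    c_from)``), so exact single-histogram reweighting applies: native
    samples get weight ``exp(-slope * (c_to - c_from))``, everything else
    weight 1.  Sampling at high urea (shallow native well, fast
    native/unfolded exchange) and reweighting down gives far smaller errors
    than direct simulation near the transition.  The standard error comes
    from block averaging of the per-block weighted ratio.
    """
    r = np.asarray(r_samples, dtype=float)
    if r.size == 0:
        raise ValueError("need at least one sample")
    b1 = model.edges[1]
    nat = (r <= b1).astype(float)
    w = np.where(nat > 0, math.exp(-model.urea_slope * (c_to - c_from)), 1.0)
    f = float((w * nat).sum() / w.sum())
    _, tau = block_standard_error(nat)
    b = max(1, int(math.ceil(5.0 * tau)))
    nb = len(r) // b
    if nb >= 4:
        wn = (w * nat)[: nb * b].reshape(nb, b).sum(axis=1)
        wt = w[: nb * b].reshape(nb, b).sum(axis=1)
        fk = wn / wt
        se = float(np.std(fk, ddof=1) / math.sqrt(nb))
    else:
        se = float(np.sqrt(f * (1 - f) * tau / len(r)))
    return EstimateResult(f, se, len(r), tau)


def reweighted_c50(
    r_samples: np.ndarray,
    model: ProteinModel,
    c_from: float,
    c_lo: float = 0.5,
    c_hi: float = 6.0,
) -> float:
    """c50 from one sample set via continuous urea reweighting.

    Root of ``reweight_f_native(.., c) = 1/2`` in ``c``; exact up to
    sampling noise because the reweighted curve is smooth and strictly
    decreasing in c.
    """
    from scipy.optimize import brentq

    def g(c):
        return reweight_f_native(r_samples, model, c_from, c).value - 0.5

    g_lo, g_hi = g(c_lo), g(c_hi)
    if g_lo * g_hi > 0:
        raise ValueError(
            f"reweighted curve does not cross 0.5 on [{c_lo}, {c_hi}] M "
            f"(f = {g_lo + 0.5:.4g} .. {g_hi + 0.5:.4g})"
        )
    return float(brentq(g, c_lo, c_hi, xtol=1e-9))


@dataclass
class DistributionEstimate:
    """Normalised histogram of the separation over the model bins.

    ``bin_fractions`` follows the same membership convention as the model
    (half-open bins, last closed); ``unreliable`` flags bins whose estimated
    probability is below 1e-3 and hence dominated by stochastic error.
    """

    bin_fractions: np.ndarray
    unreliable: np.ndarray
    fine_edges: np.ndarray
    fine_density: np.ndarray
    n_samples: int


def estimate_distribution(
    r_samples: np.ndarray, model: ProteinModel, n_sub: int = 4
) -> DistributionEstimate:
    r = np.asarray(r_samples, dtype=float)
    if r.size == 0:
        raise ValueError("need at least one sample")
    pot = model.build_potential(0.0)
    counts = np.zeros(pot.n_bins)
    idx = np.searchsorted(pot.edges, r, side="right") - 1
    idx = np.where(r == pot.edges[-1], pot.n_bins - 1, idx)
    inside = (idx >= 0) & (idx < pot.n_bins)
    np.add.at(counts, idx[inside], 1.0)
    fractions = counts / r.size
    fine_edges = np.concatenate(
        [
            np.linspace(a, b, n_sub + 1)[:-1]
            for a, b in zip(pot.edges[:-1], pot.edges[1:])
        ]
        + [[pot.edges[-1]]]
    )
    hist, _ = np.histogram(r, bins=fine_edges)
    widths = np.diff(fine_edges)
    fine_density = hist / (r.size * widths)
    return DistributionEstimate(
        bin_fractions=fractions,
        unreliable=fractions < 1e-3,
        fine_edges=fine_edges,
        fine_density=fine_density,
        n_samples=r.size,
    )


# ------------------------------------------------------------------ running


def run_cell(
    spec: CrowdedSystemSpec,
    seed_seq: np.random.SeedSequence,
    n_seeds: int = 4,
    alternate_starts: bool = True,
) -> tuple[EstimateResult, list[np.ndarray]]:
    """Run ``n_seeds`` independent trajectories of one grid cell.

    With ``alternate_starts`` every other seed begins from an unfolded
    (mid-bin-3) separation instead of the native one, so that slow
    native/unfolded interconversion shows up as between-seed variance
    rather than as a silent initialisation bias.

    Returns the pooled native-fraction estimate and the per-seed separation
    samples (burn-in already discarded).
    """
    children = seed_seq.spawn(n_seeds)
    per_seed = []
    all_samples = []
    b1 = spec.model.edges[1]
    edges = spec.model.edges
    unfolded_r0 = 0.5 * (edges[2] + edges[3])
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        spec_k = (
            replace(spec, start_separation=unfolded_r0)
            if alternate_starts and k % 2 == 1
            else spec
        )
        state, inter = build_system(spec_k, rng)
        sim = make_simulation(state, inter, spec, rng)
        burn = spec.burn_in_fraction * spec.production_tu
        if burn > 0:
            sim.run(burn)
        samples = sim.run(
            spec.production_tu - burn, sample_interval=spec.sample_interval
        )
        per_seed.append(estimate_f_native(samples.r, b1))
        all_samples.append(samples.r)
    return pool_estimates(per_seed), all_samples


def run_experiment_grid(config, progress: bool = False):
    """Run the full (R_c, phi) x c_urea grid: theory and DMD side by side.

    ``config`` is a :class:`crowdfold.io.ExperimentConfig`.  Returns a dict
    with pandas DataFrames ``curves`` (c_urea_M, f_native, stderr, source
    per cell) and ``c50`` (R_c, phi, c50_M, method).  Per-cell failures are
    logged and the grid continues.
    """
    import pandas as pd

    model = config.model
    curves_rows = []
    c50_rows = []
    cells = [(None, 0.0)] + [(rc, phi) for rc in config.R_c for phi in config.phi if phi > 0]
    root_seq = np.random.SeedSequence(config.seed)
    cell_seqs = root_seq.spawn(len(cells))
    for (rc, phi), seq in zip(cells, cell_seqs):
        label_rc = rc if rc is not None else float("nan")
        # ---- theory
        if phi > 0:
            fluid = CrowderFluid.from_ratio(rc, phi, model.subunit_radius)
            pmf = crowding_pmf(fluid)
            u_crowd, bps = pmf, [pmf.r_i]
        else:
            u_crowd, bps = None, []
        f_theory = [
            fraction_native(model, c, u_crowd, breakpoints=bps) for c in config.c_urea
        ]
        curves_rows += [
            {
                "R_c": label_rc,
                "phi": phi,
                "c_urea_M": c,
                "f_native": f,
                "stderr": 0.0,
                "source": "theory",
            }
            for c, f in zip(config.c_urea, f_theory)
        ]
        try:
            c50_rows.append(
                {
                    "R_c": label_rc,
                    "phi": phi,
                    "c50_M": solve_c50(model, u_crowd, breakpoints=bps),
                    "method": "theory",
                }
            )
        except ValueError as exc:
            log.warning("theory c50 failed for R_c=%s phi=%s: %s", rc, phi, exc)
        # ---- DMD
        f_dmd, se_dmd = [], []
        for c in config.c_urea:
            spec = replace(
                config.base_spec, c_urea=c, R_c=(rc if rc is not None else 1.0), phi=phi
            )
            try:
                est, _ = run_cell(spec, seq.spawn(1)[0], n_seeds=config.n_seeds)
            except Exception as exc:  # continue the grid on per-cell failure
                log.error("DMD cell failed (R_c=%s phi=%s c=%s): %s", rc, phi, c, exc)
                f_dmd.append(np.nan)
                se_dmd.append(np.nan)
                continue
            if progress:
                print(f"R_c={rc} phi={phi} c={c}: f_native = {est.value:.3f} +- {est.stderr:.3f}")
            f_dmd.append(est.value)
            se_dmd.append(est.stderr)
        curves_rows += [
            {
                "R_c": label_rc,
                "phi": phi,
                "c_urea_M": c,
                "f_native": f,
                "stderr": s,
                "source": "dmd",
            }
            for c, f, s in zip(config.c_urea, f_dmd, se_dmd)
        ]
        good = ~np.isnan(f_dmd)
        try:
            c50_rows.append(
                {
                    "R_c": label_rc,
                    "phi": phi,
                    "c50_M": c50_from_curve(
                        np.asarray(config.c_urea)[good], np.asarray(f_dmd)[good]
                    ),
                    "method": "dmd",
                }
            )
        except ValueError as exc:
            log.warning("DMD c50 failed for R_c=%s phi=%s: %s", rc, phi, exc)
    return {
        "curves": pd.DataFrame(curves_rows),
        "c50": pd.DataFrame(c50_rows),
    }
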