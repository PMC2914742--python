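"""Analytical equilibrium statistics of the two-subunit model.

The relative separation of the subunits lives in three dimensions, so the
density of states carries the radial Jacobian r**2.  The equilibrium density
is

    P(r) dr = w(r) exp(-U(r)/kT) dr / Z,   w(r) = r**2,

normalised over the accessible range between the hard walls.  For a purely
piecewise-constant potential the per-bin probability mass has the closed
form  exp(-U_i/kT) * (b_i**3 - b_{i-1}**3) / 3,  which is used both as a fast
path and as an internal cross-check of the adaptive quadrature.

A ``radial_weight=False`` escape hatch (w = 1) is provided for pedagogy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import integrate, optimize

from crowdfold.model import NATIVE_BIN, HistogramPotential, ProteinModel

__all__ = [
    "EquilibriumDistribution",
    "DenaturationCurve",
    "equilibrium_distribution",
    "bin_fractions",
    "closed_form_bin_fractions",
    "fraction_native",
    "solve_c50",
    "closed_form_c50",
    "c50_from_curve",
]


def _total_potential(
    pot: HistogramPotential, u_crowd: Callable | None
) -> Callable[[np.ndarray], np.ndarray]:
    if u_crowd is None:
        return pot.evaluate_array

    def u_total(r):
        r = np.asarray(r, dtype=float)
        return pot.evaluate_array(r) + np.asarray(u_crowd(r), dtype=float)

    return u_total


@dataclass
class EquilibriumDistribution:
    """Normalised equilibrium density of the inter-subunit separation.

    ``r`` and ``density`` give a dense plotting grid; ``Z`` is the partition
    integral of the unnormalised weight, and ``u_total`` the total potential
    used to build the distribution (retained so that bin masses can be
    recomputed by quadrature at full precision).
    """

    r: np.ndarray
    density: np.ndarray
    Z: float
    edges: tuple[float, ...]
    T: float = 1.0
    radial_weight: bool = True
    u_total: Callable = field(repr=False, default=None)
    breakpoints: tuple[float, ...] = ()

    def pdf(self, r) -> np.ndarray:
        """Evaluate the normalised density at arbitrary separations."""
        r = np.asarray(r, dtype=float)
        u = self.u_total(r)
        w = r**2 if self.radial_weight else np.ones_like(r)
        out = np.where(np.isfinite(u), w * np.exp(-np.where(np.isfinite(u), u, 0.0) / self.T), 0.0)
        return out / self.Z


def _bin_mass_quad(dist_u, a, b, T, radial_weight, breakpoints=()):
    """Unnormalised probability mass of [a, b] by adaptive quadrature."""

    def integrand(r):
        u = dist_u(np.array([r]))[0]
        if not np.isfinite(u):
            return 0.0
        w = r * r if radial_weight else 1.0
        return w * math.exp(-u / T)

    pts = [p for p in breakpoints if a < p < b]
    val, _ = integrate.quad(integrand, a, b, points=pts or None, limit=200)
    return val


def equilibrium_distribution(
    pot: HistogramPotential,
    u_crowd: Callable | None = None,
    T: float = 1.0,
    radial_weight: bool = True,
    n_grid: int = 2000,
    breakpoints: Sequence[float] = (),
) -> EquilibriumDistribution:
    """Equilibrium distribution of r for total potential ``U0 + U_crowd``.

    Parameters
    ----------
    pot
        Histogram potential (hard walls define the accessible range).
    u_crowd
        Optional continuous depletion potential added inside the walls.
    breakpoints
        Interior points where ``u_crowd`` is non-smooth (e.g. the isolation
        distance); quadrature panels are split there.

    Raises
    ------
    ValueError
        If the configuration space is empty (potential infinite everywhere).
    """
    u_total = _total_potential(pot, u_crowd)
    if all(not math.isfinite(e) for e in pot.energies):
        raise ValueError("potential is infinite everywhere: empty configuration space")
    edges = pot.edges
    Z = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        Z += _bin_mass_quad(u_total, a, b, T, radial_weight, breakpoints)
    if Z <= 0 or not math.isfinite(Z):
        raise ValueError("partition integral vanished: empty configuration space")
    r = np.linspace(edges[0], edges[-1], n_grid)
    u = u_total(r)
    w = r**2 if radial_weight else np.ones_like(r)
    dens = np.where(np.isfinite(u), w * np.exp(-np.clip(u, -700, 700) / T), 0.0) / Z
    return EquilibriumDistribution(
        r=r,
        density=dens,
        Z=Z,
        edges=edges,
        T=T,
        radial_weight=radial_weight,
        u_total=u_total,
        breakpoints=tuple(breakpoints),
    )


def bin_fractions(dist: EquilibriumDistribution, pot: HistogramPotential) -> np.ndarray:
    """Probability mass of each histogram bin, by quadrature over the density."""
    fracs = np.empty(pot.n_bins)
    for i, (a, b) in enumerate(zip(pot.edges[:-1], pot.edges[1:])):
        fracs[i] = (
            _bin_mass_quad(dist.u_total, a, b, dist.T, dist.radial_weight, dist.breakpoints)
            / dist.Z
        )
    return fracs


def closed_form_bin_fractions(
    pot: HistogramPotential, T: float = 1.0, radial_weight: bool = True
) -> np.ndarray:
    """Per-bin fractions for a purely piecewise-constant potential.

    fraction_i is proportional to exp(-U_i/T) * (b_i**3 - b_{i-1}**3) with the
    radial weight (or to the bin width without it).
    """
    edges = np.asarray(pot.edges)
    u = np.asarray(pot.energies)
    if radial_weight:
        shells = (edges[1:] ** 3 - edges[:-1] ** 3) / 3.0
    else:
        shells = edges[1:] - edges[:-1]
    # subtract min for overflow safety; cancels on normalisation
    weights = np.exp(-(u - u.min()) / T) * shells
    return weights / weights.sum()


def fraction_native(
    model: ProteinModel,
    c_urea: float,
    u_crowd: Callable | None = None,
    T: float = 1.0,
    radial_weight: bool = True,
    breakpoints: Sequence[float] = (),
) -> float:
    """Equilibrium native (bin-1) fraction at ``c_urea`` [M].

    Uses the closed-form partition sum when no crowding potential is given,
    otherwise adaptive quadrature with the continuous depletion potential
    added inside every bin.
    """
    pot = model.build_potential(c_urea)
    if u_crowd is None:
        return float(closed_form_bin_fractions(pot, T, radial_weight)[NATIVE_BIN])
    dist = equilibrium_distribution(
        pot, u_crowd, T=T, radial_weight=radial_weight, n_grid=2, breakpoints=breakpoints
    )
    return float(bin_fractions(dist, pot)[NATIVE_BIN])


def solve_c50(
    model: ProteinModel,
    u_crowd: Callable | None = None,
    c_lo: float = 0.0,
    c_hi: float = 10.0,
    T: float = 1.0,
    breakpoints: Sequence[float] = (),
) -> float:
    """Urea concentration at which the native fraction crosses 1/2.

    Root-finding by bisection on the strictly decreasing f_native(c); the
    returned concentration satisfies |f_native(c) - 0.5| < 1e-6.

    Raises
    ------
    ValueError
        If f_native - 0.5 does not change sign on [c_lo, c_hi]; the message
        reports the bracketing values.
    """

    def g(c):
        return fraction_native(model, c, u_crowd, T=T, breakpoints=breakpoints) - 0.5

    g_lo, g_hi = g(c_lo), g(c_hi)
    if g_lo * g_hi > 0:
        raise ValueError(
            f"f_native - 0.5 does not cross zero on [{c_lo}, {c_hi}] M: "
            f"f({c_lo}) = {g_lo + 0.5:.6g}, f({c_hi}) = {g_hi + 0.5:.6g}"
        )
    c50 = optimize.brentq(g, c_lo, c_hi, xtol=1e-12, rtol=1e-14)
    assert abs(g(c50)) < 1e-6
    return float(c50)


def closed_form_c50(model: ProteinModel, T: float = 1.0) -> float:
    """Dilute-solution c50 from the algebraic root of the partition sum.

    Solves exp(-U1(c)/T) * (b1^3 - b0^3) = sum_{i>=2} exp(-U_i/T) (b_i^3 - b_{i-1}^3)
    for c, which is linear in c through U1(c) = intercept + slope * c.
    """
    edges = np.asarray(model.edges)
    shells = edges[1:] ** 3 - edges[:-1] ** 3
    s = float(np.sum(np.exp(-np.asarray(model.nonnative_energies) / T) * shells[1:]))
    # exp(-(a + b c)/T) * shells[0] = s  =>  c = (-a - T ln(s / shells[0])) / b
    return float(
        (-model.urea_intercept - T * math.log(s / shells[0])) / model.urea_slope
    )


def c50_from_curve(c_urea: np.ndarray, f_native: np.ndarray) -> float:
    """c50 from a discrete (possibly noisy) denaturation curve.

    The curve is first made non-increasing by the pool-adjacent-violators
    algorithm, then the 0.5 level is located by piecewise-linear
    interpolation across the crossing.

    Raises
    ------
    ValueError
        If the monotonised curve never crosses 0.5.
    """
    c = np.asarray(c_urea, dtype=float)
    f = np.asarray(f_native, dtype=float)
    order = np.argsort(c)
    c, f = c[order], f[order]
    g = _pav_nonincreasing(f)
    above = g >= 0.5
    if not above.any() or above.all():
        raise ValueError(
            f"denaturation curve does not cross 0.5 on [{c[0]}, {c[-1]}] M "
            f"(f range {g.min():.3g}..{g.max():.3g})"
        )
    i = int(np.nonzero(above)[0][-1])  # last point at or above 0.5
    if i == len(c) - 1:
        return float(c[-1])
    f0, f1 = g[i], g[i + 1]
    if f0 == f1:
        return float(0.5 * (c[i] + c[i + 1]))
    return float(c[i] + (f0 - 0.5) / (f0 - f1) * (c[i + 1] - c[i]))


def _pav_nonincreasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators projection onto non-increasing sequences."""
    y = np.asarray(y, dtype=float)
    # fit non-decreasing to -y
    vals = list(-y)
    weights = [1.0] * len(vals)
    means: list[float] = []
    counts: list[float] = []
    for v, w in zip(vals, weights):
        means.append(v)
        counts.append(w)
        while len(means) > 1 and means[-2] > means[-1]:
            m2, c2 = means.pop(), counts.pop()
            m1, c1 = means.pop(), counts.pop()
            means.append((m1 * c1 + m2 * c2) / (c1 + c2))
            counts.append(c1 + c2)
    out = np.empty(len(vals))
    i = 0
    for m, cnt in zip(means, counts):
        out[i : i + int(cnt)] = m
        i += int(cnt)
    return -out


@dataclass
class DenaturationCurve:
    """f_native versus urea concentration, optionally with standard errors."""

    c_urea: np.ndarray
    f_native: np.ndarray
    stderr: np.ndarray | None = None
    source: str = "theory"

    def __post_init__(self):
        self.c_urea = np.asarray(self.c_urea, dtype=float)
        self.f_native = np.asarray(self.f_native, dtype=float)
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)
        if np.any((self.f_native < 0) | (self.f_native > 1)):
            raise ValueError("f_native values must lie in [0, 1]")

    def c50(self) -> float:
        return c50_from_curve(self.c_urea, self.f_native)

    def to_frame(self):
        import pandas as pd

        err = self.stderr if self.stderr is not None else np.full_like(self.f_native, np.nan)
        return pd.DataFrame(
            {
                "c_urea_M": self.c_urea,
                "f_native": self.f_native,
                "stderr": err,
                "source": self.source,
            }
        )
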