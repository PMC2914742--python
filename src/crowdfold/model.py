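"""Two-subunit protein model and its urea-dependent histogram pair potential.

The "protein" is two hard spheres of radius 13 A whose centre-to-centre
separation ``r`` is governed by a piecewise-constant potential on six bins
between a hard core at 26 A and a hard outer wall at 104 A.  Bin 1 is the
native well; its depth varies linearly with urea concentration.  The radius
of gyration of the doublet is ``r / 2``.

Energies are in units of kT (kT = 1 in reduced units).
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_EDGES",
    "DEFAULT_NONNATIVE_KT",
    "DEFAULT_SUBUNIT_RADIUS",
    "DEFAULT_UREA_INTERCEPT",
    "DEFAULT_UREA_SLOPE",
    "NATIVE_BIN",
    "HistogramPotential",
    "ProteinModel",
    "build_potential",
    "radius_of_gyration",
]

#: Bin boundaries b0..b6 of the dilute-solution potential [A].
DEFAULT_EDGES: tuple[float, ...] = (26.0, 28.6, 41.6, 57.2, 72.8, 88.4, 104.0)

#: Urea-independent energies of bins 2..6 [kT].
DEFAULT_NONNATIVE_KT: tuple[float, ...] = (4.0, 0.0, 1.0, 3.0, 6.0)

#: Radius of one subunit sphere [A]; the hard core sits at twice this value.
DEFAULT_SUBUNIT_RADIUS: float = 13.0

#: Native-well depth at zero urea [kT].
DEFAULT_UREA_INTERCEPT: float = -10.8

#: Linear urea coefficient of the native well [kT / M].
DEFAULT_UREA_SLOPE: float = 3.3

#: Zero-based index of the native bin.
NATIVE_BIN: int = 0


@dataclass(frozen=True)
class HistogramPotential:
    """Piecewise-constant radial pair potential with hard inner and outer walls.

    Separations below ``edges[0]`` or above ``edges[-1]`` are inaccessible
    (infinite energy).  Bin membership is half-open, ``edges[i] <= r <
    edges[i+1]``, except that the final bin is closed at the outer wall.
    The boundary convention is a zero-measure choice; it is applied
    identically by the analytic theory and by trajectory analysis.

    Parameters
    ----------
    edges
        Strictly increasing bin boundaries [A]; one more than the number of bins.
    energies
        Energy of each bin [kT].
    """

    edges: tuple[float, ...]
    energies: tuple[float, ...]

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        energies = tuple(float(u) for u in self.energies)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "energies", energies)
        if len(edges) < 2:
            raise ValueError("need at least two edges")
        if len(energies) != len(edges) - 1:
            raise ValueError(
                f"{len(edges)} edges require {len(edges) - 1} energies, "
                f"got {len(energies)}"
            )
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError(f"edges must be strictly increasing: {edges}")
        if any(not math.isfinite(u) for u in energies):
            raise ValueError("bin energies must be finite")

    @property
    def n_bins(self) -> int:
        return len(self.energies)

    @property
    def hard_core(self) -> float:
        """Inner hard-wall position [A]."""
        return self.edges[0]

    @property
    def outer_wall(self) -> float:
        """Outer hard-wall position [A]."""
        return self.edges[-1]

    def bin_index(self, r: float) -> int:
        """Zero-based bin containing separation ``r``, or -1 outside the walls."""
        if r < 0:
            raise ValueError(f"separation must be non-negative, got {r}")
        if r < self.edges[0] or r > self.edges[-1]:
            return -1
        if r == self.edges[-1]:
            return self.n_bins - 1
        return bisect_right(self.edges, r) - 1

    def evaluate(self, r: float) -> float:
        """Potential energy [kT] at separation ``r``; ``inf`` outside the walls."""
        i = self.bin_index(r)
        return math.inf if i < 0 else self.energies[i]

    __call__ = evaluate

    def evaluate_array(self, r: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`evaluate`."""
        r = np.asarray(r, dtype=float)
        if np.any(r < 0):
            raise ValueError("separations must be non-negative")
        idx = np.searchsorted(self.edges, r, side="right") - 1
        idx = np.where(r == self.edges[-1], self.n_bins - 1, idx)
        out = np.full(r.shape, math.inf)
        inside = (idx >= 0) & (idx < self.n_bins)
        out[inside] = np.asarray(self.energies)[idx[inside]]
        return out

    def with_energies(self, energies) -> "HistogramPotential":
        return HistogramPotential(self.edges, tuple(energies))

    def to_dict(self) -> dict:
        return {
            "edges_angstrom": list(self.edges),
            "energies_kT": list(self.energies),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HistogramPotential":
        return cls(tuple(d["edges_angstrom"]), tuple(d["energies_kT"]))


@dataclass(frozen=True)
class ProteinModel:
    """The two-subunit model: geometry plus the urea-dependent potential family.

    ``subunit_radius`` fixes the hard core at ``2 * subunit_radius``, which
    must coincide with the first edge.  Bin 1 (index 0) is the native well
    with energy ``urea_intercept + urea_slope * c_urea``; bins 2..6 carry
    the urea-independent ``nonnative_energies``.
    """

    subunit_radius: float = DEFAULT_SUBUNIT_RADIUS
    edges: tuple[float, ...] = DEFAULT_EDGES
    nonnative_energies: tuple[float, ...] = DEFAULT_NONNATIVE_KT
    urea_intercept: float = DEFAULT_UREA_INTERCEPT
    urea_slope: float = DEFAULT_UREA_SLOPE

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", tuple(float(e) for e in self.edges))
        object.__setattr__(
            self, "nonnative_energies", tuple(float(u) for u in self.nonnative_energies)
        )
        if self.subunit_radius <= 0:
            raise ValueError("subunit_radius must be positive")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError(f"edges must be strictly increasing: {self.edges}")
        if not math.isclose(self.edges[0], 2.0 * self.subunit_radius):
            raise ValueError(
                f"hard core {self.edges[0]} must equal twice the subunit radius "
                f"({2 * self.subunit_radius})"
            )
        if len(self.nonnative_energies) != len(self.edges) - 2:
            raise ValueError("need one non-native energy per bin beyond the first")

    @property
    def hard_core(self) -> float:
        return self.edges[0]

    @property
    def native_boundary(self) -> float:
        """Outer edge of the native bin, b1 [A]."""
        return self.edges[1]

    def native_energy(self, c_urea: float) -> float:
        """Native-well energy [kT] at urea concentration ``c_urea`` [M]."""
        if c_urea < 0:
            raise ValueError(f"urea concentration must be >= 0, got {c_urea}")
        return self.urea_intercept + self.urea_slope * c_urea

    def build_potential(self, c_urea: float) -> HistogramPotential:
        """Histogram potential at urea concentration ``c_urea`` [M]."""
        energies = (self.native_energy(c_urea),) + self.nonnative_energies
        return HistogramPotential(self.edges, energies)

    def to_dict(self) -> dict:
        return {
            "subunit_radius_angstrom": self.subunit_radius,
            "edges_angstrom": list(self.edges),
            "energies_kT": list(self.nonnative_energies),
            "urea_intercept_kT": self.urea_intercept,
            "urea_slope_kT_per_M": self.urea_slope,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProteinModel":
        known = {
            "subunit_radius_angstrom",
            "edges_angstrom",
            "energies_kT",
            "urea_intercept_kT",
            "urea_slope_kT_per_M",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown model keys: {sorted(unknown)}")
        kwargs = {}
        if "subunit_radius_angstrom" in d:
            kwargs["subunit_radius"] = float(d["subunit_radius_angstrom"])
        if "edges_angstrom" in d:
            kwargs["edges"] = tuple(d["edges_angstrom"])
        if "energies_kT" in d:
            kwargs["nonnative_energies"] = tuple(d["energies_kT"])
        if "urea_intercept_kT" in d:
            kwargs["urea_intercept"] = float(d["urea_intercept_kT"])
        if "urea_slope_kT_per_M" in d:
            kwargs["urea_slope"] = float(d["urea_slope_kT_per_M"])
        return cls(**kwargs)


def build_potential(c_urea: float, model: ProteinModel | None = None) -> HistogramPotential:
    """Build the histogram potential at ``c_urea`` [M] for ``model`` (default model if None)."""
    return (model or ProteinModel()).build_potential(c_urea)


def radius_of_gyration(r):
    """Radius of gyration of the doublet at separation ``r``: r / 2."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation must be non-negative")
    out = r / 2.0
    return float(out) if out.ndim == 0 else out
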