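"""Step-wise (square-well / histogram) pair potentials for event-driven dynamics."""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass

from crowdfold.model import HistogramPotential

__all__ = ["StepPairPotential"]


@dataclass(frozen=True)
class StepPairPotential:
    """Radial pair potential that is piecewise constant between boundaries.

    ``boundaries`` are strictly increasing interaction distances; the
    innermost is always a hard core (separations below it are forbidden).
    ``levels[i]`` is the energy of shell i, the open interval between
    ``boundaries[i]`` and ``boundaries[i+1]``; the last shell extends to
    infinity unless ``outer_wall`` is set, in which case the outermost
    boundary is a second hard wall and there are ``len(boundaries) - 1``
    shells.

    A plain hard sphere is ``StepPairPotential((sigma,), (0.0,))``.
    """

    boundaries: tuple[float, ...]
    levels: tuple[float, ...]
    outer_wall: bool = False

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.boundaries)
        lv = tuple(float(x) for x in self.levels)
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "levels", lv)
        if not b:
            raise ValueError("need at least one boundary (the hard core)")
        if any(v <= u for u, v in zip(b, b[1:])):
            raise ValueError(f"boundaries must be strictly increasing: {b}")
        expected = len(b) - 1 if self.outer_wall else len(b)
        if len(lv) != expected:
            raise ValueError(
                f"{len(b)} boundaries with outer_wall={self.outer_wall} "
                f"require {expected} shell energies, got {len(lv)}"
            )
        if any(not math.isfinite(v) for v in lv):
            raise ValueError("shell energies must be finite")

    @property
    def n_shells(self) -> int:
        return len(self.levels)

    @property
    def hard_core(self) -> float:
        return self.boundaries[0]

    @property
    def max_range(self) -> float:
        """Largest distance at which this potential can generate an event."""
        return self.boundaries[-1]

    @property
    def is_plain_hard_sphere(self) -> bool:
        return len(self.boundaries) == 1 and not self.outer_wall

    def shell_of(self, r: float, v_r: float = 0.0, tol: float = 1e-9) -> int:
        """Shell index containing separation ``r``.

        Exactly at a boundary (within ``tol``) the side is decided by the
        sign of the radial velocity ``v_r``: a receding pair is assigned to
        the outer shell, an approaching pair to the inner one (so that a
        just-resolved event is not immediately re-detected).
        """
        b = self.boundaries
        k = bisect_right(b, r)
        # snap to a boundary if within tolerance
        for j in (k - 1, k):
            if 0 <= j < len(b) and abs(r - b[j]) <= tol:
                k = j + 1 if v_r > 0 else j
                break
        shell = k - 1
        if shell < 0:
            raise ValueError(f"separation {r} is inside the hard core {b[0]}")
        if shell > self.n_shells - 1:
            if self.outer_wall:
                raise ValueError(f"separation {r} is outside the outer wall {b[-1]}")
            shell = self.n_shells - 1
        return shell

    def energy(self, shell: int) -> float:
        return self.levels[shell]

    def pending_boundaries(self, shell: int):
        """Boundaries reachable from ``shell``.

        Yields ``(boundary_index, sigma, is_hard, dU)`` where ``dU`` is the
        energy change if the boundary is crossed (0 for hard walls).
        """
        b = self.boundaries
        # inner boundary (approached from above)
        sigma = b[shell]
        if shell == 0:
            yield shell, sigma, True, 0.0
        else:
            yield shell, sigma, False, self.levels[shell - 1] - self.levels[shell]
        # outer boundary, if any (approached from below)
        outer = shell + 1
        if outer < len(b):
            if self.outer_wall and outer == len(b) - 1:
                yield outer, b[outer], True, 0.0
            else:
                yield outer, b[outer], False, self.levels[shell + 1] - self.levels[shell]

    @classmethod
    def hard_sphere(cls, sigma: float) -> "StepPairPotential":
        return cls((float(sigma),), (0.0,))

    @classmethod
    def from_histogram(cls, pot: HistogramPotential) -> "StepPairPotential":
        """Map a walled histogram potential onto a step potential.

        The inner edge becomes the hard core, interior edges finite steps,
        and the outer edge a hard outer wall.
        """
        return cls(pot.edges, pot.energies, outer_wall=True)
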