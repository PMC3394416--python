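"""Shear-number arithmetic and barrel geometry.

For a regular n-strand barrel with shear number S, rise per residue h and
inter-strand distance d, the strands tilt against the barrel axis by

    tan(theta) = h * S / (d * n)

The shear number of a closed barrel is the sum of the n relative shears of
consecutive strand pairs around the circle; an open sheet has n-1 terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .config import RunConfig

__all__ = [
    "BarrelGeometry",
    "slant_angle",
    "shear_number",
    "span_residues",
    "enumerate_nS",
]


def slant_angle(n: int, S: int, h: float = 3.3, d: float = 4.4) -> float:
    """Slant angle theta (radians, in [0, pi/2)) of strands vs the axis."""
    if n <= 0:
        raise ValueError("n must be positive")
    if S < 0:
        raise ValueError("S must be non-negative")
    return math.atan(h * S / (d * n))


def shear_number(relative_shears: Sequence[int], closed: bool = True) -> int:
    """Sum of relative shears: the shear number of a barrel (or sheet).

    A closed n-strand barrel carries n relative shears (one per circular
    adjacency); an open sheet carries n-1.  ``closed`` only documents the
    caller's intent; the value is the plain sum either way.
    """
    if not relative_shears:
        raise ValueError("empty relative-shear list")
    return int(sum(relative_shears))


def span_residues(theta: float, membrane_thickness: float = 30.0,
                  h: float = 3.3) -> int:
    """Residues needed to cross the membrane at tilt theta from the axis.

    A strand tilted by theta advances h*cos(theta) along the axis per
    residue, so crossing a slab of the given thickness takes
    ceil(thickness / (h cos theta)) residues.
    """
    if not 0 <= theta < math.pi / 2:
        raise ValueError("theta must lie in [0, pi/2)")
    if membrane_thickness < 0:
        raise ValueError("membrane thickness must be non-negative")
    if membrane_thickness == 0:
        return 0
    return math.ceil(membrane_thickness / (h * math.cos(theta)))


@dataclass(frozen=True)
class BarrelGeometry:
    """Derived geometry of an (n, S) barrel under a given configuration."""

    n: int
    S: int
    theta: float
    span_residues: int

    @classmethod
    def from_nS(cls, n: int, S: int,
                config: RunConfig | None = None) -> "BarrelGeometry":
        config = config or RunConfig()
        theta = slant_angle(n, S, config.h, config.d)
        return cls(n=n, S=S, theta=theta,
                   span_residues=span_residues(
                       theta, config.membrane_thickness, config.h))


def enumerate_nS(N: int, config: RunConfig | None = None) -> list[tuple[int, int]]:
    """All (n, S) couples worth scanning for a sequence of length N.

    n is even in the configured range, S even in [n, 2n], and the sequence
    must at least accommodate n strands of minimal length separated by
    minimal loops.  Sorted by (n, S); may be empty for short sequences.
    """
    config = config or RunConfig()
    min_per_strand = config.strand_len_bounds[0] + config.loop_len_bounds[0]
    out: list[tuple[int, int]] = []
    for n in config.n_values():
        if n * min_per_strand > N:
            continue
        for S in config.s_values(n):
            out.append((n, S))
    return out
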