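"""Protofibril lattice geometry of a fibrin fiber cross-section.

A fibrin fiber is modeled through one cross-section: a square lattice of
protofibril cross-sections. A fiber of diameter ``d`` (nm) that is a fraction
``p`` protein, built from solid cylindrical protofibrils of diameter 4.8 nm,
needs

    n = p * (d / 4.8)**2 = p * d**2 / 23.04

protofibrils. ``n`` is rounded to the nearest square number by rounding
``sqrt(n)`` to the nearest integer lattice side, so a 72.7 nm fiber at
p = 0.21 becomes a 7 x 7 grid of 49 protofibrils.

Protofibrils are 4-connected (von Neumann neighborhoods). The same adjacency
drives both plasmin crawling between protofibrils and the spatial weights of
the Moran's I analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PROTOFIBRIL_DIAMETER_NM",
    "DEFAULT_PROTEIN_FRACTION",
    "FiberSpec",
    "CrossSection",
    "protofibril_count",
    "grid_side",
    "build_cross_section",
    "adjacency_weights",
]

#: Diameter of a single protofibril cross-section, nm.
PROTOFIBRIL_DIAMETER_NM = 4.8

#: Protein volume fraction of a fibrin fiber used throughout the model.
DEFAULT_PROTEIN_FRACTION = 0.21


def protofibril_count(
    diameter_nm: float,
    protein_fraction: float = DEFAULT_PROTEIN_FRACTION,
    protofibril_diameter_nm: float = PROTOFIBRIL_DIAMETER_NM,
) -> float:
    """Real-valued number of protofibrils in a fiber cross-section.

    Ratio of the protein area of the fiber cross-section to the area of one
    protofibril cross-section: ``p * d**2 / d_pf**2`` (the pi/4 factors
    cancel). Not rounded; see :func:`grid_side` for the lattice side.
    """
    if not diameter_nm > 0:
        raise ValueError(f"diameter_nm must be > 0, got {diameter_nm}")
    if not 0 < protein_fraction <= 1:
        raise ValueError(
            f"protein_fraction must be in (0, 1], got {protein_fraction}"
        )
    if not protofibril_diameter_nm > 0:
        raise ValueError("protofibril_diameter_nm must be > 0")
    return protein_fraction * (diameter_nm / protofibril_diameter_nm) ** 2


def grid_side(
    diameter_nm: float,
    protein_fraction: float = DEFAULT_PROTEIN_FRACTION,
    protofibril_diameter_nm: float = PROTOFIBRIL_DIAMETER_NM,
) -> int:
    """Side of the square protofibril grid for a fiber of this diameter.

    ``sqrt(protofibril_count)`` rounded half-away-from-zero to the nearest
    integer, e.g. 72.7 nm at p = 0.21 gives sqrt(48.2) = 6.94 -> 7.
    """
    n = protofibril_count(diameter_nm, protein_fraction, protofibril_diameter_nm)
    side = int(math.floor(math.sqrt(n) + 0.5))
    if side < 1:
        raise ValueError(
            f"fiber of diameter {diameter_nm} nm holds no protofibril grid"
        )
    return side


@dataclass(frozen=True)
class FiberSpec:
    """Physical description of a fibrin fiber.

    Parameters
    ----------
    diameter_nm
        Fiber diameter in nm; must exceed the protofibril diameter.
    protein_fraction
        Fraction of the cross-section area that is protein, in (0, 1].
    protofibril_diameter_nm
        Diameter of one protofibril, nm.
    """

    diameter_nm: float
    protein_fraction: float = DEFAULT_PROTEIN_FRACTION
    protofibril_diameter_nm: float = PROTOFIBRIL_DIAMETER_NM

    def __post_init__(self) -> None:
        if not 0 < self.protein_fraction <= 1:
            raise ValueError(
                f"protein_fraction must be in (0, 1], got {self.protein_fraction}"
            )
        if not self.diameter_nm > self.protofibril_diameter_nm:
            raise ValueError(
                "diameter_nm must exceed protofibril_diameter_nm "
                f"({self.diameter_nm} <= {self.protofibril_diameter_nm})"
            )

    @property
    def protofibril_count(self) -> float:
        return protofibril_count(
            self.diameter_nm, self.protein_fraction, self.protofibril_diameter_nm
        )

    @property
    def side(self) -> int:
        return grid_side(
            self.diameter_nm, self.protein_fraction, self.protofibril_diameter_nm
        )

    def cross_section(self) -> "CrossSection":
        return build_cross_section(self.side)


@dataclass(frozen=True)
class CrossSection:
    """A side x side protofibril lattice with 4-connected adjacency.

    Protofibrils are indexed row-major: index = row * side + col. The
    flattened neighbor arrays (``neighbors_flat``, ``neighbor_offsets``) are
    the form consumed by the simulation kernels; ``neighbors`` is the
    per-protofibril view of the same structure.
    """

    side: int
    neighbors_flat: np.ndarray = field(repr=False)  # int64, concatenated lists
    neighbor_offsets: np.ndarray = field(repr=False)  # int64, len n+1
    edge_indices: np.ndarray = field(repr=False)  # int64, perimeter indices

    @property
    def n_protofibrils(self) -> int:
        return self.side * self.side

    @property
    def neighbors(self) -> list[np.ndarray]:
        off = self.neighbor_offsets
        return [
            self.neighbors_flat[off[i] : off[i + 1]]
            for i in range(self.n_protofibrils)
        ]

    def degree(self, i: int) -> int:
        return int(self.neighbor_offsets[i + 1] - self.neighbor_offsets[i])


def build_cross_section(side: int) -> CrossSection:
    """Build the 4-connected lattice for a ``side x side`` grid."""
    if side < 1:
        raise ValueError(f"side must be >= 1, got {side}")
    nbrs: list[list[int]] = []
    edge: list[int] = []
    for r in range(side):
        for c in range(side):
            cur: list[int] = []
            if r > 0:
                cur.append((r - 1) * side + c)
            if r < side - 1:
                cur.append((r + 1) * side + c)
            if c > 0:
                cur.append(r * side + c - 1)
            if c < side - 1:
                cur.append(r * side + c + 1)
            nbrs.append(cur)
            if r == 0 or r == side - 1 or c == 0 or c == side - 1:
                edge.append(r * side + c)
    offsets = np.zeros(side * side + 1, dtype=np.int64)
    np.cumsum([len(x) for x in nbrs], out=offsets[1:])
    flat = np.fromiter(
        (j for cur in nbrs for j in cur), dtype=np.int64, count=int(offsets[-1])
    )
    return CrossSection(
        side=side,
        neighbors_flat=flat,
        neighbor_offsets=offsets,
        edge_indices=np.asarray(edge, dtype=np.int64),
    )


def adjacency_weights(cs: CrossSection) -> np.ndarray:
    """Binary (0/1) spatial weights matrix of direct-neighbor adjacency.

    Symmetric with zero diagonal; identical to the structure plasmin uses to
    pick crawl destinations, and the weights used by the Moran's I analysis.
    """
    n = cs.n_protofibrils
    w = np.zeros((n, n), dtype=np.int64)
    off = cs.neighbor_offsets
    for i in range(n):
        w[i, cs.neighbors_flat[off[i] : off[i + 1]]] = 1
    return w
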