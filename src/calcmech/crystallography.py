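"""Slip and twin systems of calcite and Schmid-factor analysis.

Calcite deforms plastically on a small set of crystallographic systems:
e-type deformation twinning {-1018}<40-41> (unidirectional, three
symmetry-equivalent variants), r-type rhombohedral slip {10-14}<-2021>
(bidirectional, three variants) and f-type slip {-1012}<2-201>
(bidirectional, six variants: each f plane contains two <2-201>-type
directions).  This module enumerates the twelve systems in Miller-Bravais
indices, converts them to Cartesian geometry for the hexagonal structural
cell, and evaluates Schmid factors m = cos(phi) * cos(lambda) for an
arbitrary uniaxial load.

The sign bookkeeping matters physically: under uniaxial compression along
the load axis n, the resolved shear stress on a system (plane normal p,
shear direction d) acting along +d is proportional to -(n.p)(n.d) = -m.
A system whose allowed shear sense is only +d (an e twin) is therefore
*not* activated when m > 0 under compression, which is exactly why c-axis
compression of calcite activates r slip in its negative sense while
leaving e twinning dormant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HexagonalLattice",
    "MbPlane",
    "MbDirection",
    "SlipSystem",
    "SchmidResult",
    "plane_normal_cartesian",
    "direction_cartesian",
    "calcite_system_catalog",
    "schmid_factor",
    "rank_active_systems",
    "C_AXIS",
]

#: Unit vector along the crystallographic c axis in the Cartesian frame.
C_AXIS = np.array([0.0, 0.0, 1.0])

# Default structural-cell parameters of calcite (hexagonal setting), in
# Angstrom.  Miller-Bravais indices of the deformation systems are
# interpreted in this cell.
CALCITE_A = 4.99
CALCITE_C = 17.06


@dataclass(frozen=True)
class HexagonalLattice:
    """Hexagonal cell with basis a1 along x, a2 at 120 deg, c along z."""

    a: float = CALCITE_A
    c: float = CALCITE_C

    def __post_init__(self) -> None:
        if self.a <= 0 or self.c <= 0:
            raise ValueError("lattice parameters must be positive")

    @property
    def direct_basis(self) -> np.ndarray:
        """Row vectors a1, a2, a3 in Cartesian coordinates."""
        a, c = self.a, self.c
        return np.array(
            [
                [a, 0.0, 0.0],
                [-a / 2.0, a * np.sqrt(3.0) / 2.0, 0.0],
                [0.0, 0.0, c],
            ]
        )

    @property
    def reciprocal_basis(self) -> np.ndarray:
        """Row vectors b1, b2, b3 (crystallographic convention, no 2*pi)."""
        a1, a2, a3 = self.direct_basis
        volume = float(np.dot(a1, np.cross(a2, a3)))
        return np.array(
            [
                np.cross(a2, a3) / volume,
                np.cross(a3, a1) / volume,
                np.cross(a1, a2) / volume,
            ]
        )


@dataclass(frozen=True)
class MbPlane:
    """Lattice plane (h k i l) in Miller-Bravais indices, h + k + i = 0."""

    h: int
    k: int
    i: int
    l: int

    def __post_init__(self) -> None:
        if self.h + self.k + self.i != 0:
            raise ValueError(f"plane indices must satisfy h+k+i=0, got {self}")

    @property
    def miller(self) -> tuple[int, int, int]:
        """Three-index (h k l) form."""
        return (self.h, self.k, self.l)

    def __str__(self) -> str:
        return f"({self.h} {self.k} {self.i} {self.l})"


@dataclass(frozen=True)
class MbDirection:
    """Lattice direction [u v t w] in Miller-Bravais indices, u + v + t = 0."""

    u: int
    v: int
    t: int
    w: int

    def __post_init__(self) -> None:
        if self.u + self.v + self.t != 0:
            raise ValueError(f"direction indices must satisfy u+v+t=0, got {self}")

    @property
    def miller(self) -> tuple[int, int, int]:
        """Three-index [U V W] form: U = u - t, V = v - t, W = w."""
        return (self.u - self.t, self.v - self.t, self.w)

    def contained_in(self, plane: MbPlane) -> bool:
        """Zone condition hu + kv + it + lw = 0."""
        return (
            plane.h * self.u + plane.k * self.v + plane.i * self.t + plane.l * self.w
            == 0
        )

    def __str__(self) -> str:
        return f"[{self.u} {self.v} {self.t} {self.w}]"


@dataclass(frozen=True)
class SlipSystem:
    """A deformation system: plane, in-plane shear direction, family, sense.

    ``sense`` is "positive" for unidirectional twinning (shear allowed only
    along +direction) and "bidirectional" for ordinary slip.
    """

    plane: MbPlane
    direction: MbDirection
    family: str  # "e" | "r" | "f"
    sense: str = "bidirectional"  # "positive" | "negative" | "bidirectional"

    def __post_init__(self) -> None:
        if self.family not in ("e", "r", "f"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.sense not in ("positive", "negative", "bidirectional"):
            raise ValueError(f"unknown sense {self.sense!r}")
        if not self.direction.contained_in(self.plane):
            raise ValueError(
                f"direction {self.direction} does not lie in plane {self.plane}"
            )

    def __str__(self) -> str:
        return f"{self.family} {self.plane}{self.direction} ({self.sense})"


@dataclass(frozen=True)
class SchmidResult:
    """Schmid factor of one system for one load.

    ``schmid_factor`` is signed: m = (n.p)(n.d) for load axis n, plane
    normal p and shear direction d.  ``resolved_sense`` is the sense in
    which shear actually proceeds under the stated load sign, and
    ``activated`` says whether that sense is allowed by the system.
    """

    system: SlipSystem
    schmid_factor: float
    resolved_sense: str  # "positive" | "negative" | "none"
    activated: bool


def plane_normal_cartesian(plane: MbPlane, lattice: HexagonalLattice) -> np.ndarray:
    """Unit normal of a lattice plane via the reciprocal basis."""
    h, k, l = plane.miller
    g = h * lattice.reciprocal_basis[0] + k * lattice.reciprocal_basis[1] + l * lattice.reciprocal_basis[2]
    norm = np.linalg.norm(g)
    if norm == 0:
        raise ValueError(f"plane {plane} maps to the zero vector")
    return g / norm


def direction_cartesian(direction: MbDirection, lattice: HexagonalLattice) -> np.ndarray:
    """Unit vector of a lattice direction via the direct basis."""
    u, v, w = direction.miller
    r = u * lattice.direct_basis[0] + v * lattice.direct_basis[1] + w * lattice.direct_basis[2]
    norm = np.linalg.norm(r)
    if norm == 0:
        raise ValueError(f"direction {direction} maps to the zero vector")
    return r / norm


def _cyclic_variants(h: int, k: int, i: int, l: int) -> list[tuple[int, int, int, int]]:
    """The three cyclic permutations of the basal indices (h, k, i)."""
    return [(h, k, i, l), (i, h, k, l), (k, i, h, l)]


def calcite_system_catalog(
    lattice: HexagonalLattice | None = None,
) -> list[SlipSystem]:
    """The twelve deformation systems of calcite.

    Returns 3 e-twin systems (positive sense only), 3 r-slip systems and
    6 f-slip systems, in that order.  Each plane of a family is paired
    with every family direction satisfying the zone condition; for e and
    r this gives exactly one direction per plane, for f exactly two.
    """
    if lattice is None:
        lattice = HexagonalLattice()

    families = [
        ("e", (-1, 0, 1, 8), (4, 0, -4, 1), "positive"),
        ("r", (1, 0, -1, 4), (-2, 0, 2, 1), "bidirectional"),
        ("f", (-1, 0, 1, 2), (2, -2, 0, 1), "bidirectional"),
    ]
    catalog: list[SlipSystem] = []
    for family, plane_proto, dir_proto, sense in families:
        planes = [MbPlane(*idx) for idx in _cyclic_variants(*plane_proto)]
        directions = [MbDirection(*idx) for idx in _cyclic_variants(*dir_proto)]
        for plane in planes:
            for d in directions:
                if d.contained_in(plane):
                    catalog.append(SlipSystem(plane, d, family, sense))
    # sanity: the crystallographically required multiplicities
    counts = {f: sum(1 for s in catalog if s.family == f) for f in "erf"}
    assert counts == {"e": 3, "r": 3, "f": 6}, counts
    return catalog


def _as_unit_axis(load_axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(load_axis, dtype=float)
    if axis.shape != (3,):
        raise ValueError("load axis must be a 3-vector")
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("load axis must be non-zero")
    if not np.isclose(norm, 1.0, atol=1e-9):
        warnings.warn("load axis was not a unit vector; normalizing", stacklevel=3)
    return axis / norm


def schmid_factor(
    load_axis: np.ndarray,
    system: SlipSystem,
    lattice: HexagonalLattice | None = None,
    load_sign: str = "compression",
) -> SchmidResult:
    """Schmid factor and activation of one system under uniaxial load.

    m = cos(phi) cos(lambda) with phi the angle between load axis and
    plane normal and lambda the angle between load axis and shear
    direction.  For a compressive load the shear resolved along the
    system's +direction has the sign of -m; for tension, of +m.
    """
    if lattice is None:
        lattice = HexagonalLattice()
    if load_sign not in ("compression", "tension"):
        raise ValueError("load_sign must be 'compression' or 'tension'")
    axis = _as_unit_axis(load_axis)
    normal = plane_normal_cartesian(system.plane, lattice)
    shear_dir = direction_cartesian(system.direction, lattice)
    m = float(np.dot(axis, normal) * np.dot(axis, shear_dir))

    shear_along_plus = -m if load_sign == "compression" else m
    if abs(m) < 1e-14:
        resolved = "none"
        activated = False
    elif shear_along_plus > 0:
        resolved = "positive"
        activated = system.sense in ("positive", "bidirectional")
    else:
        resolved = "negative"
        activated = system.sense in ("negative", "bidirectional")
    return SchmidResult(system, m, resolved, activated)


def rank_active_systems(
    load_axis: np.ndarray,
    catalog: list[SlipSystem] | None = None,
    lattice: HexagonalLattice | None = None,
    load_sign: str = "compression",
    degeneracy_tol: float = 1e-9,
) -> list[list[SchmidResult]]:
    """Activatable systems ranked by |m| descending, degenerate ties grouped.

    Returns a list of groups; systems within a group share |m| to within
    ``degeneracy_tol`` (symmetry-equivalent variants under a symmetric
    load appear together).
    """
    if lattice is None:
        lattice = HexagonalLattice()
    if catalog is None:
        catalog = calcite_system_catalog(lattice)
    results = [
        schmid_factor(load_axis, s, lattice, load_sign) for s in catalog
    ]
    active = sorted(
        (r for r in results if r.activated),
        key=lambda r: -abs(r.schmid_factor),
    )
    groups: list[list[SchmidResult]] = []
    for r in active:
        if groups and abs(abs(groups[-1][0].schmid_factor) - abs(r.schmid_factor)) <= degeneracy_tol:
            groups[-1].append(r)
        else:
            groups.append([r])
    return groups


def catalog_table(
    lattice: HexagonalLattice | None = None,
    load_axis: np.ndarray | None = None,
    load_sign: str = "compression",
):
    """All twelve systems with Cartesian geometry and (optionally) Schmid data.

    Returns a pandas DataFrame; a convenience export used by the examples.
    """
    import pandas as pd

    if lattice is None:
        lattice = HexagonalLattice()
    rows = []
    for sys_ in calcite_system_catalog(lattice):
        row = {
            "family": sys_.family,
            "plane": str(sys_.plane),
            "direction": str(sys_.direction),
            "sense": sys_.sense,
        }
        if load_axis is not None:
            res = schmid_factor(load_axis, sys_, lattice, load_sign)
            row.update(
                schmid_factor=res.schmid_factor,
                abs_m=abs(res.schmid_factor),
                resolved_sense=res.resolved_sense,
                activated=res.activated,
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    if load_axis is not None:
        df = df.sort_values("abs_m", ascending=False, ignore_index=True)
    return df
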