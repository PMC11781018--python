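"""Search spaces, Z-matrix internal coordinates, and Cartesian conversion.

A :class:`SearchSpace` is a box over named internal coordinates (bond
distances in Angstrom, bond/dihedral angles in degrees) or over abstract
coordinates for analytic model surfaces.  Molecular spaces additionally carry
a Z-matrix topology that maps coordinate values to Cartesian positions.

Placement convention: atom 1 sits at the origin, atom 2 on the +z axis, and
atom 3 in the xz-plane (x >= 0).  Dihedral angles follow the IUPAC right-hand
rule with 0 degrees = syn (eclipsed).  Angles and dihedrals are stored in
degrees throughout and converted to radians only inside the trigonometric
routines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial.distance import pdist

DISTANCE = "distance"
ANGLE = "angle"
DIHEDRAL = "dihedral"
ABSTRACT = "abstract"

_COORD_KINDS = (DISTANCE, ANGLE, DIHEDRAL, ABSTRACT)


class DegenerateFrameError(ValueError):
    """Raised when three Z-matrix reference atoms are colinear, so the
    dihedral construction frame is undefined."""


class UndefinedPairError(ValueError):
    """Raised when a pairwise-distance query needs at least two atoms."""


@dataclass(frozen=True)
class ZMatrixAtom:
    """One Z-matrix row.

    ``distance``/``angle``/``dihedral`` are either the name of a search-space
    coordinate or a fixed float (Angstrom / degrees).  Reference atoms are
    0-based indices of previously defined atoms.
    """

    element: str
    distance_ref: Optional[int] = None
    angle_ref: Optional[int] = None
    dihedral_ref: Optional[int] = None
    distance: Union[str, float, None] = None
    angle: Union[str, float, None] = None
    dihedral: Union[str, float, None] = None


@dataclass(frozen=True)
class SearchSpace:
    """Box-bounded feasible region over named internal coordinates."""

    names: tuple
    kinds: tuple
    lower: np.ndarray
    upper: np.ndarray
    topology: Optional[tuple] = None  # tuple[ZMatrixAtom, ...] for molecules

    def __post_init__(self):
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "kinds", tuple(self.kinds))
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if self.topology is not None:
            object.__setattr__(self, "topology", tuple(self.topology))
        d = len(self.names)
        if len(set(self.names)) != d:
            raise ValueError("coordinate names must be unique")
        if not (len(self.kinds) == lower.size == upper.size == d):
            raise ValueError("names, kinds and bounds must have equal length")
        for k in self.kinds:
            if k not in _COORD_KINDS:
                raise ValueError(f"unknown coordinate kind {k!r}")
        if np.any(lower >= upper):
            raise ValueError("lower bound must be strictly below upper bound")
        for name, kind, lo, up in zip(self.names, self.kinds, lower, upper):
            if kind == DISTANCE and lo <= 0.0:
                raise ValueError(f"distance {name}: bounds must be positive")
            if kind == ANGLE and (lo < 0.0 or up > 180.0):
                raise ValueError(f"angle {name}: bounds must lie in [0, 180]")
            if kind == DIHEDRAL and (lo < -180.0 or up > 180.0):
                raise ValueError(
                    f"dihedral {name}: bounds must lie in [-180, 180]"
                )
        if self.topology is not None:
            self._validate_topology()

    def _validate_topology(self):
        known = set(self.names)
        for i, atom in enumerate(self.topology):
            refs = (atom.distance_ref, atom.angle_ref, atom.dihedral_ref)
            n_refs = min(i, 3)
            for r in refs[:n_refs]:
                if r is None or not (0 <= r < i):
                    raise ValueError(
                        f"atom {i}: references must point to previously "
                        f"defined atoms"
                    )
            for label in (atom.distance, atom.angle, atom.dihedral):
                if isinstance(label, str) and label not in known:
                    raise ValueError(
                        f"atom {i}: unknown coordinate name {label!r}"
                    )

    @property
    def ndim(self) -> int:
        return len(self.names)

    @property
    def is_molecular(self) -> bool:
        return self.topology is not None

    @property
    def bounds(self) -> list:
        """Bounds as [(lo, hi), ...], the scipy optimizer convention."""
        return list(zip(self.lower, self.upper))

    def contains(self, values) -> bool:
        v = np.asarray(values, dtype=float)
        return bool(np.all(v >= self.lower - 1e-12) and np.all(v <= self.upper + 1e-12))

    def clip(self, values) -> np.ndarray:
        return np.clip(np.asarray(values, dtype=float), self.lower, self.upper)

    def index_of(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class Geometry:
    """A point in internal-coordinate space, with Cartesian coordinates
    derived on demand for molecular spaces."""

    values: np.ndarray
    space: SearchSpace
    _cartesian: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.space.ndim,):
            raise ValueError(
                f"expected {self.space.ndim} coordinate values, "
                f"got shape {self.values.shape}"
            )

    @property
    def elements(self) -> list:
        if not self.space.is_molecular:
            return []
        return [a.element for a in self.space.topology]

    @property
    def cartesian(self) -> np.ndarray:
        if self._cartesian is None:
            self._cartesian = to_cartesian(self)
        return self._cartesian


def _resolve(label, geom: Geometry) -> float:
    if isinstance(label, str):
        return float(geom.values[geom.space.index_of(label)])
    return float(label)


def to_cartesian(geom: Geometry) -> np.ndarray:
    """Convert a Z-matrix geometry to an N x 3 Cartesian array (Angstrom).

    Atom 1 at the origin, atom 2 on the +z axis, atom 3 in the xz-plane.
    Raises :class:`DegenerateFrameError` when the three reference atoms of a
    dihedral-bearing atom are colinear.
    """
    space = geom.space
    if not space.is_molecular:
        raise ValueError("Cartesian conversion requires a Z-matrix topology")
    if not np.all(np.isfinite(geom.values)):
        raise ValueError("geometry values must be finite")
    topo = space.topology
    xyz = np.zeros((len(topo), 3))
    for i, atom in enumerate(topo):
        if i == 0:
            continue
        r = _resolve(atom.distance, geom)
        if i == 1:
            xyz[1] = (0.0, 0.0, r)
            continue
        theta = np.deg2rad(_resolve(atom.angle, geom))
        a = xyz[atom.distance_ref]
        b = xyz[atom.angle_ref]
        u = b - a
        nu = np.linalg.norm(u)
        if nu < 1e-10:
            raise DegenerateFrameError(
                f"atom {i}: distance and angle reference atoms coincide"
            )
        u = u / nu
        if i == 2:
            # third atom: fix the remaining rotational freedom to the
            # xz-plane (x >= 0); reference atoms lie on the z axis.
            e2 = np.array([1.0, 0.0, 0.0])
        else:
            c = xyz[atom.dihedral_ref]
            w = (c - b) - np.dot(c - b, u) * u
            nw = np.linalg.norm(w)
            if nw < 1e-10:
                raise DegenerateFrameError(
                    f"atom {i}: dihedral reference frame is colinear"
                )
            e2 = w / nw
        e3 = np.cross(u, e2)
        phi = np.deg2rad(_resolve(atom.dihedral, geom)) if i >= 3 else 0.0
        direction = (
            np.cos(theta) * u
            + np.sin(theta) * (np.cos(phi) * e2 - np.sin(phi) * e3)
        )
        xyz[i] = a + r * direction
    return xyz


def measure_distance(p0, p1) -> float:
    return float(np.linalg.norm(np.asarray(p1) - np.asarray(p0)))


def measure_angle(p0, p1, p2) -> float:
    """Angle p0-p1-p2 in degrees."""
    v1 = np.asarray(p0) - np.asarray(p1)
    v2 = np.asarray(p2) - np.asarray(p1)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def measure_dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees (IUPAC right-hand rule)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def internals_from_cartesian(space: SearchSpace, xyz: np.ndarray) -> np.ndarray:
    """Measure the named internal coordinates of ``space`` from Cartesians.

    Inverse of :func:`to_cartesian` for the same topology (used for
    round-trip checks and for importing external structures).
    """
    if not space.is_molecular:
        raise ValueError("requires a Z-matrix topology")
    values = np.full(space.ndim, np.nan)
    for i, atom in enumerate(space.topology):
        if i >= 1 and isinstance(atom.distance, str):
            values[space.index_of(atom.distance)] = measure_distance(
                xyz[i], xyz[atom.distance_ref]
            )
        if i >= 2 and isinstance(atom.angle, str):
            values[space.index_of(atom.angle)] = measure_angle(
                xyz[i], xyz[atom.distance_ref], xyz[atom.angle_ref]
            )
        if i >= 3 and isinstance(atom.dihedral, str):
            values[space.index_of(atom.dihedral)] = measure_dihedral(
                xyz[i],
                xyz[atom.distance_ref],
                xyz[atom.angle_ref],
                xyz[atom.dihedral_ref],
            )
    return values


def min_pair_distance(geom: Geometry) -> float:
    """Minimum Euclidean distance (Angstrom) over all unordered atom pairs."""
    xyz = geom.cartesian
    if xyz.shape[0] < 2:
        raise UndefinedPairError("need at least two atoms for a pair distance")
    return float(pdist(xyz).min())


def has_collision(geom: Geometry, threshold: float = 0.5) -> bool:
    """True iff some atom pair is strictly closer than ``threshold`` Angstrom.

    Abstract (non-molecular) spaces have no atoms, so they never collide.
    The comparison is strict: a pair at exactly the threshold is kept.
    """
    if threshold < 0:
        raise ValueError("collision threshold must be non-negative")
    if not geom.space.is_molecular:
        return False
    return min_pair_distance(geom) < threshold


def sample_uniform(space: SearchSpace, n: int, rng) -> np.ndarray:
    """Draw ``n`` points, each coordinate independent uniform within bounds.

    ``rng`` is a :class:`numpy.random.Generator` or an integer seed.
    Returns an (n, d) array.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return rng.uniform(space.lower, space.upper, size=(n, space.ndim))


def formaldehyde_like_space() -> SearchSpace:
    """Four-atom H2CO-type Z-matrix space: three distances, two angles,
    one dihedral, with the customary search bounds for bond rearrangement
    (r1 in [0.5, 2.0] A; r2, r3 in [0.5, 2.5] A; angles in [0, 180] deg;
    dihedral in [-180, 180] deg)."""
    topology = (
        ZMatrixAtom("C"),
        ZMatrixAtom("O", distance_ref=0, distance="r1"),
        ZMatrixAtom("H", distance_ref=0, angle_ref=1, distance="r2", angle="a1"),
        ZMatrixAtom(
            "H",
            distance_ref=0,
            angle_ref=1,
            dihedral_ref=2,
            distance="r3",
            angle="a2",
            dihedral="d1",
        ),
    )
    return SearchSpace(
        names=("r1", "r2", "r3", "a1", "a2", "d1"),
        kinds=(DISTANCE, DISTANCE, DISTANCE, ANGLE, ANGLE, DIHEDRAL),
        lower=np.array([0.5, 0.5, 0.5, 0.0, 0.0, -180.0]),
        upper=np.array([2.0, 2.5, 2.5, 180.0, 180.0, 180.0]),
        topology=topology,
    )


def read_xyz(path):
    """Read a plain XYZ file -> (elements, coords, comment)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = int(lines[0].strip())
    comment = lines[1] if len(lines) > 1 else ""
    elements, coords = [], []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        elements.append(parts[0])
        coords.append([float(p) for p in parts[1:4]])
    return elements, np.asarray(coords, dtype=float), comment


def write_xyz(path, elements: Sequence[str], coords: np.ndarray, comment: str = ""):
    coords = np.asarray(coords, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"{len(elements)}\n{comment}\n")
        for el, (x, y, z) in zip(elements, coords):
            fh.write(f"{el} {x:.10f} {y:.10f} {z:.10f}\n")
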