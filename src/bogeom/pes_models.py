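"""Energy oracles: two-state diabatic model surfaces and noise injection.

An oracle is any callable mapping a coordinate vector (internal coordinates,
aligned with a :class:`~bogeom.internal_coords.SearchSpace`) to an
:class:`EnergyRecord` with one or two electronic energies in kcal/mol.  The
shipped :class:`TwoStateModel` is an analytic stand-in for an electronic-
structure backend: two multi-dimensional quadratic diabats coupled linearly
through one designated coordinate, so the adiabatic surfaces

    E-/+ = (V1 + V2)/2 -/+ sqrt(((V1 - V2)/2)^2 + W^2),   W = c * q_coupling

exhibit a true conical intersection on the seam {q_coupling = 0, V1 = V2}.
The location and energy of the minimum-energy crossing (MECI) and of the
ground-state global minimum are available independently of the optimizer
(closed form and grid refinement respectively), which makes these surfaces
usable as test oracles.

Uniform energy noise (default half-width 2.0 kcal/mol, the magnitude of
errors observed in energy measurements on present-day quantum hardware) can
be layered on any oracle to emulate NISQ measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np
from scipy.optimize import minimize

from .internal_coords import ABSTRACT, SearchSpace


class NoIntersectionError(ValueError):
    """The two diabats never cross on the zero-coupling hyperplane."""


@dataclass(frozen=True)
class EnergyRecord:
    """One or two electronic state energies (kcal/mol) for a geometry."""

    e_s0: float
    e_s1: Optional[float] = None
    noisy: bool = False
    geometry_ref: Optional[str] = None

    @property
    def gap(self) -> Optional[float]:
        """E(S1) - E(S0), signed (noise may make it negative)."""
        if self.e_s1 is None:
            return None
        return self.e_s1 - self.e_s0


@dataclass(frozen=True)
class TwoStateModel:
    """Two quadratic diabats with linear coupling on one coordinate.

    V1(q) = sum_j k1_j (q_j - a_j)^2
    V2(q) = sum_j k2_j (q_j - b_j)^2 + delta
    W(q)  = coupling * q[coupling_index]

    Force constants in kcal/mol per unit^2, ``delta`` and energies in
    kcal/mol.
    """

    k1: np.ndarray
    k2: np.ndarray
    a: np.ndarray
    b: np.ndarray
    delta: float
    coupling: float
    coupling_index: int

    def __post_init__(self):
        for name in ("k1", "k2", "a", "b"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.k1.shape == self.k2.shape == self.a.shape == self.b.shape):
            raise ValueError("parameter arrays must share one shape")
        if np.any(self.k1 <= 0) or np.any(self.k2 <= 0):
            raise ValueError("force constants must be strictly positive")
        if not 0 <= self.coupling_index < self.k1.size:
            raise ValueError("coupling_index out of range")

    @property
    def ndim(self) -> int:
        return self.k1.size

    def diabats(self, X):
        """V1, V2 at points X of shape (..., d)."""
        X = np.asarray(X, dtype=float)
        v1 = np.sum(self.k1 * (X - self.a) ** 2, axis=-1)
        v2 = np.sum(self.k2 * (X - self.b) ** 2, axis=-1) + self.delta
        return v1, v2

    def coupling_term(self, X):
        X = np.asarray(X, dtype=float)
        return self.coupling * X[..., self.coupling_index]

    def adiabatic(self, X):
        """Lower and upper adiabatic energies (E_S0, E_S1) at points X."""
        v1, v2 = self.diabats(X)
        w = self.coupling_term(X)
        mean = 0.5 * (v1 + v2)
        root = np.sqrt((0.5 * (v1 - v2)) ** 2 + w**2)
        return mean - root, mean + root

    def __call__(self, values) -> EnergyRecord:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.ndim,):
            raise ValueError(
                f"oracle expects {self.ndim} coordinates, got {values.shape}"
            )
        e0, e1 = self.adiabatic(values)
        return EnergyRecord(e_s0=float(e0), e_s1=float(e1))


def adiabatic_energies(model: TwoStateModel, values) -> tuple:
    """(E_S0, E_S1) of ``model`` at one geometry."""
    rec = model(values)
    return rec.e_s0, rec.e_s1


def analytic_meci(model: TwoStateModel, space: SearchSpace):
    """Closed-form minimum-energy point of the degeneracy seam.

    Valid for models whose diabats differ in at most one non-coupling
    ("tuning") coordinate: on the seam {q_coupling = 0, V1 = V2} the
    degeneracy condition reduces to a quadratic in that coordinate.  Among
    the real roots inside the bounds, the lower-energy one is returned with
    the remaining coordinates at their (box-clipped) diabat-1 minimum.

    Returns ``(values, energy)``; raises :class:`NoIntersectionError` when
    the diabats never cross at zero coupling.
    """
    ci = model.coupling_index
    lo, hi = space.lower, space.upper
    if not (lo[ci] <= 0.0 <= hi[ci]):
        raise NoIntersectionError("zero-coupling hyperplane outside bounds")
    differing = [
        j
        for j in range(model.ndim)
        if j != ci and (model.k1[j] != model.k2[j] or model.a[j] != model.b[j])
    ]
    if len(differing) > 1:
        raise ValueError(
            "closed-form MECI requires diabats differing in one coordinate"
        )
    # constant part of V1 - V2 on the q_coupling = 0 hyperplane
    const = (
        model.k1[ci] * model.a[ci] ** 2
        - model.k2[ci] * model.b[ci] ** 2
        - model.delta
    )

    def seam_point(q_tune=None):
        q = model.a.astype(float).copy()
        q[ci] = 0.0
        if q_tune is not None:
            q[differing[0]] = q_tune
        return np.clip(q, lo, hi)

    if not differing:
        if abs(const) > 1e-12:
            raise NoIntersectionError("diabats are parallel at zero coupling")
        q = seam_point()
        return q, float(model.adiabatic(q)[0])

    t = differing[0]
    k1t, k2t, at, bt = model.k1[t], model.k2[t], model.a[t], model.b[t]
    # k1t (q-at)^2 - k2t (q-bt)^2 + const = 0
    A = k1t - k2t
    B = -2.0 * (k1t * at - k2t * bt)
    C = k1t * at**2 - k2t * bt**2 + const
    if abs(A) < 1e-14:
        if abs(B) < 1e-14:
            raise NoIntersectionError("diabats are parallel at zero coupling")
        roots = [-C / B]
    else:
        disc = B * B - 4 * A * C
        if disc < 0:
            raise NoIntersectionError("diabats never cross at zero coupling")
        roots = [(-B - np.sqrt(disc)) / (2 * A), (-B + np.sqrt(disc)) / (2 * A)]
    candidates = []
    for r in roots:
        if lo[t] - 1e-9 <= r <= hi[t] + 1e-9:
            q = seam_point(np.clip(r, lo[t], hi[t]))
            e0, e1 = model.adiabatic(q)
            candidates.append((float(e1), q))
    if not candidates:
        raise NoIntersectionError("seam roots fall outside the search bounds")
    energy, q = min(candidates, key=lambda item: item[0])
    return q, energy


def reference_gm(model: TwoStateModel, space: SearchSpace, n_grid: int = 201):
    """Box-constrained global minimum of E_S0 by dense scan + local refinement.

    This is the *test oracle* against which campaign results are judged, not
    part of the optimization method itself.  For d <= 3 a full grid with
    ``n_grid`` points per axis is scanned; in higher dimension a large
    quasi-dense random scan seeded deterministically is used.  The best
    points are refined with L-BFGS-B.
    """
    d = space.ndim
    if d <= 3:
        axes = [np.linspace(space.lower[j], space.upper[j], n_grid) for j in range(d)]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=-1)
    else:
        rng = np.random.default_rng(2024)
        pts = rng.uniform(space.lower, space.upper, size=(max(n_grid, 20000), d))
        pts = np.vstack([pts, np.clip(model.a, space.lower, space.upper),
                         np.clip(model.b, space.lower, space.upper)])
    e0 = model.adiabatic(pts)[0]
    order = np.argsort(e0)[:20]

    def f(x):
        return model.adiabatic(x)[0]

    best_x, best_e = None, np.inf
    for idx in order:
        res = minimize(f, pts[idx], method="L-BFGS-B", bounds=space.bounds)
        if res.fun < best_e:
            best_e, best_x = float(res.fun), res.x
    return best_x, best_e


def add_uniform_noise(record: EnergyRecord, half_width: float = 2.0, rng=None) -> EnergyRecord:
    """Add independent uniform noise on [-half_width, +half_width] kcal/mol
    to each state energy.  Deterministic given ``rng`` (Generator or seed);
    the noisy flag is always set."""
    if half_width < 0:
        raise ValueError("noise half-width must be non-negative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    e_s0 = float(record.e_s0 + rng.uniform(-half_width, half_width))
    e_s1 = record.e_s1
    if e_s1 is not None:
        e_s1 = float(e_s1 + rng.uniform(-half_width, half_width))
    return replace(record, e_s0=e_s0, e_s1=e_s1, noisy=True)


class NoisyOracle:
    """Wrap an oracle so every evaluation carries fresh uniform noise.

    The noise stream is its own seeded generator, so the clean oracle is
    recoverable by regenerating the stream with the same seed.
    """

    def __init__(self, oracle: Callable, half_width: float = 2.0, seed=0):
        if half_width < 0:
            raise ValueError("noise half-width must be non-negative")
        self.oracle = oracle
        self.half_width = half_width
        self.rng = np.random.default_rng(seed)

    def __call__(self, values) -> EnergyRecord:
        return add_uniform_noise(self.oracle(values), self.half_width, self.rng)


# ---------------------------------------------------------------------------
# Shipped benchmark surfaces (parameters frozen; optima documented in tests
# via the grid and closed-form oracles above).
# ---------------------------------------------------------------------------

def benchmark_2d_model() -> TwoStateModel:
    """Default 2D benchmark: GM at (1, 0) with E_S0 = 0; MECI at (2, 0) with
    E = 30 kcal/mol, both interior to the bounds of
    :func:`benchmark_2d_space`."""
    return TwoStateModel(
        k1=[30.0, 15.0],
        k2=[20.0, 12.0],
        a=[1.0, 0.0],
        b=[3.0, 0.0],
        delta=10.0,
        coupling=6.0,
        coupling_index=1,
    )


def benchmark_2d_space() -> SearchSpace:
    return SearchSpace(
        names=("q1", "q2"),
        kinds=(ABSTRACT, ABSTRACT),
        lower=np.array([-2.0, -3.0]),
        upper=np.array([6.0, 3.0]),
    )


def benchmark_6d_model() -> TwoStateModel:
    """Six-coordinate abstract analogue of a small-molecule landscape:
    diabats differ along the first (tuning) coordinate, coupling acts on the
    last (dihedral-like) coordinate.  The diabatic offset is set so that the
    moderate-alpha argmin of the degeneracy-penalty cost keeps an S0/S1 gap
    inside the 3 kcal/mol storage filter, the regime observed for real
    small-molecule intersections; GM at ``a`` with E = 0, MECI at
    (2, 1, 0.8, -0.5, 0.5, 0) with E = 16 kcal/mol."""
    return TwoStateModel(
        k1=[25.0, 20.0, 15.0, 15.0, 10.0, 8.0],
        k2=[15.0, 20.0, 15.0, 15.0, 10.0, 8.0],
        a=[1.2, 1.0, 0.8, -0.5, 0.5, 0.0],
        b=[3.0, 1.0, 0.8, -0.5, 0.5, 0.0],
        delta=1.0,
        coupling=5.0,
        coupling_index=5,
    )


def benchmark_6d_space() -> SearchSpace:
    """Bounds deliberately wide enough to include extreme-energy regions
    (the analogue of short-contact geometries in a molecular search space,
    where energies reach thousands of kcal/mol) and a second, much less
    stable intersection point on the seam at q1 = -5 — both features of
    realistic bond-rearrangement search spaces that shape how the
    degeneracy-penalty weight behaves."""
    return SearchSpace(
        names=tuple(f"q{j}" for j in range(1, 7)),
        kinds=(ABSTRACT,) * 6,
        lower=np.array([-6.0, -4.0, -4.0, -4.0, -4.0, -5.0]),
        upper=np.array([10.0, 6.0, 6.0, 6.0, 6.0, 5.0]),
    )


ORACLE_REGISTRY = {
    "benchmark2d": benchmark_2d_model,
    "benchmark6d": benchmark_6d_model,
}


def register_oracle(name: str, factory: Callable):
    """Register an oracle factory addressable by name from configuration."""
    ORACLE_REGISTRY[name] = factory


def get_oracle(name: str):
    try:
        return ORACLE_REGISTRY[name]()
    except KeyError:
        raise KeyError(
            f"unknown oracle {name!r}; known: {sorted(ORACLE_REGISTRY)}"
        ) from None
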