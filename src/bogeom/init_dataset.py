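"""Initial training sets for a campaign.

A campaign needs a modest seed dataset of geometries with energies before
the first surrogate fit.  Any cheap generator of structurally diverse
geometries will do; the shipped samplers are seeded uniform draws over the
search space, Gaussian perturbations of a seed geometry, or a mix of both.
Every emitted structure is screened against the 0.5 Angstrom atomic
collision rule, and external datasets (e.g. from reaction-path searches)
can be imported through XYZ + CSV instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .internal_coords import (
    ABSTRACT,
    ANGLE,
    DIHEDRAL,
    DISTANCE,
    Geometry,
    SearchSpace,
    has_collision,
)
from .pes_models import EnergyRecord

UNIFORM = "uniform"
PERTURBED = "perturbed-seed"
MIXED = "mixed"

#: default perturbation scale per coordinate kind
#: (Angstrom / degrees / model-coordinate units)
DEFAULT_PERTURB_SCALES = {DISTANCE: 0.15, ANGLE: 15.0, DIHEDRAL: 30.0, ABSTRACT: 0.5}


class GenerationError(RuntimeError):
    """Could not collect enough collision-free structures."""


@dataclass(frozen=True)
class InitialSetSpec:
    """How to build the initial dataset."""

    mode: str = UNIFORM
    n_structures: int = 20
    perturb_scales: dict = field(default_factory=lambda: dict(DEFAULT_PERTURB_SCALES))
    seed_values: Optional[np.ndarray] = None
    rng_seed: int = 0

    def __post_init__(self):
        if self.mode not in (UNIFORM, PERTURBED, MIXED):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_structures < 1:
            raise ValueError("n_structures must be >= 1")
        if any(v < 0 for v in self.perturb_scales.values()):
            raise ValueError("perturbation scales must be non-negative")
        if self.mode in (PERTURBED, MIXED) and self.seed_values is None:
            raise ValueError(f"mode {self.mode!r} needs a seed geometry")


def _perturb(space: SearchSpace, seed_values, scales: dict, n: int, rng) -> np.ndarray:
    seed_values = np.asarray(seed_values, dtype=float)
    sigma = np.array([scales.get(kind, 0.0) for kind in space.kinds])
    draws = seed_values + rng.normal(0.0, 1.0, size=(n, space.ndim)) * sigma
    return np.clip(draws, space.lower, space.upper)


def generate_initial_set(
    spec: InitialSetSpec,
    space: SearchSpace,
    oracle,
    collision_threshold: float = 0.5,
    retry_cap: int = 50,
) -> Tuple[np.ndarray, List[EnergyRecord]]:
    """Draw ``spec.n_structures`` collision-free geometries and attach their
    oracle energies.  Deterministic given ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    kept: List[np.ndarray] = []
    for _ in range(retry_cap):
        need = spec.n_structures - len(kept)
        if need <= 0:
            break
        if spec.mode == UNIFORM:
            draws = rng.uniform(space.lower, space.upper, size=(need, space.ndim))
        elif spec.mode == PERTURBED:
            draws = _perturb(space, spec.seed_values, spec.perturb_scales, need, rng)
        else:  # mixed: alternate sources
            n_half = (need + 1) // 2
            draws = np.vstack(
                [
                    rng.uniform(space.lower, space.upper, size=(n_half, space.ndim)),
                    _perturb(
                        space, spec.seed_values, spec.perturb_scales,
                        need - n_half, rng,
                    ),
                ]
            )
        for values in draws:
            if len(kept) >= spec.n_structures:
                break
            if not has_collision(Geometry(values, space), collision_threshold):
                kept.append(values)
    if len(kept) < spec.n_structures:
        raise GenerationError(
            f"collected only {len(kept)}/{spec.n_structures} collision-free "
            f"structures within {retry_cap} rounds"
        )
    X = np.vstack(kept)
    records = [oracle(x) for x in X]
    return X, records


def save_initial_set(out_dir, space: SearchSpace, X, records) -> None:
    """Write an initial dataset as ``energies.csv`` (one row per structure:
    internal coordinates, e_s0, e_s1, noisy) plus one XYZ file per structure
    for molecular spaces.  The format round-trips with
    :func:`load_initial_set`, so externally generated datasets (e.g. from
    reaction-path searches) can be dropped in."""
    from pathlib import Path

    from .internal_coords import to_cartesian, write_xyz

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = list(space.names) + ["e_s0", "e_s1", "noisy"]
    with open(out / "energies.csv", "w") as fh:
        fh.write(",".join(header) + "\n")
        for i, (x, rec) in enumerate(zip(X, records)):
            e1 = "" if rec.e_s1 is None else repr(float(rec.e_s1))
            row = [repr(float(v)) for v in x] + [
                repr(float(rec.e_s0)), e1, str(int(rec.noisy))
            ]
            fh.write(",".join(row) + "\n")
            if space.is_molecular:
                geom = Geometry(np.asarray(x, dtype=float), space)
                write_xyz(
                    out / f"structure_{i + 1:04d}.xyz",
                    geom.elements,
                    to_cartesian(geom),
                    f"e_s0={rec.e_s0}" + (f" e_s1={rec.e_s1}" if rec.e_s1 is not None else ""),
                )


def load_initial_set(in_dir, space: SearchSpace):
    """Inverse of :func:`save_initial_set`; returns ``(X, records)``."""
    from pathlib import Path

    path = Path(in_dir) / "energies.csv"
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        expected = list(space.names) + ["e_s0", "e_s1", "noisy"]
        if header != expected:
            raise ValueError(f"unexpected columns {header}, wanted {expected}")
        rows, records = [], []
        for line in fh:
            parts = line.rstrip("\n").split(",")
            rows.append([float(p) for p in parts[: space.ndim]])
            e_s0 = float(parts[space.ndim])
            e_s1 = None if parts[space.ndim + 1] == "" else float(parts[space.ndim + 1])
            records.append(
                EnergyRecord(e_s0=e_s0, e_s1=e_s1, noisy=bool(int(parts[space.ndim + 2])))
            )
    return np.asarray(rows, dtype=float), records


def deduplicate(X: np.ndarray, tolerance: float) -> np.ndarray:
    """Greedily keep rows whose Euclidean internal-coordinate distance to
    every previously kept row exceeds ``tolerance``.  Returns kept indices."""
    if tolerance <= 0:
        raise ValueError("tolerance must be strictly positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    kept: List[int] = []
    for i, row in enumerate(X):
        if all(np.linalg.norm(row - X[j]) > tolerance for j in kept):
            kept.append(i)
    return np.asarray(kept, dtype=int)
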