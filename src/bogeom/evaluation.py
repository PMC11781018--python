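"""Deviation of a found geometry from a reference: energies and RMSD.

RMSD is computed after optimal superposition (translation to the centroids
plus the best proper rotation, via SVD with determinant correction).  When a
reference exists in two mirror-image conformers, ``allow_mirror=True`` also
superposes against the reflected reference and reports the smaller value.
Atoms are matched by their Z-matrix identity; no permutation search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .pes_models import EnergyRecord


class IncompatibleStructuresError(ValueError):
    """Atom counts or element orders differ between the two structures."""


@dataclass(frozen=True)
class EvaluationReport:
    """Found-minus-reference energy deltas (kcal/mol), the signed gap at the
    found geometry, and the (optionally mirror-aware) RMSD in Angstrom."""

    delta_e_s0: float
    delta_e_s1: Optional[float]
    gap: Optional[float]
    rmsd: float
    reference_id: Optional[str] = None

    def as_dict(self) -> dict:
        return {
            "delta_e_s0_kcal_mol": self.delta_e_s0,
            "delta_e_s1_kcal_mol": self.delta_e_s1,
            "gap_kcal_mol": self.gap,
            "rmsd_angstrom": self.rmsd,
            "reference_id": self.reference_id,
        }


def _superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    # align_vectors returns the proper rotation minimizing the residual;
    # recompute the residual explicitly (its reported rssd loses precision
    # to cancellation for near-exact matches)
    rot, _ = Rotation.align_vectors(a, b)
    diff = a - rot.apply(b)
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def kabsch_rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    allow_mirror: bool = False,
    elements_a: Optional[Sequence[str]] = None,
    elements_b: Optional[Sequence[str]] = None,
) -> float:
    """Minimum RMSD (Angstrom) over translation + proper rotation, and over
    the reflection image of ``coords_b`` when ``allow_mirror``."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise IncompatibleStructuresError(
            f"coordinate shapes differ: {a.shape} vs {b.shape}"
        )
    if elements_a is not None and elements_b is not None:
        if list(elements_a) != list(elements_b):
            raise IncompatibleStructuresError("element orders differ")
    rmsd = _superposed_rmsd(a, b)
    if allow_mirror:
        mirrored = b * np.array([-1.0, 1.0, 1.0])
        rmsd = min(rmsd, _superposed_rmsd(a, mirrored))
    return rmsd


def evaluate_against_reference(
    found_coords: np.ndarray,
    found_record: EnergyRecord,
    ref_coords: np.ndarray,
    ref_record: EnergyRecord,
    allow_mirror: bool = False,
    elements: Optional[Sequence[str]] = None,
    reference_id: Optional[str] = None,
) -> EvaluationReport:
    """Report found-minus-reference energy deltas and superposition RMSD."""
    delta_e_s1 = None
    if found_record.e_s1 is not None and ref_record.e_s1 is not None:
        delta_e_s1 = found_record.e_s1 - ref_record.e_s1
    return EvaluationReport(
        delta_e_s0=found_record.e_s0 - ref_record.e_s0,
        delta_e_s1=delta_e_s1,
        gap=found_record.gap,
        rmsd=kabsch_rmsd(
            found_coords, ref_coords, allow_mirror, elements, elements
        ),
        reference_id=reference_id,
    )
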