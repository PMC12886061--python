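"""EQD2 conversion, dose mapping onto the current anatomy, and accumulation.

Physical doses are converted to the equieffective dose in 2 Gy fractions
under the linear-quadratic model,

    EQD2_v = D_v * (D_v / n + alpha/beta) / (2 + alpha/beta),

with the voxel's per-fraction dose taken as ``d = D_v / n`` (so escalated
regions deliver proportionally more per fraction).  alpha/beta is 2 Gy for
the spinal cord and 3 Gy for the other organs-at-risk by default, and the
conversion is done per organ with that organ's ratio, so the artificial
step a single mixed-tissue conversion would create never enters any DVH.

The order of operations is fixed: the previous-course *physical* dose is
mapped onto the current CT first and converted to EQD2 afterwards; the
reverse order is deliberately not offered.  No tissue-recovery discounting
is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import EQD2, PHYSICAL, CaseBundle, CentreSubmission, DoseGrid, ImageGrid, SpatialTransform
from .transform_apply import apply_to_dose


def to_eqd2(dose: DoseGrid, alpha_beta_Gy: float,
            n_fractions: int | None = None) -> DoseGrid:
    """Convert a physical dose to EQD2 with the given alpha/beta (Gy)."""
    if alpha_beta_Gy <= 0:
        raise ValueError("alpha/beta must be positive")
    if dose.dose_kind != PHYSICAL:
        raise ValueError("to_eqd2 expects a physical dose")
    n = dose.n_fractions if n_fractions is None else int(n_fractions)
    if n < 1:
        raise ValueError("n_fractions must be >= 1")
    d = np.asarray(dose.values, dtype=float)
    eqd2 = d * (d / n + alpha_beta_Gy) / (2.0 + alpha_beta_Gy)
    return DoseGrid(grid=dose.grid, values=eqd2, dose_kind=EQD2,
                    coverage=dose.coverage)


def map_and_convert(prev_physical: DoseGrid, transform: SpatialTransform,
                    target_grid: ImageGrid, alpha_beta_Gy: float,
                    n_fractions: int | None = None) -> DoseGrid:
    """Map the previous physical dose onto ``target_grid``, then convert to EQD2."""
    mapped = apply_to_dose(prev_physical, transform, target_grid)
    return to_eqd2(mapped, alpha_beta_Gy, n_fractions=n_fractions)


def accumulate(a: DoseGrid, b: DoseGrid) -> DoseGrid:
    """Voxelwise sum of two EQD2 doses on the same grid (commutative)."""
    if a.dose_kind != EQD2 or b.dose_kind != EQD2:
        raise ValueError("accumulation is defined for EQD2 doses only")
    if not a.grid.same_geometry(b.grid):
        raise ValueError("cannot accumulate doses on different grids")
    return DoseGrid(grid=a.grid, values=np.asarray(a.values, float) + np.asarray(b.values, float),
                    dose_kind=EQD2)


@dataclass
class OrganDoseSet:
    """Per-organ EQD2 triple on the current grid."""

    organ: str
    mapped_prev_eqd2: DoseGrid
    current_eqd2: DoseGrid
    cumulative_eqd2: DoseGrid
    coverage: float | None


def per_organ_eqd2_set(bundle: CaseBundle, submission: CentreSubmission):
    """EQD2 triples (mapped previous, current, cumulative) per organ.

    Each organ is converted with its own alpha/beta from the case's table.
    Organs present in the case but absent from the submission's transferred
    masks are excluded with a reason code.

    Returns
    -------
    (dict organ -> OrganDoseSet, dict organ -> reason)
    """
    mapped_phys = submission.mapped_dose
    results = {}
    excluded = {}
    for organ in bundle.organs:
        if organ not in submission.masks:
            excluded[organ] = "missing_from_submission"
            continue
        ab = bundle.alpha_beta[organ]
        mapped_eqd2 = to_eqd2(mapped_phys, ab, n_fractions=bundle.course_prev.n_fractions)
        current_eqd2 = to_eqd2(bundle.dose_current, ab,
                               n_fractions=bundle.course_current.n_fractions)
        results[organ] = OrganDoseSet(
            organ=organ,
            mapped_prev_eqd2=mapped_eqd2,
            current_eqd2=current_eqd2,
            cumulative_eqd2=accumulate(mapped_eqd2, current_eqd2),
            coverage=mapped_phys.coverage,
        )
    return results, excluded
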