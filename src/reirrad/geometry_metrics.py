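"""Contour-agreement metrics within the dose-restricted evaluation volume.

Five metrics quantify how well a transferred organ matches a reference:
Dice similarity (DSC), surface Dice within 3 mm (SDSC-3 mm), mean surface
distance (MSD), 98th-percentile Hausdorff distance (HD-98%), and distance
between centres of mass (DCM).  All are evaluated after restricting both
structures cranio-caudally to the axial slices where the current plan's
EQD2 dose reaches 2 Gy, while retaining full transversal extent.

Surfaces are the centres of boundary voxels (foreground voxels with at
least one face-adjacent background neighbour); directed distances come
from the exact Euclidean distance transform on the anisotropic grid.  MSD
and HD-98% pool the two directed distance samples into one set before
averaging / taking the percentile — one defensible convention, recorded as
a dialect flag since directed and per-direction-averaged variants exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion, distance_transform_edt

from .core_model import DoseGrid, ImageGrid, StructureMask

#: Conventions that other toolchains may implement differently.
DIALECT_FLAGS = (
    "surface=boundary-voxel-centres(face-connectivity)",
    "surface-distances=pooled-both-directions",
    "percentile=linear-interpolation",
)

METRICS = ("DSC", "SDSC3", "MSD", "HD98", "DCM")

_FACE_STRUCT = np.array(
    [[[0, 0, 0], [0, 1, 0], [0, 0, 0]],
     [[0, 1, 0], [1, 1, 1], [0, 1, 0]],
     [[0, 0, 0], [0, 1, 0], [0, 0, 0]]], dtype=bool)


@dataclass
class MetricRecord:
    """One metric value for one (case, centre, method, organ, reference)."""

    case_id: str
    centre_id: str
    method: str
    organ: str
    reference: str  # "consensus" | "delineated"
    metric: str
    value: float
    defined: bool = True
    reason: str = ""


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


# ---------------------------------------------------------------------------
# restriction
# ---------------------------------------------------------------------------


def restrict_cranio_caudal(mask: StructureMask, current_eqd2: DoseGrid,
                           dose_threshold_Gy: float = 2.0) -> StructureMask:
    """Zero the mask outside the dose-qualifying cranio-caudal extent.

    Axial (z) slices between the lowest and highest slice whose maximum
    EQD2 dose reaches ``dose_threshold_Gy`` are kept in full transversal
    extent; everything outside is zeroed.  If no slice qualifies the result
    is an (allowed) empty mask.
    """
    if not mask.grid.same_geometry(current_eqd2.grid):
        raise ValueError("mask and dose must share one grid")
    slice_max = np.asarray(current_eqd2.values).max(axis=(0, 1))
    qualifying = np.flatnonzero(slice_max >= dose_threshold_Gy)
    out = np.zeros_like(mask.voxels)
    if qualifying.size:
        lo, hi = int(qualifying[0]), int(qualifying[-1])
        out[:, :, lo:hi + 1] = mask.voxels[:, :, lo:hi + 1]
    return StructureMask(organ=mask.organ, grid=mask.grid, voxels=out, allow_empty=True)


# ---------------------------------------------------------------------------
# metric kernels
# ---------------------------------------------------------------------------


def dice(a: StructureMask, b: StructureMask) -> float:
    """Volumetric overlap 2|A∩B| / (|A|+|B|)."""
    if a.is_empty and b.is_empty:
        raise ValueError("DSC is undefined for two empty masks")
    av = a.voxels > 0
    bv = b.voxels > 0
    return 2.0 * float(np.logical_and(av, bv).sum()) / float(av.sum() + bv.sum())


def boundary_voxels(mask: StructureMask) -> np.ndarray:
    """Foreground voxels with >= 1 face-adjacent background neighbour."""
    fg = mask.voxels > 0
    interior = binary_erosion(fg, structure=_FACE_STRUCT, border_value=0)
    return fg & ~interior


def surface_distances(a: StructureMask, b: StructureMask):
    """Directed boundary-to-boundary distance samples (mm), both directions.

    Returns ``(d_ab, d_ba)``: for each boundary voxel centre of A the
    distance to the nearest boundary voxel centre of B, and vice versa.
    """
    if a.is_empty or b.is_empty:
        raise ValueError("surface distances require two non-empty masks")
    spacing = a.grid.spacing
    ba = boundary_voxels(a)
    bb = boundary_voxels(b)
    dt_b = distance_transform_edt(~bb, sampling=spacing)
    dt_a = distance_transform_edt(~ba, sampling=spacing)
    return dt_b[ba], dt_a[bb]


def surface_dice(a: StructureMask, b: StructureMask, tau_mm: float = 3.0) -> float:
    """Fraction of the two surfaces lying within ``tau_mm`` of each other."""
    d_ab, d_ba = surface_distances(a, b)
    return float(((d_ab <= tau_mm).sum() + (d_ba <= tau_mm).sum())
                 / (d_ab.size + d_ba.size))


def mean_surface_distance(a: StructureMask, b: StructureMask) -> float:
    """Mean of the pooled directed surface distances (mm)."""
    d_ab, d_ba = surface_distances(a, b)
    return float(np.concatenate([d_ab, d_ba]).mean())


def hausdorff_percentile(a: StructureMask, b: StructureMask, p: float = 98.0) -> float:
    """p-th percentile (linear interpolation) of pooled surface distances (mm)."""
    d_ab, d_ba = surface_distances(a, b)
    return float(np.percentile(np.concatenate([d_ab, d_ba]), p))


def centre_of_mass_distance(a: StructureMask, b: StructureMask) -> float:
    """Euclidean distance between foreground centroids in world mm."""
    if a.is_empty or b.is_empty:
        raise ValueError("DCM requires two non-empty masks")
    ca = a.foreground_world_coords().mean(axis=0)
    cb = b.foreground_world_coords().mean(axis=0)
    return float(np.linalg.norm(ca - cb))


def _all_metrics(a: StructureMask, b: StructureMask, tau_mm: float,
                 hd_pct: float) -> dict:
    d_ab, d_ba = surface_distances(a, b)
    pooled = np.concatenate([d_ab, d_ba])
    return {
        "DSC": dice(a, b),
        "SDSC3": float(((d_ab <= tau_mm).sum() + (d_ba <= tau_mm).sum()) / pooled.size),
        "MSD": float(pooled.mean()),
        "HD98": float(np.percentile(pooled, hd_pct)),
        "DCM": centre_of_mass_distance(a, b),
    }


# ---------------------------------------------------------------------------
# benchmark evaluation
# ---------------------------------------------------------------------------


def evaluate_all(submissions, references: dict, current_eqd2: DoseGrid,
                 case_id: str, dose_threshold_Gy: float = 2.0,
                 tau_mm: float = 3.0, hd_pct: float = 98.0) -> list:
    """All five metrics for every (centre, method, organ, reference kind).

    ``references`` maps reference kind ("consensus", "delineated") to a
    dict of organ masks on the current grid.  The cranio-caudal dose
    restriction is applied to both compared masks before any metric.
    Combinations with an empty restricted mask are recorded as undefined
    with a reason code rather than dropped.
    """
    restricted_refs = {
        kind: {organ: restrict_cranio_caudal(m, current_eqd2, dose_threshold_Gy)
               for organ, m in organs.items()}
        for kind, organs in references.items()
    }
    records = []
    for sub in submissions:
        for organ, mask in sub.masks.items():
            restricted_sub = restrict_cranio_caudal(mask, current_eqd2, dose_threshold_Gy)
            for kind, organs in restricted_refs.items():
                if organ not in organs:
                    records.extend(_undefined(case_id, sub, organ, kind, "missing_reference"))
                    continue
                ref = organs[organ]
                if restricted_sub.is_empty or ref.is_empty:
                    reason = ("empty_after_restriction"
                              if (mask.voxels.any() and organs[organ] is not None)
                              else "empty_mask")
                    records.extend(_undefined(case_id, sub, organ, kind, reason))
                    continue
                values = _all_metrics(restricted_sub, ref, tau_mm, hd_pct)
                for metric, value in values.items():
                    records.append(MetricRecord(
                        case_id=case_id, centre_id=sub.centre_id, method=sub.method,
                        organ=organ, reference=kind, metric=metric, value=value))
    return records


def _undefined(case_id, sub, organ, kind, reason):
    return [MetricRecord(case_id=case_id, centre_id=sub.centre_id, method=sub.method,
                         organ=organ, reference=kind, metric=metric,
                         value=float("nan"), defined=False, reason=reason)
            for metric in METRICS]
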