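"""Apply, compose, invert and fit spatial transforms on voxel grids.

Everything here works in the pull-back convention: a transform maps a point
on the target (current) grid to its source location on the moving (previous)
volume, and resampling pulls source values back onto the target lattice.
Binary masks are resampled with trilinear interpolation and thresholded at
0.5, which gives smoother surfaces than nearest-neighbour at the coarse
spacings used here; samples falling outside the source volume are background
for masks and 0 Gy for doses (with the in-volume fraction reported as a
coverage figure so silent extrapolation cannot corrupt downstream DVHs).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial.transform import Rotation

from .core_model import DoseGrid, ImageGrid, SpatialTransform, StructureMask


def _pull_back_sample(values: np.ndarray, source_grid: ImageGrid,
                      transform: SpatialTransform, target_grid: ImageGrid,
                      cval: float = 0.0):
    """Sample ``values`` (on source_grid) at transform(target voxel centres).

    Returns the interpolated array on the target grid and the fraction of
    target voxels whose mapped location lies inside the source volume.
    """
    pts = target_grid.all_world_coords()
    src_pts = transform.map_points(pts)
    vox = source_grid.world_to_voxel(src_pts)
    coords = np.moveaxis(vox, -1, 0)
    out = map_coordinates(np.asarray(values, dtype=float), coords, order=1,
                          mode="constant", cval=cval)
    size = np.asarray(source_grid.size)
    inside = np.all((vox >= 0) & (vox <= size - 1), axis=-1)
    coverage = float(inside.mean())
    return out, coverage


def apply_to_mask(mask: StructureMask, transform: SpatialTransform,
                  target_grid: ImageGrid) -> StructureMask:
    """Transfer a binary mask onto ``target_grid`` through a pull-back map."""
    interp, _ = _pull_back_sample(mask.voxels, mask.grid, transform, target_grid)
    return StructureMask(organ=mask.organ, grid=target_grid,
                         voxels=(interp >= 0.5), allow_empty=True)


def apply_to_dose(dose: DoseGrid, transform: SpatialTransform,
                  target_grid: ImageGrid) -> DoseGrid:
    """Map a dose distribution onto ``target_grid``; fraction metadata is kept.

    Out-of-volume samples are set to 0 Gy; the returned grid's ``coverage``
    attribute records the fraction of target voxels mapped from inside the
    source volume.
    """
    interp, coverage = _pull_back_sample(dose.values, dose.grid, transform, target_grid)
    return DoseGrid(grid=target_grid, values=np.clip(interp, 0.0, None),
                    dose_kind=dose.dose_kind, n_fractions=dose.n_fractions,
                    coverage=coverage)


def compose(outer: SpatialTransform, inner: SpatialTransform,
            grid: ImageGrid) -> SpatialTransform:
    """Pull-back composition ``x -> outer(inner(x))`` sampled on ``grid``.

    The result is a dense field on ``grid``, except that composing with an
    exact identity short-circuits to the other operand and composing two
    rigid transforms yields the exact rigid composition.
    """
    if inner.is_identity():
        return outer
    if outer.is_identity():
        return inner
    if outer.kind == "rigid6" and inner.kind == "rigid6":
        Ro, to = outer.rotation_matrix(), outer.rigid[3:]
        Ri, ti = inner.rotation_matrix(), inner.rigid[3:]
        R = Ro @ Ri
        t = Ro @ ti + to
        return SpatialTransform.from_rigid(Rotation.from_matrix(R).as_euler("xyz"), t)
    pts = grid.all_world_coords()
    mapped = outer.map_points(inner.map_points(pts))
    return SpatialTransform.from_field(mapped - pts, grid)


def invert_field(transform: SpatialTransform, grid: ImageGrid,
                 n_iter: int = 20, tol: float = 1e-3) -> SpatialTransform:
    """Approximate inverse of a displacement transform by fixed-point iteration.

    Solves ``v(y) = -u(y + v(y))`` on ``grid``; converges for the smooth,
    moderate-amplitude fields the phantom produces.
    """
    pts = grid.all_world_coords()
    v = np.zeros_like(pts)
    for _ in range(n_iter):
        v_new = (pts + v) - transform.map_points(pts + v)
        step = np.max(np.abs(v_new - v))
        v = v_new
        if step < tol:
            break
    return SpatialTransform.from_field(v, grid)


def fit_rigid(field: SpatialTransform, roi: StructureMask) -> SpatialTransform:
    """Least-squares proper rigid fit (Procrustes) to a field over an ROI.

    Finds the rotation ``R`` (det = +1) and translation ``t`` minimising
    ``sum_i ||R x_i + t - field(x_i)||^2`` over the ROI voxel centres —
    the rigid transform a centre would obtain by aligning on that region.

    Raises
    ------
    ValueError
        If the ROI is empty or its points are (near-)collinear, which leaves
        the rotation about the line undetermined.
    """
    if roi.is_empty:
        raise ValueError("rigid fit requires a non-empty ROI")
    x = roi.foreground_world_coords()
    y = field.map_points(x)
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    x0 = x - xc
    sv = np.linalg.svd(x0, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise ValueError("degenerate ROI: points are collinear, rigid fit is underdetermined")
    H = x0.T @ (y - yc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = yc - R @ xc
    angles = Rotation.from_matrix(R).as_euler("xyz")
    return SpatialTransform.from_rigid(angles, t)
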