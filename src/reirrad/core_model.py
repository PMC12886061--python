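"""Shared geometric and dosimetric containers and their on-disk form.

All spatial quantities live in a single fixed patient-based world frame:
voxel indices are 0-based, world coordinates are millimetres, and a voxel
index ``i`` maps to ``origin + axes @ (spacing * i)``.  Volumes are stored
as NIfTI-1 (one file per mask/dose/displacement field) next to a
``case.json`` sidecar holding fractionation and alpha/beta metadata.

Transforms use the pull-back convention throughout: a transform attached to
a submission maps a point on the current (reirradiation) CT to its source
location on the previous CT, because structures and doses are always
materialised on the current anatomy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy.spatial.transform import Rotation

#: The eight thoracic organs-at-risk evaluated by the benchmark.
ORGANS = (
    "aorta",
    "bronchi",
    "oesophagus",
    "heart",
    "lung_left",
    "lung_right",
    "spinal_cord",
    "trachea",
)

#: Default linear-quadratic sensitivity ratios (Gy): nerve tissue vs soft tissue.
DEFAULT_ALPHA_BETA = {organ: 3.0 for organ in ORGANS}
DEFAULT_ALPHA_BETA["spinal_cord"] = 2.0

PHYSICAL = "physical"
EQD2 = "EQD2"

RIR = "RIR"
DIR = "DIR"


class CaseIOError(ValueError):
    """Raised when an on-disk case or submission violates the schema."""


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageGrid:
    """Physical geometry of a voxel lattice.

    Parameters
    ----------
    origin : (3,) array-like
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    spacing : (3,) array-like
        Voxel spacing in mm along each lattice axis; strictly positive.
    size : (3,) tuple of int
        Number of voxels along each axis; each >= 1.
    axes : (3, 3) array-like, optional
        Direction-cosine matrix (columns are the lattice axes in world
        space); must be orthonormal.  Defaults to the identity.
    """

    origin: tuple
    spacing: tuple
    size: tuple
    axes: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float)
        spacing = np.asarray(self.spacing, dtype=float)
        size = np.asarray(self.size, dtype=int)
        axes = np.asarray(self.axes, dtype=float)
        if origin.shape != (3,) or spacing.shape != (3,) or size.shape != (3,):
            raise ValueError("origin, spacing and size must be 3-vectors")
        if np.any(spacing <= 0):
            raise ValueError("spacing components must be strictly positive")
        if np.any(size < 1):
            raise ValueError("size components must be >= 1")
        if axes.shape != (3, 3) or not np.allclose(axes.T @ axes, np.eye(3), atol=1e-6):
            raise ValueError("axes must be a 3x3 orthonormal matrix")
        object.__setattr__(self, "origin", tuple(origin))
        object.__setattr__(self, "spacing", tuple(spacing))
        object.__setattr__(self, "size", tuple(int(s) for s in size))
        object.__setattr__(self, "axes", tuple(tuple(row) for row in axes))

    # -- conversions ------------------------------------------------------

    @property
    def origin_a(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)

    @property
    def spacing_a(self) -> np.ndarray:
        return np.asarray(self.spacing, dtype=float)

    @property
    def axes_a(self) -> np.ndarray:
        return np.asarray(self.axes, dtype=float)

    @property
    def shape(self) -> tuple:
        return self.size

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_a))

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (..., 3) 0-based voxel indices to world mm coordinates."""
        idx = np.asarray(indices, dtype=float)
        return self.origin_a + (idx * self.spacing_a) @ self.axes_a.T

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map (..., 3) world mm coordinates to fractional voxel indices."""
        pts = np.asarray(points, dtype=float)
        return ((pts - self.origin_a) @ self.axes_a) / self.spacing_a

    def all_world_coords(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (*size, 3)."""
        idx = np.stack(
            np.meshgrid(*(np.arange(s) for s in self.size), indexing="ij"), axis=-1
        )
        return self.voxel_to_world(idx)

    def affine(self) -> np.ndarray:
        """NIfTI-style 4x4 affine mapping voxel indices to world mm."""
        aff = np.eye(4)
        aff[:3, :3] = self.axes_a * self.spacing_a[np.newaxis, :]
        aff[:3, 3] = self.origin_a
        return aff

    @classmethod
    def from_affine(cls, affine: np.ndarray, size) -> "ImageGrid":
        mat = np.asarray(affine, dtype=float)[:3, :3]
        spacing = np.linalg.norm(mat, axis=0)
        axes = mat / spacing[np.newaxis, :]
        return cls(origin=tuple(affine[:3, 3]), spacing=tuple(spacing), size=tuple(size), axes=axes)

    def same_geometry(self, other: "ImageGrid", tol: float = 1e-6) -> bool:
        return (
            self.size == other.size
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.axes, other.axes, atol=tol)
        )


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------


@dataclass
class StructureMask:
    """A named binary organ mask bound to a grid."""

    organ: str
    grid: ImageGrid
    voxels: np.ndarray
    allow_empty: bool = False

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.shape != self.grid.size:
            raise ValueError(
                f"mask array shape {self.voxels.shape} does not match grid size {self.grid.size}"
            )
        self.voxels = (self.voxels > 0).astype(np.uint8)
        if not self.allow_empty and not self.voxels.any():
            raise ValueError(f"mask for {self.organ!r} is empty and not flagged allow_empty")

    @property
    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    @property
    def volume_cm3(self) -> float:
        return float(self.voxels.sum()) * self.grid.voxel_volume_cm3

    def foreground_world_coords(self) -> np.ndarray:
        idx = np.argwhere(self.voxels > 0)
        return self.grid.voxel_to_world(idx)


@dataclass
class DoseGrid:
    """A dose array in Gy (physical or EQD2) with fractionation metadata."""

    grid: ImageGrid
    values: np.ndarray
    dose_kind: str = PHYSICAL
    n_fractions: int | None = None
    coverage: float | None = None  # fraction of voxels mapped from inside the source volume

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.shape != self.grid.size:
            raise ValueError(
                f"dose array shape {self.values.shape} does not match grid size {self.grid.size}"
            )
        if self.dose_kind not in (PHYSICAL, EQD2):
            raise ValueError(f"unknown dose_kind {self.dose_kind!r}")
        if np.any(self.values < -1e-6) or not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite and non-negative")
        self.values = np.clip(self.values, 0.0, None)
        if self.dose_kind == EQD2:
            if self.n_fractions is not None:
                raise ValueError("EQD2 doses carry no fraction count")
        else:
            if self.n_fractions is None or self.n_fractions < 1:
                raise ValueError("physical doses require a positive fraction count")
            self.n_fractions = int(self.n_fractions)


@dataclass
class SpatialTransform:
    """A rigid 6DoF transform or a dense displacement field (pull-back).

    ``map_points(x)`` sends a world point on the fixed (current) image to its
    source location on the moving (previous) image.  Rigid transforms act as
    ``x -> R x + t`` with ``R`` a proper rotation built from extrinsic XYZ
    Euler angles; dense fields act as ``x -> x + u(x)`` with ``u`` sampled
    trilinearly (mm) on ``field_grid`` and taken as zero outside it.
    """

    kind: str  # "rigid6" | "dense_field"
    rigid: np.ndarray | None = None  # (6,) = (rx, ry, rz [rad], tx, ty, tz [mm])
    field: np.ndarray | None = None  # (*grid.size, 3) displacement mm
    field_grid: ImageGrid | None = None
    direction: str = "current_to_prev"

    def __post_init__(self):
        if self.kind == "rigid6":
            self.rigid = np.asarray(self.rigid, dtype=float).reshape(6)
            if not np.all(np.isfinite(self.rigid)):
                raise ValueError("rigid parameters must be finite")
        elif self.kind == "dense_field":
            if self.field_grid is None:
                raise ValueError("dense_field transforms need a field_grid")
            self.field = np.asarray(self.field, dtype=float)
            if self.field.shape != (*self.field_grid.size, 3):
                raise ValueError("displacement field shape must be (*grid.size, 3)")
            if not np.all(np.isfinite(self.field)):
                raise ValueError("displacement field must be finite everywhere")
        else:
            raise ValueError(f"unknown transform kind {self.kind!r}")

    # -- constructors -----------------------------------------------------

    @classmethod
    def identity(cls) -> "SpatialTransform":
        return cls(kind="rigid6", rigid=np.zeros(6))

    @classmethod
    def from_rigid(cls, angles_rad, translation_mm) -> "SpatialTransform":
        return cls(kind="rigid6", rigid=np.concatenate([np.asarray(angles_rad, float),
                                                        np.asarray(translation_mm, float)]))

    @classmethod
    def from_field(cls, field: np.ndarray, grid: ImageGrid) -> "SpatialTransform":
        return cls(kind="dense_field", field=field, field_grid=grid)

    # -- behaviour --------------------------------------------------------

    def rotation_matrix(self) -> np.ndarray:
        if self.kind != "rigid6":
            raise ValueError("rotation_matrix is defined for rigid transforms only")
        R = Rotation.from_euler("xyz", self.rigid[:3]).as_matrix()
        if np.linalg.det(R) <= 0:
            raise ValueError("rigid rotation must be proper (det = +1)")
        return R

    def map_points(self, points: np.ndarray) -> np.ndarray:
        """Apply the pull-back map to (..., 3) world points."""
        pts = np.asarray(points, dtype=float)
        if self.kind == "rigid6":
            return pts @ self.rotation_matrix().T + self.rigid[3:]
        from scipy.ndimage import map_coordinates

        vox = self.field_grid.world_to_voxel(pts)
        coords = np.moveaxis(vox, -1, 0)
        disp = np.stack(
            [
                map_coordinates(self.field[..., c], coords, order=1, mode="constant", cval=0.0)
                for c in range(3)
            ],
            axis=-1,
        )
        return pts + disp

    def is_identity(self, tol: float = 0.0) -> bool:
        if self.kind == "rigid6":
            return bool(np.all(np.abs(self.rigid) <= tol))
        return bool(np.all(np.abs(self.field) <= tol))


# ---------------------------------------------------------------------------
# case and submission bundles
# ---------------------------------------------------------------------------


@dataclass
class CourseInfo:
    """Fractionation metadata for one treatment course."""

    name: str
    n_fractions: int
    prescription_Gy: float

    def __post_init__(self):
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.prescription_Gy <= 0:
            raise ValueError("prescription must be positive")


@dataclass
class CaseBundle:
    """One reirradiation case: paired anatomies, doses and metadata."""

    case_id: str
    grid_prev: ImageGrid
    grid_current: ImageGrid
    masks_prev: dict
    masks_current: dict
    dose_prev: DoseGrid
    dose_current: DoseGrid
    course_prev: CourseInfo
    course_current: CourseInfo
    alpha_beta: dict
    gt_transform: SpatialTransform | None = None

    def __post_init__(self):
        organs = set(self.masks_prev) | set(self.masks_current)
        missing = sorted(o for o in organs if o not in self.alpha_beta)
        if missing:
            raise ValueError(f"alpha/beta table missing entries for organs: {missing}")
        for organ, ab in self.alpha_beta.items():
            if ab <= 0:
                raise ValueError(f"alpha/beta for {organ!r} must be positive")
        for organ, mask in self.masks_prev.items():
            if not mask.grid.same_geometry(self.grid_prev):
                raise ValueError(f"previous-course mask {organ!r} is not on the previous grid")
        for organ, mask in self.masks_current.items():
            if not mask.grid.same_geometry(self.grid_current):
                raise ValueError(f"current-course mask {organ!r} is not on the current grid")
        if self.dose_prev.dose_kind != PHYSICAL or self.dose_current.dose_kind != PHYSICAL:
            raise ValueError("case bundles store physical doses")

    @property
    def organs(self) -> list:
        return sorted(set(self.masks_prev) & set(self.masks_current))


@dataclass
class CentreSubmission:
    """One centre's registration result for one case and one method."""

    centre_id: str
    method: str  # RIR | DIR
    transform: SpatialTransform
    masks: dict  # organ -> StructureMask on the current grid
    mapped_dose: DoseGrid  # previous physical dose mapped to the current grid

    def __post_init__(self):
        if self.method not in (RIR, DIR):
            raise ValueError(f"method must be {RIR!r} or {DIR!r}")
        if self.method == RIR and self.transform.kind != "rigid6":
            raise ValueError("RIR submissions must carry a rigid6 transform")
        if self.method == DIR and self.transform.kind != "dense_field":
            raise ValueError("DIR submissions must carry a dense_field transform")


# ---------------------------------------------------------------------------
# on-disk representation
# ---------------------------------------------------------------------------


def _save_volume(path: Path, array: np.ndarray, grid: ImageGrid, dtype) -> None:
    img = nib.Nifti1Image(np.asarray(array, dtype=dtype), grid.affine())
    nib.save(img, str(path))


def _load_volume(path: Path) -> tuple[np.ndarray, ImageGrid]:
    if not path.exists():
        raise CaseIOError(f"missing volume file: {path.name}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    grid = ImageGrid.from_affine(img.affine, data.shape[:3])
    return data, grid


def _mask_filename(course: str, organ: str) -> str:
    return f"{course}_mask_{organ}.nii.gz"


def write_case(bundle: CaseBundle, directory) -> None:
    """Write a :class:`CaseBundle` to ``directory`` (NIfTI + case.json)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "case_id": bundle.case_id,
        "courses": [
            {"name": "previous", "n_fractions": bundle.course_prev.n_fractions,
             "prescription_Gy": bundle.course_prev.prescription_Gy},
            {"name": "current", "n_fractions": bundle.course_current.n_fractions,
             "prescription_Gy": bundle.course_current.prescription_Gy},
        ],
        "alpha_beta": {k: float(v) for k, v in sorted(bundle.alpha_beta.items())},
        "organs": {
            "previous": {o: {"empty": bool(m.is_empty)} for o, m in sorted(bundle.masks_prev.items())},
            "current": {o: {"empty": bool(m.is_empty)} for o, m in sorted(bundle.masks_current.items())},
        },
        "gt_transform": None,
    }
    for organ, mask in bundle.masks_prev.items():
        _save_volume(directory / _mask_filename("previous", organ), mask.voxels, bundle.grid_prev, np.uint8)
    for organ, mask in bundle.masks_current.items():
        _save_volume(directory / _mask_filename("current", organ), mask.voxels, bundle.grid_current, np.uint8)
    _save_volume(directory / "previous_dose_physical.nii.gz", bundle.dose_prev.values,
                 bundle.grid_prev, np.float32)
    _save_volume(directory / "current_dose_physical.nii.gz", bundle.dose_current.values,
                 bundle.grid_current, np.float32)
    if bundle.gt_transform is not None:
        sidecar["gt_transform"] = _write_transform(bundle.gt_transform, directory, "gt_transform")
    (directory / "case.json").write_text(json.dumps(sidecar, indent=2))


def _write_transform(transform: SpatialTransform, directory: Path, stem: str) -> dict:
    if transform.kind == "rigid6":
        return {"kind": "rigid6", "rigid": [float(v) for v in transform.rigid]}
    _save_volume(directory / f"{stem}_field.nii.gz", transform.field, transform.field_grid, np.float32)
    return {"kind": "dense_field", "file": f"{stem}_field.nii.gz"}


def _read_transform(entry: Mapping, directory: Path) -> SpatialTransform:
    if entry["kind"] == "rigid6":
        return SpatialTransform(kind="rigid6", rigid=np.asarray(entry["rigid"], dtype=float))
    data, grid = _load_volume(directory / entry["file"])
    return SpatialTransform.from_field(np.asarray(data, dtype=float), grid)


def read_case(directory) -> CaseBundle:
    """Read a case directory written by :func:`write_case`, fully validated."""
    directory = Path(directory)
    sidecar_path = directory / "case.json"
    if not sidecar_path.exists():
        raise CaseIOError(f"missing sidecar: {sidecar_path.name}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise CaseIOError(f"sidecar {sidecar_path.name} is not valid JSON: {exc}") from exc
    for key in ("case_id", "courses", "alpha_beta", "organs"):
        if key not in sidecar:
            raise CaseIOError(f"sidecar {sidecar_path.name} lacks required key {key!r}")
    courses = {c["name"]: CourseInfo(c["name"], c["n_fractions"], c["prescription_Gy"])
               for c in sidecar["courses"]}
    if set(courses) != {"previous", "current"}:
        raise CaseIOError(f"sidecar {sidecar_path.name} must declare 'previous' and 'current' courses")
    alpha_beta = {k: float(v) for k, v in sidecar["alpha_beta"].items()}

    masks = {"previous": {}, "current": {}}
    grids = {}
    for course in ("previous", "current"):
        for organ, meta in sidecar["organs"][course].items():
            if organ not in alpha_beta:
                raise CaseIOError(
                    f"sidecar {sidecar_path.name}: organ {organ!r} present but missing from alpha_beta"
                )
            fname = _mask_filename(course, organ)
            data, grid = _load_volume(directory / fname)
            grids.setdefault(course, grid)
            if not grid.same_geometry(grids[course]):
                raise CaseIOError(f"grid mismatch in {fname}")
            masks[course][organ] = StructureMask(organ=organ, grid=grid, voxels=data,
                                                 allow_empty=bool(meta.get("empty", False)))
    dose_arrays = {}
    for course in ("previous", "current"):
        fname = f"{course}_dose_physical.nii.gz"
        data, grid = _load_volume(directory / fname)
        if course in grids and not grid.same_geometry(grids[course]):
            raise CaseIOError(f"grid mismatch in {fname}")
        grids.setdefault(course, grid)
        dose_arrays[course] = DoseGrid(grid=grid, values=data, dose_kind=PHYSICAL,
                                       n_fractions=courses[course].n_fractions)
    gt = None
    if sidecar.get("gt_transform"):
        gt = _read_transform(sidecar["gt_transform"], directory)
    return CaseBundle(
        case_id=sidecar["case_id"],
        grid_prev=grids["previous"],
        grid_current=grids["current"],
        masks_prev=masks["previous"],
        masks_current=masks["current"],
        dose_prev=dose_arrays["previous"],
        dose_current=dose_arrays["current"],
        course_prev=courses["previous"],
        course_current=courses["current"],
        alpha_beta=alpha_beta,
        gt_transform=gt,
    )


def write_submission(sub: CentreSubmission, directory) -> None:
    """Write a centre submission (transform, masks, mapped dose) to disk."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grid = sub.mapped_dose.grid
    meta = {
        "centre_id": sub.centre_id,
        "method": sub.method,
        "transform": _write_transform(sub.transform, directory, "transform"),
        "organs": {o: {"empty": bool(m.is_empty)} for o, m in sorted(sub.masks.items())},
        "mapped_dose": {"n_fractions": sub.mapped_dose.n_fractions,
                        "coverage": sub.mapped_dose.coverage},
    }
    for organ, mask in sub.masks.items():
        _save_volume(directory / f"mask_{organ}.nii.gz", mask.voxels, grid, np.uint8)
    _save_volume(directory / "mapped_dose_physical.nii.gz", sub.mapped_dose.values, grid, np.float32)
    (directory / "submission.json").write_text(json.dumps(meta, indent=2))


def read_submission(directory) -> CentreSubmission:
    directory = Path(directory)
    meta_path = directory / "submission.json"
    if not meta_path.exists():
        raise CaseIOError(f"missing sidecar: {meta_path.name}")
    meta = json.loads(meta_path.read_text())
    dose_data, grid = _load_volume(directory / "mapped_dose_physical.nii.gz")
    masks = {}
    for organ, organ_meta in meta["organs"].items():
        data, mgrid = _load_volume(directory / f"mask_{organ}.nii.gz")
        if not mgrid.same_geometry(grid):
            raise CaseIOError(f"grid mismatch in mask_{organ}.nii.gz")
        masks[organ] = StructureMask(organ=organ, grid=mgrid, voxels=data,
                                     allow_empty=bool(organ_meta.get("empty", False)))
    dose = DoseGrid(grid=grid, values=dose_data, dose_kind=PHYSICAL,
                    n_fractions=meta["mapped_dose"]["n_fractions"],
                    coverage=meta["mapped_dose"].get("coverage"))
    return CentreSubmission(
        centre_id=meta["centre_id"],
        method=meta["method"],
        transform=_read_transform(meta["transform"], directory),
        masks=masks,
        mapped_dose=dose,
    )
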