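"""Thorax-like phantom cases and simulated multi-centre registrations.

The generator emulates the statistical structure of a national reirradiation
benchmarking exercise: seven lung-cancer cases, each with a previous-course
and a current-course anatomy related by a smooth ground-truth deformation,
eight thoracic organs-at-risk, two dose distributions whose 50% isodoses
overlap, and six simulated centres each producing one rigid (RIR) and one
deformable (DIR) registration with centre-specific error.

Centre variability is modelled as smooth random residual displacement
fields plus per-centre jitter of the region-of-interest used for the rigid
fit, reflecting that inter-centre variation in clinical registration is
driven chiefly by user choices and workflows rather than by the algorithms
themselves.  The deformable submission is the ground-truth field composed
with the centre's smooth random residual field; the rigid submission is
the least-squares proper rigid (Procrustes) fit to the ground-truth field
over the centre's jittered ROI, composed with a small random *rigid*
residual of matching RMS amplitude, so the stored transform stays rigid
while still carrying the centre's workflow error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core_model import (
    DEFAULT_ALPHA_BETA,
    DIR,
    PHYSICAL,
    RIR,
    CaseBundle,
    CentreSubmission,
    CourseInfo,
    DoseGrid,
    ImageGrid,
    SpatialTransform,
    StructureMask,
)
from .transform_apply import apply_to_dose, apply_to_mask, compose, fit_rigid, invert_field

# ---------------------------------------------------------------------------
# clinical case table
# ---------------------------------------------------------------------------

#: The seven benchmark cases.  Stereotactic schemes (3 fractions) escalate the
#: gross tumour volume to 150% of prescription; the 50 Gy/24 fx scheme
#: escalates the mean GTV dose to 65 Gy (factor 1.3); normofractionated
#: schemes are homogeneous (factor 1.0).  Case 7 developed an atelectasis
#: between courses and is generated as the large-deformation stress scenario.
CLINICAL_CASES = (
    dict(case_id="case_1", sex="F", age=73, interval_months=55,
         prev=dict(dose_Gy=30.0, n_fractions=3, ptv_cc=29.0, escalation=1.5),
         current=dict(dose_Gy=66.0, n_fractions=33, ptv_cc=79.0, escalation=1.0),
         stress=False),
    dict(case_id="case_2", sex="F", age=79, interval_months=13,
         prev=dict(dose_Gy=30.0, n_fractions=3, ptv_cc=19.0, escalation=1.5),
         current=dict(dose_Gy=50.0, n_fractions=24, ptv_cc=166.0, escalation=1.3),
         stress=False),
    dict(case_id="case_3", sex="F", age=67, interval_months=46,
         prev=dict(dose_Gy=60.0, n_fractions=30, ptv_cc=212.0, escalation=1.0),
         current=dict(dose_Gy=40.0, n_fractions=3, ptv_cc=19.0, escalation=1.5),
         stress=False),
    dict(case_id="case_4", sex="M", age=89, interval_months=57,
         prev=dict(dose_Gy=30.0, n_fractions=3, ptv_cc=53.0, escalation=1.5),
         current=dict(dose_Gy=30.0, n_fractions=3, ptv_cc=20.0, escalation=1.5),
         stress=False),
    dict(case_id="case_5", sex="F", age=81, interval_months=85,
         prev=dict(dose_Gy=45.0, n_fractions=3, ptv_cc=45.0, escalation=1.5),
         current=dict(dose_Gy=50.0, n_fractions=24, ptv_cc=54.0, escalation=1.3),
         stress=False),
    dict(case_id="case_6", sex="M", age=64, interval_months=14,
         prev=dict(dose_Gy=60.0, n_fractions=30, ptv_cc=98.0, escalation=1.0),
         current=dict(dose_Gy=50.0, n_fractions=24, ptv_cc=92.0, escalation=1.3),
         stress=False),
    dict(case_id="case_7", sex="M", age=77, interval_months=10,
         prev=dict(dose_Gy=66.0, n_fractions=33, ptv_cc=697.0, escalation=1.0),
         current=dict(dose_Gy=50.0, n_fractions=24, ptv_cc=26.0, escalation=1.3),
         stress=True),
)


def clinical_case_table() -> pd.DataFrame:
    """The case characteristics as a flat table (one row per case)."""
    rows = []
    for case in CLINICAL_CASES:
        rows.append({
            "case_id": case["case_id"], "sex": case["sex"], "age": case["age"],
            "interval_months": case["interval_months"],
            "prev_dose_Gy": case["prev"]["dose_Gy"],
            "prev_n_fractions": case["prev"]["n_fractions"],
            "prev_ptv_cc": case["prev"]["ptv_cc"],
            "current_dose_Gy": case["current"]["dose_Gy"],
            "current_n_fractions": case["current"]["n_fractions"],
            "current_ptv_cc": case["current"]["ptv_cc"],
            "stress": case["stress"],
        })
    return pd.DataFrame(rows)


def case_table_medians() -> dict:
    """Median previous/current PTV volumes (cm^3) and inter-course interval (months)."""
    table = clinical_case_table()
    return {
        "median_prev_ptv_cc": float(table["prev_ptv_cc"].median()),
        "median_current_ptv_cc": float(table["current_ptv_cc"].median()),
        "median_interval_months": float(table["interval_months"].median()),
    }


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class PhantomParams:
    """Parameters of one phantom case.

    The default lattice is 96 x 96 x 64 voxels at (2, 2, 3) mm, i.e. a
    192 mm cube of thorax.  Organ geometry is defined in absolute mm for
    that cube and scaled with the grid's physical extent, so coarser test
    grids cover the same anatomy.
    """

    case_id: str = "case_1"
    size: tuple = (96, 96, 64)
    spacing: tuple = (2.0, 2.0, 3.0)
    # ground-truth deformation
    deform_amplitude_mm: float = 10.0    # max displacement of the random part
    deform_smoothness_mm: float = 30.0   # Gaussian kernel scale of the random part
    affine_rotation_deg: float = 1.0
    affine_translation_mm: float = 2.0
    # dose model
    prev_prescription_Gy: float = 30.0
    prev_n_fractions: int = 3
    prev_escalation: float = 1.5
    prev_ptv_cc: float = 45.0
    current_prescription_Gy: float = 66.0
    current_n_fractions: int = 33
    current_escalation: float = 1.0
    current_ptv_cc: float = 79.0
    target_centre_mm: tuple = (30.0, 0.0, 5.0)
    prev_target_offset_mm: tuple = (8.0, 4.0, 3.0)
    penumbra_width_mm: float = 3.0
    # stress scenario (atelectasis-like collapse of the left lung)
    collapse_amplitude_mm: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.deform_amplitude_mm < 0 or self.collapse_amplitude_mm < 0:
            raise ValueError("deformation and collapse amplitudes must be >= 0")
        if self.penumbra_width_mm <= 0:
            raise ValueError("penumbra width must be positive")

    @classmethod
    def for_clinical_case(cls, index: int, **overrides) -> "PhantomParams":
        """Parameters seeded from row ``index`` (0-based) of the case table."""
        case = CLINICAL_CASES[index]
        return cls(
            case_id=case["case_id"],
            prev_prescription_Gy=case["prev"]["dose_Gy"],
            prev_n_fractions=case["prev"]["n_fractions"],
            prev_escalation=case["prev"]["escalation"],
            prev_ptv_cc=case["prev"]["ptv_cc"],
            current_prescription_Gy=case["current"]["dose_Gy"],
            current_n_fractions=case["current"]["n_fractions"],
            current_escalation=case["current"]["escalation"],
            current_ptv_cc=case["current"]["ptv_cc"],
            **overrides,
        )


@dataclass
class CentreErrorModel:
    """Residual registration error of a simulated centre.

    ``sigma_dir_mm`` / ``sigma_rir_mm`` are root-mean-square amplitudes of
    the smooth random residual displacement field for the deformable and
    rigid workflows; the deformable default is smaller, reflecting its
    better organ alignment.  ``roi_jitter_mm`` perturbs the anchor of the
    ROI each centre uses for its rigid fit (anatomical-focus preference).
    """

    sigma_rir_mm: float = 3.0
    sigma_dir_mm: float = 1.0
    smoothness_mm: float = 25.0
    roi_jitter_mm: float = 10.0
    roi_radius_mm: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if min(self.sigma_rir_mm, self.sigma_dir_mm, self.roi_jitter_mm) < 0:
            raise ValueError("error amplitudes must be >= 0")
        if self.roi_radius_mm <= 0 or self.smoothness_mm <= 0:
            raise ValueError("ROI radius and smoothness must be positive")


# ---------------------------------------------------------------------------
# analytic anatomy
# ---------------------------------------------------------------------------


def _centred_grid(size, spacing) -> ImageGrid:
    size = np.asarray(size, int)
    spacing = np.asarray(spacing, float)
    origin = -(size - 1) * spacing / 2.0
    return ImageGrid(origin=tuple(origin), spacing=tuple(spacing), size=tuple(size))


def _ellipsoid(coords, centre, radii) -> np.ndarray:
    d = (coords - np.asarray(centre)) / np.asarray(radii)
    return np.sum(d * d, axis=-1) <= 1.0


def _zcylinder(coords, cx, cy, radius, zlo=-np.inf, zhi=np.inf) -> np.ndarray:
    r2 = (coords[..., 0] - cx) ** 2 + (coords[..., 1] - cy) ** 2
    return (r2 <= radius**2) & (coords[..., 2] >= zlo) & (coords[..., 2] <= zhi)


def _tube(coords, a, b, radius) -> np.ndarray:
    """Voxels within ``radius`` of segment a-b."""
    a = np.asarray(a, float)
    ab = np.asarray(b, float) - a
    ap = coords - a
    t = np.clip(np.tensordot(ap, ab, axes=([-1], [0])) / (ab @ ab), 0.0, 1.0)
    closest = a + t[..., np.newaxis] * ab
    d2 = np.sum((coords - closest) ** 2, axis=-1)
    return d2 <= radius**2


def _analytic_organs(grid: ImageGrid, lung_left_shift_mm: float = 0.0,
                     lung_left_scale: float = 1.0) -> dict:
    """The eight organ masks as boolean arrays on ``grid``.

    ``lung_left_shift_mm``/``lung_left_scale`` implement the atelectasis-like
    collapse of the stress scenario (medial-superior shift plus shrinkage of
    the left lung); at (0, 1) the anatomy is the nominal one.
    """
    coords = grid.all_world_coords()
    extent = np.asarray(grid.size) * np.asarray(grid.spacing)
    s = extent / 192.0  # organ geometry is specified for a 192 mm cube

    def pt(x, y, z):
        return (x * s[0], y * s[1], z * s[2])

    zmax = extent[2]

    cord = _zcylinder(coords, *pt(0, 55, 0)[:2], 5.0 * s[0])
    trachea = _zcylinder(coords, *pt(0, 18, 0)[:2], 7.0 * s[0], zlo=20.0 * s[2], zhi=zmax)
    oesophagus = _zcylinder(coords, *pt(0, 38, 0)[:2], 5.0 * s[0])
    aorta = _zcylinder(coords, *pt(-20, 35, 0)[:2], 9.0 * s[0])
    heart = _ellipsoid(coords, pt(-12, -22, -35), (30 * s[0], 26 * s[1], 28 * s[2]))
    bronchus_r = _tube(coords, pt(0, 18, 20), pt(38, 4, -8), 5.5 * s[0])
    bronchus_l = _tube(coords, pt(0, 18, 20), pt(-38, 4, -8), 5.5 * s[0])

    mediastinum = cord | trachea | oesophagus | aorta | heart
    bronchi = (bronchus_r | bronchus_l) & ~mediastinum
    lung_right = _ellipsoid(coords, pt(45, 0, 5), (34 * s[0], 50 * s[1], 75 * s[2])) & ~mediastinum
    left_centre = pt(-45 + lung_left_shift_mm * 0.8 / s[0], 0,
                     5 + lung_left_shift_mm * 0.4 / s[2])
    left_radii = (34 * s[0] * lung_left_scale, 50 * s[1] * lung_left_scale,
                  75 * s[2] * lung_left_scale)
    lung_left = _ellipsoid(coords, left_centre, left_radii) & ~mediastinum

    return {
        "aorta": aorta, "bronchi": bronchi, "oesophagus": oesophagus,
        "heart": heart, "lung_left": lung_left, "lung_right": lung_right,
        "spinal_cord": cord, "trachea": trachea,
    }


def _sigmoid_dose(grid: ImageGrid, centre, r50_mm: float, width_mm: float,
                  dmax_Gy: float) -> np.ndarray:
    """Spherical target dose with sigmoid fall-off; 50% isodose at r50."""
    coords = grid.all_world_coords()
    r = np.linalg.norm(coords - np.asarray(centre, float), axis=-1)
    return dmax_Gy / (1.0 + np.exp((r - r50_mm) / width_mm))


def _ptv_radius_mm(ptv_cc: float, extent_mm: np.ndarray) -> float:
    r = (3.0 * ptv_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return float(min(r, 0.17 * float(extent_mm.min())))  # keep targets inside the phantom


# ---------------------------------------------------------------------------
# ground-truth deformation
# ---------------------------------------------------------------------------


def _smooth_random_field(grid: ImageGrid, amplitude_mm: float, smoothness_mm: float,
                         rng: np.random.Generator, norm: str = "max") -> np.ndarray:
    """Smooth random 3-vector displacement field, scaled to amplitude (mm)."""
    if amplitude_mm == 0:
        return np.zeros((*grid.size, 3))
    sigma_vox = np.asarray(smoothness_mm) / np.asarray(grid.spacing)
    field = np.stack(
        [gaussian_filter(rng.standard_normal(grid.size), sigma=sigma_vox) for _ in range(3)],
        axis=-1,
    )
    mag = np.linalg.norm(field, axis=-1)
    scale_ref = mag.max() if norm == "max" else np.sqrt(np.mean(mag**2))
    if scale_ref == 0:
        return np.zeros((*grid.size, 3))
    return field * (amplitude_mm / scale_ref)


def _negative_jacobian_fraction(field: np.ndarray, spacing) -> float:
    grads = [np.gradient(field[..., c], *spacing, edge_order=1) for c in range(3)]
    J = np.empty((*field.shape[:3], 3, 3))
    for i in range(3):
        for j in range(3):
            J[..., i, j] = grads[i][j] + (1.0 if i == j else 0.0)
    det = np.linalg.det(J)
    return float(np.mean(det <= 0))


def _ground_truth_transform(grid: ImageGrid, params: PhantomParams,
                            rng: np.random.Generator) -> SpatialTransform:
    field = _smooth_random_field(grid, params.deform_amplitude_mm,
                                 params.deform_smoothness_mm, rng, norm="max")
    angle = np.deg2rad(params.affine_rotation_deg)
    if angle != 0 or params.affine_translation_mm != 0:
        axis_angles = rng.uniform(-angle, angle, size=3)
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", axis_angles).as_matrix()
        b = rng.uniform(-params.affine_translation_mm, params.affine_translation_mm, size=3)
        coords = grid.all_world_coords()
        field = field + coords @ (R - np.eye(3)).T + b
    frac = _negative_jacobian_fraction(field, grid.spacing)
    if frac > 0.01:
        raise ValueError(
            f"ground-truth field folds: {frac:.1%} of voxels have non-positive "
            "Jacobian determinant (> 1% gate); reduce deform_amplitude_mm or "
            "increase deform_smoothness_mm"
        )
    return SpatialTransform.from_field(field, grid)


# ---------------------------------------------------------------------------
# case generation
# ---------------------------------------------------------------------------


def generate_case(params: PhantomParams) -> CaseBundle:
    """Generate one phantom case with ground-truth deformation and doses.

    The current-course anatomy is built from analytic shapes; the
    previous-course anatomy is that anatomy carried through the (inverted)
    ground-truth deformation, so the stored pull-back transform maps the
    current masks exactly back onto the previous ones (up to resampling).
    """
    rng = np.random.default_rng(params.seed)
    grid = _centred_grid(params.size, params.spacing)
    extent = np.asarray(grid.size) * np.asarray(grid.spacing)

    organ_arrays = _analytic_organs(grid)
    masks_current = {
        organ: StructureMask(organ=organ, grid=grid, voxels=arr, allow_empty=True)
        for organ, arr in organ_arrays.items()
    }

    gt = _ground_truth_transform(grid, params, rng)
    gt_inv = invert_field(gt, grid)
    masks_prev = {
        organ: apply_to_mask(mask, gt_inv, grid)
        for organ, mask in masks_current.items()
    }

    scale = extent / 192.0
    c_cur = np.asarray(params.target_centre_mm) * scale
    c_prev = c_cur + np.asarray(params.prev_target_offset_mm) * scale
    r50_cur = _ptv_radius_mm(params.current_ptv_cc, extent)
    r50_prev = _ptv_radius_mm(params.prev_ptv_cc, extent)

    dose_current = DoseGrid(
        grid=grid,
        values=_sigmoid_dose(grid, c_cur, r50_cur, params.penumbra_width_mm,
                             params.current_prescription_Gy * params.current_escalation),
        dose_kind=PHYSICAL, n_fractions=params.current_n_fractions)
    dose_prev = DoseGrid(
        grid=grid,
        values=_sigmoid_dose(grid, c_prev, r50_prev, params.penumbra_width_mm,
                             params.prev_prescription_Gy * params.prev_escalation),
        dose_kind=PHYSICAL, n_fractions=params.prev_n_fractions)

    return CaseBundle(
        case_id=params.case_id,
        grid_prev=grid, grid_current=grid,
        masks_prev=masks_prev, masks_current=masks_current,
        dose_prev=dose_prev, dose_current=dose_current,
        course_prev=CourseInfo("previous", params.prev_n_fractions,
                               params.prev_prescription_Gy),
        course_current=CourseInfo("current", params.current_n_fractions,
                                  params.current_prescription_Gy),
        alpha_beta=dict(DEFAULT_ALPHA_BETA),
        gt_transform=gt,
    )


def generate_stress_case(params: PhantomParams) -> CaseBundle:
    """A case with an atelectasis-like change no smooth field explains.

    The previous-course anatomy is nominal; on the current course the left
    lung has collapsed (shifted medially/superiorly and shrunk by
    ``collapse_amplitude_mm``), so neither rigid nor deformable simulated
    registrations can align it, and the pipeline should flag the case
    instead of crashing.
    """
    bundle = generate_case(params)
    amp = params.collapse_amplitude_mm
    if amp == 0:
        return bundle
    scale = max(0.35, 1.0 - amp / 80.0)
    collapsed = _analytic_organs(bundle.grid_current, lung_left_shift_mm=amp,
                                 lung_left_scale=scale)
    bundle.masks_current["lung_left"] = StructureMask(
        organ="lung_left", grid=bundle.grid_current,
        voxels=collapsed["lung_left"], allow_empty=True)
    return bundle


# ---------------------------------------------------------------------------
# simulated centres
# ---------------------------------------------------------------------------


def _roi_mask(bundle: CaseBundle, anchor_mm: np.ndarray, radius_mm: float) -> StructureMask:
    coords = bundle.grid_current.all_world_coords()
    d = np.linalg.norm(coords - anchor_mm, axis=-1)
    return StructureMask(organ="roi", grid=bundle.grid_current,
                         voxels=d <= radius_mm, allow_empty=True)


def _rigid_residual(rng: np.random.Generator, sigma_mm: float,
                    anchor_mm: np.ndarray, radius_mm: float) -> SpatialTransform:
    """A small random rigid perturbation with ~``sigma_mm`` RMS displacement.

    Half of the displacement variance is a pure translation, half a small
    rotation about the ROI anchor (whose displacement scales with the
    characteristic radius), so the residual stays rigid and the RIR
    submission keeps a rigid6 transform.
    """
    if sigma_mm == 0:
        return SpatialTransform.identity()
    t = rng.normal(0.0, sigma_mm / np.sqrt(6.0), size=3)
    angle_sd = sigma_mm / np.sqrt(2.0) / max(radius_mm, 1.0) / np.sqrt(3.0)
    angles = rng.normal(0.0, angle_sd, size=3)
    from scipy.spatial.transform import Rotation

    R = Rotation.from_euler("xyz", angles).as_matrix()
    # rotate about the anchor: x -> R (x - a) + a + t
    offset = anchor_mm - R @ anchor_mm + t
    return SpatialTransform.from_rigid(angles, offset)


def simulate_centres(bundle: CaseBundle, n_centres: int,
                     error_model: CentreErrorModel | None = None) -> list:
    """Simulate ``n_centres`` centres, each submitting one RIR and one DIR.

    DIR: ground-truth field composed with a centre-specific smooth random
    residual field (RMS ``sigma_dir_mm``).  RIR: Procrustes rigid fit to
    the ground-truth field over a sphere around a centre-jittered anchor
    near the current target, composed with a small random rigid residual
    (RMS ``sigma_rir_mm``).  Transferred masks and the mapped
    previous-course physical dose are produced from each stored transform.
    """
    if n_centres < 2:
        raise ValueError("at least 2 centres are required (variability is undefined otherwise)")
    if bundle.gt_transform is None:
        raise ValueError("bundle lacks a ground-truth transform; cannot simulate centres")
    err = error_model or CentreErrorModel()
    grid = bundle.grid_current
    gt = bundle.gt_transform

    # dose-weighted anchor of the current plan (stands in for the tumour focus)
    coords = grid.all_world_coords()
    w = np.asarray(bundle.dose_current.values, float)
    anchor0 = (coords * w[..., np.newaxis]).sum(axis=(0, 1, 2)) / w.sum()

    submissions = []
    children = np.random.SeedSequence(err.seed).spawn(n_centres)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        centre_id = f"centre_{i + 1:02d}"

        resid_dir = _smooth_random_field(grid, err.sigma_dir_mm, err.smoothness_mm,
                                         rng, norm="rms")
        jitter = (rng.normal(0.0, err.roi_jitter_mm, size=3)
                  if err.roi_jitter_mm > 0 else np.zeros(3))

        t_dir = compose(gt, SpatialTransform.from_field(resid_dir, grid), grid)
        roi = _roi_mask(bundle, anchor0 + jitter, err.roi_radius_mm)
        rigid_fit = fit_rigid(gt, roi)
        t_rir = compose(rigid_fit,
                        _rigid_residual(rng, err.sigma_rir_mm, anchor0,
                                        err.roi_radius_mm), grid)

        for method, transform in ((RIR, t_rir), (DIR, t_dir)):
            masks = {organ: apply_to_mask(mask, transform, grid)
                     for organ, mask in bundle.masks_prev.items()}
            mapped = apply_to_dose(bundle.dose_prev, transform, grid)
            submissions.append(CentreSubmission(
                centre_id=centre_id, method=method, transform=transform,
                masks=masks, mapped_dose=mapped))
    return submissions
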