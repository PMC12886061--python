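"""DVHs, near-maximum constraints, inter-centre DVH bands and band areas.

Cumulative dose-volume histograms are sampled on a uniform 0.1 Gy axis with
the >= convention: ``V(d)`` is the organ fraction (and absolute cm^3)
receiving at least ``d`` Gy, so every curve starts at 100% and is
non-increasing.  The near-maximum constraint D_0.3cm^3 — the minimum dose
received by the hottest 0.3 cm^3 — is read off the absolute-volume curve by
linear interpolation.  The spread of curves across centres is summarised by
pointwise bands (min/max and quartiles) and by the band area: the integral
over dose of the inter-centre interquartile range of volume, in Gy.%.

Constraint distributions are symmetrised for display by subtracting the
midpoint (min+max)/2 of each case/organ/method group, placing the extreme
centres at +/- range/2 around 0 Gy (a dialect choice: the group midpoint,
not the median).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import DoseGrid, StructureMask

DEFAULT_BIN_GY = 0.1


@dataclass
class DVHCurve:
    """A cumulative DVH on a uniform dose axis."""

    dose_Gy: np.ndarray       # 0, bin, 2*bin, ...
    volume_pct: np.ndarray    # fraction of organ volume >= dose, in %
    volume_cm3: np.ndarray    # same in absolute cm^3
    organ_volume_cm3: float
    keys: dict = field(default_factory=dict)  # case/centre/method/organ/dose label

    @property
    def bin_Gy(self) -> float:
        return float(self.dose_Gy[1] - self.dose_Gy[0]) if self.dose_Gy.size > 1 else DEFAULT_BIN_GY


@dataclass
class BandSummary:
    """Pointwise spread of DVH curves across centres."""

    dose_Gy: np.ndarray
    vmin: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    vmax: np.ndarray
    band_area_minmax: float  # Gy.%
    band_area_iqr: float     # Gy.%


def compute_dvh(dose: DoseGrid, mask: StructureMask, bin_Gy: float = DEFAULT_BIN_GY,
                keys: dict | None = None) -> DVHCurve:
    """Cumulative DVH of ``dose`` over ``mask`` at ``bin_Gy`` sampling."""
    if not dose.grid.same_geometry(mask.grid):
        raise ValueError("dose and mask must share one grid")
    if mask.is_empty:
        raise ValueError("DVH of an empty mask is undefined")
    organ_dose = np.asarray(dose.values, float)[mask.voxels > 0]
    n_vox = organ_dose.size
    dmax = float(organ_dose.max())
    n_bins = int(np.ceil(dmax / bin_Gy)) + 2  # one point past the max so V ends at 0
    axis = np.arange(n_bins) * bin_Gy
    # V(d) = fraction of voxels with dose >= d, via a sorted search
    sorted_dose = np.sort(organ_dose)
    n_ge = n_vox - np.searchsorted(sorted_dose, axis, side="left")
    frac = n_ge / n_vox
    voxel_cm3 = mask.grid.voxel_volume_cm3
    return DVHCurve(dose_Gy=axis, volume_pct=100.0 * frac,
                    volume_cm3=frac * n_vox * voxel_cm3,
                    organ_volume_cm3=n_vox * voxel_cm3,
                    keys=dict(keys or {}))


def dose_at_volume(curve: DVHCurve, v_abs_cm3: float = 0.3):
    """Near-maximum dose D_v: minimum dose to the hottest ``v_abs_cm3``.

    Finds the smallest grid dose with absolute volume <= ``v_abs_cm3`` and
    interpolates linearly between the bracketing grid points.

    Returns
    -------
    (dose_Gy, flagged) : the flag is set when the organ is smaller than
    ``v_abs_cm3``, in which case the maximum dose is returned.
    """
    v = curve.volume_cm3
    if curve.organ_volume_cm3 < v_abs_cm3:
        nonzero = np.flatnonzero(v > 0)
        return float(curve.dose_Gy[nonzero[-1]] if nonzero.size else 0.0), True
    below = np.flatnonzero(v <= v_abs_cm3)
    k = int(below[0])
    if k == 0:
        return float(curve.dose_Gy[0]), False
    v_hi, v_lo = v[k - 1], v[k]  # v_hi > v_abs >= v_lo
    if v_hi == v_lo:
        return float(curve.dose_Gy[k]), False
    t = (v_hi - v_abs_cm3) / (v_hi - v_lo)
    return float(curve.dose_Gy[k - 1] + t * curve.bin_Gy), False


def _common_axis(curves):
    bin_Gy = curves[0].bin_Gy
    for c in curves[1:]:
        if abs(c.bin_Gy - bin_Gy) > 1e-12:
            raise ValueError("curves must share one dose bin width")
    n = max(c.dose_Gy.size for c in curves)
    axis = np.arange(n) * bin_Gy
    stacked = np.zeros((len(curves), n))
    for i, c in enumerate(curves):
        stacked[i, :c.volume_pct.size] = c.volume_pct  # pad with 0% past each max dose
    return axis, stacked


def band(curves) -> BandSummary:
    """Pointwise min/max and quartiles of DVH curves across centres."""
    if len(curves) < 2:
        raise ValueError("a DVH band requires at least 2 curves")
    axis, stacked = _common_axis(curves)
    vmin = stacked.min(axis=0)
    vmax = stacked.max(axis=0)
    q25 = np.percentile(stacked, 25, axis=0)
    q75 = np.percentile(stacked, 75, axis=0)
    bin_Gy = float(axis[1] - axis[0]) if axis.size > 1 else DEFAULT_BIN_GY
    return BandSummary(dose_Gy=axis, vmin=vmin, q25=q25, q75=q75, vmax=vmax,
                       band_area_minmax=float((vmax - vmin).sum() * bin_Gy),
                       band_area_iqr=float((q75 - q25).sum() * bin_Gy))


def band_area_iqr(curves) -> float:
    """Area (Gy.%) of the inter-centre interquartile range of the DVH curves."""
    return band(curves).band_area_iqr


def symmetrize(values) -> np.ndarray:
    """Centre a group of per-centre values on its min-max midpoint."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("symmetrisation requires at least 2 values")
    return values - (values.min() + values.max()) / 2.0


def curves_to_frame(curves) -> pd.DataFrame:
    """Long-format export of DVH curves (keys + dose + volumes)."""
    frames = []
    for c in curves:
        df = pd.DataFrame({"dose_Gy": c.dose_Gy, "volume_pct": c.volume_pct,
                           "volume_cm3": c.volume_cm3})
        for k, v in c.keys.items():
            df[k] = v
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
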