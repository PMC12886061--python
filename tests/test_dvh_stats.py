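"""DVH computation, near-maximum constraints, bands and symmetrisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reirrad import (
    DoseGrid,
    ImageGrid,
    StructureMask,
    band,
    band_area_iqr,
    compute_dvh,
    dose_at_volume,
    symmetrize,
)
from tests.conftest import random_blob


def _case(grid, dose_values, mask_values):
    dose = DoseGrid(grid=grid, values=dose_values, dose_kind="EQD2")
    mask = StructureMask(organ="o", grid=grid, voxels=mask_values)
    return dose, mask


def _grid(size=(10, 10, 10), spacing=(10.0, 10.0, 10.0)):
    # 1 cm^3 voxels by default: volumes are easy to reason about
    return ImageGrid(origin=(0, 0, 0), spacing=spacing, size=size)


def test_uniform_dose_is_a_step_function():
    grid = _grid()
    dose, mask = _case(grid, np.full(grid.size, 10.0), np.ones(grid.size))
    curve = compute_dvh(dose, mask)
    at = lambda d: curve.volume_pct[int(round(d / 0.1))]
    assert at(0.0) == 100.0
    assert at(10.0) == 100.0  # >= convention includes the max
    assert curve.volume_pct[-1] == 0.0


def test_half_and_half_organ():
    grid = _grid()
    values = np.full(grid.size, 4.0)
    values[5:] = 8.0
    dose, mask = _case(grid, values, np.ones(grid.size))
    curve = compute_dvh(dose, mask)
    assert curve.volume_pct[int(round(6.0 / 0.1))] == pytest.approx(50.0)


def test_every_curve_is_monotone_and_starts_at_100(rng):
    grid = _grid(size=(12, 12, 12), spacing=(4.0, 4.0, 4.0))
    for seed in range(5):
        r = np.random.default_rng(seed)
        dose, mask = _case(grid, r.random(grid.size) * 30,
                           random_blob(grid, r).voxels)
        curve = compute_dvh(dose, mask)
        assert curve.volume_pct[0] == 100.0
        assert np.all(np.diff(curve.volume_pct) <= 1e-12)


@pytest.mark.parametrize("seed", range(6))
def test_dvh_matches_per_voxel_counting_oracle(seed):
    rng = np.random.default_rng(seed)
    grid = _grid(size=tuple(rng.integers(8, 21, size=3)), spacing=(2.0, 2.0, 3.0))
    dose, mask = _case(grid, rng.random(grid.size) * 25, random_blob(grid, rng).voxels)
    curve = compute_dvh(dose, mask)
    organ = np.asarray(dose.values)[mask.voxels > 0]
    for k, d in enumerate(curve.dose_Gy):
        expected = 100.0 * np.mean(organ >= d)
        assert curve.volume_pct[k] == pytest.approx(expected, abs=1e-9)


class TestDoseAtVolume:
    def test_uniform_organ_returns_its_dose(self):
        grid = _grid()  # 1000 voxels x 1 cm^3
        dose, mask = _case(grid, np.full(grid.size, 10.0), np.ones(grid.size))
        d, flagged = dose_at_volume(compute_dvh(dose, mask), 0.3)
        assert not flagged
        assert d == pytest.approx(10.0, abs=0.1)

    def test_hot_subvolume_sets_the_constraint(self):
        # 1 cm^3 at 5 Gy plus 0.3 cm^3 at 20 Gy -> D_0.3cc = 20 Gy
        grid = ImageGrid(origin=(0, 0, 0), spacing=(10.0, 10.0, 1.0), size=(1, 1, 13))
        values = np.full(grid.size, 5.0)
        values[0, 0, 10:] = 20.0  # 3 voxels x 0.1 cm^3
        dose, mask = _case(grid, values, np.ones(grid.size))
        d, flagged = dose_at_volume(compute_dvh(dose, mask), 0.3)
        assert not flagged
        assert d == pytest.approx(20.0, abs=0.1)

    def test_linear_ramp_inverts_analytically(self):
        # 100 voxels of 0.1 cm^3, dose = 0.1 Gy per voxel step (0 .. 9.9 Gy):
        # the hottest 0.3 cm^3 are the 3 voxels at 9.7, 9.8, 9.9 Gy
        grid = ImageGrid(origin=(0, 0, 0), spacing=(10.0, 10.0, 1.0), size=(1, 1, 100))
        values = 0.1 * np.arange(100).reshape(grid.size)
        dose, mask = _case(grid, values, np.ones(grid.size))
        d, flagged = dose_at_volume(compute_dvh(dose, mask), 0.3)
        assert not flagged
        assert d == pytest.approx(9.7, abs=0.11)

    def test_inverts_the_absolute_dvh_within_one_bin(self, rng):
        grid = _grid(size=(12, 12, 12), spacing=(5.0, 5.0, 5.0))
        dose, mask = _case(grid, rng.random(grid.size) * 40, random_blob(grid, rng).voxels)
        curve = compute_dvh(dose, mask)
        d, _ = dose_at_volume(curve, 0.3)
        k = int(np.floor(d / curve.bin_Gy))
        v_at = np.interp(d, curve.dose_Gy, curve.volume_cm3)
        assert abs(v_at - 0.3) <= max(curve.volume_cm3[max(k - 1, 0)]
                                      - curve.volume_cm3[min(k + 1, len(curve.dose_Gy) - 1)],
                                      1e-9)

    def test_organ_smaller_than_constraint_is_flagged(self):
        grid = ImageGrid(origin=(0, 0, 0), spacing=(1.0, 1.0, 1.0), size=(5, 5, 5))
        values = np.full(grid.size, 7.0)
        dose, mask = _case(grid, values, np.ones(grid.size))  # 0.125 cm^3 total
        d, flagged = dose_at_volume(compute_dvh(dose, mask), 0.3)
        assert flagged
        assert d == pytest.approx(7.0, abs=0.1)


class TestBands:
    def _curves(self, offsets, support=50.0):
        grid = _grid()
        curves = []
        for off in offsets:
            values = np.full(grid.size, support)
            dose = DoseGrid(grid=grid, values=values, dose_kind="EQD2")
            mask = StructureMask(organ="o", grid=grid, voxels=np.ones(grid.size))
            c = compute_dvh(dose, mask)
            c.volume_pct = np.clip(c.volume_pct - off, 0.0, 100.0)
            curves.append(c)
        return curves

    def test_identical_curves_have_zero_width_band(self):
        curves = self._curves([0.0, 0.0, 0.0])
        summary = band(curves)
        assert summary.band_area_minmax == 0.0
        assert summary.band_area_iqr == 0.0

    def test_two_curves_iqr_is_half_the_minmax_width(self):
        curves = self._curves([0.0, 10.0])
        summary = band(curves)
        np.testing.assert_allclose(summary.q75 - summary.q25,
                                   (summary.vmax - summary.vmin) / 2.0, atol=1e-9)

    def test_two_vertically_offset_curves_have_hand_computable_area(self):
        # 10% offset over a 50 Gy support: min-max area = 10 x 50 = 500 Gy.%,
        # IQR area = half of that for two curves
        curves = self._curves([0.0, 10.0], support=50.0)
        summary = band(curves)
        assert summary.band_area_minmax == pytest.approx(500.0, rel=0.01)
        assert summary.band_area_iqr == pytest.approx(250.0, rel=0.01)

    def test_band_envelops_every_input_curve(self, phantom_case, rng):
        curves = self._curves(rng.uniform(0, 20, size=6))
        summary = band(curves)
        axis_len = summary.dose_Gy.size
        for c in curves:
            v = np.zeros(axis_len)
            v[:c.volume_pct.size] = c.volume_pct
            assert np.all(v >= summary.vmin - 1e-9)
            assert np.all(v <= summary.vmax + 1e-9)

    def test_area_invariant_under_centre_permutation_and_scales_with_spread(self):
        curves = self._curves([0.0, 4.0, 8.0, 12.0])
        assert band_area_iqr(curves) == pytest.approx(band_area_iqr(curves[::-1]))
        doubled = self._curves([0.0, 8.0, 16.0, 24.0])
        assert band_area_iqr(doubled) == pytest.approx(2 * band_area_iqr(curves),
                                                       rel=0.05)

    def test_single_curve_is_an_error(self):
        with pytest.raises(ValueError):
            band(self._curves([0.0]))


@pytest.mark.parametrize("values,expected", [
    ([10.0, 14.0], [-2.0, 2.0]),
    ([5.0, 5.0, 5.0], [0.0, 0.0, 0.0]),
    ([1.0, 3.0, 9.0], [-4.0, -2.0, 4.0]),
])
def test_symmetrize_centres_on_group_midpoint(values, expected):
    np.testing.assert_allclose(symmetrize(values), expected)


def test_symmetrize_needs_two_values():
    with pytest.raises(ValueError):
        symmetrize([1.0])


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=-1e3, max_value=1e3), min_size=2, max_size=12))
def test_symmetrized_extremes_sit_at_plus_minus_half_range(values):
    centred = symmetrize(values)
    half_range = (max(values) - min(values)) / 2.0
    assert centred.max() == pytest.approx(half_range, abs=1e-9)
    assert centred.min() == pytest.approx(-half_range, abs=1e-9)
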