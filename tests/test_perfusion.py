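"""Two-volume perfusion math: MIP, C_in, M_T, Eq-inversion, CFR, binning."""

import dataclasses

import numpy as np
import pytest

from fpact.perfusion import (
    NoEnhancementError,
    bin_voxels,
    compute_cfr,
    compute_cin,
    compute_perfusion,
    compute_tissue_mass,
    mip_combine,
)
from fpact.phantom import LinearRampAIF, simulate_acquisition
from fpact.volume import BinaryMask, GridMismatchError, VolumeScan


def vol(arr, spacing=(1.0, 1.0, 1.0), **kw):
    return VolumeScan(np.asarray(arr, dtype=np.float32), spacing, **kw)


def full_mask(shape, spacing=(1.0, 1.0, 1.0), role="myocardium"):
    return BinaryMask(np.ones(shape, dtype=bool), spacing, role=role)


class TestMipCombine:
    def test_single_volume_is_identity(self):
        v = vol(np.arange(8.0).reshape(2, 2, 2))
        np.testing.assert_array_equal(mip_combine([v]).hu, v.hu)

    def test_disjoint_bright_regions_union(self):
        a = np.zeros((4, 4, 4))
        b = np.zeros((4, 4, 4))
        a[0], b[3] = 100.0, 200.0
        out = mip_combine([vol(a), vol(b)]).hu
        assert out[0].max() == 100.0 and out[3].max() == 200.0

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(3)
        vols = [vol(rng.normal(size=(5, 4, 3))) for _ in range(4)]
        out = mip_combine(vols).hu
        oracle = np.stack([v.hu for v in vols]).max(axis=0)
        np.testing.assert_array_equal(out, oracle)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(GridMismatchError):
            mip_combine([vol(np.zeros((2, 2, 2))), vol(np.zeros((3, 2, 2)))])


class TestComputeCin:
    def test_hand_arithmetic(self):
        shape = (3, 3, 3)
        v1 = vol(np.full(shape, 340.0), time_s=0.0)
        v2 = vol(np.full(shape, 460.0), time_s=5.0)
        roi = full_mask(shape, role="aortic-root")
        assert compute_cin(v1, v2, roi, baseline_hu=40.0) == pytest.approx(360.0)

    def test_zero_enhancement_rejected(self):
        shape = (3, 3, 3)
        v = vol(np.full(shape, 40.0))
        roi = full_mask(shape, role="aortic-root")
        with pytest.raises(NoEnhancementError):
            compute_cin(v, v, roi, baseline_hu=40.0)

    def test_matches_analytic_tdc_on_phantom(self, noiseless_small):
        vols, truth = simulate_acquisition(noiseless_small)
        t1, t2 = 10, 20
        cin = compute_cin(
            vols[t1], vols[t2], truth.aorta, noiseless_small.baseline_blood_hu
        )
        aif = noiseless_small.aif
        expected = (
            float(aif.value(vols[t1].time_s)) + float(aif.value(vols[t2].time_s))
        ) / 2.0
        assert cin == pytest.approx(expected, rel=1e-5)


class TestTissueMass:
    def test_printed_voxel_size_arithmetic(self):
        arr = np.zeros((100, 100, 10), dtype=bool)
        arr.ravel()[:100_000] = True
        mask = BinaryMask(arr.reshape(100, 100, 10), (0.43, 0.43, 0.5))
        assert compute_tissue_mass(mask) == pytest.approx(9.754, abs=0.001)

    def test_one_millilitre_voxel(self):
        mask = BinaryMask(np.ones((1, 1, 1), dtype=bool), (10.0, 10.0, 10.0))
        assert compute_tissue_mass(mask) == pytest.approx(1.055)

    def test_linearity_in_voxel_count(self):
        a = BinaryMask(np.ones((4, 4, 2), dtype=bool), (1.0, 1.0, 1.0))
        b = BinaryMask(np.ones((4, 4, 4), dtype=bool), (1.0, 1.0, 1.0))
        assert compute_tissue_mass(b) == pytest.approx(2 * compute_tissue_mass(a))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            compute_tissue_mass(BinaryMask(np.zeros((2, 2, 2), dtype=bool), (1, 1, 1)))


def two_volume_setup(dhu=42.2, cin_enh=400.0, dt_s=6.0, shape=(6, 6, 6)):
    """Uniform myocardium + separate aortic ROI with prescribed enhancement."""
    myo_arr = np.zeros(shape, dtype=bool)
    myo_arr[:, :, :3] = True
    roi_arr = np.zeros(shape, dtype=bool)
    roi_arr[:, :, 4:] = True
    hu1 = np.zeros(shape)
    hu2 = np.zeros(shape)
    hu1[myo_arr], hu2[myo_arr] = 50.0, 50.0 + dhu
    hu1[roi_arr] = hu2[roi_arr] = 40.0 + cin_enh  # constant: mean = cin + baseline
    v1 = vol(hu1, time_s=0.0)
    v2 = vol(hu2, time_s=dt_s)
    return v1, v2, BinaryMask(myo_arr, (1, 1, 1)), BinaryMask(roi_arr, (1, 1, 1), "aortic-root")


class TestComputePerfusion:
    def test_closed_form_inversion(self):
        """dHU 42.2 HU over 0.1 min with C_in 400 HU -> exactly 1 mL/min/g."""
        v1, v2, myo, roi = two_volume_setup()
        res = compute_perfusion(v1, v2, myo, roi, baseline_hu=40.0)
        assert res.p_ave == pytest.approx(42.2 / (0.1 * 400.0 * 1.055), rel=1e-6)
        assert res.p_ave == pytest.approx(1.0, rel=1e-3)
        inside = res.perfusion_map[myo.data]
        assert inside == pytest.approx(res.p_ave, rel=1e-6)

    def test_mask_mean_equals_p_ave(self):
        rng = np.random.default_rng(0)
        v1, v2, myo, roi = two_volume_setup()
        v2 = vol(v2.hu + rng.normal(0, 5, v2.shape) * myo.data, time_s=v2.time_s)
        res = compute_perfusion(v1, v2, myo, roi, baseline_hu=40.0)
        assert float(np.nanmean(res.perfusion_map[myo.data])) == pytest.approx(
            res.p_ave, rel=1e-9
        )

    def test_zero_change_subregion_maps_to_zero(self):
        v1, v2, myo, roi = two_volume_setup()
        hu2 = v2.hu.copy()
        hu2[0, :, :3] = 50.0  # no enhancement in one myocardial slab
        v2b = vol(hu2, time_s=v2.time_s)
        res = compute_perfusion(v1, v2b, myo, roi, baseline_hu=40.0)
        assert np.allclose(res.perfusion_map[0, :, :3], 0.0)
        assert res.p_ave < 1.0

    def test_scale_invariance_of_enhancement(self):
        """Scaling all enhancements (tissue and blood) leaves P unchanged."""
        v1, v2, myo, roi = two_volume_setup()
        res = compute_perfusion(v1, v2, myo, roi, baseline_hu=40.0)
        k = 2.5
        def scaled(v):
            hu = v.hu.copy().astype(np.float64)
            hu[myo.data] = 50.0 + k * (hu[myo.data] - 50.0)
            hu[roi.data] = 40.0 + k * (hu[roi.data] - 40.0)
            return vol(hu, time_s=v.time_s)
        res2 = compute_perfusion(scaled(v1), scaled(v2), myo, roi, baseline_hu=40.0)
        assert res2.p_ave == pytest.approx(res.p_ave, rel=1e-6)

    def test_negative_mean_enhancement_rejected(self):
        v1, v2, myo, roi = two_volume_setup(dhu=-10.0)
        with pytest.raises(NoEnhancementError, match="no net myocardial"):
            compute_perfusion(v1, v2, myo, roi, baseline_hu=40.0)

    def test_nonpositive_dt_rejected(self):
        v1, v2, myo, roi = two_volume_setup(dt_s=0.0)
        with pytest.raises(ValueError, match="V2 time"):
            compute_perfusion(v1, v2, myo, roi, baseline_hu=40.0)

    def test_linear_aif_recovery_is_exact(self, small_spec):
        """With a linear arterial ramp the two-point C_in is exact, so the
        per-voxel map recovers ground truth to float precision."""
        spec = dataclasses.replace(
            small_spec,
            aif=LinearRampAIF(slope_hu_per_s=20.0, t0_s=1.0),
            frame_times_s=(5.0, 11.0),
            frame_ma=(50.0, 200.0),
            noise_sigma_ref_hu=0.0,
        )
        vols, truth = simulate_acquisition(spec, condition="stress")
        res = compute_perfusion(
            vols[0], vols[1], truth.myo, truth.aorta, spec.baseline_blood_hu
        )
        m = truth.myo.data
        rel = res.perfusion_map[m] / truth.perfusion_stress[m] - 1.0
        assert np.nanmax(np.abs(rel)) < 1e-3


class TestCfr:
    def _pair(self, p_stress, p_rest, shape=(6, 6, 6)):
        v1, v2, myo, roi = two_volume_setup(dhu=42.2 * p_rest, shape=shape)
        rest = compute_perfusion(v1, v2, myo, roi, baseline_hu=40.0)
        v1, v2, myo, roi = two_volume_setup(dhu=42.2 * p_stress, shape=shape)
        stress = compute_perfusion(v1, v2, myo, roi, baseline_hu=40.0)
        return stress, rest

    def test_identical_maps_give_unity(self):
        stress, rest = self._pair(1.0, 1.0)
        cfr = compute_cfr(stress, rest)
        assert np.allclose(cfr[rest.mask.data], 1.0)

    def test_four_to_one_ratio(self):
        stress, rest = self._pair(2.0, 0.5)
        cfr = compute_cfr(stress, rest)
        assert cfr[rest.mask.data] == pytest.approx(4.0, rel=1e-3)

    def test_floor_flags_undefined(self):
        stress, rest = self._pair(2.0, 0.5)
        rest.perfusion_map[0, 0, 0] = 0.01  # voxel inside the mask
        cfr = compute_cfr(stress, rest, rest_floor=0.1)
        assert np.isnan(cfr[0, 0, 0])


class TestBinVoxels:
    def test_factor_one_identity(self):
        arr = np.random.default_rng(0).normal(size=(4, 4, 4))
        np.testing.assert_array_equal(bin_voxels(arr, 1), arr)

    def test_uniform_map_unchanged(self):
        arr = np.full((8, 8, 8), 3.3)
        assert np.allclose(bin_voxels(arr, 4), 3.3)

    def test_all_nan_block_stays_undefined(self):
        arr = np.full((4, 4, 4), np.nan)
        arr[2:, 2:, 2:] = 1.0
        out = bin_voxels(arr, 2)
        assert np.isnan(out[0, 0, 0]) and out[1, 1, 1] == 1.0

    def test_binning_reduces_noise_rmse(self):
        """Monte-Carlo: block-mean binning strictly lowers voxelwise RMSE."""
        rng = np.random.default_rng(42)
        truth = np.full((32, 32, 32), 2.0)
        noisy = truth + rng.normal(0, 1.0, truth.shape)
        rmse_raw = np.sqrt(np.mean((noisy - truth) ** 2))
        binned = bin_voxels(noisy, 4)
        rmse_binned = np.sqrt(np.mean((binned - 2.0) ** 2))
        assert rmse_binned < rmse_raw
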