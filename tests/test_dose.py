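"""Voxel S-value dose engine: kernels, convolution, cDVH, isodose."""

import itertools

import numpy as np
import pytest

from y90quant.dose import (
    DoseMap,
    SValueKernel,
    cdvh,
    cumulated_activity,
    dose_convolve,
    dose_voi_summary,
    interpolate_kernel,
    isodose_levels,
    load_kernel_csv,
    make_synthetic_kernel,
    save_kernel_csv,
)
from y90quant.imgcore import UnitsError, VoiMask, VoxelGrid


def _const_kernel(voxel_size, value, extent=1, center_boost=1e-9):
    v = np.full((2 * extent + 1,) * 3, value, float)
    v[extent, extent, extent] += center_boost  # keep self-dose maximal
    return SValueKernel(voxel_size=voxel_size, values=v)


def _activity(data, spacing=4.664, units="MBq_s"):
    return VoxelGrid(np.asarray(data, float), (spacing,) * 3, units=units)


class TestKernel:
    def test_invariants(self):
        with pytest.raises(ValueError):
            SValueKernel(3.0, np.ones((2, 2, 2)))  # even extents
        bad = np.ones((3, 3, 3))
        bad[0, 0, 0] = 5.0  # max off-centre
        with pytest.raises(ValueError):
            SValueKernel(3.0, bad)
        with pytest.raises(ValueError):
            SValueKernel(-1.0, np.ones((1, 1, 1)))

    def test_synthetic_kernel_energy_normalised(self):
        k = make_synthetic_kernel(4.664, extent=3)
        mass_kg = 0.4664**3 / 1000.0
        assert (k.values * mass_kg).sum() == pytest.approx(
            0.9337 * 1.602e-13 * 1e9, rel=1e-9
        )
        assert k.s_self == k.values.max()

    def test_symmetry_of_synthetic_kernel(self):
        k = make_synthetic_kernel(3.0, extent=2)
        assert k.s(1, 0, 0) == pytest.approx(k.s(-1, 0, 0))
        assert k.s(1, 0, 0) == pytest.approx(k.s(0, 0, 1))

    def test_csv_round_trip(self, tmp_path):
        k = make_synthetic_kernel(3.0, extent=2)
        save_kernel_csv(k, tmp_path / "k.csv")
        back = load_kernel_csv(tmp_path / "k.csv")
        assert back.voxel_size == k.voxel_size
        np.testing.assert_allclose(back.values, k.values, rtol=1e-6)

    def test_shipped_kernels_load(self):
        from importlib.resources import files

        for name in ("synthetic_y90_svalues_3mm.csv", "synthetic_y90_svalues_6mm.csv"):
            k = load_kernel_csv(files("y90quant.data") / name)
            assert k.s_self > 0

    def test_bad_units_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("# voxel_size_mm: 3\n# units: Gy/decay\ni,j,k,S_value\n0,0,0,1.0\n")
        with pytest.raises(ValueError, match="units"):
            load_kernel_csv(p)


class TestInterpolateKernel:
    def test_degenerate_equal_parents(self):
        k3 = _const_kernel(3.0, 2.5)
        k6 = _const_kernel(6.0, 2.5)
        out = interpolate_kernel(k3, k6, 4.5)
        np.testing.assert_allclose(out.values, k3.values)
        assert out.voxel_size == 4.5

    def test_clinical_voxel_size_linear_blend(self):
        k3 = _const_kernel(3.0, 1.0)
        k6 = _const_kernel(6.0, 4.0)
        out = interpolate_kernel(k3, k6, 4.664)
        assert out.s(0, 0, 0) == pytest.approx(1.0 + (1.664 / 3.0) * 3.0, abs=1e-6)

    def test_endpoints_identity(self):
        k3 = make_synthetic_kernel(3.0, extent=2)
        k6 = make_synthetic_kernel(6.0, extent=2)
        np.testing.assert_allclose(interpolate_kernel(k3, k6, 3.0).values, k3.values)
        np.testing.assert_allclose(interpolate_kernel(k3, k6, 6.0).values, k6.values)

    def test_betweenness(self):
        k3 = make_synthetic_kernel(3.0, extent=2)
        k6 = make_synthetic_kernel(6.0, extent=2)
        out = interpolate_kernel(k3, k6, 4.664)
        lo = np.minimum(k3.values, k6.values)
        hi = np.maximum(k3.values, k6.values)
        assert ((out.values >= lo - 1e-15) & (out.values <= hi + 1e-15)).all()

    def test_out_of_range_needs_flag(self):
        k3 = make_synthetic_kernel(3.0, extent=1)
        k6 = make_synthetic_kernel(6.0, extent=1)
        with pytest.raises(ValueError, match="extrapolate"):
            interpolate_kernel(k3, k6, 7.0)
        out = interpolate_kernel(k3, k6, 7.0, extrapolate=True)
        assert out.voxel_size == 7.0

    def test_distance_method_endpoint(self):
        k3 = make_synthetic_kernel(3.0, extent=2)
        k6 = make_synthetic_kernel(6.0, extent=2)
        out = interpolate_kernel(k3, k6, 3.0, method="distance")
        np.testing.assert_allclose(
            out.s(0, 0, 0), k3.s(0, 0, 0), rtol=1e-9
        )


class TestCumulatedActivity:
    def test_zero_activity(self):
        a = _activity(np.zeros((3, 3, 3)), units="MBq")
        assert not cumulated_activity(a).data.any()

    def test_permanent_implant_integral(self):
        a = _activity(np.ones((2, 2, 2)), units="MBq")
        out = cumulated_activity(a, half_life_h=64.05)
        assert out.units == "MBq_s"
        assert out.data[0, 0, 0] == pytest.approx(64.05 * 3600 / np.log(2), rel=1e-9)
        assert out.data[0, 0, 0] == pytest.approx(332_657, rel=1e-4)

    def test_linearity_in_half_life(self):
        a = _activity(np.ones((2, 2, 2)), units="MBq")
        np.testing.assert_allclose(
            cumulated_activity(a, 20.0).data * 2.0, cumulated_activity(a, 40.0).data
        )

    def test_units_enforced(self):
        with pytest.raises(UnitsError):
            cumulated_activity(_activity(np.ones((2, 2, 2)), units="cps"))


class TestDoseConvolve:
    def test_delta_kernel(self):
        k = SValueKernel(4.664, np.array([[[2.0]]]))
        a = _activity(np.zeros((4, 4, 4)))
        a.data[1, 2, 3] = 1.0
        d = dose_convolve(a, k)
        assert d.grid.data[1, 2, 3] == pytest.approx(2.0)
        assert d.grid.data.sum() == pytest.approx(2.0)

    def test_matches_brute_force_triple_loop(self, rng):
        a = _activity(rng.uniform(0, 5, (5, 5, 5)))
        kern = make_synthetic_kernel(4.664, extent=1)
        d = dose_convolve(a, kern, engine="direct")
        expected = np.zeros((5, 5, 5))
        for t in itertools.product(range(5), repeat=3):
            acc = 0.0
            for s in itertools.product(range(5), repeat=3):
                off = tuple(t[i] - s[i] for i in range(3))
                if all(abs(o) <= 1 for o in off):
                    acc += a.data[s] * kern.s(*off)
            expected[t] = acc
        np.testing.assert_allclose(d.grid.data, expected, atol=1e-10)

    def test_superposition(self):
        kern = make_synthetic_kernel(4.664, extent=2)
        a1 = _activity(np.zeros((8, 8, 8)))
        a1.data[2, 2, 2] = 1.0
        a2 = _activity(np.zeros((8, 8, 8)))
        a2.data[5, 5, 5] = 1.0
        both = _activity(a1.data + a2.data)
        np.testing.assert_allclose(
            dose_convolve(both, kern).grid.data,
            dose_convolve(a1, kern).grid.data + dose_convolve(a2, kern).grid.data,
            rtol=1e-12,
        )

    def test_engines_agree(self, rng):
        a = _activity(rng.uniform(0, 5, (12, 12, 12)))
        kern = make_synthetic_kernel(4.664, extent=2)
        d1 = dose_convolve(a, kern, engine="direct").grid.data
        d2 = dose_convolve(a, kern, engine="transform").grid.data
        np.testing.assert_allclose(d2, d1, rtol=1e-6, atol=1e-9)

    def test_energy_bookkeeping_for_interior_sources(self, rng):
        """Total dose x mass equals cumulated activity x kernel sum x mass."""
        kern = make_synthetic_kernel(4.664, extent=2)
        a = _activity(np.zeros((12, 12, 12)))
        a.data[3:9, 3:9, 3:9] = rng.uniform(0, 10, (6, 6, 6))
        d = dose_convolve(a, kern)
        assert d.grid.data.sum() == pytest.approx(
            a.data.sum() * kern.values.sum(), rel=1e-9
        )

    def test_spacing_mismatch_rejected(self, rng):
        a = _activity(rng.uniform(0, 1, (4, 4, 4)), spacing=6.0)
        with pytest.raises(ValueError, match="voxel"):
            dose_convolve(a, make_synthetic_kernel(4.664, extent=1))

    def test_units_enforced(self, rng):
        a = _activity(rng.uniform(0, 1, (4, 4, 4)), units="MBq")
        with pytest.raises(UnitsError):
            dose_convolve(a, make_synthetic_kernel(4.664, extent=1))


def _dose_map(data, spacing=4.664):
    return DoseMap(VoxelGrid(np.asarray(data, float), (spacing,) * 3, units="mGy"))


class TestCdvh:
    def test_uniform_dose_is_step(self):
        d = _dose_map(np.full((4, 4, 4), 5000.0))  # 5 Gy
        dvh = cdvh(d, VoiMask(np.ones((4, 4, 4))), n_bins=10)
        assert dvh.cumulative_fraction[0] == 1.0
        assert (dvh.cumulative_fraction == 1.0).all()  # all edges <= max = 5 Gy

    def test_two_voxel_enumeration(self):
        data = np.zeros((2, 1, 1))
        data[0], data[1] = 1000.0, 3000.0
        d = _dose_map(data)
        dvh = cdvh(d, VoiMask(np.ones((2, 1, 1))), n_bins=3)  # edges 0,1,2,3 Gy
        assert dvh.cumulative_fraction[2] == pytest.approx(0.5)

    def test_monotone_non_increasing(self, rng):
        d = _dose_map(rng.uniform(0, 9000, (8, 8, 8)))
        dvh = cdvh(d, VoiMask(rng.uniform(size=(8, 8, 8)) > 0.3), n_bins=64)
        assert (np.diff(dvh.cumulative_fraction) <= 1e-12).all()

    def test_area_equals_mean_dose(self, rng):
        d = _dose_map(rng.uniform(0, 40000, (10, 10, 10)))
        voi = VoiMask(rng.uniform(size=(10, 10, 10)) > 0.4)
        dvh = cdvh(d, voi, n_bins=512)
        mean_gy = d.grid.data[voi.data].mean() / 1000.0
        assert dvh.mean_dose_estimate() == pytest.approx(mean_gy, rel=0.01)

    def test_empty_voi_rejected(self, rng):
        d = _dose_map(rng.uniform(0, 1, (4, 4, 4)))
        with pytest.raises(ValueError):
            cdvh(d, VoiMask(np.zeros((4, 4, 4))))


class TestIsodose:
    def test_levels_and_nesting(self, rng):
        d = _dose_map(rng.uniform(0, 100, (8, 8, 8)))
        levels = isodose_levels(d, [80, 50, 20])
        m80 = levels[80.0]["mask"].data
        m50 = levels[50.0]["mask"].data
        m20 = levels[20.0]["mask"].data
        assert (m80 <= m50).all() and (m50 <= m20).all()

    def test_p100_is_argmax_and_p0_is_everything(self, rng):
        d = _dose_map(rng.uniform(1, 100, (6, 6, 6)))
        levels = isodose_levels(d, [100, 0])
        top = levels[100.0]["mask"].data
        assert top.sum() >= 1
        assert d.grid.data[top].min() == d.grid.data.max()
        assert levels[0.0]["mask"].data.all()

    def test_zero_dose_rejected(self):
        with pytest.raises(ValueError):
            isodose_levels(_dose_map(np.zeros((3, 3, 3))), [50])


class TestDoseVoiSummary:
    def test_uniform_tumor_dose(self):
        data = np.full((6, 6, 6), 2000.0)
        t = np.zeros((6, 6, 6), bool)
        t[:3] = True
        data[t] = 10_000.0  # 10 Gy
        out = dose_voi_summary(_dose_map(data), VoiMask(t, "tumor"), VoiMask(~t, "healthy_liver"))
        assert out["mean_tumor_Gy"] == pytest.approx(10.0)
        assert out["mean_healthy_Gy"] == pytest.approx(2.0)

    def test_self_dose_only_closed_form(self):
        """With a pure self-dose kernel, tumor mean = A_vox x S_self / 1000."""
        s_self = 0.7
        kern = SValueKernel(4.664, np.array([[[s_self]]]))
        a = _activity(np.zeros((6, 6, 6)))
        t = np.zeros((6, 6, 6), bool)
        t[2:4, 2:4, 2:4] = True
        a.data[t] = 123.0
        d = dose_convolve(a, kern)
        out = dose_voi_summary(d, VoiMask(t, "tumor"), VoiMask(~t, "healthy_liver"))
        assert out["mean_tumor_Gy"] == pytest.approx(123.0 * s_self / 1000.0, rel=1e-12)

    def test_overlapping_masks_rejected(self, rng):
        d = _dose_map(rng.uniform(0, 1, (4, 4, 4)))
        m = VoiMask(np.ones((4, 4, 4)), "tumor")
        with pytest.raises(ValueError, match="overlap"):
            dose_voi_summary(d, m, VoiMask(np.ones((4, 4, 4)), "healthy_liver"))


def test_dose_linearity_in_administered_activity(rng):
    """Doubling the activity map doubles every dose statistic."""
    kern = make_synthetic_kernel(4.664, extent=2)
    a = _activity(rng.uniform(0, 5, (10, 10, 10)))
    a2 = _activity(a.data * 2.0)
    d1 = dose_convolve(a, kern).grid.data
    d2 = dose_convolve(a2, kern).grid.data
    np.testing.assert_allclose(d2, 2.0 * d1, rtol=1e-12)
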