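import numpy as np
import pytest

from bonespect.grid import VoxelGrid
from bonespect.quantify import (AcquisitionMeta, CalibrationFactor, PairingError,
                                SUVPEAK_RADIUS_MM, cf_for_condition, compute_cf,
                                delineate_mtv, suv_map, suv_peak,
                                total_bone_uptake, quantify_lesions)
from oracles import flood_fill_26


def grid(data, spacing=(6.0, 6.0, 6.0), kind="count_density", meta=None):
    return VoxelGrid(np.asarray(data, dtype=float), spacing, kind, meta or {})


def cyl_meta(conc=5000.0, duration=720.0):
    return AcquisitionMeta(injected_bq=1.0, body_weight_g=1.0,
                           duration_s=duration, true_conc_bq_ml=conc)


class TestCalibrationFactor:
    def test_unit_cf_fixed_point(self):
        # density/duration numerically equal to the true concentration -> CF 1
        meta = cyl_meta(conc=5.0, duration=720.0)
        vol = grid(np.full((16, 16, 32), 5.0 * 720.0))
        cf = compute_cf(vol, meta, roi_radius_mm=20.0)
        assert cf.value_bq_per_cps == pytest.approx(1.0)

    def test_halving_density_doubles_cf(self):
        meta = cyl_meta()
        a = compute_cf(grid(np.full((16, 16, 32), 800.0)), meta)
        b = compute_cf(grid(np.full((16, 16, 32), 400.0)), meta)
        assert b.value_bq_per_cps == pytest.approx(2 * a.value_bq_per_cps)

    def test_slice_offset_outside_volume_rejected(self):
        vol = grid(np.ones((16, 16, 4)))            # 24 mm axial extent
        with pytest.raises(ValueError, match="outside"):
            compute_cf(vol, cyl_meta(), slice_offsets_cm=(-2, -1, 0, 1, 2))

    def test_bsac_conditions_map_to_uac_factor(self):
        table = {c: CalibrationFactor(v, c, (c,)) for c, v in
                 [("CTAC", 4148.7), ("UAC", 3098.1), ("AC_MINUS", 10299.3),
                  ("NC", 32667.6)]}
        table["UAC"] = CalibrationFactor(3098.1, "UAC",
                                         ("UAC", "BSAC_N", "BSAC_M"))
        assert cf_for_condition(table, "BSAC_N").value_bq_per_cps == 3098.1
        assert cf_for_condition(table, "BSAC_M").value_bq_per_cps == 3098.1
        assert cf_for_condition(table, "CTAC").value_bq_per_cps == 4148.7
        with pytest.raises(PairingError):
            cf_for_condition(table, "FBP")


class TestSuvMap:
    def test_hand_computed_example(self):
        # CF 4148.7 Bq/cps, 1000 count/cc, 720 s, 70 kg, 740 MBq -> 0.545
        cf = CalibrationFactor(4148.7, "CTAC", ("CTAC",))
        meta = AcquisitionMeta(7.40e8, 70_000.0, 720.0)
        vol = grid(np.full((2, 2, 2), 1000.0))
        suv = suv_map(vol, cf, meta)
        expect = 4148.7 * 1000.0 / 720.0 * 70_000.0 / 7.40e8
        assert suv.data[0, 0, 0] == pytest.approx(expect)
        assert expect == pytest.approx(0.545, abs=5e-4)

    def test_linearity_in_meta(self):
        cf = CalibrationFactor(1000.0, "CTAC", ("CTAC",))
        vol = grid(np.full((2, 2, 2), 500.0))
        base = suv_map(vol, cf, AcquisitionMeta(1e8, 60_000.0, 720.0)).data
        dbl_inj = suv_map(vol, cf, AcquisitionMeta(2e8, 60_000.0, 720.0)).data
        dbl_wt = suv_map(vol, cf, AcquisitionMeta(1e8, 120_000.0, 720.0)).data
        np.testing.assert_allclose(dbl_inj, base / 2)
        np.testing.assert_allclose(dbl_wt, base * 2)
        assert not suv_map(grid(np.zeros((2, 2, 2))), cf,
                           AcquisitionMeta(1e8, 60_000.0, 720.0)).data.any()

    def test_definitional_fixed_point_suv_one(self):
        # CF*density/duration = injected/weight -> SUV = 1 everywhere
        meta = AcquisitionMeta(7e8, 70_000.0, 720.0)
        density = (7e8 / 70_000.0) * 720.0 / 2000.0
        suv = suv_map(grid(np.full((2, 2, 2), density)),
                      CalibrationFactor(2000.0, "NC", ("NC",)), meta)
        np.testing.assert_allclose(suv.data, 1.0)

    def test_condition_pairing_guard(self):
        cf = CalibrationFactor(1.0, "UAC", ("UAC", "BSAC_N", "BSAC_M"))
        vol = grid(np.ones((2, 2, 2)), meta={"condition": "NC"})
        with pytest.raises(PairingError):
            suv_map(vol, cf, AcquisitionMeta(1e8, 7e4, 720.0))

    def test_decay_correction_optional(self):
        cf = CalibrationFactor(1000.0, "CTAC", ("CTAC",))
        meta = AcquisitionMeta(1e8, 7e4, 720.0, interval_s=6.0067 * 3600.0)
        vol = grid(np.ones((2, 2, 2)))
        plain = suv_map(vol, cf, meta).data
        decayed = suv_map(vol, cf, meta, decay_correct=True).data
        np.testing.assert_allclose(decayed, plain * 2.0, rtol=1e-9)


class TestDelineation:
    def test_isolated_hot_voxel_has_one_voxel_mtv(self):
        data = np.ones((11, 11, 11))
        data[5, 5, 5] = 10.0
        suv = grid(data, kind="suv")
        q = delineate_mtv(suv, (0.0, 0.0, 0.0), fractions=(0.5,))
        assert q.mtv_cc[0.5] == pytest.approx(suv.voxel_volume_cc)
        assert q.suv_max == 10.0

    def test_voxel_exactly_at_threshold_included(self):
        data = np.zeros((11, 11, 11))
        data[5, 5, 5] = 10.0
        data[5, 5, 6] = 5.0          # exactly 50 % of SUVmax
        q = delineate_mtv(grid(data, kind="suv"), (0.0, 0.0, 0.0),
                          fractions=(0.5,))
        assert q.mtv_cc[0.5] == pytest.approx(2 * 0.216)

    def test_only_the_seed_component_counts(self):
        data = np.zeros((21, 21, 5))
        data[4:7, 4:7, 2] = 8.0      # blob with the max
        data[5, 5, 2] = 10.0
        data[14:17, 14:17, 2] = 9.0  # disjoint hotter-than-threshold blob
        suv = grid(data, kind="suv")
        q = delineate_mtv(suv, (-30.0, -30.0, 0.0), fractions=(0.5,),
                          search_radius_mm=50.0)
        members = q.members[0.5]
        oracle = flood_fill_26(data >= 5.0, q.max_voxel)
        assert np.array_equal(members, oracle)
        assert members.sum() == 9

    def test_mtv_nested_in_threshold(self, rng):
        data = rng.random((15, 15, 9))
        data[7, 7, 4] = 3.0
        q = delineate_mtv(grid(data, kind="suv"), (0.0, 0.0, 0.0))
        assert q.mtv_cc[0.50] >= q.mtv_cc[0.55] >= q.mtv_cc[0.60]
        assert q.suv_mean[0.5] <= q.suv_max
        assert q.suv_peak <= q.suv_max

    def test_all_zero_region_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            delineate_mtv(grid(np.zeros((9, 9, 9)), kind="suv"),
                          (0.0, 0.0, 0.0))


class TestSuvPeak:
    def test_radius_is_one_cc_sphere(self):
        assert SUVPEAK_RADIUS_MM == pytest.approx(6.2035, abs=1e-4)

    def test_constant_region_returns_constant(self):
        suv = grid(np.full((11, 11, 11), 3.3), spacing=(2.0, 2.0, 2.0),
                   kind="suv")
        assert suv_peak(suv, (5, 5, 5)) == pytest.approx(3.3)

    def test_isolated_voxel_divided_by_sphere_membership(self):
        sp = 3.0
        data = np.zeros((15, 15, 15))
        data[7, 7, 7] = 20.0
        suv = grid(data, spacing=(sp,) * 3, kind="suv")
        # brute-force sphere membership count at this spacing
        offs = np.arange(-3, 4) * sp
        d2 = (offs[:, None, None] ** 2 + offs[None, :, None] ** 2 +
              offs[None, None, :] ** 2)
        n_sphere = int((d2 <= SUVPEAK_RADIUS_MM ** 2).sum())
        assert suv_peak(suv, (7, 7, 7)) == pytest.approx(20.0 / n_sphere)


class TestTotalBoneUptake:
    def _lesion(self, lid, mtv, mean, thr=0.5):
        from bonespect.quantify import LesionQuant
        q = LesionQuant(lid, "CTAC", suv_max=mean * 2, suv_peak=mean,
                        max_voxel=(0, 0, 0))
        q.mtv_cc[thr] = mtv
        q.suv_mean[thr] = mean
        return q

    def test_arithmetic(self):
        assert total_bone_uptake([self._lesion(0, 2.0, 5.0)], 0.5) == 10.0
        both = [self._lesion(0, 1.0, 3.0), self._lesion(1, 2.0, 4.0)]
        assert total_bone_uptake(both, 0.5) == 11.0
        assert total_bone_uptake([], 0.5) == 0.0

    def test_missing_threshold_rejected(self):
        with pytest.raises(ValueError):
            total_bone_uptake([self._lesion(0, 1.0, 1.0, thr=0.5)], 0.6)


def test_quantify_lesions_assigns_ids_and_condition():
    data = np.zeros((21, 21, 9))
    data[5, 5, 4] = 10.0
    data[15, 15, 4] = 8.0
    suv = grid(data, kind="suv")
    xs, ys, zs = suv.world_coords()
    seeds = [(xs[5], ys[5], zs[4]), (xs[15], ys[15], zs[4])]
    out = quantify_lesions(suv, seeds, condition="NC", search_radius_mm=20.0)
    assert [q.lesion_id for q in out] == [0, 1]
    assert {q.condition for q in out} == {"NC"}
    assert out[0].suv_max == 10.0 and out[1].suv_max == 8.0
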