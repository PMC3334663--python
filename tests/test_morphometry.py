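import numpy as np
import pytest

import osteoct as o

SP = 8.7
VOX = SP  # one-voxel tolerance for direct-3D thickness recovery


class TestBoneVolume:
    def test_all_bone_voi(self, full_voi):
        mask = o.BinaryVolume(np.ones((8, 8, 8), dtype=bool), SP)
        _, _, bvtv = o.bone_volume(mask, full_voi((8, 8, 8)))
        assert bvtv == 100.0

    def test_counting_oracle(self, full_voi):
        vox = np.zeros(8000, dtype=bool)
        vox[:1234] = True
        rng = np.random.default_rng(0)
        rng.shuffle(vox)
        mask = o.BinaryVolume(vox.reshape(20, 20, 20), SP)
        bv, tv, bvtv = o.bone_volume(mask, full_voi((20, 20, 20)))
        assert bvtv == pytest.approx(15.425)
        assert bv == pytest.approx(1234 * SP**3 / 1e9)

    def test_empty_voi_rejected(self):
        mask = o.BinaryVolume(np.ones((4, 4, 4), dtype=bool), SP)
        empty = o.VoiMask(np.zeros((4, 4, 4), dtype=bool), "total", SP)
        with pytest.raises(ValueError, match="empty"):
            o.bone_volume(mask, empty)


class TestLocalThickness:
    def test_solid_sphere(self):
        z, y, x = np.ogrid[-14:15, -14:15, -14:15]
        ball = z**2 + y**2 + x**2 <= 10**2
        tmap = o.local_thickness_map(ball, SP)
        # interior reads the inscribed-sphere diameter, within one voxel
        assert abs(tmap[ball].max() - 20 * SP) <= VOX
        center = tmap[14, 14, 14]
        assert abs(center - 20 * SP) <= VOX

    def test_slab_away_from_borders(self, slab_phantom, interior_voi):
        mask, truth = slab_phantom
        tmap = o.local_thickness_map(mask.voxels, SP)
        interior = interior_voi(mask.voxels.shape, 35).voxels & mask.voxels
        assert np.abs(tmap[interior] - truth.thickness_true).max() <= VOX

    def test_single_voxel_structure(self):
        vox = np.zeros((5, 5, 5), dtype=bool)
        vox[2, 2, 2] = True
        tmap = o.local_thickness_map(vox, SP)
        assert tmap[2, 2, 2] == pytest.approx(2 * SP)

    def test_thickness_bounded_by_inscribed_sphere(self, rod_phantom):
        from scipy import ndimage as ndi
        mask, _ = rod_phantom
        tmap = o.local_thickness_map(mask.voxels, SP)
        edt = ndi.distance_transform_edt(np.pad(mask.voxels, 1))[1:-1, 1:-1,
                                                                 1:-1]
        assert tmap.max() <= 2 * edt.max() * SP + VOX

    def test_background_domain_requires_voi(self, slab_phantom):
        mask, _ = slab_phantom
        with pytest.raises(ValueError, match="VOI"):
            o.local_thickness(mask, "background")


class TestMeanThickness:
    def test_uniform_map(self):
        vox = np.ones((4, 4, 4), dtype=bool)
        tmap = o.ThicknessMap(np.full((4, 4, 4), 87.0), vox, "bone", SP)
        assert o.mean_thickness(tmap) == 87.0

    def test_slab_phantom_mean(self, slab_phantom, interior_voi):
        mask, truth = slab_phantom
        tmap = o.local_thickness(mask, "bone")
        interior = interior_voi(mask.voxels.shape, 35).voxels
        got = o.mean_thickness(tmap, interior)
        assert abs(got - truth.thickness_true) <= VOX

    def test_two_slab_mixture(self):
        # equal volumes of 10- and 20-voxel slabs -> mean 15 voxels +- 1
        vox = np.zeros((90, 80, 80), dtype=bool)
        vox[10:20] = True   # 10-voxel slab
        vox[35:55] = True   # 20-voxel slab
        vox[70:80] = True   # second 10-voxel slab (equal total volumes)
        tmap = o.local_thickness_map(vox, SP)
        sel = vox.copy()
        sel[:, :30, :] = sel[:, -30:, :] = False
        sel[:, :, :30] = sel[:, :, -30:] = False
        assert abs(tmap[sel].mean() - 15 * SP) <= VOX

    def test_empty_domain_rejected(self):
        tmap = o.ThicknessMap(np.zeros((3, 3, 3)),
                              np.zeros((3, 3, 3), dtype=bool), "bone", SP)
        with pytest.raises(ValueError, match="empty"):
            o.mean_thickness(tmap)


class TestTrabecularNumber:
    def test_printed_style_values(self):
        # BV/TV 16.8 %, Tb.Th 94 um -> 1.8 /mm at one decimal
        assert round(o.trabecular_number(16.8, 94), 1) == 1.8

    def test_closed_form(self):
        assert o.trabecular_number(50.0, 100.0) == pytest.approx(5.0)

    def test_zero_bvtv(self):
        assert o.trabecular_number(0.0, 94.0) == 0.0

    def test_zero_thickness_rejected(self):
        with pytest.raises(ValueError):
            o.trabecular_number(10.0, 0.0)


class TestComputeMorphometry:
    def make_vois(self, shape, margin=6):
        med = np.zeros(shape, dtype=bool)
        lat = np.zeros(shape, dtype=bool)
        half = shape[2] // 2
        med[:, margin:-margin, margin:half] = True
        lat[:, margin:-margin, half:-margin] = True
        return {"medial": o.VoiMask(med, "medial", SP),
                "lateral": o.VoiMask(lat, "lateral", SP)}

    def test_total_bv_is_sum_of_parts(self, slab_phantom):
        mask, _ = slab_phantom
        res = o.compute_morphometry(mask, self.make_vois(mask.voxels.shape))
        assert res["total"].bv == pytest.approx(
            res["medial"].bv + res["lateral"].bv, abs=1e-15)

    def test_symmetric_compartments_identical(self, slab_phantom):
        mask, _ = slab_phantom
        res = o.compute_morphometry(mask, self.make_vois(mask.voxels.shape))
        assert res["medial"].bvtv == pytest.approx(res["lateral"].bvtv)
        assert res["medial"].tbth == pytest.approx(res["lateral"].tbth)

    def test_grf_phantom_bvtv(self):
        mask, truth = o.make_grf_phantom(0.20, 26.1, SP, (64, 64, 64), seed=7)
        med = np.zeros((64, 64, 64), dtype=bool)
        lat = np.zeros((64, 64, 64), dtype=bool)
        med[:, :, :32], lat[:, :, 32:] = True, True
        vois = {"medial": o.VoiMask(med, "medial", SP),
                "lateral": o.VoiMask(lat, "lateral", SP)}
        res = o.compute_morphometry(mask, vois)
        assert abs(res["total"].bvtv - 20.0) < 0.5

    def test_tbn_consistent_with_invariant(self, slab_phantom):
        mask, _ = slab_phantom
        res = o.compute_morphometry(mask, self.make_vois(mask.voxels.shape))
        m = res["total"]
        assert m.tbn == pytest.approx((m.bvtv / 100) / (m.tbth / 1000))

    def test_missing_compartment_rejected(self, slab_phantom, full_voi):
        mask, _ = slab_phantom
        with pytest.raises(ValueError, match="lateral"):
            o.compute_morphometry(
                mask, {"medial": full_voi(mask.voxels.shape)})


class TestScaleEquivariance:
    def test_doubling_spacing(self, interior_voi):
        mask1, _ = o.make_slab_phantom(104.4, 261.0, SP, (130, 64, 64))
        mask2 = o.BinaryVolume(mask1.voxels, 2 * SP)
        voi = interior_voi(mask1.voxels.shape, 20)
        voi2 = o.VoiMask(voi.voxels, "total", 2 * SP)
        t1 = o.local_thickness_map(mask1.voxels, SP)
        t2 = o.local_thickness_map(mask2.voxels, 2 * SP)
        assert np.allclose(t2, 2 * t1)
        bv1 = o.bone_volume(mask1, voi)
        bv2 = o.bone_volume(mask2, voi2)
        assert bv2[0] == pytest.approx(8 * bv1[0])
        assert bv2[2] == pytest.approx(bv1[2])  # BV/TV unchanged


class TestComplementarity:
    def test_tbsp_equals_complement_tbth(self, slab_phantom, interior_voi):
        """Tb.Sp of a mask is Tb.Th of its complement within the VOI."""
        mask, truth = slab_phantom
        voi = interior_voi(mask.voxels.shape, 35)
        tbsp_map = o.local_thickness(mask, "background", voi)
        complement = o.BinaryVolume(voi.voxels & ~mask.voxels, SP)
        tbth_of_complement = o.local_thickness(complement, "bone")
        sel = complement.voxels & ~_shell(voi.voxels)
        assert np.allclose(tbsp_map.values[sel],
                           tbth_of_complement.values[sel])

    def test_resolution_refinement_monotone(self):
        """Halving the voxel size does not worsen thickness recovery."""
        errs = []
        for spacing, dims in ((17.4, (66, 48, 48)), (8.7, (130, 96, 96))):
            mask, truth = o.make_slab_phantom(104.4, 261.0, spacing, dims)
            tmap = o.local_thickness_map(mask.voxels, spacing)
            m = int(35 * 8.7 / spacing)
            sel = mask.voxels.copy()
            sel[:, :m] = sel[:, -m:] = sel[:, :, :m] = sel[:, :, -m:] = False
            errs.append(abs(tmap[sel].mean() - truth.thickness_true))
        assert errs[1] <= errs[0] + 1e-9


def _shell(voi):
    from scipy import ndimage as ndi
    return voi & ~ndi.binary_erosion(voi)
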