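"""Homogenisation: rigid registration recovery and in-plane downsampling."""

import numpy as np
import pytest

from conftest import SMALL_GEOM, small_spec
from ldq.fat_fraction import ff_map
from ldq.geometry import Geometry
from ldq.phantom import generate_phantom
from ldq.preprocess import downsample_inplane, homogenise
from ldq.registration import RegistrationParams, ncc, rigid_register, RegistrationError
from ldq.volumes import DixonVolume, LabelMap

FAST_PARAMS = RegistrationParams(iterations=100, samples=500_000, pyramid=(2, 1))


class TestDownsample:
    def test_paper_voxel_size_and_count(self, rng):
        geom = Geometry((8, 8, 4), (0.47, 0.47, 1.95))
        grid = rng.random((8, 8, 4))
        out, g2 = downsample_inplane(grid, geom, 2, "image")
        assert g2.spacing == pytest.approx((0.94, 0.94, 1.95))
        assert grid.size / out.size == 4.0  # four-fold memory reduction
        assert g2.shape == (4, 4, 4)

    def test_constant_grid_stays_constant(self):
        geom = Geometry((4, 4, 2), (1, 1, 1))
        out, _ = downsample_inplane(np.full((4, 4, 2), 7.5), geom, 2, "image")
        np.testing.assert_allclose(out, 7.5)

    def test_block_average(self):
        geom = Geometry((2, 2, 1), (1, 1, 1))
        grid = np.array([[[1.0], [2.0]], [[3.0], [6.0]]])
        out, _ = downsample_inplane(grid, geom, 2, "image")
        assert out[0, 0, 0] == pytest.approx(3.0)

    def test_label_mode_majority_and_lowest_code_tie_break(self):
        geom = Geometry((2, 2, 1), (1, 1, 1))
        tie = np.array([[[1], [1]], [[2], [2]]], dtype=np.int16)
        out, _ = downsample_inplane(tie, geom, 2, "label")
        assert out[0, 0, 0] == 1  # tie -> lowest code
        maj = np.array([[[2], [2]], [[2], [5]]], dtype=np.int16)
        out, _ = downsample_inplane(maj, geom, 2, "label")
        assert out[0, 0, 0] == 2

    def test_odd_shape_cropped(self, rng):
        geom = Geometry((5, 5, 2), (1, 1, 1))
        out, g2 = downsample_inplane(rng.random((5, 5, 2)), geom, 2, "image")
        assert out.shape == (2, 2, 2)
        assert g2.shape == (2, 2, 2)

    def test_invalid_factor(self):
        geom = Geometry((4, 4, 2), (1, 1, 1))
        with pytest.raises(ValueError):
            downsample_inplane(np.zeros((4, 4, 2)), geom, 0)

    def test_ff_commutes_with_downsampling_on_block_constant_grids(self):
        # piecewise-constant on 2x2-aligned blocks: FF(avg) == avg(FF) exactly
        geom = Geometry((4, 4, 2), (1, 1, 1))
        water = np.zeros((4, 4, 2), dtype=np.float32)
        fat = np.zeros((4, 4, 2), dtype=np.float32)
        water[:2], fat[:2] = 0.8, 0.2
        water[2:], fat[2:] = 0.5, 0.5
        vol = DixonVolume(water + fat, water, fat, geom)
        ff_then_down, _ = downsample_inplane(ff_map(vol).ff, geom, 2, "image")
        w2, g2 = downsample_inplane(water, geom, 2, "image")
        f2, _ = downsample_inplane(fat, geom, 2, "image")
        down_then_ff = ff_map(DixonVolume(w2 + f2, w2, f2, g2)).ff
        np.testing.assert_allclose(ff_then_down, down_then_ff, atol=1e-6)


class TestRigidRegistration:
    def test_identity_recovery(self, clean_phantom):
        vol = clean_phantom[0]
        t = rigid_register(vol, vol, FAST_PARAMS)
        assert max(abs(a) for a in t.rotation_deg) < 0.1
        assert max(abs(v) for v in t.translation_mm) < 0.1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_known_translation_recovery(self, seed):
        spec = small_spec(noise_sd=0.0, deformation_mm=0.0, seed=seed)
        fixed, _, _ = generate_phantom(spec)
        # shift by +4 mm in x = 1 voxel at 4 mm spacing (exact under roll)
        moved = DixonVolume(
            np.roll(fixed.in_phase, 1, axis=0),
            np.roll(fixed.water, 1, axis=0),
            np.roll(fixed.fat, 1, axis=0),
            fixed.geometry,
            "moved",
        )
        t = rigid_register(moved, fixed, FAST_PARAMS)
        # resampling convention: transform maps fixed points into moving space
        assert t.translation_mm[0] == pytest.approx(4.0, abs=0.5)
        assert abs(t.translation_mm[1]) < 0.5

    @pytest.mark.parametrize("angle", [5.0])
    def test_known_rotation_recovery(self, angle):
        # default (finer) grid: the rotated "ground truth" image is itself
        # interpolated, so recovery accuracy tracks voxel size
        from scipy import ndimage
        from ldq.phantom import PhantomSpec

        spec = PhantomSpec(noise_sd=0.0, deformation_mm=0.0, seed=3)
        fixed, _, _ = generate_phantom(spec)
        rot = lambda g: np.clip(ndimage.rotate(g, angle, axes=(0, 1), reshape=False, order=1), 0, None)
        moved = DixonVolume(rot(fixed.in_phase), rot(fixed.water), rot(fixed.fat), fixed.geometry, "rot")
        t = rigid_register(moved, fixed, FAST_PARAMS)
        assert abs(abs(t.rotation_deg[2]) - angle) < 0.5

    def test_transform_inverse_composes_to_identity(self):
        from ldq.registration import RigidTransform

        t = RigidTransform((3.0, -2.0, 5.0), (4.0, -1.0, 2.0), (10.0, 10.0, 10.0))
        inv = t.inverse()
        comp = t.to_sitk()
        pt = (1.0, 2.0, 3.0)
        roundtrip = inv.to_sitk().TransformPoint(comp.TransformPoint(pt))
        assert np.allclose(roundtrip, pt, atol=1e-6)

    def test_non_overlapping_volumes_rejected(self, clean_phantom):
        vol = clean_phantom[0]
        far = Geometry(vol.geometry.shape, vol.geometry.spacing, origin=(10_000.0, 0.0, 0.0))
        moved = DixonVolume(vol.in_phase, vol.water, vol.fat, far, "far")
        with pytest.raises(RegistrationError, match="overlap"):
            rigid_register(moved, vol, FAST_PARAMS)


class TestHomogenise:
    def test_single_volume_is_downsampled_copy(self, clean_phantom):
        vol, lmap, _, _ = clean_phantom
        vols, labels, geom = homogenise([vol], [lmap], factor=2)
        assert geom.shape == (16, 16, 16)
        ref, g2 = downsample_inplane(vol.in_phase, vol.geometry, 2, "image")
        np.testing.assert_allclose(vols[0].in_phase, ref, atol=1e-6)

    def test_shifted_copy_realigned(self):
        spec = small_spec(noise_sd=0.0, deformation_mm=0.0, seed=8, subject_id="a")
        ref, lmap, _ = generate_phantom(spec)
        shifted = DixonVolume(
            np.roll(ref.in_phase, 1, axis=0),
            np.roll(ref.water, 1, axis=0),
            np.roll(ref.fat, 1, axis=0),
            ref.geometry,
            "b",
        )
        vols, _, _ = homogenise([ref, shifted], None, reference_index=0, factor=1, params=FAST_PARAMS)
        rng_range = ref.in_phase.max() - ref.in_phase.min()
        diff = np.abs(vols[1].in_phase - ref.in_phase).mean()
        assert diff < 0.02 * rng_range

    def test_label_counts_preserved_under_downsampling(self):
        # finer default grid so the smallest muscle has enough voxels for
        # the count comparison to be meaningful
        from ldq.phantom import PhantomSpec

        vol, lmap, _ = generate_phantom(PhantomSpec(noise_sd=0.0, deformation_mm=0.0, seed=2))
        _, labels, _ = homogenise([vol], [lmap], factor=2)
        for code in lmap.codes:
            before = int((lmap.labels == code).sum())
            after = int((labels[0].labels == code).sum())
            assert after * 4 == pytest.approx(before, rel=0.05)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            homogenise([], None)
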