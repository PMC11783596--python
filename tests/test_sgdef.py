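import numpy as np
import pytest

from sgdefaug.core import ImageGeometry, structures_to_labelmap
from sgdefaug.dvf import warp
from sgdefaug.sgdef import (
    SgDefParams,
    StructureTransform,
    build_structure_dvf,
    build_structure_pullback,
    expand_dataset,
    mask_centroid_mm,
    mask_extent_mm,
    sample_structure_transform,
    sgdef_augment,
)


@pytest.fixture
def box_mask():
    geom = ImageGeometry((48, 48, 48), (2.0, 2.0, 2.0), (-47.0, -47.0, -47.0))
    mask = np.zeros(geom.size, dtype=bool)
    mask[16:32, 16:32, 16:32] = True
    return geom, mask


class TestSampleStructureTransform:
    def test_zero_limits_give_identity_transform(self, box_mask, rng):
        geom, mask = box_mask
        params = SgDefParams(displacement_limit_mm=0, scale_limit_mm=0)
        t = sample_structure_transform(mask, geom, params, rng)
        assert t.translation == (0.0, 0.0, 0.0)
        assert t.scale == (1.0, 1.0, 1.0)

    def test_translation_components_within_limit(self, box_mask, rng):
        geom, mask = box_mask
        params = SgDefParams()
        draws = np.array(
            [sample_structure_transform(mask, geom, params, rng).translation
             for _ in range(500)]
        )
        assert np.abs(draws).max() <= 40.0

    def test_scale_bounds_for_60mm_extent(self, rng):
        # 30 voxels at 2 mm = 60 mm extent: delta in [-30, 40], scale in [1/2, 5/3]
        geom = ImageGeometry((64, 64, 64), (2.0, 2.0, 2.0))
        mask = np.zeros(geom.size, dtype=bool)
        mask[10:40, 10:40, 10:40] = True
        np.testing.assert_allclose(mask_extent_mm(mask, geom), 60.0)
        params = SgDefParams()
        scales = np.array(
            [sample_structure_transform(mask, geom, params, rng).scale
             for _ in range(2000)]
        )
        assert scales.min() >= 0.5 - 1e-12
        assert scales.max() <= 5.0 / 3.0 + 1e-12
        # both halves of the support are visited
        assert scales.min() < 0.6 and scales.max() > 1.5

    def test_empty_mask_rejected(self, rng):
        geom = ImageGeometry((8, 8, 8))
        with pytest.raises(ValueError, match="empty"):
            sample_structure_transform(
                np.zeros(geom.size, bool), geom, SgDefParams(), rng
            )

    def test_isotropic_scaling_uses_one_factor(self, box_mask, rng):
        geom, mask = box_mask
        params = SgDefParams(isotropic_scaling=True)
        t = sample_structure_transform(mask, geom, params, rng)
        assert t.scale[0] == t.scale[1] == t.scale[2]


class TestBuildStructureField:
    def test_identity_transform_gives_zero_field(self, box_mask):
        geom, mask = box_mask
        t = StructureTransform("s", (0, 0, 0), (1, 1, 1), tuple(mask_centroid_mm(mask, geom)))
        assert not build_structure_dvf(mask, t, 5.0, geom).vectors.any()
        assert not build_structure_pullback(mask, t, 5.0, geom).vectors.any()

    def test_translation_vector_at_centroid(self, box_mask):
        # organ much larger than 3 sigma: smoothed forward vector at the
        # centroid equals the drawn translation within 1%
        geom, mask = box_mask
        c = mask_centroid_mm(mask, geom)
        t = StructureTransform("s", (8.0, -6.0, 4.0), (1, 1, 1), tuple(c))
        fld = build_structure_dvf(mask, t, 5.0, geom)
        centre_idx = tuple(np.round(geom.world_to_index(c)).astype(int))
        v = fld.vectors[centre_idx]
        assert np.linalg.norm(v - np.array(t.translation)) < 0.01 * np.linalg.norm(t.translation)

    def test_smoothing_never_exceeds_unsmoothed_max_norm(self, box_mask, rng):
        geom, mask = box_mask
        c = mask_centroid_mm(mask, geom)
        for _ in range(10):
            t = StructureTransform(
                "s", tuple(rng.uniform(-40, 40, 3)), tuple(rng.uniform(0.6, 1.6, 3)), tuple(c)
            )
            raw = build_structure_dvf(mask, t, 5.0, geom, smooth=False)
            smoothed = build_structure_dvf(mask, t, 5.0, geom)
            assert smoothed.max_norm_mm() <= raw.max_norm_mm() + 1e-9


class TestSgdefAugment:
    def test_zero_limits_reproduce_input_bit_exactly(self, phantom, rng):
        img, ss = phantom
        params = SgDefParams(displacement_limit_mm=0, scale_limit_mm=0)
        out_img, out_ss, record = sgdef_augment(img, ss, params, rng)
        np.testing.assert_array_equal(out_img.values, img.values)
        for name in ss.names:
            np.testing.assert_array_equal(out_ss[name], ss[name])
        assert len(record.steps) == 8

    def test_record_lists_a_permutation_of_all_organs(self, phantom, rng):
        img, ss = phantom
        _, _, record = sgdef_augment(img, ss, SgDefParams(), rng)
        assert sorted(s.structure for s in record.steps) == sorted(ss.names)

    def test_output_structures_disjoint(self, phantom):
        img, ss = phantom
        for seed in (0, 1):
            _, out_ss, _ = sgdef_augment(
                img, ss, SgDefParams(), np.random.default_rng(seed)
            )
            assert out_ss.is_disjoint()

    def test_translation_recovery(self, phantom, phantom_labelmap):
        # forced pure translation: output centroid shift matches the drawn
        # vector within max(1 voxel, 5 % of |t|)
        _, ss = phantom
        geom = ss.geometry
        lv = phantom_labelmap
        mask = ss["left_kidney"]
        k = list(ss.names).index("left_kidney") + 1
        c0 = mask_centroid_mm(mask, geom)
        g = np.random.default_rng(99)
        for mag in (10.0, 25.0):
            v = g.normal(size=3)
            v *= mag / np.linalg.norm(v)
            t = StructureTransform("left_kidney", tuple(v), (1, 1, 1), tuple(c0))
            fld = build_structure_pullback(mask, t, 5.0, geom)
            out = warp(lv, fld).labels == k
            err = np.linalg.norm(mask_centroid_mm(out, geom) - c0 - v)
            assert err <= max(max(geom.spacing), 0.05 * mag)

    def test_scaling_recovery(self, phantom, phantom_labelmap):
        # forced pure scaling: voxel-count ratio tracks det(S) within 10 %
        _, ss = phantom
        geom = ss.geometry
        mask = ss["stomach"]
        k = list(ss.names).index("stomach") + 1
        c0 = mask_centroid_mm(mask, geom)
        for det in (0.7, 1.4):
            s = det ** (1 / 3)
            t = StructureTransform("stomach", (0, 0, 0), (s, s, s), tuple(c0))
            out = warp(phantom_labelmap, build_structure_pullback(mask, t, 5.0, geom)).labels == k
            ratio = out.sum() / mask.sum()
            assert abs(ratio - det) <= 0.1 * det


class TestExpandDataset:
    def test_factor_one_returns_originals_only(self, phantom):
        out, records = expand_dataset([phantom], SgDefParams(expansion_factor=1))
        assert len(out) == 1
        assert records == [None]

    def test_counts_and_determinism(self, phantom):
        img, ss = phantom
        params = SgDefParams(expansion_factor=3, seed=11)
        out1, rec1 = expand_dataset([(img, ss), (img, ss)], params)
        out2, _ = expand_dataset([(img, ss), (img, ss)], params)
        assert len(out1) == 6
        for (a_img, a_ss), (b_img, b_ss) in zip(out1, out2):
            np.testing.assert_array_equal(a_img.values, b_img.values)
            for n in a_ss.names:
                np.testing.assert_array_equal(a_ss[n], b_ss[n])

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            expand_dataset([], SgDefParams())
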