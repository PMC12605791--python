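import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hsdetect as h
from hsdetect.atlas import SubfieldAtlas
from hsdetect.io import ImagePair


def _pair_from(intensity, labels, cortex=frozenset({3})):
    aff = np.eye(4)
    return ImagePair(np.asarray(intensity, float), aff,
                     np.asarray(labels, np.int32), aff.copy(),
                     cortex, voxel_aligned=True)


class TestCortexStats:
    def test_direct_arithmetic(self):
        labels = np.zeros((3, 3, 3), np.int32)
        labels[0, 0, :3] = 3
        intensity = np.zeros((3, 3, 3))
        intensity[0, 0, :3] = [8.0, 10.0, 12.0]
        mu, sigma = h.cortex_stats(_pair_from(intensity, labels))
        assert mu == pytest.approx(10.0)
        assert sigma == pytest.approx(2.0)  # sample SD convention

    def test_constant_cortex_is_degenerate(self):
        labels = np.zeros((3, 3, 3), np.int32)
        labels[0] = 3
        intensity = np.full((3, 3, 3), 10.0)
        with pytest.raises(h.DegenerateDataError):
            h.cortex_stats(_pair_from(intensity, labels))

    def test_mask_locality(self):
        labels = np.zeros((4, 4, 4), np.int32)
        labels[0] = 3
        rng = np.random.default_rng(0)
        intensity = rng.normal(100, 10, (4, 4, 4))
        base = h.cortex_stats(_pair_from(intensity, labels))
        intensity2 = intensity.copy()
        intensity2[labels != 3] += 500.0
        assert h.cortex_stats(_pair_from(intensity2, labels)) == base


class TestVoxelZscores:
    def test_matches_elementwise_oracle(self, phantom_pair):
        atlas = SubfieldAtlas.default()
        mu, sigma = h.cortex_stats(phantom_pair)
        z = h.voxel_zscores(phantom_pair, mu, sigma, "CA1-head", "left", atlas)
        code = atlas.label_map[("CA1-head", "left")]
        vals = phantom_pair.intensity[phantom_pair.labels == code]
        assert np.allclose(np.sort(z), np.sort((vals - mu) / sigma))
        # trivial anchors
        assert (0.0 - mu + mu) / sigma == 0.0
        assert ((mu + 2 * sigma) - mu) / sigma == pytest.approx(2.0)

    def test_absent_subfield_is_schema_error(self, phantom_pair):
        atlas = SubfieldAtlas.default()
        mu, sigma = h.cortex_stats(phantom_pair)
        missing = ImagePair(phantom_pair.intensity,
                            phantom_pair.intensity_affine,
                            np.where(phantom_pair.labels ==
                                     atlas.label_map[("CA1-head", "left")],
                                     0, phantom_pair.labels),
                            phantom_pair.labels_affine,
                            phantom_pair.cortex_labels, voxel_aligned=True)
        with pytest.raises(h.SchemaError, match="CA1-head"):
            h.voxel_zscores(missing, mu, sigma, "CA1-head", "left", atlas)


class TestRelativeZscore:
    @pytest.mark.parametrize("z,expected", [
        (np.full(10, 2.0), 2.0),          # sum 2N / N
        (np.full(10, 0.5), 0.0),          # none exceed threshold
        (np.array([3.0] * 5 + [0.0] * 5), 1.5),
    ])
    def test_known_values(self, z, expected):
        assert h.relative_zscore(z) == pytest.approx(expected)

    def test_empty_region_rejected(self):
        with pytest.raises(h.ValidationError):
            h.relative_zscore(np.array([]))

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=50),
           st.integers(0, 49), st.floats(0.0, 5.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_single_voxel(self, zs, idx, bump):
        z = np.asarray(zs)
        before = h.relative_zscore(z)
        z2 = z.copy()
        z2[idx % z.size] += bump
        assert h.relative_zscore(z2) >= before - 1e-12

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=50),
           st.floats(0.0, 3.0), st.floats(0.01, 2.0))
    @settings(max_examples=100, deadline=None)
    def test_threshold_sweep_monotone(self, zs, t1, dt):
        z = np.asarray(zs)
        assert h.relative_zscore(z, t1) >= h.relative_zscore(z, t1 + dt) - 1e-12


class TestLrFlairRatio:
    def test_conventions(self):
        assert h.lr_flair_ratio(0.3, 0.3) == 1.0
        assert h.lr_flair_ratio(0.0, 0.0) == 1.0
        assert h.lr_flair_ratio(0.4, 0.2) == pytest.approx(2.0)
        assert h.lr_flair_ratio(0.4, 0.0) == 10.0  # capped

    def test_reciprocal_identity_when_both_positive(self, phantom_pair):
        block = h.compute_flair_block(phantom_pair)
        for sf in h.INCLUDED_SUBFIELDS:
            l, r = block.rel_z[(sf, "left")], block.rel_z[(sf, "right")]
            if l > 0 and r > 0:
                prod = block.lr_ratio[(sf, "left")] * block.lr_ratio[(sf, "right")]
                assert prod == pytest.approx(1.0, abs=1e-12)


class TestResampling:
    def test_constant_intensity_stays_constant(self, phantom_pair):
        const = ImagePair(np.full_like(phantom_pair.intensity, 7.0),
                          phantom_pair.intensity_affine,
                          phantom_pair.labels, phantom_pair.labels_affine,
                          phantom_pair.cortex_labels, voxel_aligned=True)
        out = h.resample_to_subfield_space(const, target_resolution=0.5)
        assert np.allclose(out.intensity, 7.0)

    def test_upsampling_scales_label_counts(self):
        labels = np.zeros((16, 16, 16), np.int32)
        labels[2, 2, 2] = 3  # a cortex voxel so validate() passes downstream
        labels[6:10, 6:10, 6:10] = 237   # 4^3 box
        labels[10:12, 6:10, 6:10] = 239  # 2x4x4 box
        intensity = np.zeros((16, 16, 16))
        pair = _pair_from(intensity, labels)
        out = h.resample_to_subfield_space(pair, target_resolution=0.5)
        n1 = int((out.labels == 237).sum())
        n2 = int((out.labels == 239).sum())
        # ~8x the voxel count, boundaries within one target voxel
        assert 6 ** 3 <= n1 <= 10 ** 3       # ~8 x 64 = 512
        assert 3 * 7 * 7 <= n2 <= 5 * 9 * 9  # ~4 x 8 x 8 = 256
        assert out.voxel_aligned

    def test_empty_subfield_bbox_rejected(self):
        labels = np.zeros((8, 8, 8), np.int32)
        labels[0] = 3  # cortex only
        with pytest.raises(h.ValidationError):
            h.resample_to_subfield_space(_pair_from(np.zeros((8, 8, 8)), labels))


class TestAffineIntensityInvariance:
    def test_linear_intensity_map_leaves_features(self, phantom_pair):
        base = h.compute_flair_block(phantom_pair)
        mapped = ImagePair(3.0 * phantom_pair.intensity + 40.0,
                           phantom_pair.intensity_affine,
                           phantom_pair.labels, phantom_pair.labels_affine,
                           phantom_pair.cortex_labels, voxel_aligned=True)
        out = h.compute_flair_block(mapped)
        assert out.cortex_mu == pytest.approx(3 * base.cortex_mu + 40)
        for k in base.rel_z:
            assert out.rel_z[k] == pytest.approx(base.rel_z[k], abs=1e-8)
            assert out.lr_ratio[k] == pytest.approx(base.lr_ratio[k], abs=1e-6)


def test_compute_flair_block_requires_alignment(phantom_pair):
    unaligned = ImagePair(phantom_pair.intensity,
                          phantom_pair.intensity_affine,
                          phantom_pair.labels, phantom_pair.labels_affine,
                          phantom_pair.cortex_labels, voxel_aligned=False)
    with pytest.raises(h.ValidationError):
        h.compute_flair_block(unaligned)
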