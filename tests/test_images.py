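"""Image I/O, smoothing and regional extraction."""

import numpy as np
import pandas as pd
import pytest

from morphnet import images
from morphnet.images import (AtlasParcellation, GMMap, extract_regional_samples,
                             load_gm_map, region_mean_table, resample_atlas_to,
                             save_gm_map, smooth_gm_map)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _toy_atlas(shape=(6, 6, 6)):
    labels = np.zeros(shape, dtype=np.int32)
    labels.ravel()[:5] = 1
    labels.ravel()[10:17] = 2
    regions = pd.DataFrame({"region_id": [1, 2], "region_name": ["a", "b"]})
    return AtlasParcellation(labels=labels, regions=regions, affine=np.eye(4))


class TestGMMapIO:
    def test_write_then_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, size=(8, 9, 10))
        gm = GMMap("s1", vals, np.diag([2.0, 2.0, 2.0, 1.0]))
        p = tmp_path / "s1.nii.gz"
        save_gm_map(gm, p)
        back = load_gm_map(p, subject_id="s1")
        np.testing.assert_array_equal(back.values, vals)
        np.testing.assert_allclose(back.affine, gm.affine)

    def test_negative_voxels_clipped_and_counted(self, tmp_path, caplog):
        import nibabel as nib
        vals = np.ones((4, 4, 4))
        vals[0, 0, 0] = vals[1, 1, 1] = vals[2, 2, 2] = -0.5
        nib.save(nib.Nifti1Image(vals, np.eye(4)), str(tmp_path / "neg.nii"))
        with caplog.at_level("WARNING"):
            gm = load_gm_map(tmp_path / "neg.nii")
        assert np.all(gm.values >= 0)
        assert "3" in caplog.text

    def test_4d_input_rejected(self, tmp_path):
        import nibabel as nib
        nib.save(nib.Nifti1Image(np.ones((4, 4, 4, 2)), np.eye(4)),
                 str(tmp_path / "4d.nii"))
        with pytest.raises(ValueError, match="3D"):
            load_gm_map(tmp_path / "4d.nii")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_gm_map(tmp_path / "absent.nii")

    def test_nonfinite_rejected_with_count(self, tmp_path):
        import nibabel as nib
        vals = np.ones((4, 4, 4))
        vals[0, 0, :2] = np.nan
        nib.save(nib.Nifti1Image(vals, np.eye(4)), str(tmp_path / "nan.nii"))
        with pytest.raises(ValueError, match="2 non-finite"):
            load_gm_map(tmp_path / "nan.nii")


class TestSmoothing:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(1)
        gm = GMMap("s", rng.uniform(0, 1, (10, 10, 10)), np.eye(4))
        out = smooth_gm_map(gm, 0.0)
        np.testing.assert_array_equal(out.values, gm.values)

    def test_impulse_matches_sampled_gaussian(self):
        """A unit impulse smoothed at 8 mm on 2 mm voxels reproduces the
        closed-form 3D Gaussian with sigma = 8/2.3548/2 voxels."""
        shape = (33, 33, 33)
        vals = np.zeros(shape)
        vals[16, 16, 16] = 1.0
        gm = GMMap("s", vals, np.diag([2.0, 2.0, 2.0, 1.0]))
        out = smooth_gm_map(gm, 8.0)
        sigma = 8.0 * FWHM_TO_SIGMA / 2.0
        ax = np.arange(33) - 16.0
        g1 = np.exp(-0.5 * (ax / sigma) ** 2)
        oracle = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
        oracle /= oracle.sum()
        assert np.abs(out.values - oracle).max() < 1e-6

    def test_sum_conserved_for_interior_impulse(self):
        vals = np.zeros((33, 33, 33))
        vals[16, 16, 16] = 2.5
        gm = GMMap("s", vals, np.diag([2.0, 2.0, 2.0, 1.0]))
        out = smooth_gm_map(gm, 8.0)
        assert abs(out.values.sum() - 2.5) / 2.5 < 1e-6

    def test_linearity(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, (12, 12, 12))
        y = rng.uniform(0, 1, (12, 12, 12))
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        a, b = 0.7, 1.3
        lhs = smooth_gm_map(GMMap("s", a * x + b * y, aff), 6.0).values
        rhs = (a * smooth_gm_map(GMMap("s", x, aff), 6.0).values
               + b * smooth_gm_map(GMMap("s", y, aff), 6.0).values)
        np.testing.assert_allclose(lhs, rhs, atol=1e-6)

    def test_negative_fwhm_rejected(self):
        gm = GMMap("s", np.ones((4, 4, 4)), np.eye(4))
        with pytest.raises(ValueError):
            smooth_gm_map(gm, -1.0)


class TestExtraction:
    def test_direct_indexing_two_regions(self):
        atlas = _toy_atlas()
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 1, atlas.labels.shape)
        gm = GMMap("s", vals, np.eye(4))
        rs = extract_regional_samples(gm, atlas)
        assert len(rs.samples[1]) == 5 and len(rs.samples[2]) == 7
        np.testing.assert_array_equal(rs.samples[1], vals.ravel()[:5])
        np.testing.assert_array_equal(rs.samples[2], vals.ravel()[10:17])

    def test_constant_map(self):
        atlas = _toy_atlas()
        gm = GMMap("s", np.full(atlas.labels.shape, 0.5), np.eye(4))
        rs = extract_regional_samples(gm, atlas)
        for v in rs.samples.values():
            assert np.all(v == 0.5)

    def test_partition_property(self):
        """Total extracted sample count equals the nonzero-label voxel count."""
        from morphnet.simulate import generate_atlas
        atlas = generate_atlas((24, 24, 24), 30, seed=5)
        gm = GMMap("s", np.random.default_rng(0).uniform(0, 1, (24, 24, 24)),
                   atlas.affine)
        rs = extract_regional_samples(gm, atlas)
        total = sum(len(v) for v in rs.samples.values())
        assert total == int((atlas.labels > 0).sum())

    def test_grid_mismatch_raises(self):
        atlas = _toy_atlas()
        gm = GMMap("s", np.ones((5, 5, 5)), np.eye(4))
        with pytest.raises(ValueError, match="mismatch"):
            extract_regional_samples(gm, atlas)


class TestAtlas:
    def test_atlas_round_trip(self, tmp_path):
        from morphnet.simulate import generate_atlas
        atlas = generate_atlas((24, 24, 24), 30, seed=5)
        images.save_atlas(atlas, tmp_path / "a.nii.gz", tmp_path / "a.tsv")
        back = images.load_atlas(tmp_path / "a.nii.gz", tmp_path / "a.tsv")
        np.testing.assert_array_equal(back.labels, atlas.labels)
        assert back.regions["region_name"].tolist() == \
            atlas.regions["region_name"].tolist()

    def test_label_not_in_table_rejected(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[0, 0, 0] = 7
        regions = pd.DataFrame({"region_id": [1], "region_name": ["a"]})
        with pytest.raises(ValueError, match="absent"):
            AtlasParcellation(labels=labels, regions=regions, affine=np.eye(4))

    def test_nearest_neighbor_resampling_identity_and_shift(self):
        atlas = _toy_atlas()
        gm_same = GMMap("s", np.ones(atlas.labels.shape), np.eye(4))
        assert resample_atlas_to(atlas, gm_same) is atlas
        # same grid, shifted world origin: labels shift by one voxel
        aff = np.eye(4)
        aff[0, 3] = 1.0
        gm_shift = GMMap("s", np.ones(atlas.labels.shape), aff)
        res = resample_atlas_to(atlas, gm_shift)
        np.testing.assert_array_equal(res.labels[:-1], atlas.labels[1:])


class TestRegionMeans:
    def test_mean_values(self):
        atlas = _toy_atlas()
        vals = np.zeros(atlas.labels.shape)
        vals.ravel()[:5] = [0.2, 0.4, 0.6, 0.4, 0.4]
        vals.ravel()[10:17] = 0.8
        gm = GMMap("s1", vals, np.eye(4))
        rs = extract_regional_samples(gm, atlas)
        table = region_mean_table([rs], atlas)
        assert table.loc[0, "1"] == pytest.approx(0.4)
        assert table.loc[0, "2"] == pytest.approx(0.8)

    def test_identical_maps_identical_rows(self):
        atlas = _toy_atlas()
        vals = np.random.default_rng(4).uniform(0, 1, atlas.labels.shape)
        rs1 = extract_regional_samples(GMMap("s1", vals, np.eye(4)), atlas)
        rs2 = extract_regional_samples(GMMap("s2", vals, np.eye(4)), atlas)
        table = region_mean_table([rs1, rs2], atlas)
        assert np.array_equal(table.iloc[0, 1:].to_numpy(dtype=float),
                              table.iloc[1, 1:].to_numpy(dtype=float))

    def test_inconsistent_region_sets_rejected(self):
        atlas = _toy_atlas()
        gm = GMMap("s1", np.ones(atlas.labels.shape), np.eye(4))
        rs = extract_regional_samples(gm, atlas)
        rs_bad = images.RegionalSamples("s2", {1: np.ones(5)})
        with pytest.raises(ValueError, match="region set"):
            region_mean_table([rs, rs_bad], atlas)
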