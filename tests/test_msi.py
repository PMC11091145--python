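import numpy as np
import pandas as pd
import pytest

from msiflux import msi
from msiflux.exceptions import (
    EmptyImageError,
    EmptySelectionError,
    FormatError,
    NotNormalizedError,
)


def make_table(rows):
    return pd.DataFrame(rows, columns=msi.FEATURE_COLUMNS)


class TestPixelCsv:
    def test_roundtrip_preserves_coords_and_values(self, toy_image, tmp_path):
        path = tmp_path / "img.csv"
        msi.write_pixel_csv(toy_image, path)
        back = msi.read_pixel_csv(path)
        np.testing.assert_array_equal(back.coords, toy_image.coords)
        np.testing.assert_allclose(back.intensities, toy_image.intensities, atol=1e-9)
        np.testing.assert_allclose(back.mz, toy_image.mz, atol=1e-6)

    def test_minimal_file(self, tmp_path):
        path = tmp_path / "two.csv"
        path.write_text("x,y,100.5,200.25,300.125\n0,0,1,2,3\n1,0,4,5,6\n")
        img = msi.read_pixel_csv(path)
        assert img.n_pixels == 2 and img.n_features == 3
        # coords are (row, col) = (y, x)
        np.testing.assert_array_equal(img.coords, [[0, 0], [0, 1]])

    def test_unsorted_mz_header_sorted_with_columns(self, tmp_path):
        path = tmp_path / "swap.csv"
        path.write_text("x,y,300.0,100.0\n0,0,7,1\n")
        img = msi.read_pixel_csv(path)
        np.testing.assert_allclose(img.mz, [100.0, 300.0])
        np.testing.assert_allclose(img.intensities[0], [1.0, 7.0])

    def test_duplicate_coordinate_names_the_pixel(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("x,y,100.0\n3,5,1\n3,5,2\n")
        with pytest.raises(FormatError, match="x=3, y=5"):
            msi.read_pixel_csv(path)

    @pytest.mark.parametrize(
        "body",
        ["0,0,-1\n", "0,0\n"],
        ids=["negative-intensity", "ragged-row"],
    )
    def test_malformed_rows_rejected(self, tmp_path, body):
        path = tmp_path / "bad.csv"
        path.write_text("x,y,100.0\n" + body)
        with pytest.raises(FormatError):
            msi.read_pixel_csv(path)


class TestTicNormalize:
    def test_divides_each_pixel_by_its_sum(self, toy_image):
        out, dropped = msi.tic_normalize(toy_image)
        assert dropped == 0
        np.testing.assert_allclose(out.intensities[0], [0.2, 0.3, 0.5])
        np.testing.assert_allclose(out.intensities.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_pixel_dropped_and_counted(self):
        img = msi.SpectralImage(
            coords=[[0, 0], [0, 1]],
            mz=[100.0, 200.0],
            intensities=[[1.0, 1.0], [0.0, 0.0]],
        )
        out, dropped = msi.tic_normalize(img)
        assert dropped == 1 and out.n_pixels == 1

    def test_all_zero_image_is_an_error(self):
        img = msi.SpectralImage(
            coords=[[0, 0]], mz=[100.0], intensities=[[0.0]]
        )
        with pytest.raises(EmptyImageError):
            msi.tic_normalize(img)

    def test_renormalizing_is_a_state_error_but_values_are_fixed_points(
        self, toy_image
    ):
        out, _ = msi.tic_normalize(toy_image)
        with pytest.raises(NotNormalizedError):
            msi.tic_normalize(out)
        sums = out.intensities.sum(axis=1)
        np.testing.assert_allclose(
            out.intensities / sums[:, None], out.intensities, atol=1e-12
        )


class TestCountMatrix:
    def test_floor_of_100x(self):
        img = msi.SpectralImage(
            coords=[[0, 0], [0, 1], [1, 0]],
            mz=[100.0, 200.0],
            intensities=[[0.237, 0.763], [1.0, 0.0], [0.0099, 0.9901]],
            normalized=True,
        )
        counts = msi.to_count_matrix(img)
        np.testing.assert_array_equal(counts, [[23, 76], [100, 0], [0, 99]])
        assert counts.min() >= 0 and counts.max() <= 100

    def test_requires_normalized_image(self, toy_image):
        with pytest.raises(NotNormalizedError):
            msi.to_count_matrix(toy_image)


class TestSelectLipidFeatures:
    table = make_table(
        [
            (380.0, "low_mz", np.nan, "lipid", 10.0, np.nan),
            (500.0, "matrix_sig", np.nan, "matrix", 9.0, np.nan),
            (766.5, "pt_marker", np.nan, "lipid", 5.0, np.nan),
            (810.5, "noisy", np.nan, "lipid", 2.0, np.nan),
        ]
    )

    def make_image(self):
        return msi.SpectralImage(
            coords=[[0, 0]],
            mz=[380.0, 500.0, 766.5, 810.5],
            intensities=[[1.0, 2.0, 3.0, 4.0]],
            feature_names=["low_mz", "matrix_sig", "pt_marker", "noisy"],
        )

    def test_mz_snr_and_matrix_filters(self):
        out = msi.select_lipid_features(self.make_image(), self.table)
        assert list(out.mz) == [766.5]
        assert out.feature_names == ["pt_marker"]

    def test_all_qualifying_is_identity(self):
        img = self.make_image()
        out = msi.select_lipid_features(img, self.table, min_mz=0, min_snr=0)
        keep = self.table["kind"] != "matrix"
        assert list(out.mz) == list(img.mz[keep.to_numpy()])

    def test_empty_selection_is_an_error(self):
        with pytest.raises(EmptySelectionError):
            msi.select_lipid_features(self.make_image(), self.table, min_mz=1000)


class TestAnnotateFeatures:
    reference = pd.DataFrame({"mz": [885.5499, 760.585], "name": ["PI 38:4", "PC 34:1"]})

    def test_within_tolerance_matches_with_ppm_error(self):
        (match,) = msi.annotate_features([885.549], self.reference)
        assert match.name == "PI 38:4"
        assert match.ppm_error == pytest.approx(1.016, abs=0.01)

    def test_outside_tolerance_unmatched(self):
        (match,) = msi.annotate_features([885.570], self.reference)
        assert match is None  # ≈22.7 ppm

    def test_exact_value_matches_at_zero_ppm(self):
        (match,) = msi.annotate_features([885.5499], self.reference)
        assert match.ppm_error == 0.0

    def test_exact_tie_left_unmatched_with_flag(self):
        ref = pd.DataFrame({"mz": [100.0, 100.0], "name": ["a", "b"]})
        (match,) = msi.annotate_features([100.0005], ref)
        assert match.ambiguous and match.ref_index is None


class TestHotspotClip:
    def test_caps_at_the_empirical_quantile(self):
        values = np.arange(1.0, 101.0)
        out = msi.hotspot_clip(values, 0.99)
        assert out.max() == pytest.approx(np.quantile(values, 0.99))
        np.testing.assert_array_equal(out[:-1], values[:-1])

    def test_constant_vector_unchanged(self):
        out = msi.hotspot_clip(np.full(10, 3.5))
        np.testing.assert_array_equal(out, np.full(10, 3.5))

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.1, 1.5])
    def test_quantile_bounds(self, q):
        with pytest.raises(ValueError):
            msi.hotspot_clip(np.arange(5.0), q)


class TestDatasetStats:
    def test_study_scale_totals(self):
        counts = [2394033 - 72546 * 32] + [72546] * 32
        stats = msi.dataset_stats(counts, pixel_size_um=5.0)
        assert stats.total_pixels == 2394033
        assert stats.mean_pixels_per_section == 72546
        assert stats.mean_area_mm2 == 1.8

    def test_tiny_section_area(self):
        stats = msi.dataset_stats([4], pixel_size_um=5.0)
        assert stats.section_areas_mm2[0] == pytest.approx(1e-4)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            msi.dataset_stats([])

    def test_accepts_images(self, toy_image):
        stats = msi.dataset_stats([toy_image])
        assert stats.total_pixels == 3
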