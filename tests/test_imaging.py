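import numpy as np
import pandas as pd
import pytest

from voxelprot.imaging import (
    build_voxel_image,
    cv_summary,
    export_gallery,
    read_grid_csv,
    render_protein_image,
    write_grid_csv,
)
from voxelprot.matrices import SampleMetadata

from conftest import make_metadata
from test_qc import protein_matrix


def grid_metadata(coords, study="img"):
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": [f"v{r}{c}" for r, c in coords],
                "study_id": study,
                "group": "S",
                "voxel_row": [r for r, _ in coords],
                "voxel_col": [c for _, c in coords],
                "voxel_size_um": 100.0,
            }
        )
    )


class TestBuildVoxelImage:
    def test_unoccupied_cell_gets_sentinel(self):
        meta = grid_metadata([(0, 0), (0, 1), (1, 0)])
        values = pd.Series([1.0, 2.0, 3.0], index=["v00", "v01", "v10"])
        img = build_voxel_image(values, meta, "P1")
        assert img.shape == (2, 2)
        assert np.isnan(img.grid[1, 1])
        assert img.grid[0, 1] == 2.0

    def test_single_run_gives_1x1_grid(self):
        meta = grid_metadata([(0, 0)])
        img = build_voxel_image(pd.Series([4.2], index=["v00"]), meta, "P1")
        assert img.shape == (1, 1) and img.grid[0, 0] == 4.2

    def test_flattening_recovers_input(self):
        meta = grid_metadata([(0, 0), (0, 1), (1, 1), (2, 0)])
        values = pd.Series([1.0, 2.0, np.nan, 4.0], index=["v00", "v01", "v11", "v20"])
        img = build_voxel_image(values, meta, "P1")
        for (r, c), sid in img.sample_at.items():
            v = values[sid]
            assert (np.isnan(v) and np.isnan(img.grid[r, c])) or img.grid[r, c] == v
        assert len(img.sample_at) == 4


class TestRendering:
    def test_minmax_scaling_maps_extremes_to_unit_interval(self, tmp_path):
        meta = grid_metadata([(0, 0), (0, 1), (1, 0), (1, 1)])
        values = pd.Series([2.0, 4.0, 8.0, 6.0], index=["v00", "v01", "v10", "v11"])
        img = build_voxel_image(values, meta, "P1")
        scaled = render_protein_image(img, tmp_path / "p1.png")
        assert scaled.min() == 0.0 and scaled.max() == 1.0
        assert (tmp_path / "p1.png").exists() and (tmp_path / "p1.csv").exists()

    def test_percentile_scaling_clips_extreme_cell(self, tmp_path):
        coords = [(0, c) for c in range(10)]
        meta = grid_metadata(coords)
        vals = pd.Series([1.0] * 9 + [1000.0], index=[f"v{r}{c}" for r, c in coords])
        img = build_voxel_image(vals, meta, "P1")
        scaled = render_protein_image(
            img, tmp_path / "p.png", scaling="percentile", p_lo=5, p_hi=95
        )
        assert scaled[0, 9] == 1.0

    def test_constant_image_renders_uniformly(self, tmp_path):
        meta = grid_metadata([(0, 0), (0, 1)])
        img = build_voxel_image(pd.Series([3.0, 3.0], index=["v00", "v01"]), meta, "P1")
        scaled = render_protein_image(img, tmp_path / "c.png")
        assert (scaled == scaled[0, 0]).all()

    def test_all_missing_image_rejected(self, tmp_path):
        meta = grid_metadata([(0, 0)])
        img = build_voxel_image(pd.Series([np.nan], index=["v00"]), meta, "P1")
        with pytest.raises(ValueError, match="all-missing"):
            render_protein_image(img, tmp_path / "x.png")

    def test_sidecar_round_trips_exactly(self, tmp_path):
        meta = grid_metadata([(0, 0), (0, 1), (1, 0)])
        values = pd.Series([1.23456789012345, np.nan, 7.5], index=["v00", "v01", "v10"])
        img = build_voxel_image(values, meta, "P1")
        write_grid_csv(img, tmp_path / "g.csv")
        back = read_grid_csv(tmp_path / "g.csv")
        np.testing.assert_array_equal(np.isnan(back), np.isnan(img.grid))
        np.testing.assert_array_equal(back[~np.isnan(back)], img.grid[~np.isnan(img.grid)])


class TestCvSummary:
    def test_identical_replicates_have_zero_cv(self):
        prot = protein_matrix({"P": [3.0, 3.0, 3.0]}, ["r1", "r2", "r3"])
        assert cv_summary(prot)["table"].loc["P", "cv"] == 0.0

    def test_linear_values_1_2_3_give_cv_half(self):
        prot = protein_matrix(
            {"P": list(np.log2([1.0, 2.0, 3.0]))}, ["r1", "r2", "r3"]
        )
        assert cv_summary(prot)["table"].loc["P", "cv"] == pytest.approx(0.5)

    def test_single_observation_protein_excluded(self):
        prot = protein_matrix(
            {"P": [1.0, np.nan, np.nan], "Q": [1.0, 1.5, 2.0]}, ["r1", "r2", "r3"]
        )
        assert list(cv_summary(prot)["table"].index) == ["Q"]

    def test_cv_invariant_to_global_linear_rescaling(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(20, 0.3, size=(10, 6))
        prot = protein_matrix(
            {f"P{i}": list(vals[i]) for i in range(10)}, [f"r{j}" for j in range(6)]
        )
        scaled = protein_matrix(
            {f"P{i}": list(vals[i] + np.log2(10.0)) for i in range(10)},
            [f"r{j}" for j in range(6)],
        )
        np.testing.assert_allclose(
            cv_summary(prot)["table"]["cv"], cv_summary(scaled)["table"]["cv"], rtol=1e-10
        )


class TestGallery:
    def _images(self, n):
        meta = grid_metadata([(0, 0), (0, 1), (1, 0), (1, 1)])
        out = {}
        rng = np.random.default_rng(1)
        for i in range(n):
            vals = pd.Series(rng.uniform(1, 5, 4), index=["v00", "v01", "v10", "v11"])
            out[f"PROT{i}"] = build_voxel_image(vals, meta, f"PROT{i}")
        return out

    def test_one_raster_one_csv_per_analyte_plus_index(self, tmp_path):
        export_gallery(self._images(4), tmp_path / "g")
        files = sorted(p.name for p in (tmp_path / "g").iterdir())
        assert files.count("index.html") == 1
        assert sum(f.endswith(".png") for f in files) == 4
        assert sum(f.endswith(".csv") for f in files) == 4

    def test_index_is_deterministic(self, tmp_path):
        export_gallery(self._images(3), tmp_path / "a")
        export_gallery(self._images(3), tmp_path / "b")
        assert (tmp_path / "a/index.html").read_bytes() == (tmp_path / "b/index.html").read_bytes()

    def test_gallery_csv_round_trips(self, tmp_path):
        images = self._images(1)
        export_gallery(images, tmp_path / "g")
        back = read_grid_csv(tmp_path / "g" / "PROT0.csv")
        np.testing.assert_array_equal(back, images["PROT0"].grid)
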