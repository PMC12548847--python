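import numpy as np
import pandas as pd
import pytest

from embryocal.synthdata import make_cohort_layouts, SimConfig, simulate_embryo_dataset
from embryocal.traceio import (
    EmbryoMovie,
    FormatError,
    LabelingError,
    ROILabelMap,
    extract_traces,
    read_movie,
    read_traces,
    traces_to_wide,
    wide_to_traces,
    write_movie,
    write_traces,
)


def _movie(frames, **kw):
    return EmbryoMovie(frames=np.asarray(frames), **kw)


def _labels(arr, tissue):
    return ROILabelMap(labels=np.asarray(arr), tissue=tissue)


class TestExtractTraces:
    def test_constant_region_gives_constant_trace(self):
        frames = np.full((3, 4, 4), 7.0)
        labels = np.zeros((4, 4), int)
        labels[1:3, 1:3] = 1
        out = extract_traces(_movie(frames), _labels(labels, {1: "emVE"}))
        assert np.allclose(out["intensity"], 7.0)
        assert len(out) == 3

    def test_mean_of_two_pixels(self):
        frames = np.zeros((2, 2, 2))
        frames[0, 0, 0], frames[0, 0, 1] = 3.0, 5.0
        labels = np.array([[1, 1], [0, 0]])
        out = extract_traces(_movie(frames), _labels(labels, {1: "ExE"}))
        assert out["intensity"].iloc[0] == pytest.approx(4.0)

    def test_matches_per_pixel_brute_force(self, rng):
        frames = rng.uniform(0, 100, size=(10, 20, 20))
        labels = rng.integers(0, 4, size=(20, 20))
        tissue = {1: "epiblast", 2: "emVE", 3: "exVE"}
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # fragmented regions
            out = extract_traces(_movie(frames), _labels(labels, tissue))
        for cid in (1, 2, 3):
            got = out[out["cell_id"] == cid]["intensity"].to_numpy()
            expected = []
            for t in range(10):
                acc, n = 0.0, 0
                for y in range(20):
                    for x in range(20):
                        if labels[y, x] == cid:
                            acc += frames[t, y, x]
                            n += 1
                expected.append(acc / n)
            np.testing.assert_allclose(got, expected)

    def test_extraction_is_linear(self, rng):
        a = rng.uniform(0, 10, size=(4, 6, 6))
        b = rng.uniform(0, 10, size=(4, 6, 6))
        labels = np.zeros((6, 6), int)
        labels[2:5, 2:5] = 1
        lab = _labels(labels, {1: "ExE"})
        sum_of = (
            extract_traces(_movie(a), lab)["intensity"].to_numpy()
            + extract_traces(_movie(b), lab)["intensity"].to_numpy()
        )
        of_sum = extract_traces(_movie(a + b), lab)["intensity"].to_numpy()
        np.testing.assert_allclose(of_sum, sum_of)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(FormatError):
            extract_traces(
                _movie(np.zeros((3, 4, 4))),
                _labels(np.ones((5, 5), int), {1: "emVE"}),
            )

    def test_label_missing_from_tissue_table_rejected(self):
        with pytest.raises(LabelingError):
            _labels(np.ones((2, 2), int), {})


class TestMovieIO:
    def test_16bit_roundtrip_exact(self, tmp_path, rng):
        frames = rng.integers(0, 65535, size=(5, 16, 16), dtype=np.uint16)
        movie = _movie(frames, frame_interval_s=2.0, pixel_size_um=0.25)
        write_movie(movie, tmp_path / "m.tif")
        back = read_movie(tmp_path / "m.tif")
        np.testing.assert_array_equal(back.frames, frames)
        assert back.frame_interval_s == 2.0
        assert back.pixel_size_um == 0.25

    def test_missing_sidecar_defaults_with_warning(self, tmp_path, caplog):
        import tifffile

        tifffile.imwrite(tmp_path / "m.tif", np.zeros((3, 4, 4), np.uint16))
        with caplog.at_level("WARNING"):
            movie = read_movie(tmp_path / "m.tif")
        assert movie.frame_interval_s == 5.0
        assert "sidecar" in caplog.text

    def test_rgb_stack_rejected(self, tmp_path):
        import tifffile

        tifffile.imwrite(
            tmp_path / "rgb.tif", np.zeros((3, 8, 8, 3), np.uint8)
        )
        with pytest.raises(FormatError):
            read_movie(tmp_path / "rgb.tif")

    def test_single_frame_rejected(self):
        with pytest.raises(FormatError):
            _movie(np.zeros((1, 4, 4)))


class TestTraceTableIO:
    def test_cohort_roundtrip_identical(self, tmp_path):
        layouts = make_cohort_layouts(3, {"epiblast": 5, "ExE": 5, "emVE": 4, "exVE": 4})
        frames = [
            simulate_embryo_dataset(SimConfig(seed=i), lay)[0]
            for i, lay in enumerate(layouts)
        ]
        df = pd.concat(frames, ignore_index=True)
        write_traces(df, tmp_path / "t.csv")
        back = read_traces(tmp_path / "t.csv")
        merged = back.merge(
            df, on=["embryo_id", "cell_id", "frame"], suffixes=("_r", "_w")
        )
        np.testing.assert_allclose(
            merged["intensity_r"], merged["intensity_w"], rtol=1e-6
        )
        assert len(back) == len(df)

    def test_nonuniform_frame_count_rejected(self):
        df = pd.DataFrame(
            {
                "embryo_id": ["e"] * 5,
                "cell_id": [1, 1, 1, 2, 2],
                "tissue": ["emVE"] * 5,
                "frame": [0, 1, 2, 0, 1],
                "time_s": [0, 5, 10, 0, 5],
                "intensity": [1.0] * 5,
            }
        )
        with pytest.raises(FormatError):
            write_traces(df, "/dev/null")

    def test_missing_column_rejected(self, tmp_path):
        pd.DataFrame({"cell_id": [1], "frame": [0]}).to_csv(
            tmp_path / "bad.csv", index=False
        )
        with pytest.raises(FormatError):
            read_traces(tmp_path / "bad.csv")

    def test_reference_cohort_tissue_tally(self):
        """A table shaped like the 1,126-cell reference dataset loads and
        its per-tissue tallies reproduce the published cell counts."""
        layouts = make_cohort_layouts(14)
        frames = []
        cfg = dict(
            tissue_rates={t: 0.0 for t in ("epiblast", "ExE", "emVE", "exVE")},
            drift_amplitude=0.0,
        )
        for i, lay in enumerate(layouts):
            frames.append(
                simulate_embryo_dataset(SimConfig(seed=i, **cfg), lay)[0]
            )
        df = pd.concat(frames, ignore_index=True)
        meta, _ = traces_to_wide(df)
        tally = meta.groupby("tissue")["cell_id"].size().to_dict()
        assert tally == {"epiblast": 323, "ExE": 430, "emVE": 205, "exVE": 168}
        assert sum(tally.values()) == 1126

    def test_wide_roundtrip(self, small_layout):
        df, _ = simulate_embryo_dataset(SimConfig(seed=4), small_layout)
        meta, mat = traces_to_wide(df)
        back = wide_to_traces(meta, mat, frame_interval_s=5.0)
        np.testing.assert_allclose(
            back["intensity"].to_numpy(),
            df.sort_values(["embryo_id", "cell_id", "frame"])["intensity"].to_numpy(),
        )
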