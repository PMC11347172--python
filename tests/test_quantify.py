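import numpy as np
import pandas as pd
import pytest

from nucleoshuttle import imgio, quantify
from nucleoshuttle.quantify import (
    derive_regions,
    extract_features,
    nuclear_intensity_series,
    ratio_series,
    recover_kinetics,
)
from nucleoshuttle.simulate import CHANNEL_ROLES, SimConfig, render_movie


def _stack_from(pixels, interval=5.0):
    return imgio.ImageStack(pixels, dict(CHANNEL_ROLES), interval)


def _truth_regions(truth, n_frames):
    regions = derive_regions(truth.nucleus_labels, truth.nucleolus_labels)
    return [regions] * n_frames


def region_means_loop(image, mask):
    """Naive per-pixel oracle for a region mean."""
    total, count = 0.0, 0
    for y in range(image.shape[0]):
        for x in range(image.shape[1]):
            if mask[y, x]:
                total += float(image[y, x])
                count += 1
    return total / count if count else float("nan")


class TestDeriveRegions:
    def test_set_subtraction_areas(self):
        nuclei = np.zeros((20, 20), dtype=int)
        nuclei[0:10, 0:10] = 1  # 100 px nucleus
        nucleoli = np.zeros((20, 20), dtype=int)
        nucleoli[2:6, 2:7] = 1  # 20 px nucleolus inside it
        regions = derive_regions(nuclei, nucleoli)
        assert regions.nucleolar_mask(1).sum() == 20
        assert regions.nucleoplasm_mask(1).sum() == 80

    def test_majority_overlap_assignment(self):
        nuclei = np.zeros((10, 40), dtype=int)
        nuclei[:, 0:15] = 1   # nucleus A
        nuclei[:, 15:40] = 2  # nucleus B
        nucleoli = np.zeros((10, 40), dtype=int)
        nucleoli[4:5, 12:19] = 1  # 3 px in A, 4 px in B -> B
        nucleoli[6:9, 5:20] = 2   # 30 px in A, 15 px in B -> A
        regions = derive_regions(nuclei, nucleoli)
        assert regions.assignment == {1: 2, 2: 1}
        # clipped to the assigned nucleus
        assert (regions.nucleolar_owner[nucleoli == 2] == 0).sum() == 15

    def test_tie_goes_to_lower_label(self):
        nuclei = np.zeros((10, 20), dtype=int)
        nuclei[:, 0:10] = 1
        nuclei[:, 10:20] = 2
        nucleoli = np.zeros((10, 20), dtype=int)
        nucleoli[4:6, 8:12] = 1  # 4 px in each nucleus
        regions = derive_regions(nuclei, nucleoli)
        assert regions.assignment == {1: 1}

    def test_orphan_nucleolus_discarded(self):
        nuclei = np.zeros((20, 20), dtype=int)
        nuclei[0:8, 0:8] = 1
        nucleoli = np.zeros((20, 20), dtype=int)
        nucleoli[12:16, 12:16] = 1  # entirely outside
        regions = derive_regions(nuclei, nucleoli)
        assert regions.assignment == {}
        assert regions.n_discarded == 1
        assert regions.nucleoplasm_mask(1).sum() == 64  # nucleus unchanged

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            derive_regions(np.zeros((5, 5), int), np.zeros((6, 6), int))

    def test_area_conservation_on_simulated_frame(self, noisy_movie):
        """|nucleus| == |nucleolar| + |nucleoplasm| for every cell."""
        _, truth = noisy_movie
        regions = derive_regions(truth.nucleus_labels, truth.nucleolus_labels)
        for cell in regions.cell_labels:
            n_area = (truth.nucleus_labels == cell).sum()
            assert (
                regions.nucleolar_mask(cell).sum()
                + regions.nucleoplasm_mask(cell).sum()
                == n_area
            )


class TestExtractFeatures:
    def test_uniform_image_means(self):
        nuclei = np.zeros((12, 12), dtype=int)
        nuclei[2:10, 2:10] = 1
        nucleoli = np.zeros((12, 12), dtype=int)
        nucleoli[4:6, 4:6] = 1
        pixels = np.full((1, 3, 12, 12), 7.0)
        regions = [derive_regions(nuclei, nucleoli)]
        feats = extract_features(_stack_from(pixels), regions)
        row = feats.iloc[0]
        assert row["mean_poi_nucleolar"] == 7.0
        assert row["mean_poi_nucleoplasm"] == 7.0
        assert row["mean_nuclear_stain"] == 7.0

    def test_toy_means_match_hand_values(self):
        nuclei = np.zeros((5, 5), dtype=int)
        nuclei[0:4, 0:4] = 1
        nucleoli = np.zeros((5, 5), dtype=int)
        nucleoli[0, 0:3] = 1
        poi = np.full((5, 5), 10.0)
        poi[0, 0:3] = 30.0
        pixels = np.zeros((1, 3, 5, 5))
        pixels[0, CHANNEL_ROLES["poi"]] = poi
        feats = extract_features(_stack_from(pixels), [derive_regions(nuclei, nucleoli)])
        row = feats.iloc[0]
        assert row["mean_poi_nucleolar"] == 30.0
        assert row["mean_poi_nucleoplasm"] == 10.0

    def test_means_equal_naive_pixel_loop(self, noisy_movie):
        """Vectorized region means equal a brute-force per-pixel loop."""
        pixels, truth = noisy_movie
        regions = derive_regions(truth.nucleus_labels, truth.nucleolus_labels)
        feats = extract_features(
            _stack_from(pixels), [regions] * pixels.shape[0]
        )
        poi = pixels[0, CHANNEL_ROLES["poi"]].astype(float)
        f0 = feats[feats["frame"] == 0].set_index("cell")
        for cell in list(regions.cell_labels)[:5]:
            expect = region_means_loop(poi, regions.nucleolar_mask(cell))
            got = f0.loc[cell, "mean_poi_nucleolar"]
            if np.isnan(expect):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expect, rel=1e-12)
            assert f0.loc[cell, "mean_poi_nucleoplasm"] == pytest.approx(
                region_means_loop(poi, regions.nucleoplasm_mask(cell)), rel=1e-12
            )

    def test_cell_without_nucleolus_marked_missing(self):
        nuclei = np.zeros((10, 10), dtype=int)
        nuclei[1:5, 1:5] = 1
        nuclei[6:9, 6:9] = 2  # no nucleolus
        nucleoli = np.zeros((10, 10), dtype=int)
        nucleoli[2:4, 2:4] = 1
        pixels = np.full((1, 3, 10, 10), 4.0)
        feats = extract_features(_stack_from(pixels), [derive_regions(nuclei, nucleoli)])
        by_cell = feats.set_index("cell")
        assert np.isnan(by_cell.loc[2, "mean_poi_nucleolar"])
        assert not np.isnan(by_cell.loc[1, "mean_poi_nucleolar"])


def _features_table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "image", "cell", "frame",
            "mean_poi_nucleolar", "mean_poi_nucleoplasm", "mean_nuclear_stain",
            "area_nucleus", "area_nucleolar", "area_nucleoplasm",
        ],
    )


class TestRatioSeries:
    def test_uniform_image_gives_zero_series(self):
        rows = [("i", c, f, 5.0, 5.0, 9.0, 100, 20, 80)
                for c in (1, 2) for f in (0, 1)]
        series = ratio_series(_features_table(rows), {"i": "ctrl"})
        assert np.allclose(series.table["mean_ratio_minus1"], 0.0)

    def test_single_cell_arithmetic(self):
        rows = [("i", 1, 0, 30.0, 10.0, 9.0, 100, 20, 80)]
        series = ratio_series(_features_table(rows), {"i": "c"})
        assert series.table["mean_ratio_minus1"].iloc[0] == pytest.approx(2.0)

    def test_sem_across_images_hand_value(self):
        """Image means 1, 2, 3 -> mean 2, SEM = 1/sqrt(3) = 0.5774."""
        rows = [(f"img{k}", 1, 0, (m + 1) * 10.0, 10.0, 9.0, 100, 20, 80)
                for k, m in enumerate([1.0, 2.0, 3.0])]
        grouping = {f"img{k}": "c" for k in range(3)}
        series = ratio_series(_features_table(rows), grouping)
        row = series.table.iloc[0]
        assert row["mean_ratio_minus1"] == pytest.approx(2.0)
        assert row["sem"] == pytest.approx(1.0 / np.sqrt(3), abs=1e-4)
        assert row["n_images"] == 3

    def test_zero_nucleoplasm_cells_excluded_and_counted(self):
        rows = [
            ("i", 1, 0, 30.0, 10.0, 9.0, 100, 20, 80),
            ("i", 2, 0, 30.0, 0.0, 9.0, 100, 20, 80),   # excluded
            ("i", 3, 0, np.nan, 10.0, 9.0, 100, 0, 100),  # excluded
        ]
        series = ratio_series(_features_table(rows), {"i": "c"})
        assert series.table["n_cells"].iloc[0] == 1
        assert series.n_excluded == 2

    def test_time_column_uses_frame_interval(self):
        rows = [("i", 1, f, 30.0, 10.0, 9.0, 100, 20, 80) for f in range(4)]
        series = ratio_series(_features_table(rows), {"i": "c"}, frame_interval_min=5.0)
        assert list(series.table["time_min"]) == [0.0, 5.0, 10.0, 15.0]
        assert list(series.table["iteration"]) == [0, 1, 2, 3]

    def test_ratio_invariant_under_global_scaling(self, noise_free_movie):
        """Multiplying the POI channel by c > 0 leaves r unchanged."""
        pixels, truth = noise_free_movie
        regions = _truth_regions(truth, pixels.shape[0])
        feats1 = extract_features(_stack_from(pixels), regions, "i")
        scaled = pixels.copy()
        scaled[:, CHANNEL_ROLES["poi"]] *= 3.7
        feats2 = extract_features(_stack_from(scaled), regions, "i")
        s1 = ratio_series(feats1, {"i": "c"}).table["mean_ratio_minus1"]
        s2 = ratio_series(feats2, {"i": "c"}).table["mean_ratio_minus1"]
        assert np.allclose(s1, s2, rtol=1e-12)

    def test_end_to_end_identity_with_truth_masks(self, noise_free_movie):
        """Pipeline on truth masks returns exactly E(t) - 1 per frame."""
        pixels, truth = noise_free_movie
        regions = _truth_regions(truth, pixels.shape[0])
        feats = extract_features(_stack_from(pixels), regions, "i")
        series = ratio_series(feats, {"i": "c"})
        expected = truth.enrichment_series()["enrichment"].to_numpy() - 1.0
        got = series.table.sort_values("iteration")["mean_ratio_minus1"].to_numpy()
        assert np.allclose(got, expected, rtol=1e-10, atol=1e-12)


class TestNuclearIntensitySeries:
    def test_constant_movie_gives_flat_series(self):
        rows = [("i", c, f, 30.0, 10.0, 42.0, 100, 20, 80)
                for c in (1, 2) for f in range(3)]
        series = nuclear_intensity_series(_features_table(rows), {"i": "c"})
        assert np.allclose(series.table["mean_nuclear_intensity"], 42.0)

    def test_doubled_stain_doubles_series(self, noise_free_movie):
        pixels, truth = noise_free_movie
        regions = _truth_regions(truth, pixels.shape[0])
        feats1 = extract_features(_stack_from(pixels), regions, "i")
        doubled = pixels.copy()
        doubled[:, CHANNEL_ROLES["nuclear_stain"]] *= 2.0
        feats2 = extract_features(_stack_from(doubled), regions, "i")
        s1 = nuclear_intensity_series(feats1, {"i": "c"}).table
        s2 = nuclear_intensity_series(feats2, {"i": "c"}).table
        assert np.allclose(
            s2["mean_nuclear_intensity"], 2.0 * s1["mean_nuclear_intensity"]
        )


class TestRecoverKinetics:
    def test_recovery_on_noise_free_truth_series(self):
        cfg = SimConfig(
            image_size_px=(260, 260), n_cells=10, n_frames=25, seed=3,
            E0=3.0, E_inf=1.2, tau_min=30.0,
        ).without_noise()
        pixels, truth = render_movie(cfg)
        regions = _truth_regions(truth, cfg.n_frames)
        feats = extract_features(_stack_from(pixels), regions, "i")
        series = ratio_series(feats, {"i": "c"})
        fit = recover_kinetics(series)
        assert fit.identifiable and fit.success
        assert fit.tau_min == pytest.approx(30.0, rel=0.01)
        assert fit.E0 == pytest.approx(3.0, rel=0.01)
        assert fit.E_inf == pytest.approx(1.2, rel=0.01)

    def test_flat_series_flagged_unidentifiable(self):
        table = pd.DataFrame(
            {
                "condition": "c", "time_min": np.arange(10) * 5.0,
                "iteration": np.arange(10), "mean_ratio_minus1": 0.5,
                "sem": 0.0, "n_images": 1, "n_cells": 10,
            }
        )
        fit = recover_kinetics(table)
        assert not fit.identifiable
        assert np.isnan(fit.tau_min)
        assert fit.E0 == pytest.approx(fit.E_inf)

    def test_too_few_frames_rejected(self):
        table = pd.DataFrame(
            {
                "condition": "c", "time_min": np.arange(3) * 5.0,
                "iteration": np.arange(3), "mean_ratio_minus1": [2.0, 1.0, 0.5],
                "sem": 0.0, "n_images": 1, "n_cells": 10,
            }
        )
        with pytest.raises(ValueError, match="5 post-treatment"):
            recover_kinetics(table)

    def test_multiple_conditions_require_selection(self):
        table = pd.DataFrame(
            {
                "condition": ["a"] * 6 + ["b"] * 6,
                "time_min": list(np.arange(6) * 5.0) * 2,
                "iteration": list(np.arange(6)) * 2,
                "mean_ratio_minus1": np.r_[np.linspace(2, 0.2, 6), np.linspace(2, 1, 6)],
                "sem": 0.0, "n_images": 1, "n_cells": 10,
            }
        )
        with pytest.raises(ValueError, match="condition"):
            recover_kinetics(table)
        fit = recover_kinetics(table, condition="a")
        assert fit.success


class TestDoseOrdering:
    def test_lower_einf_gives_pointwise_lower_plateau(self):
        """Conditions with lower plateau enrichment stay below throughout."""
        series_by_einf = {}
        for einf in (1.2, 1.5, 2.0):
            cfg = SimConfig(
                image_size_px=(260, 260), n_cells=10, n_frames=22, seed=40,
                E_inf=einf,
            )
            pixels, truth = render_movie(cfg)
            regions = _truth_regions(truth, cfg.n_frames)
            feats = extract_features(_stack_from(pixels), regions, "i")
            tab = ratio_series(feats, {"i": "c"}).table.sort_values("iteration")
            series_by_einf[einf] = tab["mean_ratio_minus1"].to_numpy()
        late = slice(19, None)
        assert (series_by_einf[1.2][late] < series_by_einf[1.5][late]).all()
        assert (series_by_einf[1.5][late] < series_by_einf[2.0][late]).all()
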