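"""Image pipeline: segmentation, measurement, normalization, positivity, colocalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from tempcode import imagequant, synthdata
from tempcode.imagequant import (
    SegmentationConfig,
    call_positive,
    classify_cells,
    colocalization_fraction,
    extract_records,
    normalize_and_trim,
    segment_nuclei,
)
from tempcode.synthdata import SectionImage


def _disc_image(shape, centers, radius, value=1000.0, background=0.0):
    img = np.full(shape, background)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    for r0, c0 in centers:
        img[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2] = value
    return img


class TestSegmentNuclei:
    def test_all_zero_image_gives_empty_label_map(self):
        labels = segment_nuclei(np.zeros((64, 64)), SegmentationConfig())
        assert labels.max() == 0

    def test_well_separated_discs_match_flood_fill_count(self):
        centers = [(20, 20), (20, 80), (60, 50), (100, 20), (100, 80)]
        img = _disc_image((128, 100), centers, radius=7)
        labels = segment_nuclei(img, SegmentationConfig())
        _, n_oracle = ndimage.label(img > 500)
        assert n_oracle == 5
        assert labels.max() == 5
        assert sorted(np.unique(labels)) == list(range(6))  # contiguous from 1

    def test_watershed_splits_touching_pair(self):
        # two discs overlapping by less than one radius: distance transform
        # has two maxima, so the watershed must cut them apart
        img = _disc_image((80, 80), [(40, 30), (40, 42)], radius=8)
        dist = ndimage.distance_transform_edt(img > 500)
        assert len(np.unique(np.round(dist.max()))) >= 1  # sanity on the oracle input
        labels = segment_nuclei(img, SegmentationConfig(min_seed_distance=6))
        assert labels.max() == 2

    def test_even_block_size_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            SegmentationConfig(adaptive_block_size=50)

    def test_non_2d_input_rejected(self):
        with pytest.raises(ValueError, match="2D"):
            segment_nuclei(np.zeros((4, 4, 2)), SegmentationConfig())

    def test_noise_free_sections_counted_exactly(self, clean_section):
        spec, image, truth = clean_section
        labels = segment_nuclei(image.channels["DAPI"], SegmentationConfig())
        assert labels.max() == spec.n_nuclei == len(truth)


def _toy_image(label_arrays: dict[str, np.ndarray]) -> SectionImage:
    return SectionImage(channels=label_arrays)


class TestExtractRecords:
    def test_area_filter_and_uniform_means(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[2:8, 2:8] = 1     # area 36: kept
        labels[12, 12] = 2       # area 1: dropped
        chan = np.where(labels == 1, 7.0, 0.0)
        img = _toy_image({"DAPI": chan, "X": chan * 2})
        recs = extract_records(labels, img, SegmentationConfig(area_min=10, area_max=100))
        assert list(recs["label"]) == [1]
        assert recs.loc[0, "mean_DAPI"] == pytest.approx(7.0)
        assert recs.loc[0, "mean_X"] == pytest.approx(14.0)

    def test_three_pixel_mean(self):
        labels = np.zeros((5, 5), dtype=int)
        labels[1, 1:4] = 1
        chan = np.zeros((5, 5))
        chan[1, 1:4] = [1.0, 2.0, 3.0]
        img = _toy_image({"DAPI": chan})
        recs = extract_records(labels, img, SegmentationConfig(area_min=1, area_max=10))
        assert recs.loc[0, "mean_DAPI"] == pytest.approx(2.0)

    def test_shape_mismatch_rejected(self):
        img = _toy_image({"DAPI": np.zeros((4, 4))})
        with pytest.raises(ValueError, match="shapes differ"):
            extract_records(np.zeros((5, 5), dtype=int), img, SegmentationConfig())


def _records(vals, channel="TF"):
    return pd.DataFrame({f"mean_{channel}": vals})


class TestNormalizeAndTrim:
    def test_min_max_rescale(self):
        out = normalize_and_trim(_records([10.0, 20.0, 30.0]), "TF")
        assert list(out["norm_TF"]) == pytest.approx([0.0, 0.5, 1.0])

    def test_trim_counts_per_tail(self):
        # 0.3% of 1000 objects: 3 brightest and 3 dimmest flagged
        out = normalize_and_trim(_records(np.arange(1000.0)), "TF")
        trimmed = out[out["trimmed_TF"]]
        assert len(trimmed) == 6
        assert set(trimmed.index) == {0, 1, 2, 997, 998, 999}

    def test_small_section_trims_nothing(self):
        # round(0.3) = 0 per tail at N=100
        out = normalize_and_trim(_records(np.arange(100.0)), "TF")
        assert not out["trimmed_TF"].any()

    def test_constant_channel_normalizes_to_zero(self, caplog):
        with caplog.at_level("WARNING"):
            out = normalize_and_trim(_records([5.0, 5.0, 5.0]), "TF")
        assert (out["norm_TF"] == 0).all()
        assert "constant" in caplog.text

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=2, max_value=2000),
        frac=st.floats(min_value=0.0, max_value=0.02),
    )
    def test_trim_count_invariant(self, n, frac):
        rng = np.random.default_rng(n)
        out = normalize_and_trim(_records(rng.normal(size=n) * 100), "TF", trim_fraction=frac)
        k = int(np.floor(frac * n + 0.5))
        assert out["trimmed_TF"].sum() == min(2 * k, n)

    def test_normalization_is_rank_preserving(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=50)
        out = normalize_and_trim(_records(vals), "TF")
        assert (np.argsort(out["norm_TF"]) == np.argsort(vals)).all()


class TestClassifyAndCall:
    def _norm_records(self, vals, channel):
        recs = _records(vals, channel)
        return normalize_and_trim(recs, channel)

    def test_sox2_presence_means_progenitor(self):
        recs = self._norm_records([0.0, 9.0, 10.0], "Sox2")
        out = classify_cells(recs, "Sox2", "sox2_absence")
        assert list(out["cell_class"]) == ["neuron", "progenitor", "progenitor"]

    def test_huc_presence_means_neuron(self):
        recs = self._norm_records([0.0, 9.0, 10.0], "HuC")
        out = classify_cells(recs, "HuC", "huc_presence")
        assert list(out["cell_class"]) == ["progenitor", "neuron", "neuron"]

    def test_class_boundary_is_strict(self):
        recs = pd.DataFrame({"norm_HuC": [0.25, 0.2500001]})
        out = classify_cells(recs, "HuC", "huc_presence")
        assert list(out["cell_class"]) == ["progenitor", "neuron"]

    def test_unknown_mode_rejected(self):
        recs = pd.DataFrame({"norm_HuC": [0.5]})
        with pytest.raises(ValueError, match="mode"):
            classify_cells(recs, "HuC", "huc_always")

    def test_unnormalized_class_channel_rejected(self):
        with pytest.raises(ValueError, match="not normalized"):
            classify_cells(_records([1.0], "HuC"), "HuC")

    def test_positive_boundary_is_strict(self):
        recs = pd.DataFrame(
            {"norm_TF": [0.25, 0.26, 0.9], "trimmed_TF": [False, False, True]}
        )
        out = call_positive(recs, "TF", threshold=0.25)
        # exactly 0.25 is negative; trimmed records are never positive
        assert list(out["positive_TF"]) == [False, True, False]

    def test_call_requires_normalization(self):
        with pytest.raises(ValueError, match="not normalized"):
            call_positive(_records([1.0]), "TF")

    def test_positivity_invariant_to_affine_rescale(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=400) * 50 + 200
        a = call_positive(normalize_and_trim(_records(vals), "TF"), "TF")
        b = call_positive(normalize_and_trim(_records(vals * 3.7 + 11.0), "TF"), "TF")
        assert (a["positive_TF"] == b["positive_TF"]).all()
        assert (a["trimmed_TF"] == b["trimmed_TF"]).all()


def _coloc_records(rows):
    return pd.DataFrame(
        rows,
        columns=["cell_class", "trimmed_TF", "trimmed_EdU", "positive_TF", "positive_EdU"],
    )


class TestColocalization:
    def test_four_of_five_double_positive(self):
        rows = [("neuron", False, False, tf, True) for tf in (True, True, True, True, False)]
        res = colocalization_fraction(_coloc_records(rows), "TF")
        assert (res.n_edu_pos_neurons, res.n_double_pos) == (5, 4)
        assert res.percent == pytest.approx(80.0)

    def test_extremes_and_undefined(self):
        none_pos = [("neuron", False, False, False, True)] * 3
        assert colocalization_fraction(_coloc_records(none_pos), "TF").percent == 0.0
        all_pos = [("neuron", False, False, True, True)] * 3
        assert colocalization_fraction(_coloc_records(all_pos), "TF").percent == 100.0
        res = colocalization_fraction(_coloc_records([("neuron", False, False, True, False)]), "TF")
        assert res.undefined and res.percent == 0.0

    def test_progenitors_and_trimmed_cells_excluded(self):
        rows = [
            ("neuron", False, False, True, True),
            ("progenitor", False, False, True, True),  # not a neuron
            ("neuron", True, False, True, True),        # trimmed on TF
            ("neuron", False, False, False, True),
        ]
        res = colocalization_fraction(_coloc_records(rows), "TF")
        assert (res.n_edu_pos_neurons, res.n_double_pos) == (2, 1)

    def test_adding_double_positive_never_decreases_percent(self):
        rng = np.random.default_rng(1)
        rows = [
            ("neuron", False, False, bool(rng.random() < 0.5), bool(rng.random() < 0.7))
            for _ in range(50)
        ]
        base = colocalization_fraction(_coloc_records(rows), "TF").percent
        grown = colocalization_fraction(
            _coloc_records(rows + [("neuron", False, False, True, True)]), "TF"
        ).percent
        assert grown >= base


class TestEndToEndRecovery:
    def test_pipeline_percent_tracks_ground_truth(self, program):
        # averaged over seeds, pipeline estimate within 5 points of truth
        diffs = []
        for seed in range(5):
            spec = synthdata.SectionSpec(edu_pulse_day=11.5, tf_channel="Nfib")
            image, truth = synthdata.generate_section(spec, program, seed)
            _, res = imagequant.quantify_section(image, edu_day=11.5)
            neurons = truth[truth["cell_class"] == "neuron"]
            edu_pos = neurons[neurons["edu_true"]]
            truth_pct = 100.0 * edu_pos["tf_Nfib"].mean() if len(edu_pos) else 0.0
            diffs.append(res.percent - truth_pct)
        assert abs(np.mean(diffs)) <= 5.0
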