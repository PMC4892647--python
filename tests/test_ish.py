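"""ISH pixel classification, area accounting, ROI filtering, signal selection."""

import numpy as np
import pandas as pd
import pytest

from mirhet.ish import (
    CLASS_NAMES,
    DEFAULT_CENTROIDS,
    ColorClassConfig,
    IshInputError,
    IshQuantRecord,
    apply_roi_filter,
    classify_pixels,
    compute_area_fractions,
    quantify_image,
    records_from_table,
    select_signal_fraction,
)
from mirhet.simulate import gen_ish_image


def _uniform(color, shape=(20, 20)):
    img = np.empty(shape + (3,), dtype=np.uint8)
    img[...] = color
    return img


FULL = np.ones((20, 20), dtype=bool)


@pytest.mark.parametrize("cls", CLASS_NAMES)
def test_centroid_self_assignment(cls):
    """A uniform image at a class centroid is labelled 100% that class."""
    labels = classify_pixels(_uniform(DEFAULT_CENTROIDS[cls]), FULL)
    assert (labels == CLASS_NAMES.index(cls)).all()


def test_tissue_free_image_has_no_blue():
    labels = classify_pixels(_uniform(DEFAULT_CENTROIDS["tissue_free"]), FULL)
    record = compute_area_fractions(labels, FULL, 1.0)
    assert record.fraction_TBp == 0.0


def test_composed_image_proportions_match_generator_truth():
    """10%/20%/70% centroid-coloured pixels recover those proportions."""
    rng = np.random.default_rng(0)
    n = 100 * 100
    assignment = rng.permutation(
        [0] * (n // 10) + [1] * (n // 5) + [3] * (n - n // 10 - n // 5)
    )
    colors = np.array(
        [DEFAULT_CENTROIDS[c] for c in ("iB", "wB", "pB", "nuclear_red")],
        dtype=np.uint8,
    )
    img = colors[assignment].reshape(100, 100, 3)
    mask = np.ones((100, 100), dtype=bool)
    labels = classify_pixels(img, mask)
    in_roi = labels[mask]
    assert (in_roi == 0).mean() == pytest.approx(0.10)
    assert (in_roi == 1).mean() == pytest.approx(0.20)
    assert (in_roi == 3).mean() == pytest.approx(0.70)


def test_classifier_input_validation():
    img = _uniform(DEFAULT_CENTROIDS["iB"])
    with pytest.raises(IshInputError, match="foreground"):
        classify_pixels(img, np.zeros((20, 20), dtype=bool))
    with pytest.raises(IshInputError, match="dimensions"):
        classify_pixels(img, np.ones((10, 10), dtype=bool))


def test_area_fraction_arithmetic():
    """1 Mpx ROI at 1 um/px with 150k blue pixels: 1 mm^2 ROI, TBp 0.15."""
    labels = np.full((1000, 1000), CLASS_NAMES.index("nuclear_red"), dtype=np.int16)
    labels.ravel()[:150_000] = CLASS_NAMES.index("wB")
    mask = np.ones((1000, 1000), dtype=bool)
    record = compute_area_fractions(labels, mask, pixel_size_um=1.0)
    assert record.roi_area == pytest.approx(1.0)
    assert record.fraction_TBp == pytest.approx(0.15)
    assert record.fraction_iB == 0.0


def test_all_intense_blue_extremes():
    labels = np.full((10, 10), CLASS_NAMES.index("iB"), dtype=np.int16)
    mask = np.ones((10, 10), dtype=bool)
    record = compute_area_fractions(labels, mask, 1.0)
    assert record.fraction_TBp == 1.0
    assert record.fraction_iB == 1.0
    assert record.fraction_wpB == 0.0


def test_fraction_scale_invariance():
    """Fractions do not depend on the physical pixel size."""
    img, mask, _ = gen_ish_image({"iB": 0.08, "wB": 0.04}, size=(80, 80), rng=5)
    small = quantify_image(img, mask, pixel_size_um=0.22)
    large = quantify_image(img, mask, pixel_size_um=2.0)
    assert small.fraction_TBp == pytest.approx(large.fraction_TBp)
    assert small.fraction_iB == pytest.approx(large.fraction_iB)
    assert small.roi_area != large.roi_area


def test_blue_area_conservation():
    """fraction_iB plus the wB+pB share equals fraction_TBp exactly."""
    img, mask, _ = gen_ish_image(
        {"iB": 0.05, "wB": 0.10, "pB": 0.02}, size=(100, 100), rng=9
    )
    record = quantify_image(img, mask, pixel_size_um=1.0)
    assert record.fraction_iB + record.fraction_wpB == pytest.approx(
        record.fraction_TBp, abs=1e-15
    )


def test_artefact_mask_is_cut_from_roi():
    img = _uniform(DEFAULT_CENTROIDS["iB"], (20, 20))
    artefact = np.zeros((20, 20), dtype=bool)
    artefact[:10] = True
    record = quantify_image(img, FULL, pixel_size_um=1.0, artefact_mask=artefact)
    assert record.roi_area == pytest.approx(200 * 1e-6)
    assert record.fraction_iB == 1.0


def _record(roi_area, mirna="miR-21", patient="P1", sample="S1", tbp=0.1, ib=0.02):
    wpb = tbp - ib
    return IshQuantRecord(
        patient_id=patient, sample_id=sample, mirna_id=mirna,
        area_iB=ib * roi_area, area_wB=0.7 * wpb * roi_area,
        area_pB=0.3 * wpb * roi_area, roi_area=roi_area,
    )


def test_roi_filter_boundary_convention():
    records, report = apply_roi_filter(
        [_record(1.9, patient="P1"), _record(2.0, patient="P2"),
         _record(5.0, patient="P3")],
        min_area=2.0,
    )
    flags = {r.patient_id: r.excluded for r in records}
    assert flags == {"P1": True, "P2": False, "P3": False}
    assert records[0].exclusion_reason == "small_roi"
    row = report.set_index("mirna_id").loc["miR-21"]
    assert row["n_patients_excluded"] == 1
    assert row["excluded_patients"] == "P1"


def test_roi_filter_no_exclusions():
    records, report = apply_roi_filter([_record(3.0), _record(4.0)], 2.0)
    assert not any(r.excluded for r in records)
    assert report["n_patients_excluded"].sum() == 0


@pytest.mark.parametrize(
    "mirna, purpose, tbp, ib, expected",
    [
        ("miR-125b", "icc", 0.05, 0.002, 0.048),   # wpB rule for miR-125b
        ("miR-21", "icc", 0.30, 0.06, 0.30),       # TBp for the others
        ("miR-125b", "concordance", 0.05, 0.002, 0.05),  # TBp cross-modality
    ],
)
def test_select_signal_fraction_rules(mirna, purpose, tbp, ib, expected):
    record = _record(4.0, mirna=mirna, tbp=tbp, ib=ib)
    assert select_signal_fraction(record, purpose) == pytest.approx(expected)


def test_select_signal_fraction_refuses_excluded_record():
    (record,), _ = apply_roi_filter([_record(1.0)], 2.0)
    with pytest.raises(IshInputError, match="excluded"):
        select_signal_fraction(record, "icc")


def test_tabular_bypass_roundtrip():
    table = pd.DataFrame(
        {
            "patient_id": ["P1"], "sample_id": ["S1"], "mirna_id": ["miR-145"],
            "area_iB": [0.05], "area_wB": [0.2], "area_pB": [0.05],
            "roi_area_mm2": [5.0],
        }
    )
    (record,) = records_from_table(table)
    assert record.fraction_TBp == pytest.approx(0.06)
    with pytest.raises(IshInputError, match="missing columns"):
        records_from_table(table.drop(columns=["roi_area_mm2"]))


def test_record_invariants_enforced():
    with pytest.raises(IshInputError):
        IshQuantRecord("P", "S", "m", area_iB=0.1, area_wB=0.0, area_pB=0.0,
                       roi_area=0.0)
    with pytest.raises(IshInputError):
        IshQuantRecord("P", "S", "m", area_iB=3.0, area_wB=0.0, area_pB=0.0,
                       roi_area=1.0)


def test_fitted_centroids_classify_their_own_samples():
    rng = np.random.default_rng(1)
    samples = {
        "iB": np.clip(np.array(DEFAULT_CENTROIDS["iB"]) + rng.normal(0, 3, (50, 3)),
                      0, 255),
    }
    config = ColorClassConfig.fit_from_samples(samples)
    labels = classify_pixels(_uniform(config.centroids["iB"]), FULL, config)
    assert (labels == CLASS_NAMES.index("iB")).all()
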