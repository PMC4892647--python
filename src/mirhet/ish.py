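"""Chromogenic ISH quantification by colour-class area fractions.

A pathologist-marked region of interest (ROI) in an NBT/BCIP-stained,
nuclear-fast-red-counterstained section is partitioned into six pixel
classes: intense blue (iB, the strong hybridization signal), weak blue
(wB, background-level signal), purple blue (pB, blue over nuclear red),
nuclear red counterstain, unstained tissue, and tissue-free glass.

The expression estimate is an area fraction — classified blue area over
total ROI area:

    TBp  = (iB + wB + pB) / ROI        all blue colours
    wpB  = TBp - iB/ROI                blue excluding the intense class

wpB exists because for miR-125b the intense-blue class marks enteric
neurons, present regardless of cancer, and is therefore excluded from
the reliability analysis of that probe; cross-modality comparison always
uses TBp since RT-qPCR measures total expression regardless of
localisation.

Classification is a deterministic nearest-centroid rule in a
hue-saturation-value embedding (hue handled circularly, weighted by
saturation so that grey/white pixels are matched on value alone).
Records can also be built directly from a pre-quantified area table,
bypassing images entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv

logger = logging.getLogger(__name__)

CLASS_NAMES = ("iB", "wB", "pB", "nuclear_red", "unstained", "tissue_free")
BLUE_CLASSES = ("iB", "wB", "pB")

#: default class centroids, RGB in 0-255
DEFAULT_CENTROIDS: dict[str, tuple[int, int, int]] = {
    "iB": (35, 45, 120),          # dark NBT/BCIP blue
    "wB": (150, 165, 215),        # pale blue haze
    "pB": (110, 70, 145),         # blue over nuclear red
    "nuclear_red": (205, 95, 115),
    "unstained": (235, 226, 230),
    "tissue_free": (255, 255, 255),
}

#: ROI area below which a record is excluded from statistics (mm^2)
DEFAULT_MIN_ROI_MM2 = 2.0

#: micrometres per pixel of a typical x20 brightfield scan
DEFAULT_PIXEL_SIZE_UM = 0.22

#: miRNA whose reliability analysis uses wpB instead of TBp
WPB_MIRNA = "miR-125b"


class IshInputError(ValueError):
    """Raised for malformed images, masks or quantification tables."""


@dataclass(frozen=True)
class ColorClassConfig:
    """Per-class RGB centroids (+ optional distance scale) for pixel labelling.

    Assignment is nearest-centroid, so classes are exhaustive and
    mutually exclusive; ``tolerances`` rescale per-class distances
    (a larger tolerance makes a class 'wider').
    """

    centroids: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_CENTROIDS)
    )
    tolerances: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(CLASS_NAMES) - set(self.centroids)
        if missing:
            raise IshInputError(f"missing colour-class centroids: {sorted(missing)}")

    def class_names(self) -> tuple[str, ...]:
        return CLASS_NAMES

    @classmethod
    def fit_from_samples(cls, labelled_pixels: dict[str, np.ndarray]) -> "ColorClassConfig":
        """Build centroids as the per-class mean RGB of labelled pixel samples."""
        centroids = dict(DEFAULT_CENTROIDS)
        for name, pixels in labelled_pixels.items():
            if name not in CLASS_NAMES:
                raise IshInputError(f"unknown colour class {name!r}")
            arr = np.asarray(pixels, dtype=float).reshape(-1, 3)
            centroids[name] = tuple(np.round(arr.mean(axis=0)).astype(int))
        return cls(centroids=centroids)


def _hsv_embed(rgb: np.ndarray) -> np.ndarray:
    """Map RGB (0-255) to a 3-feature space where Euclidean distance is
    meaningful: saturation-weighted circular hue (2 dims) plus value."""
    hsv = rgb2hsv(np.asarray(rgb, dtype=np.uint8))
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    return np.stack(
        [s * np.cos(2 * np.pi * h), s * np.sin(2 * np.pi * h), v], axis=-1
    )


def classify_pixels(
    image: np.ndarray,
    roi_mask: np.ndarray,
    config: ColorClassConfig | None = None,
) -> np.ndarray:
    """Assign every ROI pixel to one colour class.

    Returns an int label raster (indices into ``CLASS_NAMES``); pixels
    outside the ROI are -1. Deterministic given the config.
    """
    config = config or ColorClassConfig()
    image = np.asarray(image)
    roi_mask = np.asarray(roi_mask).astype(bool)
    if image.shape[:2] != roi_mask.shape:
        raise IshInputError(
            f"image {image.shape[:2]} and ROI mask {roi_mask.shape} dimensions differ"
        )
    if not roi_mask.any():
        raise IshInputError("ROI mask has no foreground pixels")

    feats = _hsv_embed(image[roi_mask])
    centroid_feats = _hsv_embed(
        np.array([config.centroids[c] for c in CLASS_NAMES], dtype=np.uint8).reshape(
            -1, 1, 3
        )
    ).reshape(-1, 3)
    scales = np.array([config.tolerances.get(c, 1.0) for c in CLASS_NAMES])
    dists = np.linalg.norm(feats[:, None, :] - centroid_feats[None, :, :], axis=2)
    labels_in_roi = np.argmin(dists / scales[None, :], axis=1)

    labels = np.full(roi_mask.shape, -1, dtype=np.int16)
    labels[roi_mask] = labels_in_roi
    return labels


@dataclass(frozen=True)
class IshQuantRecord:
    """Per-ROI class areas and derived signal fractions for one sample."""

    patient_id: str
    sample_id: str
    mirna_id: str
    area_iB: float          # mm^2
    area_wB: float
    area_pB: float
    roi_area: float
    deepest: bool = False
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.roi_area <= 0:
            raise IshInputError(
                f"{self.patient_id}/{self.sample_id}/{self.mirna_id}: "
                f"ROI area must be > 0, got {self.roi_area}"
            )
        for name, a in (("iB", self.area_iB), ("wB", self.area_wB),
                        ("pB", self.area_pB)):
            if a < 0:
                raise IshInputError(f"negative {name} area: {a}")
        if self.area_iB + self.area_wB + self.area_pB > self.roi_area * (1 + 1e-9):
            raise IshInputError("blue areas exceed ROI area")

    @property
    def fraction_TBp(self) -> float:
        return (self.area_iB + self.area_wB + self.area_pB) / self.roi_area

    @property
    def fraction_iB(self) -> float:
        return self.area_iB / self.roi_area

    @property
    def fraction_wpB(self) -> float:
        return self.fraction_TBp - self.fraction_iB


def compute_area_fractions(
    labels: np.ndarray,
    roi_mask: np.ndarray,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    *,
    patient_id: str = "",
    sample_id: str = "",
    mirna_id: str = "",
    deepest: bool = False,
) -> IshQuantRecord:
    """Turn a label raster into class areas (mm^2) and signal fractions."""
    if pixel_size_um <= 0:
        raise IshInputError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    roi_mask = np.asarray(roi_mask).astype(bool)
    n_roi = int(roi_mask.sum())
    if n_roi == 0:
        raise IshInputError("ROI has zero area")
    px_mm2 = (pixel_size_um / 1000.0) ** 2
    in_roi = np.asarray(labels)[roi_mask]
    counts = {
        name: int((in_roi == i).sum()) for i, name in enumerate(CLASS_NAMES)
    }
    return IshQuantRecord(
        patient_id=patient_id,
        sample_id=sample_id,
        mirna_id=mirna_id,
        area_iB=counts["iB"] * px_mm2,
        area_wB=counts["wB"] * px_mm2,
        area_pB=counts["pB"] * px_mm2,
        roi_area=n_roi * px_mm2,
        deepest=deepest,
    )


def quantify_image(
    image: np.ndarray,
    roi_mask: np.ndarray,
    config: ColorClassConfig | None = None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    artefact_mask: np.ndarray | None = None,
    **ids,
) -> IshQuantRecord:
    """Classify then quantify; an optional artefact mask is cut out of the ROI."""
    roi_mask = np.asarray(roi_mask).astype(bool)
    if artefact_mask is not None:
        artefact_mask = np.asarray(artefact_mask).astype(bool)
        if artefact_mask.shape != roi_mask.shape:
            raise IshInputError("artefact mask dimensions differ from ROI mask")
        roi_mask = roi_mask & ~artefact_mask
    labels = classify_pixels(image, roi_mask, config)
    return compute_area_fractions(labels, roi_mask, pixel_size_um, **ids)


def apply_roi_filter(
    records: list[IshQuantRecord],
    min_area: float = DEFAULT_MIN_ROI_MM2,
) -> tuple[list[IshQuantRecord], pd.DataFrame]:
    """Flag records whose ROI is smaller than ``min_area`` mm^2.

    Exclusion is strict (< min_area); a ROI of exactly the minimum is
    retained. Also returns a per-miRNA patient-exclusion report: a
    patient drops out of a miRNA's analysis when any of their samples
    is excluded for it.
    """
    if min_area <= 0:
        raise IshInputError(f"min_area must be > 0, got {min_area}")
    out: list[IshQuantRecord] = []
    for r in records:
        if r.roi_area < min_area:
            out.append(replace(r, excluded=True, exclusion_reason="small_roi"))
            logger.info(
                "excluded %s/%s/%s: ROI %.3f mm^2 < %.3f",
                r.patient_id, r.sample_id, r.mirna_id, r.roi_area, min_area,
            )
        else:
            out.append(r)
    rows = []
    for mirna in sorted({r.mirna_id for r in out}):
        excluded_patients = sorted(
            {r.patient_id for r in out if r.mirna_id == mirna and r.excluded}
        )
        rows.append((mirna, len(excluded_patients), ";".join(excluded_patients)))
    report = pd.DataFrame(
        rows, columns=["mirna_id", "n_patients_excluded", "excluded_patients"]
    )
    return out, report


def select_signal_fraction(record: IshQuantRecord, purpose: str) -> float:
    """Pick the analysis fraction for a record.

    ``purpose="icc"``: wpB for the wpB-designated miRNA (miR-125b, to
    exclude enteric-neuron signal), TBp otherwise. ``purpose=
    "concordance"``: TBp always, matching what RT-qPCR measures.
    """
    if record.excluded:
        raise IshInputError(
            f"record {record.patient_id}/{record.sample_id}/{record.mirna_id} "
            f"is excluded ({record.exclusion_reason})"
        )
    if purpose == "icc":
        return record.fraction_wpB if record.mirna_id == WPB_MIRNA else record.fraction_TBp
    if purpose == "concordance":
        return record.fraction_TBp
    raise IshInputError(f"unknown purpose {purpose!r}")


def records_from_table(table: pd.DataFrame) -> list[IshQuantRecord]:
    """Tabular bypass: build records from a pre-quantified area table
    (columns patient_id, sample_id, mirna_id, area_iB, area_wB, area_pB,
    roi_area_mm2 and optionally deepest_flag)."""
    required = {"patient_id", "sample_id", "mirna_id",
                "area_iB", "area_wB", "area_pB", "roi_area_mm2"}
    missing = required - set(table.columns)
    if missing:
        raise IshInputError(f"ISH table missing columns: {sorted(missing)}")
    records = []
    for _, row in table.iterrows():
        records.append(
            IshQuantRecord(
                patient_id=str(row["patient_id"]),
                sample_id=str(row["sample_id"]),
                mirna_id=str(row["mirna_id"]),
                area_iB=float(row["area_iB"]),
                area_wB=float(row["area_wB"]),
                area_pB=float(row["area_pB"]),
                roi_area=float(row["roi_area_mm2"]),
                deepest=bool(row.get("deepest_flag", False)),
            )
        )
    return records


def records_to_frame(records: list[IshQuantRecord]) -> pd.DataFrame:
    rows = [
        (r.patient_id, r.sample_id, r.mirna_id, r.deepest,
         r.area_iB, r.area_wB, r.area_pB, r.roi_area,
         r.fraction_TBp, r.fraction_iB, r.fraction_wpB,
         r.excluded, r.exclusion_reason)
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["patient_id", "sample_id", "mirna_id", "deepest",
                 "area_iB", "area_wB", "area_pB", "roi_area_mm2",
                 "fraction_TBp", "fraction_iB", "fraction_wpB",
                 "excluded", "exclusion_reason"],
    )
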