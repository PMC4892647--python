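"""Cross-modality concordance between RT-qPCR and ISH.

Per miRNA, the agreement between the two expression estimates (linear
2^-dCq values and TBp area fractions) is quantified with Spearman rank
correlation on paired patient values, under two aggregations: the mean
of the available samples per patient, and the single section containing
the deepest part of the tumour. Patients missing either modality are
dropped from the pairing and counted.

Also provides the common-scale z-normalisation (per miRNA x modality)
used to plot both modalities on one axis, and the corresponding
range-plot (one vertical line per patient spanning their three
measurements, both modalities side by side).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ish import IshQuantRecord, select_signal_fraction

logger = logging.getLogger(__name__)


class ConcordanceInputError(ValueError):
    pass


@dataclass
class PairedSeries:
    """Complete (qPCR, ISH) pairs for one miRNA under one aggregation."""

    mirna_id: str
    aggregation: str  # "patient_mean" or "deepest_section"
    patient_ids: list[str]
    qpcr_values: np.ndarray
    ish_values: np.ndarray
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return len(self.patient_ids)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN ("undefined") when either vector has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConcordanceInputError("x and y must be 1-d and of equal length")
    if len(x) < 3:
        raise ConcordanceInputError(f"need n >= 3 pairs, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ConcordanceInputError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    return float(stats.spearmanr(x, y).statistic)


def aggregate_pairs(
    qpcr: pd.DataFrame,
    ish_records: list[IshQuantRecord],
    mode: str,
    mirna_id: str,
) -> PairedSeries:
    """Pair per-patient qPCR and ISH values for one miRNA.

    ``qpcr`` is a tidy expression frame (patient_id, sample_id, mirna_id,
    deepest, linear_value). The ISH side always uses the TBp fraction.
    ``mode="patient_mean"`` averages available samples per patient;
    ``mode="deepest_section"`` takes the deepest-flagged sample, dropping
    (with a warning) patients without one.
    """
    if mode not in ("patient_mean", "deepest_section"):
        raise ConcordanceInputError(f"unknown aggregation mode {mode!r}")

    q = qpcr[qpcr["mirna_id"] == mirna_id]
    usable_ish = [
        r for r in ish_records if r.mirna_id == mirna_id and not r.excluded
    ]

    def one_patient(patient: str, modality: str) -> float | None:
        if modality == "qpcr":
            sub = q[q["patient_id"] == patient]
            if mode == "deepest_section":
                sub = sub[sub["deepest"]]
            values = sub["linear_value"].to_numpy()
        else:
            recs = [r for r in usable_ish if r.patient_id == patient]
            if mode == "deepest_section":
                recs = [r for r in recs if r.deepest]
            values = np.array(
                [select_signal_fraction(r, "concordance") for r in recs]
            )
        if len(values) == 0:
            return None
        return float(values.mean())

    patients = sorted(
        set(q["patient_id"]) | {r.patient_id for r in usable_ish}
    )
    kept, qv, iv, dropped = [], [], [], 0
    for patient in patients:
        a = one_patient(patient, "qpcr")
        b = one_patient(patient, "ish")
        if a is None or b is None:
            dropped += 1
            logger.info(
                "%s %s: patient %s dropped from pairing (qpcr=%s, ish=%s)",
                mirna_id, mode, patient, a is not None, b is not None,
            )
            continue
        kept.append(patient)
        qv.append(a)
        iv.append(b)
    return PairedSeries(
        mirna_id=mirna_id,
        aggregation=mode,
        patient_ids=kept,
        qpcr_values=np.array(qv),
        ish_values=np.array(iv),
        n_dropped=dropped,
    )


def concordance_report(
    qpcr: pd.DataFrame, ish_records: list[IshQuantRecord], mirnas: list[str]
) -> pd.DataFrame:
    """One row per miRNA: rho for patient means and for deepest sections."""
    rows = []
    for mirna in mirnas:
        row: dict = {"mirna_id": mirna}
        for mode, col in (
            ("patient_mean", "rho_mean"),
            ("deepest_section", "rho_deepest"),
        ):
            try:
                pairs = aggregate_pairs(qpcr, ish_records, mode, mirna)
                row[col] = spearman_rho(pairs.qpcr_values, pairs.ish_values)
                row[f"n_{mode}"] = pairs.n
                row[f"dropped_{mode}"] = pairs.n_dropped
            except ConcordanceInputError as err:
                row[col] = math.nan
                row[f"n_{mode}"] = 0
                row[f"dropped_{mode}"] = 0
                logger.warning("%s %s: %s", mirna, mode, err)
        rows.append(row)
    return pd.DataFrame(rows)


def common_scale_normalise(values) -> np.ndarray:
    """z-score one miRNA x modality's measurements onto the common plot scale.

    Subtracts the mean over all of that series' measurements and divides
    by the sample SD (n-1); errors on zero spread.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ConcordanceInputError("need >= 2 values to standardise")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ConcordanceInputError("zero spread: cannot standardise constant values")
    return (arr - arr.mean()) / sd


def standardized_long_table(
    qpcr: pd.DataFrame, ish_records: list[IshQuantRecord]
) -> pd.DataFrame:
    """Tidy per-sample standardized values for both modalities, for plotting."""
    frames = []
    for mirna, sub in qpcr.groupby("mirna_id"):
        z = common_scale_normalise(sub["linear_value"].to_numpy())
        frames.append(
            pd.DataFrame(
                {
                    "mirna_id": mirna,
                    "modality": "qpcr",
                    "patient_id": sub["patient_id"].to_numpy(),
                    "sample_id": sub["sample_id"].to_numpy(),
                    "z_value": z,
                }
            )
        )
    usable = [r for r in ish_records if not r.excluded]
    by_mirna: dict[str, list[IshQuantRecord]] = {}
    for r in usable:
        by_mirna.setdefault(r.mirna_id, []).append(r)
    for mirna, recs in sorted(by_mirna.items()):
        values = np.array([select_signal_fraction(r, "concordance") for r in recs])
        z = common_scale_normalise(values)
        frames.append(
            pd.DataFrame(
                {
                    "mirna_id": mirna,
                    "modality": "ish",
                    "patient_id": [r.patient_id for r in recs],
                    "sample_id": [r.sample_id for r in recs],
                    "z_value": z,
                }
            )
        )
    return pd.concat(frames, ignore_index=True).sort_values(
        ["mirna_id", "modality", "patient_id", "sample_id"], ignore_index=True
    )


def range_plot(standardized: pd.DataFrame, mirna_id: str, ax=None):
    """Per-patient vertical range lines of standardized values, two
    modalities side by side, patients sorted by their mean qPCR value."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    sub = standardized[standardized["mirna_id"] == mirna_id]
    order = (
        sub[sub["modality"] == "qpcr"]
        .groupby("patient_id")["z_value"]
        .mean()
        .sort_values()
        .index.tolist()
    )
    colors = {"qpcr": "tab:blue", "ish": "tab:orange"}
    offsets = {"qpcr": -0.15, "ish": 0.15}
    for modality, g in sub.groupby("modality"):
        for i, patient in enumerate(order):
            vals = g.loc[g["patient_id"] == patient, "z_value"]
            if vals.empty:
                continue
            x = i + offsets[modality]
            ax.vlines(x, vals.min(), vals.max(), color=colors[modality], lw=2)
            ax.plot([x] * len(vals), vals, ".", color=colors[modality], ms=3)
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels(order, rotation=90, fontsize=6)
    ax.set_xlabel("patient (sorted by mean qPCR)")
    ax.set_ylabel("standardized expression")
    ax.set_title(mirna_id)
    handles = [
        __import__("matplotlib.lines", fromlist=["Line2D"]).Line2D(
            [], [], color=c, lw=2, label=m
        )
        for m, c in colors.items()
    ]
    ax.legend(handles=handles, frameon=False)
    return ax
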