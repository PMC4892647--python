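"""RT-qPCR relative quantification.

Turns raw triplicate Cq measurements into normalised linear expression
values per patient x sample x miRNA.

Cq (quantification cycle) is the PCR cycle at which the fluorescence
signal crosses the detection threshold: lower Cq means more template.
Relative quantification follows the standard comparative-Cq scheme with
a multi-reference normaliser:

    mean Cq     arithmetic mean of the (outlier-filtered) triplicate
    dCq         target mean Cq minus the arithmetic mean of the three
                reference-miRNA mean Cqs
    linear      2 ** (-dCq), assuming ~100% amplification efficiency

An all-undetected triplicate yields no expression record; the omission
is reported, never silently dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: reference miRNAs whose arithmetic-mean Cq is the normaliser
DEFAULT_NORMALISERS = ("miR-193a-5p", "miR-27a", "let-7g")

#: panel of target miRNAs quantified against the normaliser mean
DEFAULT_TARGETS = ("miR-21", "miR-31", "miR-125b", "miR-145", "miR-630")

#: maximum |Cq - triplicate median| before a replicate is dropped (cycles)
DEFAULT_OUTLIER_THRESHOLD = 0.5


class QpcrInputError(ValueError):
    """Raised for malformed Cq input (non-finite values, duplicate keys)."""


@dataclass(frozen=True)
class CqTriplicate:
    """One miRNA x patient x sample measurement with up to 3 replicates.

    ``replicate_cqs`` holds only the *detected* replicate values; an
    all-undetected triplicate has an empty tuple. ``deepest`` flags the
    tumour section containing the deepest invasive part, used downstream
    for single-sample concordance.
    """

    patient_id: str
    sample_id: str
    mirna_id: str
    replicate_cqs: tuple[float, ...]
    deepest: bool = False

    def __post_init__(self) -> None:
        if len(self.replicate_cqs) > 3:
            raise QpcrInputError(
                f"{self.key}: more than 3 replicates ({len(self.replicate_cqs)})"
            )
        for cq in self.replicate_cqs:
            if not math.isfinite(cq) or cq <= 0:
                raise QpcrInputError(
                    f"{self.key}: detected Cq must be finite and > 0, got {cq!r}"
                )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.patient_id, self.sample_id, self.mirna_id)

    @property
    def n_detected(self) -> int:
        return len(self.replicate_cqs)


@dataclass(frozen=True)
class QpcrExpression:
    """Normalised expression for one target miRNA in one tumour sample."""

    patient_id: str
    sample_id: str
    mirna_id: str
    mean_cq: float
    delta_cq: float
    linear_value: float
    deepest: bool = False


@dataclass
class ExpressionTable:
    """Result bundle of :func:`build_expression_table`."""

    records: list[QpcrExpression]
    #: (patient, sample, mirna, reason) for every omitted target measurement
    exclusions: list[tuple[str, str, str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = ["patient_id", "sample_id", "mirna_id", "deepest",
                "mean_cq", "delta_cq", "linear_value"]
        rows = [
            (r.patient_id, r.sample_id, r.mirna_id, r.deepest,
             r.mean_cq, r.delta_cq, r.linear_value)
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=cols)

    def exclusions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.exclusions,
            columns=["patient_id", "sample_id", "mirna_id", "reason"],
        )


def aggregate_triplicate(
    triplicate: CqTriplicate | tuple[float, ...],
    outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD,
) -> float | None:
    """Collapse a triplicate to its mean Cq, or ``None`` when undetected.

    With >= 2 detected replicates, a single replicate deviating from the
    triplicate median by more than ``outlier_threshold`` cycles is
    removed (the worst one, and at most one) before averaging. A lone
    detected replicate is returned as-is; no detected replicates yields
    ``None`` ("undetected").
    """
    if outlier_threshold <= 0:
        raise QpcrInputError(f"outlier_threshold must be > 0, got {outlier_threshold}")
    cqs = (
        triplicate.replicate_cqs
        if isinstance(triplicate, CqTriplicate)
        else tuple(triplicate)
    )
    if any(not math.isfinite(c) for c in cqs):
        raise QpcrInputError(f"non-finite Cq among detected replicates: {cqs}")
    if len(cqs) == 0:
        return None
    if len(cqs) == 1:
        return float(cqs[0])
    values = np.asarray(cqs, dtype=float)
    deviations = np.abs(values - np.median(values))
    if deviations.max() > outlier_threshold:
        # drop the single worst replicate; ties in deviation are broken
        # by Cq value so the rule is permutation-invariant
        candidates = np.flatnonzero(deviations == deviations.max())
        worst = candidates[np.argmax(values[candidates])]
        values = np.delete(values, worst)
    return float(values.mean())


def normalise_delta_cq(target_cq: float, normaliser_cqs: tuple[float, ...]) -> float:
    """dCq = target mean Cq minus the arithmetic mean of the reference Cqs."""
    if not math.isfinite(target_cq):
        raise QpcrInputError(f"target Cq must be finite, got {target_cq!r}")
    for cq in normaliser_cqs:
        if cq is None or not math.isfinite(cq):
            raise QpcrInputError(f"missing/non-finite normaliser Cq: {normaliser_cqs}")
    return float(target_cq - np.mean(normaliser_cqs))


def linearise(delta_cq: float) -> float:
    """Convert dCq to the linear expression scale, 2**(-dCq)."""
    return float(2.0 ** (-delta_cq))


def build_expression_table(
    triplicates: list[CqTriplicate],
    outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD,
    normaliser_ids: tuple[str, ...] = DEFAULT_NORMALISERS,
) -> ExpressionTable:
    """Compose aggregation, normalisation and linearisation over a study.

    Every (patient, sample) must carry triplicates for all normaliser
    miRNAs; every other miRNA in the input is treated as a target.
    Undetected targets and non-normalisable samples are recorded in the
    exclusion list instead of producing expression records.
    """
    seen: set[tuple[str, str, str]] = set()
    for t in triplicates:
        if t.key in seen:
            raise QpcrInputError(f"duplicate (patient, sample, miRNA) key: {t.key}")
        seen.add(t.key)

    by_sample: dict[tuple[str, str], list[CqTriplicate]] = {}
    for t in triplicates:
        by_sample.setdefault((t.patient_id, t.sample_id), []).append(t)

    records: list[QpcrExpression] = []
    exclusions: list[tuple[str, str, str, str]] = []
    for (patient, sample), group in by_sample.items():
        means = {
            t.mirna_id: aggregate_triplicate(t, outlier_threshold) for t in group
        }
        deepest_flags = {t.mirna_id: t.deepest for t in group}
        missing_norm = [
            n for n in normaliser_ids if n not in means or means[n] is None
        ]
        if missing_norm:
            for t in group:
                if t.mirna_id in normaliser_ids:
                    continue
                exclusions.append(
                    (patient, sample, t.mirna_id,
                     f"non_normalisable:missing={','.join(missing_norm)}")
                )
            logger.warning(
                "sample %s/%s not normalisable (missing %s)",
                patient, sample, missing_norm,
            )
            continue
        norm_cqs = tuple(means[n] for n in normaliser_ids)
        for t in group:
            if t.mirna_id in normaliser_ids:
                continue
            mean_cq = means[t.mirna_id]
            if mean_cq is None:
                exclusions.append((patient, sample, t.mirna_id, "undetected"))
                logger.info("undetected: %s/%s %s", patient, sample, t.mirna_id)
                continue
            dcq = normalise_delta_cq(mean_cq, norm_cqs)
            records.append(
                QpcrExpression(
                    patient_id=patient,
                    sample_id=sample,
                    mirna_id=t.mirna_id,
                    mean_cq=mean_cq,
                    delta_cq=dcq,
                    linear_value=linearise(dcq),
                    deepest=deepest_flags[t.mirna_id],
                )
            )
    records.sort(key=lambda r: (r.patient_id, r.sample_id, r.mirna_id))
    exclusions.sort()
    return ExpressionTable(records=records, exclusions=exclusions)
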