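"""End-to-end heterogeneity analysis: tables in, reports out.

Composes the stages into the full study analysis and writes:

  expression.csv       normalised qPCR expression per patient/sample/miRNA
  ish_quant.csv        ISH class areas and fractions with exclusion flags
  icc_report.csv       per miRNA x modality reliability (single / mean-of-k)
  concordance.csv      per-miRNA cross-modality Spearman correlations
  standardized.csv     common-scale z values for joint plotting
  exclusions.csv       one row per excluded record with a reason code

The run is deterministic: rerunning on the same inputs and config gives
byte-identical reports.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import concordance, ish, qpcr, reliability
from .io import RunConfig, read_ish_table, read_qpcr_table, write_csv

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Aborts the run with the failing stage in the message."""


def build_sample_matrices(
    expression: pd.DataFrame,
    ish_records: list[ish.IshQuantRecord],
    target_mirnas: list[str] | None = None,
) -> list[reliability.SampleMatrix]:
    """Assemble per-miRNA x modality patient groups for the ICC analysis.

    qPCR uses linear values; ISH uses the reliability-purpose signal
    fraction (wpB for the iB-split miRNA, TBp otherwise). A patient with
    any excluded ISH sample for a miRNA is dropped entirely from that
    miRNA's ISH matrix, mirroring the per-patient exclusion rule.
    """
    matrices = []
    qpcr_mirnas = (
        target_mirnas
        if target_mirnas is not None
        else sorted(expression["mirna_id"].unique())
    )
    for mirna in qpcr_mirnas:
        sub = expression[expression["mirna_id"] == mirna]
        if sub.empty:
            continue
        groups = {
            patient: g["linear_value"].tolist()
            for patient, g in sub.groupby("patient_id")
        }
        matrices.append(
            reliability.SampleMatrix(
                mirna_id=mirna, modality="qpcr", groups=groups, signal_type="linear"
            )
        )
    ish_mirnas = sorted({r.mirna_id for r in ish_records})
    for mirna in ish_mirnas:
        recs = [r for r in ish_records if r.mirna_id == mirna]
        excluded_patients = {r.patient_id for r in recs if r.excluded}
        groups: dict[str, list[float]] = {}
        for r in recs:
            if r.patient_id in excluded_patients:
                continue
            groups.setdefault(r.patient_id, []).append(
                ish.select_signal_fraction(r, "icc")
            )
        matrices.append(
            reliability.SampleMatrix(
                mirna_id=mirna,
                modality="ish",
                groups=groups,
                signal_type="wpB" if mirna == ish.WPB_MIRNA else "TBp",
            )
        )
    return matrices


def run_pipeline(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full analysis and write all reports under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.verbose:
        logging.getLogger("mirhet").setLevel(logging.DEBUG)

    # --- qPCR stage -----------------------------------------------------
    try:
        triplicates = read_qpcr_table(cfg.qpcr_table)
        table = qpcr.build_expression_table(
            triplicates, outlier_threshold=cfg.outlier_threshold
        )
    except (ValueError, OSError) as err:
        raise PipelineError(f"qpcr stage: {err}") from err
    expression = table.to_frame()

    # --- ISH stage ------------------------------------------------------
    ish_records: list[ish.IshQuantRecord] = []
    roi_report = pd.DataFrame(
        columns=["mirna_id", "n_patients_excluded", "excluded_patients"]
    )
    if cfg.ish_table:
        try:
            ish_df = read_ish_table(cfg.ish_table)
            ish_records = ish.records_from_table(ish_df)
            ish_records, roi_report = ish.apply_roi_filter(
                ish_records, min_area=cfg.min_roi_mm2
            )
        except (ValueError, OSError) as err:
            raise PipelineError(f"ish stage: {err}") from err

    # --- exclusion log --------------------------------------------------
    exclusion_rows = [
        {"stage": "qpcr", "patient_id": p, "sample_id": s,
         "mirna_id": m, "reason": reason}
        for (p, s, m, reason) in table.exclusions
    ]
    exclusion_rows += [
        {"stage": "ish", "patient_id": r.patient_id, "sample_id": r.sample_id,
         "mirna_id": r.mirna_id, "reason": r.exclusion_reason}
        for r in ish_records if r.excluded
    ]
    exclusions = pd.DataFrame(
        exclusion_rows,
        columns=["stage", "patient_id", "sample_id", "mirna_id", "reason"],
    ).sort_values(["stage", "mirna_id", "patient_id", "sample_id"],
                  ignore_index=True)

    # --- reliability stage ----------------------------------------------
    try:
        qpcr_excl: dict[tuple[str, str], int] = {}
        for (_, _, m, reason) in table.exclusions:
            if reason == "undetected":
                qpcr_excl[(m, "qpcr")] = qpcr_excl.get((m, "qpcr"), 0) + 1
        ish_excl = {
            (m, "ish"): sum(
                1 for r in ish_records if r.mirna_id == m and r.excluded
            )
            for m in {r.mirna_id for r in ish_records}
        }
        matrices = build_sample_matrices(expression, ish_records)
        icc = reliability.icc_report(
            matrices, exclusion_counts={**qpcr_excl, **ish_excl}
        )
    except (ValueError, KeyError) as err:
        raise PipelineError(f"reliability stage: {err}") from err

    # --- concordance stage ----------------------------------------------
    results = {
        "expression": expression,
        "ish_quant": ish.records_to_frame(ish_records),
        "icc_report": icc,
        "exclusions": exclusions,
        "roi_exclusion_report": roi_report,
    }
    if ish_records:
        try:
            shared = sorted(
                set(expression["mirna_id"]) & {r.mirna_id for r in ish_records}
            )
            results["concordance"] = concordance.concordance_report(
                expression, ish_records, shared
            )
            results["standardized"] = concordance.standardized_long_table(
                expression, ish_records
            )
        except (ValueError, KeyError) as err:
            raise PipelineError(f"concordance stage: {err}") from err

    filenames = {
        "expression": "expression.csv",
        "ish_quant": "ish_quant.csv",
        "icc_report": "icc_report.csv",
        "concordance": "concordance.csv",
        "standardized": "standardized.csv",
        "exclusions": "exclusions.csv",
        "roi_exclusion_report": "roi_exclusions.csv",
    }
    for key, frame in results.items():
        write_csv(frame, out / filenames[key])
    logger.info("pipeline complete: %d reports in %s", len(results), out)
    return results
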