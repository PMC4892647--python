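"""One-way random-effects reliability analysis.

The measurement model is

    y_ij = mu + b_i + e_ij,   b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_w^2)

with patients i as random groups and repeated tumour samples j within a
patient. The intraclass correlation

    ICC_single = sigma_b^2 / (sigma_b^2 + sigma_w^2)

is the share of total variance attributable to between-patient
differences: it is the reliability of a *single* sample as a proxy for
its patient. The reliability of the mean of k samples follows the
Spearman-Brown step-up

    ICC_mean = k * ICC_single / (1 + (k - 1) * ICC_single)

Estimation is by one-way ANOVA mean squares. For unbalanced designs
(undetected samples, small-ROI exclusions) the effective group size

    k0 = (N - sum(k_i^2) / N) / (n_groups - 1)

replaces k in the variance-component and ICC(1) estimators; reporting of
ICC_mean still targets the design k (three samples per patient).
Negative ICC estimates are reported as computed, not truncated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DESIGN_K = 3  # tumour samples per patient in the study design


class ReliabilityInputError(ValueError):
    """Raised when a sample matrix cannot support a one-way ANOVA."""


@dataclass
class SampleMatrix:
    """Per-patient measurement groups for one miRNA x modality.

    ``groups`` maps patient id to that patient's available measurement
    values (linear qPCR values or ISH area fractions); unbalanced group
    sizes are allowed, empty groups are dropped with a warning.
    """

    mirna_id: str
    modality: str  # "qpcr" or "ish"
    groups: dict[str, list[float]]
    signal_type: str = ""  # e.g. "TBp" or "wpB" for ISH

    def clean_groups(self) -> dict[str, np.ndarray]:
        out = {}
        for patient, values in self.groups.items():
            arr = np.asarray(values, dtype=float)
            if arr.size == 0:
                logger.warning(
                    "%s/%s: patient %s has no values, dropped",
                    self.mirna_id, self.modality, patient,
                )
                continue
            if not np.all(np.isfinite(arr)):
                raise ReliabilityInputError(
                    f"{self.mirna_id}/{self.modality}: non-finite value "
                    f"for patient {patient}"
                )
            out[patient] = arr
        return out


@dataclass(frozen=True)
class AnovaDecomposition:
    """Between/within mean squares and variance components."""

    n_groups: int
    total_n: int
    ms_between: float
    ms_within: float
    k0: float  # effective group size (equals k for balanced designs)

    @property
    def var_within(self) -> float:
        return self.ms_within

    @property
    def var_between(self) -> float:
        return max(0.0, (self.ms_between - self.ms_within) / self.k0)


def oneway_anova(matrix: SampleMatrix | dict[str, list[float]]) -> AnovaDecomposition:
    """Decompose variance between and within patients.

    MS_between = SS_between / (n_groups - 1) with SS_between the
    size-weighted squared deviations of group means from the grand mean;
    MS_within = SS_within / (N - n_groups).
    """
    if not isinstance(matrix, SampleMatrix):
        matrix = SampleMatrix(mirna_id="", modality="", groups=dict(matrix))
    groups = matrix.clean_groups()
    if len(groups) < 2:
        raise ReliabilityInputError(
            f"need >= 2 non-empty patient groups, got {len(groups)}"
        )
    sizes = np.array([len(v) for v in groups.values()], dtype=float)
    n_groups = len(groups)
    total_n = int(sizes.sum())
    if total_n <= n_groups:
        raise ReliabilityInputError(
            f"need replicate measurements within patients "
            f"(N={total_n}, groups={n_groups})"
        )
    all_values = np.concatenate(list(groups.values()))
    grand_mean = all_values.mean()
    group_means = np.array([v.mean() for v in groups.values()])
    ss_between = float(np.sum(sizes * (group_means - grand_mean) ** 2))
    ss_within = float(
        sum(np.sum((v - v.mean()) ** 2) for v in groups.values())
    )
    k0 = (total_n - float(np.sum(sizes**2)) / total_n) / (n_groups - 1)
    return AnovaDecomposition(
        n_groups=n_groups,
        total_n=total_n,
        ms_between=ss_between / (n_groups - 1),
        ms_within=ss_within / (total_n - n_groups),
        k0=k0,
    )


def icc_single(decomposition: AnovaDecomposition) -> float:
    """ICC(1): reliability of a single sample.

    (MSB - MSW) / (MSB + (k0 - 1) MSW); NaN ("undefined") when both mean
    squares are zero (constant data).
    """
    msb, msw, k0 = (
        decomposition.ms_between,
        decomposition.ms_within,
        decomposition.k0,
    )
    denominator = msb + (k0 - 1.0) * msw
    if denominator == 0.0:
        return math.nan
    return (msb - msw) / denominator


def icc_mean(decomposition: AnovaDecomposition) -> float:
    """ICC(k): reliability of the mean of the group's samples.

    (MSB - MSW) / MSB; NaN ("undefined") when MSB is zero.
    """
    if decomposition.ms_between == 0.0:
        return math.nan
    return (decomposition.ms_between - decomposition.ms_within) / decomposition.ms_between


def spearman_brown(icc: float, k: int) -> float:
    """Step a single-measure reliability up to the mean of k measures.

    k*r / (1 + (k-1)*r); the exact single-to-mean identity of the
    one-way model for balanced designs.
    """
    if k < 1:
        raise ReliabilityInputError(f"k must be >= 1, got {k}")
    if k > 1 and icc <= -1.0 / (k - 1):
        raise ReliabilityInputError(
            f"ICC {icc} out of the admissible range for k={k}"
        )
    return k * icc / (1.0 + (k - 1) * icc)


def icc_confidence_interval(
    decomposition: AnovaDecomposition, confidence: float = 0.95
) -> tuple[float, float]:
    """Exact-F interval for ICC_single under the balanced one-way model.

    An extension beyond the point estimates; uses k0 in place of k for
    unbalanced data (approximate there).
    """
    from scipy.stats import f as f_dist

    d = decomposition
    df1, df2 = d.n_groups - 1, d.total_n - d.n_groups
    if d.ms_within == 0:
        return (math.nan, math.nan)
    f_obs = d.ms_between / d.ms_within
    alpha = 1.0 - confidence
    f_low = f_obs / f_dist.ppf(1 - alpha / 2, df1, df2)
    f_upp = f_obs / f_dist.ppf(alpha / 2, df1, df2)
    lower = (f_low - 1) / (f_low + d.k0 - 1)
    upper = (f_upp - 1) / (f_upp + d.k0 - 1)
    return (lower, upper)


def icc_report(
    matrices: list[SampleMatrix],
    design_k: int = DESIGN_K,
    exclusion_counts: dict[tuple[str, str], int] | None = None,
) -> pd.DataFrame:
    """One reliability row per miRNA x modality.

    Per-matrix failures become flagged rows (NaN estimates plus an error
    note) rather than aborting the report. ``exclusion_counts`` maps
    (mirna_id, modality) to the number of measurements excluded upstream.
    """
    exclusion_counts = exclusion_counts or {}
    rows = []
    for m in matrices:
        row = {
            "mirna_id": m.mirna_id,
            "modality": m.modality,
            "signal_type": m.signal_type,
            "icc_single": math.nan,
            "icc_mean": math.nan,
            "n_patients": 0,
            "n_values": 0,
            "k0": math.nan,
            "design_k": design_k,
            "n_excluded": exclusion_counts.get((m.mirna_id, m.modality), 0),
            "negative_icc": False,
            "error": "",
        }
        try:
            d = oneway_anova(m)
            single = icc_single(d)
            row.update(
                icc_single=single,
                icc_mean=icc_mean(d),
                n_patients=d.n_groups,
                n_values=d.total_n,
                k0=d.k0,
                negative_icc=bool(single < 0) if math.isfinite(single) else False,
            )
        except ReliabilityInputError as err:
            row["error"] = str(err)
            logger.warning("ICC row failed for %s/%s: %s", m.mirna_id, m.modality, err)
        rows.append(row)
    return pd.DataFrame(rows)
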