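"""Cross-modality pairing, Spearman correlation, and common-scale normalisation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirhet.concordance import (
    ConcordanceInputError,
    aggregate_pairs,
    common_scale_normalise,
    concordance_report,
    spearman_rho,
    standardized_long_table,
)
from mirhet.ish import IshQuantRecord


def brute_force_spearman(x, y):
    """Independent oracle: Pearson correlation of average ranks."""

    def average_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for idx in order[i : j + 1]:
                ranks[idx] = avg
            i = j + 1
        return ranks

    rx, ry = average_ranks(list(x)), average_ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ((1, 2, 3, 4), (10, 20, 30, 40), 1.0),
        ((1, 2, 3, 4), (8, 6, 4, 2), -1.0),
        # tie case, frozen from the average-rank oracle
        ((1, 2, 2, 4), (1, 3, 2, 4), 0.9486832980505139),
    ],
)
def test_spearman_examples(x, y, expected):
    assert spearman_rho(x, y) == pytest.approx(expected)
    assert brute_force_spearman(x, y) == pytest.approx(expected)


@given(
    st.lists(st.floats(min_value=-100, max_value=100), min_size=3, max_size=12),
    st.lists(st.floats(min_value=-100, max_value=100), min_size=3, max_size=12),
)
@settings(max_examples=100, deadline=None)
def test_spearman_matches_oracle(x, y):
    n = min(len(x), len(y))
    x, y = x[:n], y[:n]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        assert math.isnan(spearman_rho(x, y))
    else:
        assert spearman_rho(x, y) == pytest.approx(
            brute_force_spearman(x, y), abs=1e-12
        )


def test_spearman_monotone_transform_invariance():
    rng = np.random.default_rng(4)
    x = rng.normal(size=20)
    y = rng.normal(size=20)
    base = spearman_rho(x, y)
    assert spearman_rho(np.exp(x), y) == pytest.approx(base)
    assert spearman_rho(x, y**3) == pytest.approx(base)
    assert spearman_rho(x, x) == 1.0


def test_spearman_degenerate_inputs():
    assert math.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))
    with pytest.raises(ConcordanceInputError):
        spearman_rho([1, 2], [3, 4])
    with pytest.raises(ConcordanceInputError):
        spearman_rho([1, 2, np.nan], [1, 2, 3])


def _expr_frame(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "sample_id", "mirna_id", "deepest",
                       "linear_value"]
    )


def _ish(patient, sample, tbp, deepest=False, mirna="miR-21", roi=5.0):
    return IshQuantRecord(
        patient_id=patient, sample_id=sample, mirna_id=mirna,
        area_iB=0.2 * tbp * roi, area_wB=0.6 * tbp * roi,
        area_pB=0.2 * tbp * roi, roi_area=roi, deepest=deepest,
    )


def test_patient_mean_aggregation():
    expr = _expr_frame(
        [("P1", f"S{j}", "miR-21", j == 2, v)
         for j, v in zip((1, 2, 3), (2.0, 4.0, 6.0))]
        + [("P2", f"S{j}", "miR-21", j == 1, v)
           for j, v in zip((1, 2, 3), (1.0, 1.0, 1.0))]
    )
    records = [_ish(p, f"S{j}", t, deepest=(j == 2 if p == "P1" else j == 1))
               for p in ("P1", "P2") for j, t in zip((1, 2, 3), (0.1, 0.2, 0.3))]
    pairs = aggregate_pairs(expr, records, "patient_mean", "miR-21")
    assert pairs.qpcr_values.tolist() == [4.0, 1.0]
    assert pairs.ish_values[0] == pytest.approx(0.2)


def test_deepest_section_selection():
    expr = _expr_frame(
        [(p, f"S{j}", "miR-21", j == 2, float(10 * i + j))
         for i, p in enumerate(("P1", "P2")) for j in (1, 2, 3)]
    )
    records = [_ish(p, f"S{j}", 0.05 * j, deepest=(j == 2))
               for p in ("P1", "P2") for j in (1, 2, 3)]
    pairs = aggregate_pairs(expr, records, "deepest_section", "miR-21")
    assert pairs.qpcr_values.tolist() == [2.0, 12.0]
    assert pairs.ish_values.tolist() == pytest.approx([0.1, 0.1])


def test_incomplete_patients_dropped_and_counted():
    expr = _expr_frame(
        [(p, "S1", "miR-21", True, 1.0 * i)
         for i, p in enumerate(("P1", "P2", "P3"))]
    )
    records = [_ish("P1", "S1", 0.1, True), _ish("P2", "S1", 0.2, True)]
    pairs = aggregate_pairs(expr, records, "patient_mean", "miR-21")
    assert pairs.patient_ids == ["P1", "P2"]
    assert pairs.n_dropped == 1


def test_excluded_ish_records_do_not_enter_pairs():
    from mirhet.ish import apply_roi_filter

    expr = _expr_frame([(p, "S1", "miR-21", True, float(i))
                        for i, p in enumerate(("P1", "P2"))])
    records = [_ish("P1", "S1", 0.1, True, roi=1.0), _ish("P2", "S1", 0.2, True)]
    records, _ = apply_roi_filter(records, 2.0)
    pairs = aggregate_pairs(expr, records, "patient_mean", "miR-21")
    assert pairs.patient_ids == ["P2"]


def test_common_scale_normalise():
    z = common_scale_normalise([1.0, 2.0, 3.0])
    assert z == pytest.approx([-1.0, 0.0, 1.0])
    with pytest.raises(ConcordanceInputError):
        common_scale_normalise([2.0, 2.0, 2.0])
    rng = np.random.default_rng(0)
    out = common_scale_normalise(rng.normal(3, 7, 40))
    assert out.mean() == pytest.approx(0.0, abs=1e-12)
    assert out.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


def test_standardized_long_table_is_zero_mean_unit_sd(study):
    from mirhet.ish import apply_roi_filter, records_from_table
    from mirhet.qpcr import build_expression_table
    from mirhet.io import read_qpcr_table
    import tempfile, os

    with tempfile.TemporaryDirectory() as tmp:
        qp = os.path.join(tmp, "q.csv")
        study["qpcr_table"].to_csv(qp, index=False)
        expr = build_expression_table(read_qpcr_table(qp)).to_frame()
    records, _ = apply_roi_filter(records_from_table(study["ish_table"]), 2.0)
    table = standardized_long_table(expr, records)
    for (_, _), g in table.groupby(["mirna_id", "modality"]):
        assert g["z_value"].mean() == pytest.approx(0.0, abs=1e-10)
        assert g["z_value"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)


def test_latent_sharing_orders_concordance():
    """Mean estimated rho increases with the generator's latent weight."""
    from mirhet.simulate import SyntheticConfig, gen_paired_study
    from mirhet.ish import apply_roi_filter, records_from_table
    from mirhet.qpcr import CqTriplicate, build_expression_table

    def mean_rho(weight, n_reps=12):
        rhos = []
        for rep in range(n_reps):
            cfg = SyntheticConfig(
                n_patients=20, latent_weight=weight, seed=1000 + rep
            )
            s = gen_paired_study(cfg)
            trips = [
                CqTriplicate(r.patient_id, r.sample_id, r.mirna_id,
                             tuple(c for c in (r.rep1_cq, r.rep2_cq, r.rep3_cq)
                                   if not math.isnan(c)),
                             bool(r.deepest_flag))
                for r in s["qpcr_table"].itertuples()
            ]
            expr = build_expression_table(trips).to_frame()
            records, _ = apply_roi_filter(
                records_from_table(s["ish_table"]), 2.0
            )
            pairs = aggregate_pairs(expr, records, "patient_mean", "miR-21")
            rhos.append(spearman_rho(pairs.qpcr_values, pairs.ish_values))
        return float(np.mean(rhos))

    low, mid, high = mean_rho(0.0), mean_rho(0.6), mean_rho(1.0)
    assert low < mid < high
    assert abs(low) < 0.25
    assert high > 0.5


def test_concordance_report_columns(study):
    from mirhet.ish import apply_roi_filter, records_from_table
    from mirhet.qpcr import CqTriplicate, build_expression_table

    trips = [
        CqTriplicate(r.patient_id, r.sample_id, r.mirna_id,
                     tuple(c for c in (r.rep1_cq, r.rep2_cq, r.rep3_cq)
                           if not math.isnan(c)),
                     bool(r.deepest_flag))
        for r in study["qpcr_table"].itertuples()
    ]
    expr = build_expression_table(trips).to_frame()
    records, _ = apply_roi_filter(records_from_table(study["ish_table"]), 2.0)
    report = concordance_report(expr, records, ["miR-21", "miR-630"])
    assert list(report["mirna_id"]) == ["miR-21", "miR-630"]
    assert report["rho_mean"].abs().le(1).all()
    assert (report["n_patient_mean"] > 3).all()
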