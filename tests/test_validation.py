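"""qPCR quantification, standard curves, rank/chi-squared tests, follow-up."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beprog.types import ContingencyTable, CtTable, ValidationError
from beprog.validation import (
    DILUTION_SERIES_NG,
    chi_squared,
    delta_delta_ct,
    fit_standard_curve,
    fold_change_summary,
    score_table,
    summarize_followup,
    wilcoxon_rank_sum,
)


def _ct_table(patients, calibrator="GAPDH"):
    """patients: list of (patient_id, group, target_ct, calibrator_ct)."""
    rows = []
    for pid, group, tct, cct in patients:
        for gene, ct in (("CYR61", tct), (calibrator, cct)):
            for rep in (1, 2):
                rows.append(
                    {
                        "patient_id": pid,
                        "group": group,
                        "timepoint": "t0",
                        "gene_id": gene,
                        "replicate_index": rep,
                        "ct": ct,
                    }
                )
    return CtTable(pd.DataFrame(rows), calibrator_gene=calibrator)


class TestDeltaDeltaCt:
    def test_all_equal_ct_gives_unity(self):
        ct = _ct_table(
            [("p1", "P-BE", 25.0, 25.0), ("c1", "nonP-BE", 25.0, 25.0)]
        )
        fc = delta_delta_ct(ct, "CYR61")
        np.testing.assert_allclose(fc["fold_change"], 1.0)

    def test_one_cycle_lower_doubles(self):
        ct = _ct_table(
            [("p1", "P-BE", 24.0, 20.0), ("c1", "nonP-BE", 25.0, 20.0)]
        )
        fc = delta_delta_ct(ct, "CYR61")
        assert fc.set_index("patient_id").loc["p1", "fold_change"] == pytest.approx(2.0)

    def test_hand_arithmetic_two_cycles(self):
        ct = _ct_table(
            [
                ("p1", "P-BE", 24.0, 20.0),
                ("c1", "nonP-BE", 26.0, 20.0),
                ("c2", "nonP-BE", 26.0, 20.0),
            ]
        )
        fc = delta_delta_ct(ct, "CYR61")
        row = fc.set_index("patient_id").loc["p1"]
        assert row["delta_delta_ct"] == pytest.approx(-2.0)
        assert row["fold_change"] == pytest.approx(4.0)

    def test_duplicates_averaged_before_delta(self):
        rows = []
        for gene, cts in (("CYR61", (23.0, 25.0)), ("GAPDH", (20.0, 20.0))):
            for rep, ct in enumerate(cts, start=1):
                rows.append(
                    dict(patient_id="p1", group="P-BE", timepoint="t0",
                         gene_id=gene, replicate_index=rep, ct=ct)
                )
        for gene in ("CYR61", "GAPDH"):
            for rep in (1, 2):
                rows.append(
                    dict(patient_id="c1", group="nonP-BE", timepoint="t0",
                         gene_id=gene, replicate_index=rep, ct=20.0)
                )
        fc = delta_delta_ct(CtTable(pd.DataFrame(rows)), "CYR61")
        # mean(23, 25) = 24 -> dCt 4 -> ddCt 4 -> FC 2^-4
        assert fc.set_index("patient_id").loc["p1", "fold_change"] == pytest.approx(
            2.0**-4
        )

    def test_missing_calibrator_names_patient(self):
        rows = pd.DataFrame(
            [
                dict(patient_id="p9", group="P-BE", timepoint="t0",
                     gene_id="CYR61", replicate_index=1, ct=24.0),
                dict(patient_id="c1", group="nonP-BE", timepoint="t0",
                     gene_id="CYR61", replicate_index=1, ct=25.0),
                dict(patient_id="c1", group="nonP-BE", timepoint="t0",
                     gene_id="GAPDH", replicate_index=1, ct=20.0),
            ]
        )
        with pytest.raises(ValidationError, match="p9"):
            delta_delta_ct(CtTable(rows), "CYR61")

    @settings(max_examples=25, deadline=None)
    @given(shift=st.floats(-5, 5, allow_nan=False))
    def test_invariant_to_per_patient_constant_shift(self, shift):
        base = [("p1", "P-BE", 24.0, 20.0), ("c1", "nonP-BE", 26.0, 20.0)]
        shifted = [("p1", "P-BE", 24.0 + shift, 20.0 + shift),
                   ("c1", "nonP-BE", 26.0, 20.0)]
        if min(24.0 + shift, 20.0 + shift) <= 0:
            return
        f0 = delta_delta_ct(_ct_table(base), "CYR61")
        f1 = delta_delta_ct(_ct_table(shifted), "CYR61")
        np.testing.assert_allclose(
            f0["fold_change"].to_numpy(), f1["fold_change"].to_numpy(), rtol=1e-9
        )

    def test_group_summary_reports_both_means(self):
        s = fold_change_summary(pd.Series([1.0, 4.0]))
        assert s["geometric_mean"] == pytest.approx(2.0)
        assert s["arithmetic_mean"] == pytest.approx(2.5)


class TestStandardCurve:
    def test_perfect_doubling_chemistry(self):
        slope = -1.0 / math.log10(2.0)  # -3.321928 cycles per decade
        ct = [30.0 + slope * math.log10(x) for x in DILUTION_SERIES_NG]
        curve = fit_standard_curve(DILUTION_SERIES_NG, ct)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-6)

    def test_collinear_points_r_squared_one(self):
        ct = [28.0 - 3.5 * math.log10(x) for x in DILUTION_SERIES_NG]
        curve = fit_standard_curve(DILUTION_SERIES_NG, ct)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_slope_minus_3_6_efficiency(self):
        ct = [28.0 - 3.6 * math.log10(x) for x in DILUTION_SERIES_NG]
        curve = fit_standard_curve(DILUTION_SERIES_NG, ct)
        assert curve.efficiency == pytest.approx(10 ** (1 / 3.6) - 1, rel=1e-9)
        assert curve.efficiency == pytest.approx(0.8957, abs=5e-4)

    def test_non_positive_mass_rejected(self):
        with pytest.raises(ValidationError, match="positive"):
            fit_standard_curve([10.0, 1.0, 0.0], [20.0, 23.0, 26.0])


def _exact_two_sided_p(x, y):
    """Enumeration oracle: all C(n+m, n) assignments of the combined ranks."""
    n, m = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    combined = sorted(x + y)
    us = []
    for idx in itertools.combinations(range(n + m), n):
        xs = [combined[i] for i in idx]
        ys = [combined[i] for i in range(n + m) if i not in idx]
        us.append(sum(1 for xi in xs for yj in ys if xi > yj))
    lower = sum(u <= u_obs for u in us) / len(us)
    upper = sum(u >= u_obs for u in us) / len(us)
    return min(1.0, 2 * min(lower, upper))


class TestWilcoxon:
    def test_exact_one_third(self):
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_small_samples(self):
        rng = np.random.default_rng(0)
        for n, m in [(2, 3), (3, 3), (4, 4), (5, 5), (4, 6)]:
            for _ in range(3):
                x = list(rng.normal(size=n))
                y = list(rng.normal(size=m))
                _, p = wilcoxon_rank_sum(x, y)
                assert p == pytest.approx(_exact_two_sided_p(x, y), abs=1e-12)

    def test_exact_close_to_approximation_at_n10(self):
        from scipy.stats import norm, rankdata

        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.normal(size=10)
            y = rng.normal(size=10) + 0.5
            _, p_exact = wilcoxon_rank_sum(x, y)  # n+m = 20 -> exact path
            u = rankdata(np.concatenate([x, y]))[:10].sum() - 10 * 11 / 2
            sigma = math.sqrt(10 * 10 / 12 * 21)
            z = max(0.0, abs(u - 50.0) - 0.5) / sigma
            p_norm = min(1.0, 2 * norm.sf(z))
            assert abs(p_exact - p_norm) < 0.02

    def test_one_sided_monotone_under_shift(self):
        x = [1.0, 2.0, 3.0, 4.0]
        ps = []
        for shift in (0.0, 1.0, 2.0, 4.0):
            y = [v + shift for v in (0.5, 1.5, 2.5, 3.4)]
            _, p = wilcoxon_rank_sum(x, y)
            u = sum(1 for xi in x for yj in y if xi > yj)
            ps.append((u, p))
        # as y shifts up, x wins fewer pairs
        us = [u for u, _ in ps]
        assert us == sorted(us, reverse=True)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError, match="non-empty"):
            wilcoxon_rank_sum([], [1.0])


def _pearson_x2(table):
    """Brute-force expected-counts computation."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    return float(((table - expected) ** 2 / expected).sum())


class TestChiSquared:
    def test_proportional_table_zero(self):
        x2, df, p = chi_squared(ContingencyTable(pd.DataFrame([[5, 5], [5, 5]])))
        assert x2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_uncorrected(self):
        t = ContingencyTable(pd.DataFrame([[8, 2], [2, 8]]))
        x2, df, _ = chi_squared(t, correction=False)
        assert (x2, df) == (pytest.approx(7.2), 1)

    def test_closed_form_yates(self):
        t = ContingencyTable(pd.DataFrame([[8, 2], [2, 8]]))
        x2, _, _ = chi_squared(t, correction=True)
        assert x2 == pytest.approx(5.0)

    def test_matches_brute_force_on_small_tables(self):
        """Sweep all 2x2 (cells <= 6) and all 2x3 (cells <= 3) tables."""
        for cells in itertools.product(range(7), repeat=4):
            arr = np.array(cells).reshape(2, 2)
            if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
                continue
            x2, _, _ = chi_squared(ContingencyTable(pd.DataFrame(arr)), correction=False)
            assert x2 == pytest.approx(_pearson_x2(arr), rel=1e-9)
        for cells in itertools.product(range(4), repeat=6):
            arr = np.array(cells).reshape(2, 3)
            if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
                continue
            x2, df, _ = chi_squared(ContingencyTable(pd.DataFrame(arr)), correction=False)
            assert df == 2
            assert x2 == pytest.approx(_pearson_x2(arr), rel=1e-9)

    def test_zero_margin_rejected(self):
        t = ContingencyTable(pd.DataFrame([[0, 0], [1, 2]]))
        with pytest.raises(ValidationError, match="zero"):
            chi_squared(t)


class TestFollowup:
    def test_pbe_mean_and_range(self, clinical_records):
        s = summarize_followup(clinical_records, "P-BE")
        assert (s["mean"], s["min"], s["max"]) == (4.6, 1, 13)

    def test_nonpbe_mean_and_range(self, clinical_records):
        s = summarize_followup(clinical_records, "nonP-BE")
        assert (s["mean"], s["max"]) == (9.4, 17)

    def test_single_record(self, clinical_records):
        one = [r for r in clinical_records if r.patient_id == "2"]
        s = summarize_followup(one, "P-BE")
        assert s["mean"] == s["min"] == s["max"] == 1

    def test_empty_group_rejected(self, clinical_records):
        pbe_only = [r for r in clinical_records if r.group == "P-BE"]
        with pytest.raises(ValidationError, match="nonP-BE"):
            summarize_followup(pbe_only, "nonP-BE")


class TestScoreTable:
    def test_row_sums_are_group_sizes(self, clinical_records):
        t = score_table(clinical_records, "ihc_cyr61", "t0")
        sums = t.counts.sum(axis=1)
        assert sums["nonP-BE"] == 10 and sums["P-BE"] == 9

    def test_counts_conserve_records(self, clinical_records):
        for marker in ("qpcr_cyr61", "ihc_taz"):
            t = score_table(clinical_records, marker, "t1")
            assert int(t.counts.to_numpy().sum()) == len(clinical_records)

    def test_empty_category_retained(self, clinical_records):
        t = score_table(clinical_records, "ihc_taz", "t0")
        assert list(t.counts.columns) == ["-", "+", "++"]

    def test_unknown_marker_rejected(self, clinical_records):
        with pytest.raises(ValidationError, match="marker"):
            score_table(clinical_records, "ihc_ecad", "t0")
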