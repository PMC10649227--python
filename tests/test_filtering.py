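"""GOF filtering, Grubbs outliers, protein aggregation, CSV dialects."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import t as student_t

from turnoverms.filtering import (
    FilterCriteria,
    PeptideRateRecord,
    aggregate_protein,
    custom_filter,
    default_filter,
    grubbs_critical_value,
    grubbs_outliers,
    read_rateconst_csv,
    write_protein_summary,
    write_rateconst_csv,
)


def record(**kw):
    base = dict(
        sequence="PEPTIDEK", charge=2, k=0.05, R2=0.97, pearson_r=0.98,
        RMSE=0.02, SD=0.03, NDP=9, avg_monoisotope_abundance=5e7,
        isotope_deviation=0.1, n_experiments=9, ci_lower=0.04, ci_upper=0.06,
    )
    base.update(kw)
    return PeptideRateRecord(**base)


BENCHMARK = FilterCriteria(
    min_R2=0.95, min_r=0.95, max_RMSE=0.05, max_SD=0.05, min_NDP=4,
    min_abundance=2e7, max_isotope_deviation=0.3,
)


class TestDefaultFilter:
    @pytest.mark.parametrize(
        "kw, expected",
        [
            # slow-turnover branch: only RMSE < 0.01 matters
            (dict(k=0.005, RMSE=0.008), True),
            (dict(k=0.005, RMSE=0.012), False),
            (dict(k=0.005, RMSE=0.008, R2=0.1, pearson_r=0.1), True),
            # fast branch: R2 > 0.9, r > 0.9, RMSE < 0.05
            (dict(k=0.05, R2=0.95, pearson_r=0.96, RMSE=0.03), True),
            (dict(k=0.05, R2=0.85, pearson_r=0.96, RMSE=0.03), False),
            (dict(k=0.05, R2=0.95, pearson_r=0.89, RMSE=0.03), False),
            (dict(k=0.05, R2=0.95, pearson_r=0.96, RMSE=0.06), False),
            # boundary senses are strict
            (dict(k=0.05, R2=0.9, pearson_r=0.96, RMSE=0.03), False),
            (dict(k=0.0099, RMSE=0.0099), True),
        ],
    )
    def test_printed_branch_logic(self, kw, expected):
        ok, _ = default_filter(record(**kw))
        assert ok is expected

    def test_missing_metric_reported(self):
        ok, reasons = default_filter(record(k=math.nan))
        assert not ok and reasons == ["missing_metric"]
        ok, reasons = default_filter(record(k=0.05, R2=math.nan))
        assert not ok and reasons == ["missing_metric"]


class TestCustomFilter:
    def test_benchmark_thresholds_pass_conforming_record(self):
        ok, reasons = custom_filter(record(R2=0.95, pearson_r=0.95, RMSE=0.05,
                                           SD=0.05, NDP=4,
                                           avg_monoisotope_abundance=2e7,
                                           isotope_deviation=0.3), BENCHMARK)
        assert ok and reasons == []

    def test_all_disabled_passes_anything(self):
        ok, _ = custom_filter(record(k=math.nan, R2=-5), FilterCriteria())
        assert ok

    def test_single_failing_clause_isolated(self):
        ok, reasons = custom_filter(record(NDP=3), BENCHMARK)
        assert not ok and reasons == ["min_NDP"]

    def test_missing_value_fails_enabled_threshold(self):
        ok, reasons = custom_filter(record(SD=math.nan), BENCHMARK)
        assert not ok and "max_SD" in reasons

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_tightening_any_threshold_shrinks_passing_set(self, data):
        """Subset property: a stricter criterion never admits a record
        that the looser one rejected."""
        rng = np.random.default_rng(0)
        records = [
            record(
                R2=data.draw(st.floats(0, 1)),
                pearson_r=data.draw(st.floats(-1, 1)),
                RMSE=data.draw(st.floats(0, 0.2)),
                SD=data.draw(st.floats(0, 0.2)),
                NDP=data.draw(st.integers(3, 9)),
            )
            for _ in range(5)
        ]
        loose = FilterCriteria(min_R2=0.9, max_RMSE=0.08, min_NDP=4)
        tight = FilterCriteria(min_R2=0.95, max_RMSE=0.08, min_NDP=4)
        pass_loose = {i for i, r in enumerate(records) if custom_filter(r, loose)[0]}
        pass_tight = {i for i, r in enumerate(records) if custom_filter(r, tight)[0]}
        assert pass_tight <= pass_loose


class TestGrubbs:
    def test_published_critical_value(self):
        # published two-sided Grubbs critical values at alpha=0.05
        assert grubbs_critical_value(5, 0.05) == pytest.approx(1.715, abs=0.001)
        assert grubbs_critical_value(10, 0.05) == pytest.approx(2.290, abs=0.001)
        assert grubbs_critical_value(20, 0.05) == pytest.approx(2.709, abs=0.001)

    def test_single_gross_outlier_detected(self):
        rates = [1.0, 1.02, 0.98, 1.01, 5.0]
        assert grubbs_outliers(rates, 0.05) == {4}

    def test_zero_variance_and_tiny_samples(self):
        assert grubbs_outliers([1.0, 1.0, 1.0]) == set()
        assert grubbs_outliers([1.0, 9.0]) == set()
        assert grubbs_outliers([]) == set()

    def test_matches_brute_force_on_random_vectors(self):
        """Independent re-implementation of the iterative two-sided test."""

        def brute(values, alpha=0.05):
            vals = list(enumerate(values))
            removed = set()
            while len(vals) >= 3:
                arr = np.array([v for _, v in vals])
                mean, sd = arr.mean(), arr.std(ddof=1)
                if sd == 0:
                    break
                g = np.abs(arr - mean) / sd
                worst = int(np.argmax(g))
                n = len(vals)
                tq = student_t.ppf(1 - alpha / (2 * n), n - 2)
                gcrit = (n - 1) / math.sqrt(n) * math.sqrt(
                    tq * tq / (n - 2 + tq * tq)
                )
                if g[worst] > gcrit:
                    removed.add(vals[worst][0])
                    vals.pop(worst)
                else:
                    break
            return removed

        rng = np.random.default_rng(123)
        for _ in range(300):
            n = int(rng.integers(3, 15))
            vals = rng.normal(0.2, 0.05, n)
            if rng.random() < 0.5:
                vals[rng.integers(n)] += rng.uniform(0.3, 2.0)
            assert grubbs_outliers(vals.tolist()) == brute(vals.tolist())


class TestAggregation:
    def test_median_odd_count(self):
        recs = [record(k=k, SD=0.02) for k in (0.1, 0.2, 0.3)]
        s = aggregate_protein("P1", recs)
        assert s.k_protein == pytest.approx(0.2)
        assert s.n_peptides_used == 3

    def test_harmonic_mean_sd_hand_value(self):
        recs = [record(k=0.1, SD=0.02), record(k=0.11, SD=0.04)]
        s = aggregate_protein("P1", recs)
        assert s.sd_protein == pytest.approx(2 / (50 + 25), abs=1e-9)

    def test_single_peptide_inherits_its_ci(self):
        s = aggregate_protein("P1", [record(k=0.08, SD=0.01)])
        assert s.k_protein == pytest.approx(0.08)
        assert s.sd_protein == pytest.approx(0.01)
        assert s.ci95 == (0.04, 0.06)  # the record's own interval

    def test_outlier_removed_before_median(self):
        recs = [record(k=k, SD=0.02) for k in (0.10, 0.102, 0.098, 0.101, 5.0)]
        s = aggregate_protein("P1", recs)
        assert s.n_peptides_used == 4
        assert s.k_protein < 0.2

    def test_zero_sd_records_excluded_from_harmonic_mean(self):
        recs = [record(k=0.1, SD=0.0), record(k=0.2, SD=0.02),
                record(k=0.3, SD=0.02)]
        s = aggregate_protein("P1", recs)
        assert s.k_protein == pytest.approx(0.2)  # zero-SD still counts here
        assert s.sd_protein == pytest.approx(0.02)

    def test_ci_contains_protein_rate(self):
        rng = np.random.default_rng(8)
        recs = [record(k=float(k), SD=float(s))
                for k, s in zip(rng.uniform(0.05, 0.15, 6),
                                rng.uniform(0.01, 0.05, 6))]
        s = aggregate_protein("P1", recs)
        assert s.ci95[0] <= s.k_protein <= s.ci95[1]

    def test_idempotent_on_outlier_free_set(self):
        rng = np.random.default_rng(21)
        ks = rng.normal(0.2, 0.01, 8)
        assert grubbs_outliers(ks.tolist()) == set()
        recs = [record(k=float(k), SD=0.02) for k in ks]
        s1 = aggregate_protein("P1", recs)
        s2 = aggregate_protein("P1", recs)
        assert s1 == s2

    def test_harmonic_le_arithmetic_mean(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            sds = rng.uniform(0.005, 0.1, int(rng.integers(2, 8)))
            recs = [record(k=0.1, SD=float(s)) for s in sds]
            agg = aggregate_protein("X", recs, alpha_grubbs=1e-9)
            assert agg.sd_protein <= sds.mean() + 1e-12


class TestCsvDialects:
    def test_rateconst_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        recs = [
            record(sequence=f"PEP{i}K", charge=int(rng.integers(1, 4)),
                   k=float(rng.uniform(0.01, 1)))
            for i in range(10)
        ]
        path = tmp_path / "P1.RateConst.csv"
        write_rateconst_csv(recs, path)
        back = read_rateconst_csv(path)
        assert len(back) == 10
        for a, b in zip(recs, back):
            assert a.sequence == b.sequence and a.charge == b.charge
            assert b.k == pytest.approx(a.k, rel=1e-5)
            assert b.RMSE == pytest.approx(a.RMSE, rel=1e-5)

    def test_header_aliases_and_extra_columns(self, tmp_path):
        path = tmp_path / "x.csv"
        path.write_text(
            "Peptides,z,Rate,r2,rmse,Mystery\nAAAK,2,0.15,0.97,0.02,foo\n"
        )
        recs = read_rateconst_csv(path)
        assert recs[0].sequence == "AAAK"
        assert recs[0].charge == 2
        assert recs[0].k == pytest.approx(0.15)
        assert recs[0].R2 == pytest.approx(0.97)

    def test_missing_mandatory_columns_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("Peptide,R2\nAAAK,0.9\n")
        with pytest.raises(ValueError, match="charge"):
            read_rateconst_csv(path)

    def test_empty_data_section(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("Peptide,Charge,RateConstant\n")
        assert read_rateconst_csv(path) == []

    def test_unparseable_numeric_kept_as_missing(self, tmp_path):
        path = tmp_path / "nan.csv"
        path.write_text("Peptide,Charge,RateConstant,RMSE\nAAAK,2,oops,0.01\n")
        recs = read_rateconst_csv(path)
        assert len(recs) == 1 and math.isnan(recs[0].k)

    def test_summary_round_trip_and_canonical_order(self, tmp_path):
        from turnoverms.filtering import ProteinRateSummary, read_protein_summary

        s1 = ProteinRateSummary("B", 0.2, 3, 0.01, (0.15, 0.25))
        s2 = ProteinRateSummary("A", 0.1, 2, 0.02, (0.05, 0.15))
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_protein_summary([s1, s2], p1)
        write_protein_summary([s2, s1], p2)
        assert p1.read_bytes() == p2.read_bytes()
        df = read_protein_summary(p1)
        assert list(df["Protein"]) == ["A", "B"]
        assert df["RateConstant"].iloc[0] == pytest.approx(0.1, rel=1e-6)

    def test_zero_proteins_header_only(self, tmp_path):
        path = tmp_path / "none.csv"
        write_protein_summary([], path)
        text = path.read_text().strip().splitlines()
        assert len(text) == 1 and text[0].startswith("Protein,")
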