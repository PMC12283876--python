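"""Composite-variable derivations, inclusion filters and longitudinal
variable selection."""

import numpy as np
import pandas as pd
import pytest

from behavclust import ingest
from behavclust.ingest import (
    CHEMSEX_DRUG_ITEMS,
    IndicatorSpec,
    censor_post_hiv,
    derive_chemsex,
    derive_negotiated_safety,
    filter_min_visits,
    select_longitudinal_variables,
)

M = np.nan


def drugs(meth=M, ket=M, ghb=M, meph=M):
    return dict(zip(CHEMSEX_DRUG_ITEMS, (meth, ket, ghb, meph)))


class TestChemsex:
    @pytest.mark.parametrize("record,expected", [
        # any listed drug often/always during sex -> chemsex
        (drugs(ghb="always", meth="never", ket="never", meph="never"), 1.0),
        (drugs(meth="often", ket="rarely", ghb="never", meph="never"), 1.0),
        (drugs(meth="never", ket="never", ghb="never", meph="never"), 0.0),
        # observed items all below threshold, one missing -> still 0
        (drugs(ket=M, meth="sometimes", ghb="sometimes", meph="sometimes"), 0.0),
        (drugs(meth="always", ket=M, ghb=M, meph=M), 1.0),
    ])
    def test_rule_table(self, record, expected):
        assert derive_chemsex(record) == expected

    def test_all_four_missing_gives_missing(self):
        assert np.isnan(derive_chemsex(drugs()))

    def test_unknown_frequency_code_named_in_error(self):
        with pytest.raises(ValueError, match="frequently"):
            derive_chemsex(drugs(meth="frequently"))


class TestNegotiatedSafety:
    @pytest.mark.parametrize("nonsteady,steady,expected", [
        ("always", "never", 1.0),      # consistent with non-steady only
        ("always", "sometimes", 1.0),
        ("never", "never", 0.0),
        ("always", "always", 0.0),     # consistent with both
        ("sometimes", "never", 0.0),
    ])
    def test_rule_table(self, nonsteady, steady, expected):
        rec = {"condom_nonsteady": nonsteady, "condom_steady": steady}
        assert derive_negotiated_safety(rec) == expected

    @pytest.mark.parametrize("nonsteady,steady", [
        ("always", M), (M, "never"), (M, M),
    ])
    def test_missing_input_propagates(self, nonsteady, steady):
        rec = {"condom_nonsteady": nonsteady, "condom_steady": steady}
        assert np.isnan(derive_negotiated_safety(rec))


class TestVectorizedDerivations:
    def test_matches_record_level_rules(self, demo_cohort):
        _, visits, _, _ = demo_cohort
        out = ingest.add_derived_items(visits)
        for idx in visits.index[:80]:
            rec = visits.loc[idx]
            for col, fn in (("chemsex", derive_chemsex),
                            ("negotiated_safety", derive_negotiated_safety)):
                expected = fn(rec)
                got = out.loc[idx, col]
                assert (np.isnan(expected) and np.isnan(got)) or expected == got

    def test_derivations_never_invent_values(self, demo_cohort):
        # missing output requires at least one missing required input
        _, visits, _, _ = demo_cohort
        out = ingest.add_derived_items(visits)
        miss = out["negotiated_safety"].isna()
        inputs_missing = (
            visits["condom_nonsteady"].isna() | visits["condom_steady"].isna()
        )
        assert (miss == inputs_missing).all()


def visit_table(rows):
    return pd.DataFrame(rows)


class TestCensorPostHiv:
    def test_records_on_or_after_diagnosis_dropped(self):
        v = visit_table([
            {"man_id": "a", "visit_date": d, "hiv_diagnosis_date": "2018-03-15"}
            for d in ("2017-05-01", "2018-02-10", "2018-06-01")
        ])
        out = censor_post_hiv(v)
        assert list(out["visit_date"]) == ["2017-05-01", "2018-02-10"]

    def test_no_diagnosis_is_identity(self):
        v = visit_table([
            {"man_id": "a", "visit_date": "2017-05-01", "hiv_diagnosis_date": M},
            {"man_id": "a", "visit_date": "2018-06-01", "hiv_diagnosis_date": M},
        ])
        pd.testing.assert_frame_equal(censor_post_hiv(v), v)

    def test_diagnosis_before_first_visit_removes_man(self):
        v = visit_table([
            {"man_id": "a", "visit_date": "2018-05-01",
             "hiv_diagnosis_date": "2017-01-01"},
            {"man_id": "b", "visit_date": "2018-05-01", "hiv_diagnosis_date": M},
        ])
        out = censor_post_hiv(v)
        assert set(out["man_id"]) == {"b"}

    def test_unparseable_diagnosis_date_raises(self):
        v = visit_table([
            {"man_id": "a", "visit_date": "2018-05-01",
             "hiv_diagnosis_date": "not-a-date"},
        ])
        with pytest.raises(Exception):
            censor_post_hiv(v)

    def test_idempotent(self):
        v = visit_table([
            {"man_id": "a", "visit_date": d, "hiv_diagnosis_date": "2018-03-15"}
            for d in ("2017-05-01", "2018-06-01")
        ])
        once = censor_post_hiv(v)
        pd.testing.assert_frame_equal(censor_post_hiv(once), once)


class TestMinVisits:
    def test_counting_boundary(self):
        rows = []
        for man, k in (("a", 1), ("b", 2), ("c", 3), ("d", 5)):
            rows += [{"man_id": man, "visit_date": f"2017-0{i+1}-01"}
                     for i in range(k)]
        v = visit_table(rows)
        assert set(filter_min_visits(v, 2)["man_id"]) == {"b", "c", "d"}
        assert set(filter_min_visits(v, 3)["man_id"]) == {"c", "d"}

    def test_identity_when_all_qualify_and_idempotent(self):
        v = visit_table([
            {"man_id": "a", "visit_date": "2017-01-01"},
            {"man_id": "a", "visit_date": "2017-02-01"},
        ])
        out = filter_min_visits(v, 2)
        pd.testing.assert_frame_equal(out, v)
        pd.testing.assert_frame_equal(filter_min_visits(out, 2), out)


class TestVariableSelection:
    @staticmethod
    def table(n_men=40, months=50, value=1.0, nan_frac=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_men):
            for t in range(0, months, 2):
                val = np.nan if rng.random() < nan_frac else value
                rows.append({"man_id": f"m{i}",
                             "visit_date": str(pd.Period("2015-01", "M") + t),
                             "x": val})
        df = pd.DataFrame(rows)
        df["visit_date"] = df["visit_date"] + "-15"
        return df

    def spec(self):
        return IndicatorSpec("x", "x", (1.0,), "increase")

    def test_qualifying_indicator_selected(self):
        out = select_longitudinal_variables(
            self.table(), [self.spec()], min_span_years=3, min_peak_freq=0.2,
            min_valid=100,
        )
        assert [s.name for s in out] == ["x"]

    def test_fully_missing_item_excluded_with_advice(self):
        with pytest.raises(ValueError, match="threshold"):
            select_longitudinal_variables(
                self.table(nan_frac=1.0), [self.spec()], 3, 0.2, 100
            )

    def test_valid_count_threshold_is_strict(self):
        t = self.table(n_men=4, months=50)  # 100 valid records
        with pytest.raises(ValueError):
            select_longitudinal_variables(t, [self.spec()], 3, 0.2, min_valid=100)
        out = select_longitudinal_variables(t, [self.spec()], 3, 0.2, min_valid=99)
        assert len(out) == 1

    def test_span_threshold_is_strict(self):
        t = self.table(months=36)  # 34 months of span: below 3 years
        with pytest.raises(ValueError):
            select_longitudinal_variables(t, [self.spec()], 3, 0.2, 10)

    def test_peak_frequency_threshold(self):
        # all-zero indicator never exceeds 20% monthly frequency
        t = self.table(value=0.0)
        with pytest.raises(ValueError):
            select_longitudinal_variables(t, [self.spec()], 3, 0.2, 10)


class TestBinarize:
    def test_multilevel_expansion_and_missingness(self):
        v = visit_table([
            {"man_id": "a", "visit_date": "2017-01-01", "online_partners": "none"},
            {"man_id": "a", "visit_date": "2017-02-01",
             "online_partners": "more_than_half"},
            {"man_id": "a", "visit_date": "2017-03-01", "online_partners": M},
        ])
        specs = [
            IndicatorSpec("online_more_than_half", "online_partners",
                          ("more_than_half",), "increase"),
            IndicatorSpec("online_up_to_half", "online_partners",
                          ("up_to_half",), "increase"),
        ]
        out = ingest.binarize(v, specs)
        assert list(out["online_more_than_half"].fillna(-1)) == [0.0, 1.0, -1]
        assert list(out["online_up_to_half"].fillna(-1)) == [0.0, 0.0, -1]

    def test_missing_source_item_raises(self):
        v = visit_table([{"man_id": "a", "visit_date": "2017-01-01"}])
        with pytest.raises(KeyError):
            ingest.binarize(v, [IndicatorSpec("x", "x")])
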