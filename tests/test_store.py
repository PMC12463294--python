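"""Parsing, deduplication, drug selection and pair counting."""

import numpy as np
import pandas as pd
import pytest

from pvsignals import (
    GeneratorConfig,
    build_drug_event_pairs,
    deduplicate,
    generate_store,
    select_drug_reports,
)
from pvsignals.store import FaersParseError, parse_quarter

from conftest import write_quarter_files


class TestParsing:
    def test_row_counts_and_fields(self, tiny_store):
        assert tiny_store.n_reports == 3
        assert set(tiny_store.demo["primaryid"]) == {"101", "102", "103"}
        # drug names normalised, roles decoded
        row = tiny_store.drugs.iloc[0]
        assert row["drug_name"] == "LANTUS SOLOSTAR"
        assert row["role"] == "primary-suspect"
        # reactions normalised; the duplicate PT rows survive parsing (they
        # collapse at pair-building time, not here)
        assert len(tiny_store.reactions) == 5
        # therapy dates merged onto drug records
        assert tiny_store.drugs.iloc[0]["therapy_start_date"] == "20200101"

    def test_missing_age_and_unit_conversion(self, tiny_store):
        demo = tiny_store.demo.set_index("primaryid")
        assert np.isnan(demo.loc["102", "age_years"])
        assert demo.loc["101", "age_years"] == 34.0
        assert demo.loc["103", "age_years"] == pytest.approx(2.0, abs=0.01)  # 24 months

    def test_missing_primary_id_column_is_hard_error(self, tmp_path):
        paths = write_quarter_files(tmp_path, demo="caseid$sex\nA1$F")
        with pytest.raises(FaersParseError, match="primaryid"):
            parse_quarter(paths)

    def test_malformed_rows_skipped(self, tmp_path):
        paths = write_quarter_files(
            tmp_path,
            demo="primaryid$caseid$sex\n1$A$F\nbroken_line_without_fields\n2$B$M",
        )
        store = parse_quarter(paths)
        assert store.n_reports == 2

    def test_synthetic_roundtrip_counts(self, small_synth):
        store, truth = small_synth
        c = store.counts()
        assert c["demo"] == truth.table_row_counts["demo"]
        assert c["drug"] == truth.table_row_counts["drug"]
        assert c["reac"] == truth.table_row_counts["reac"]
        assert c["deleted_cases"] == len(truth.deleted_case_ids)


class TestDeduplicate:
    def _store(self, tmp_path, demo, deleted="caseid\n"):
        return parse_quarter(write_quarter_files(tmp_path, demo=demo, deleted=deleted))

    def test_latest_report_date_wins(self, tmp_path):
        s = self._store(tmp_path, "primaryid$caseid$fda_dt\n1$X$20200101\n2$X$20210101")
        out = deduplicate(s)
        assert list(out.demo["primaryid"]) == ["2"]

    def test_tie_broken_by_largest_primaryid(self, tmp_path):
        s = self._store(tmp_path, "primaryid$caseid$fda_dt\n11$X$20200101\n12$X$20200101")
        out = deduplicate(s)
        assert list(out.demo["primaryid"]) == ["12"]

    def test_deleted_cases_removed(self, tmp_path):
        s = self._store(
            tmp_path, "primaryid$caseid$fda_dt\n1$X$20200101\n2$Y$20200101", "caseid\nY"
        )
        out = deduplicate(s)
        assert set(out.demo["caseid"]) == {"X"}

    def test_idempotent_and_one_report_per_case(self, small_synth):
        store, truth = small_synth
        once = deduplicate(store)
        twice = deduplicate(once)
        assert once.demo["caseid"].is_unique
        pd.testing.assert_frame_equal(
            once.demo.reset_index(drop=True), twice.demo.reset_index(drop=True)
        )

    def test_survivor_count_matches_generator(self):
        # 50 cases all duplicated, 5 deleted -> 45 survive
        store, truth = generate_store(
            GeneratorConfig(n_cases=50, duplicate_rate=1.0, deleted_fraction=0.1,
                            pregnancy_fraction=0.0, n_paternal_decoys=0,
                            n_male_decoys=0, seed=3)
        )
        assert store.n_reports > 50  # duplicates present before dedup
        assert deduplicate(store).n_reports == 45 == truth.n_surviving_reports


class TestSelectDrugReports:
    def test_substring_match_and_role_filter(self, tiny_store):
        dd = deduplicate(tiny_store)
        hit = select_drug_reports(dd, ["INSULIN GLARGINE", "LANTUS"], ["primary-suspect"])
        assert hit.report_ids == {"101", "102"}
        # 103 has a matching-name drug nowhere; same report under a
        # non-selected role is dropped
        none = select_drug_reports(dd, ["ASPIRIN"], ["primary-suspect"])
        assert none.report_ids == set()
        ss = select_drug_reports(dd, ["ASPIRIN"], ["secondary-suspect"])
        assert ss.report_ids == {"103"}

    def test_empty_pattern_list_errors(self, tiny_store):
        with pytest.raises(ValueError):
            select_drug_reports(tiny_store, [], ["primary-suspect"])

    def test_wildcard_all_roles_returns_everything(self, small_dedup):
        dd, _ = small_dedup
        from pvsignals.store import ALL_ROLES

        out = select_drug_reports(dd, ["*"], ALL_ROLES)
        assert out.report_ids == dd.report_ids

    def test_counts_match_generator_truth(self, small_dedup):
        dd, truth = small_dedup
        hit = select_drug_reports(dd)
        lbl = truth.report_labels
        expected = set(lbl.loc[lbl["exposed"] & ~lbl["deleted"], "primaryid"].astype(str))
        assert hit.report_ids == expected


class TestPairs:
    def test_distinct_pts_counted_duplicates_collapsed(self, tiny_store):
        dd = deduplicate(tiny_store)
        pairs = build_drug_event_pairs(dd, {"101"})
        # report 101 lists Hypoglycaemia twice -> one pair
        p101 = pairs[pairs["primaryid"] == "101"]
        assert len(p101) == 2
        assert set(p101["pt_name"]) == {"HYPOGLYCAEMIA", "HEADACHE"}
        assert len(pairs) == 4
        assert pairs["exposed"].sum() == 2

    def test_totals_match_generator_truth(self, small_dedup):
        dd, truth = small_dedup
        drug_ids = select_drug_reports(dd).report_ids
        pairs = build_drug_event_pairs(dd, drug_ids)
        assert len(pairs) == len(truth.pairs)
        assert pairs["exposed"].sum() == truth.pairs["exposed"].sum()

    def test_pair_invariants(self, small_dedup):
        dd, _ = small_dedup
        drug_ids = select_drug_reports(dd).report_ids
        pairs = build_drug_event_pairs(dd, drug_ids)
        assert pairs["exposed"].sum() <= len(pairs)
        assert set(pairs["primaryid"]) <= dd.report_ids
        assert not pairs.duplicated(["primaryid", "pt_name"]).any()
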