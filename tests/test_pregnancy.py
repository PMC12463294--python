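"""Pregnancy-cohort flagging, exclusion rules and assembly."""

import pandas as pd
import pytest

from pvsignals import (
    SmqTermSet,
    assemble_pregnancy_cohort,
    deduplicate,
    flag_by_indication,
    flag_by_reaction_pts,
)
from pvsignals.pregnancy import apply_exclusions
from pvsignals.store import parse_quarter

from conftest import write_quarter_files


def _mini_store(tmp_path):
    paths = write_quarter_files(
        tmp_path,
        demo="""
        primaryid$caseid$fda_dt$sex$age$age_cod
        1$A$20200101$F$30$YR
        2$B$20200101$M$40$YR
        3$C$20200101$F$70$YR
        4$D$20200101$F$25$YR
        5$E$20200101$F$28$YR
        """,
        reac="""
        primaryid$pt$pt_code
        1$Maternal exposure during pregnancy$10071408
        2$Exposure via father$10071403
        3$Maternal exposure during pregnancy$10071408
        4$Headache$
        5$Maternal exposure during pregnancy$10071408
        """,
        indi="""
        primaryid$indi_drug_seq$indi_pt
        4$1$GESTATIONAL DIABETES
        5$1$PREGNANCY
        """,
    )
    return deduplicate(parse_quarter(paths))


class TestFlagging:
    def test_reaction_flag_by_code_and_name(self, tmp_path, term_sets):
        store = _mini_store(tmp_path)
        ids = flag_by_reaction_pts(store, term_sets["pregnancy-inclusion"])
        assert ids == {"1", "2", "3", "5"}  # code 10071408 + paternal pool
        name_only = SmqTermSet(
            role="pregnancy-inclusion",
            pt_names=frozenset({"MATERNAL EXPOSURE DURING PREGNANCY"}),
        )
        assert flag_by_reaction_pts(store, name_only) == {"1", "3", "5"}

    def test_indication_exact_match(self, tmp_path, term_sets):
        store = _mini_store(tmp_path)
        ids = flag_by_indication(store, term_sets["indication-inclusion"])
        assert ids == {"4", "5"}
        narrow = SmqTermSet(role="indication-inclusion", pt_names=frozenset({"DIABETES MELLITUS"}))
        assert flag_by_indication(store, narrow) == set()

    def test_empty_term_set_errors(self, tmp_path):
        store = _mini_store(tmp_path)
        with pytest.raises(ValueError):
            flag_by_reaction_pts(store, SmqTermSet(role="pregnancy-inclusion"))
        with pytest.raises(ValueError):
            flag_by_indication(store, SmqTermSet(role="indication-inclusion"))

    def test_synthetic_stratum_flagged_exactly(self, small_dedup, term_sets):
        dd, truth = small_dedup
        rx = flag_by_reaction_pts(dd, term_sets["pregnancy-inclusion"])
        ind = flag_by_indication(dd, term_sets["indication-inclusion"])
        union = rx | ind
        truth_ids = {str(i) for i in truth.pregnancy_ids}
        decoys = {str(i) for i in truth.paternal_decoy_ids | truth.male_decoy_ids}
        assert union == truth_ids | decoys


class TestExclusions:
    def test_rules_and_reasons(self, tmp_path, term_sets):
        store = _mini_store(tmp_path)
        excluded, kept = apply_exclusions(
            store, {"1", "2", "3", "5"}, term_sets["paternal-exposure"]
        )
        by_id = {e.report_id: set(e.reasons) for e in excluded}
        # male with only a paternal-exposure flag: both rules fire
        assert by_id["2"] == {"paternal-exposure", "gender-incompatibility"}
        # female aged 70 with default bounds [6, 55]
        assert by_id["3"] == {"age"}
        assert kept == {"1", "5"}

    def test_male_kept_with_fetal_justification(self, tmp_path, term_sets):
        paths = write_quarter_files(
            tmp_path,
            demo="primaryid$caseid$fda_dt$sex\n9$Z$20200101$M",
            reac="primaryid$pt$pt_code\n9$Foetal exposure during pregnancy$10071404",
        )
        store = deduplicate(parse_quarter(paths))
        fetal = term_sets["fetal-neonatal"]
        _, kept = apply_exclusions(store, {"9"}, term_sets["paternal-exposure"], fetal_terms=fetal)
        assert kept == {"9"}
        _, kept_nofetal = apply_exclusions(store, {"9"}, term_sets["paternal-exposure"])
        assert kept_nofetal == set()


class TestAssembly:
    def _assemble(self, store, term_sets, **kw):
        return assemble_pregnancy_cohort(
            store,
            inclusion_terms=term_sets["pregnancy-inclusion"],
            indication_terms=term_sets["indication-inclusion"],
            paternal_terms=term_sets["paternal-exposure"],
            **kw,
        )

    def test_no_pregnancy_terms_anywhere_gives_empty_cohort(self, tmp_path, term_sets):
        paths = write_quarter_files(
            tmp_path,
            demo="primaryid$caseid$fda_dt$sex\n1$A$20200101$F",
            reac="primaryid$pt\n1$Headache",
        )
        store = deduplicate(parse_quarter(paths))
        cohort, flow = self._assemble(store, term_sets)
        assert cohort == set()
        assert all(v == 0 for v in flow.as_dict().values())

    def test_union_counts_double_flagged_once(self, tmp_path, term_sets):
        store = _mini_store(tmp_path)  # report 5 is flagged both ways
        cohort, flow = self._assemble(store, term_sets)
        assert flow.union_deduplicated == 5
        assert flow.smq_flagged + flow.indication_flagged == 6
        assert cohort == {"1", "4", "5"}
        assert flow.final_cohort == flow.clearly_pregnancy + flow.recovered_after_review

    def test_generator_ground_truth_cohort(self, small_dedup, term_sets):
        dd, truth = small_dedup
        cohort, flow = self._assemble(dd, term_sets)
        assert cohort == {str(i) for i in truth.pregnancy_ids}
        assert len(cohort) == 80
        assert flow.excluded == 8  # 5 paternal + 3 male decoys

    def test_monotone_in_term_sets(self, small_dedup, term_sets):
        dd, _ = small_dedup
        cohort_full, _ = self._assemble(dd, term_sets)
        # shrink the inclusion set: cohort can only shrink
        small_incl = SmqTermSet(role="pregnancy-inclusion", pt_codes=frozenset({10071408}))
        cohort_small, _ = assemble_pregnancy_cohort(
            dd,
            inclusion_terms=small_incl,
            indication_terms=term_sets["indication-inclusion"],
            paternal_terms=term_sets["paternal-exposure"],
        )
        assert cohort_small <= cohort_full
        # grow the paternal list: cohort can only shrink
        bigger_paternal = SmqTermSet(
            role="paternal-exposure",
            pt_names=term_sets["paternal-exposure"].pt_names
            | term_sets["pregnancy-inclusion"].pt_names,
        )
        cohort_pat, _ = assemble_pregnancy_cohort(
            dd,
            inclusion_terms=term_sets["pregnancy-inclusion"],
            indication_terms=term_sets["indication-inclusion"],
            paternal_terms=bigger_paternal,
        )
        assert cohort_pat <= cohort_full

    def test_order_invariance(self, small_dedup, term_sets):
        dd, _ = small_dedup
        shuffled = dd.restrict(dd.report_ids)
        shuffled.demo = shuffled.demo.sample(frac=1, random_state=5).reset_index(drop=True)
        shuffled.reactions = shuffled.reactions.sample(frac=1, random_state=6).reset_index(drop=True)
        c1, f1 = self._assemble(dd, term_sets)
        c2, f2 = self._assemble(shuffled, term_sets)
        assert c1 == c2
        assert f1.as_dict() == f2.as_dict()

    def test_cohort_disjoint_from_excluded_and_subset_of_store(self, small_dedup, term_sets):
        dd, truth = small_dedup
        cohort, flow = self._assemble(dd, term_sets)
        assert cohort <= dd.report_ids
        excluded_ids = {str(i) for i in truth.paternal_decoy_ids | truth.male_decoy_ids}
        assert cohort.isdisjoint(excluded_ids)
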