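"""Report qualification, normalization and pair-table construction."""
from __future__ import annotations

import pandas as pd
import pytest

from adrquant.qualification import (
    QualificationRules,
    build_pair_table,
    filter_by_support,
    normalize_adrs,
    normalize_drugs,
    qualify_reports,
)
from adrquant.records import ADEReport, ADRMention, DrugMention
from adrquant.vocab import Outcome
from conftest import make_report


def naive_pair_table(reports) -> dict:
    """Brute-force double-loop recount of pair contingencies."""
    drugs_of = [{m.drug_id for m in r.drugs if m.drug_id} for r in reports]
    adrs_of = [{m.pt_id for m in r.adrs if m.pt_id} for r in reports]
    combos = {
        (d, a) for ds, as_ in zip(drugs_of, adrs_of) for d in ds for a in as_
    }
    out = {}
    for d, adr in combos:
        a = sum(1 for ds, as_ in zip(drugs_of, adrs_of) if d in ds and adr in as_)
        b = sum(1 for ds, as_ in zip(drugs_of, adrs_of) if d in ds and adr not in as_)
        c = sum(1 for ds, as_ in zip(drugs_of, adrs_of) if d not in ds and adr in as_)
        dd = len(reports) - a - b - c
        out[(d, adr)] = (a, b, c, dd)
    return out


class TestQualifyReports:
    @pytest.fixture
    def mixed_reports(self):
        reports = []
        # 4 clean professional reports
        for i in range(4):
            reports.append(make_report(f"OK{i}", ["D1"], {"A1": Outcome.RECOVERED}))
        # 3 nonprofessional
        for i in range(3):
            reports.append(
                make_report(f"NP{i}", ["D1"], {"A1": None}, reporter="nonprofessional")
            )
        # 2 whose only ADR sits under an excluded SOC
        for i in range(2):
            reports.append(
                ADEReport(
                    report_id=f"SOC{i}",
                    reporter_class="professional",
                    drugs=[DrugMention(name="D1", drug_id="D1")],
                    adrs=[ADRMention(term="A9", soc="product issues", outcome=None)],
                )
            )
        # 1 with a multi-ingredient drug
        reports.append(
            make_report("MI0", ["D2"], {"A1": None}, single_ingredient=False)
        )
        return reports

    def test_hand_counted_attrition(self, mixed_reports):
        audit: dict = {}
        kept = qualify_reports(mixed_reports, audit=audit)
        assert len(kept) == 4
        rec = audit["qualification"]
        assert rec["nonprofessional"] == 3
        assert rec["excluded_soc_only"] == 2
        assert rec["non_single_ingredient_small_molecule"] == 1

    def test_identity_on_clean_input(self):
        reports = [make_report(f"R{i}", ["D1"], {"A1": None}) for i in range(5)]
        assert qualify_reports(reports) == reports

    def test_idempotent(self, mixed_reports):
        once = qualify_reports(mixed_reports)
        assert qualify_reports(once) == once

    def test_empty_input(self):
        assert qualify_reports([]) == []

    def test_duplicate_ids_keep_first(self):
        reports = [
            make_report("R1", ["D1"], {"A1": None}),
            make_report("R1", ["D2"], {"A2": None}),
        ]
        kept = qualify_reports(reports)
        assert len(kept) == 1 and kept[0].drugs[0].drug_id == "D1"

    def test_excluded_soc_mention_dropped_but_report_kept(self):
        rep = ADEReport(
            report_id="R1",
            reporter_class="professional",
            drugs=[DrugMention(name="D1", drug_id="D1")],
            adrs=[
                ADRMention(term="A1", soc="nervous system disorders"),
                ADRMention(term="A9", soc="social circumstances"),
            ],
        )
        kept = qualify_reports([rep])
        assert len(kept) == 1 and [m.term for m in kept[0].adrs] == ["A1"]

    def test_unknown_soc_retained(self):
        rep = ADEReport(
            report_id="R1",
            reporter_class="professional",
            drugs=[DrugMention(name="D1", drug_id="D1")],
            adrs=[ADRMention(term="A1", soc="mystery organ class")],
        )
        assert len(qualify_reports([rep])) == 1


class TestNormalization:
    def test_cleaned_name_route(self, toy_dictionary):
        rep = ADEReport(
            report_id="R1",
            reporter_class="professional",
            drugs=[DrugMention(name="Aspirin 81 mg tablets")],
            adrs=[ADRMention(term="Headache")],
        )
        out = normalize_drugs([rep], toy_dictionary)[0].drugs[0]
        assert out.drug_id == "DB-ASA" and out.resolution == "cleaned"

    def test_product_code_takes_precedence(self, toy_dictionary):
        rep = ADEReport(
            report_id="R1",
            reporter_class="professional",
            drugs=[DrugMention(name="ibuprofen", product_code="PC-ASA")],
            adrs=[],
        )
        out = normalize_drugs([rep], toy_dictionary)[0].drugs[0]
        assert out.drug_id == "DB-ASA" and out.resolution == "product_code"

    def test_exact_synonym_bypasses_cleaning(self, toy_dictionary):
        rep = ADEReport(
            report_id="R1",
            reporter_class="professional",
            drugs=[DrugMention(name="Acetylsalicylic Acid")],
            adrs=[],
        )
        out = normalize_drugs([rep], toy_dictionary)[0].drugs[0]
        assert out.drug_id == "DB-ASA" and out.resolution == "exact"

    def test_unknown_name_flagged_not_dropped(self, toy_dictionary):
        rep = ADEReport(
            report_id="R1",
            reporter_class="professional",
            drugs=[DrugMention(name="unobtainium")],
            adrs=[],
        )
        out = normalize_drugs([rep], toy_dictionary)
        assert len(out) == 1
        assert out[0].drugs[0].drug_id is None
        assert "no dictionary match" in out[0].drugs[0].unresolved_reason

    def test_ambiguous_cleaned_match_flagged(self, toy_dictionary):
        rep = ADEReport(
            report_id="R1",
            reporter_class="professional",
            drugs=[DrugMention(name="cold remedy capsules")],
            adrs=[],
        )
        out = normalize_drugs([rep], toy_dictionary)[0].drugs[0]
        assert out.drug_id is None and "ambiguous" in out.unresolved_reason

    def test_adr_synonym_resolution(self, toy_ontology):
        rep = ADEReport(
            report_id="R1",
            reporter_class="professional",
            drugs=[],
            adrs=[
                ADRMention(term="Head ache"),
                ADRMention(term="Nausea"),
                ADRMention(term="gibberish"),
            ],
        )
        out = normalize_adrs([rep], toy_ontology)[0].adrs
        assert [m.pt_id for m in out] == ["PT-HEAD", "PT-NAUS", None]

    def test_normalization_stable_under_reapplication(self, toy_dictionary, toy_ontology):
        rep = ADEReport(
            report_id="R1",
            reporter_class="professional",
            drugs=[DrugMention(name="aspirin")],
            adrs=[ADRMention(term="head ache")],
        )
        once = normalize_adrs(normalize_drugs([rep], toy_dictionary), toy_ontology)
        twice = normalize_adrs(normalize_drugs(once, toy_dictionary), toy_ontology)
        assert once == twice


class TestPairTable:
    def test_four_report_example(self):
        reports = [
            make_report("R1", ["D1"], {"A1": None}),
            make_report("R2", ["D1"], {"A1": None}),
            make_report("R3", ["D1"], {"A2": None}),
            make_report("R4", ["D2"], {"A1": None}),
        ]
        pairs = build_pair_table(reports).set_index(["drug_id", "adr_id"])
        row = pairs.loc[("D1", "A1")]
        assert (row.a, row.b, row.c, row.d) == (2, 1, 1, 0)

    def test_multi_adr_report_feeds_every_pair(self):
        reports = [make_report("R1", ["D1"], {"A1": Outcome.FATAL, "A2": None})]
        pairs = build_pair_table(reports).set_index(["drug_id", "adr_id"])
        assert pairs.loc[("D1", "A1")].a == 1
        assert pairs.loc[("D1", "A2")].a == 1
        assert pairs.loc[("D1", "A1")].o5 == 1
        assert pairs.loc[("D1", "A2")][["o1", "o2", "o3", "o4", "o5"]].sum() == 0

    def test_single_report_total(self):
        pairs = build_pair_table([make_report("R1", ["D1"], {"A1": None})])
        row = pairs.iloc[0]
        assert (row.a, row.b, row.c, row.d) == (1, 0, 0, 0)

    def test_matches_naive_recount(self, random_reports):
        pairs = build_pair_table(random_reports)
        oracle = naive_pair_table(random_reports)
        assert len(pairs) == len(oracle)
        for row in pairs.itertuples(index=False):
            assert (row.a, row.b, row.c, row.d) == oracle[(row.drug_id, row.adr_id)]

    def test_cell_conservation(self, random_reports):
        pairs = build_pair_table(random_reports)
        totals = pairs[["a", "b", "c", "d"]].sum(axis=1)
        assert (totals == len(random_reports)).all()

    def test_missing_outcomes_count_in_a_but_not_in_tallies(self):
        reports = [
            make_report("R1", ["D1"], {"A1": Outcome.RECOVERED}),
            make_report("R2", ["D1"], {"A1": None}),
        ]
        row = build_pair_table(reports).iloc[0]
        assert row.n_reports == 2
        assert row[["o1", "o2", "o3", "o4", "o5"]].sum() == 1


class TestSupportFilter:
    def test_drug_threshold_on_prefilter_totals(self):
        reports = [
            make_report(f"R{i}", ["BIG"], {"A1": None}) for i in range(30)
        ] + [make_report(f"S{i}", ["SMALL"], {"A1": None}) for i in range(20)]
        pairs = build_pair_table(reports)
        kept = filter_by_support(
            pairs, QualificationRules(min_drug_reports=26, min_adr_reports=2)
        )
        assert set(kept["drug_id"]) == {"BIG"}

    def test_zero_thresholds_identity(self, random_reports):
        pairs = build_pair_table(random_reports)
        kept = filter_by_support(
            pairs,
            QualificationRules(
                min_adr_reports=0, min_drug_reports=0, min_pair_reports=0
            ),
        )
        pd.testing.assert_frame_equal(kept, pairs)

    def test_pair_with_exactly_two_reports_survives_threshold_two(self):
        reports = [
            make_report(f"R{i}", ["D1"], {"A1": None}) for i in range(2)
        ]
        pairs = build_pair_table(reports)
        kept = filter_by_support(
            pairs, QualificationRules(min_drug_reports=0, min_pair_reports=2)
        )
        assert len(kept) == 1

    def test_empty_table_passthrough(self):
        empty = build_pair_table([])
        assert filter_by_support(empty).empty
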