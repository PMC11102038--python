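"""Shared fixtures: toy dictionary/ontology and report builders."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from adrquant.records import (
    ADEReport,
    ADRMention,
    ADROntology,
    ADRTerm,
    DrugDictionary,
    DrugEntry,
    DrugMention,
)
from adrquant.vocab import Outcome

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def toy_dictionary() -> DrugDictionary:
    return DrugDictionary(
        [
            DrugEntry(
                drug_id="DB-ASA",
                name="aspirin",
                synonyms=["acetylsalicylic acid"],
                product_codes=["PC-ASA"],
                atc="N02BA01",
            ),
            DrugEntry(
                drug_id="DB-IBU",
                name="ibuprofen",
                synonyms=["brufen"],
                product_codes=["PC-IBU"],
                atc="M01AE01",
            ),
            DrugEntry(
                drug_id="DB-NPX",
                name="naproxen",
                synonyms=[],
                product_codes=[],
                atc="M01AE02",
            ),
            # two entries whose cleaned names collide ("cold remedy")
            DrugEntry(drug_id="DB-CR1", name="cold remedy mg", synonyms=[]),
            DrugEntry(drug_id="DB-CR2", name="cold remedy tablets", synonyms=[]),
        ]
    )


@pytest.fixture
def toy_ontology() -> ADROntology:
    return ADROntology(
        [
            ADRTerm(
                pt_id="PT-HEAD",
                pt_name="Headache",
                soc="nervous system disorders",
                synonyms=["head ache"],
            ),
            ADRTerm(
                pt_id="PT-NAUS",
                pt_name="Nausea",
                soc="gastrointestinal disorders",
            ),
            ADRTerm(
                pt_id="PT-DEVICE",
                pt_name="Device failure",
                soc="product issues",
            ),
        ]
    )


def make_report(
    rid: str,
    drug_ids: list[str],
    adr_outcomes: dict[str, Outcome | None],
    reporter: str = "professional",
    single_ingredient: bool = True,
) -> ADEReport:
    """Report with already-normalized drug/ADR identities (for stages
    downstream of normalization)."""
    return ADEReport(
        report_id=rid,
        reporter_class=reporter,
        drugs=[
            DrugMention(name=d, drug_id=d, single_ingredient=single_ingredient)
            for d in drug_ids
        ],
        adrs=[
            ADRMention(term=a, pt_id=a, soc="nervous system disorders", outcome=oc)
            for a, oc in adr_outcomes.items()
        ],
    )


@pytest.fixture
def random_reports() -> list[ADEReport]:
    """~80 reports over 5 drugs and 6 ADRs for oracle comparisons."""
    rng = np.random.default_rng(42)
    drugs = [f"D{i}" for i in range(5)]
    adrs = [f"A{j}" for j in range(6)]
    outcomes = list(Outcome) + [None]
    reports = []
    for r in range(80):
        nd = rng.integers(1, 3)
        na = rng.integers(1, 4)
        ds = list(rng.choice(drugs, size=nd, replace=False))
        as_ = list(rng.choice(adrs, size=na, replace=False))
        adr_oc = {a: outcomes[rng.integers(len(outcomes))] for a in as_}
        reports.append(make_report(f"R{r:04d}", ds, adr_oc))
    return reports
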