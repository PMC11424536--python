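"""Shared fixtures: toy ontologies, dictionaries, and report factories."""

from __future__ import annotations

from datetime import date

import pytest

from pvsignal import DrugEntry, MeddraMap, ReportRecord, SynonymDictionary


@pytest.fixture
def toy_meddra() -> MeddraMap:
    """A miniature invented PT -> SOC map (not MedDRA content)."""
    return MeddraMap(
        {
            "Stevens-Johnson syndrome": "Skin and subcutaneous tissue disorders",
            "Rash": "Skin and subcutaneous tissue disorders",
            "Crystalluria": "Renal and urinary disorders",
            "Glomerulonephritis": "Renal and urinary disorders",
            "Agranulocytosis": "Blood and lymphatic system disorders",
            "Eosinophilic pneumonia": "Respiratory, thoracic and mediastinal disorders",
            "Nausea": "Gastrointestinal disorders",
            "Headache": "Nervous system disorders",
        },
        version="toy-1",
    )


@pytest.fixture
def toy_dictionary() -> SynonymDictionary:
    return SynonymDictionary(
        {
            "sulfasalazine": "sulfasalazine",
            "azulfidine": "sulfasalazine",
            "azulfidine en tabs": "sulfasalazine",
            "salazopyrin": "sulfasalazine",
            "sulphasalazine": "sulfasalazine",
            "methotrexate": "methotrexate",
            "mtx": "methotrexate",
        }
    )


def make_report(
    report_id: str = "1001",
    case_id: str | None = "100",
    case_version: int = 1,
    drugs: list[tuple[str, str]] = (("sulfasalazine", "PS"),),
    reactions: list[str] = ("Rash",),
    receipt_date: date | None = date(2020, 1, 1),
    **kwargs,
) -> ReportRecord:
    """Terse factory for hand-built reports in tests."""
    return ReportRecord(
        report_id=report_id,
        case_id=case_id,
        case_version=case_version,
        receipt_date=receipt_date,
        drugs=[
            DrugEntry(drug_seq=i + 1, raw_name=name, role=role)
            for i, (name, role) in enumerate(drugs)
        ],
        reactions=list(reactions),
        **kwargs,
    )


@pytest.fixture
def report_factory():
    return make_report
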