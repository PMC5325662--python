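"""Shared fixtures: a small hand-built evidence base and helpers.

Everything is generated programmatically; no fixture files ship with the
repository.
"""

from __future__ import annotations

import json

import pytest
from hypothesis import settings

settings.register_profile("dxearly", derandomize=True, deadline=None)
settings.load_profile("dxearly")

from dxearly.consultation import CodedFinding
from dxearly.evidence import EvidenceBase, PatientContext, parse_evidence_base


def toy_document() -> dict:
    """Three-RfE evidence base with hand-chosen incidences and likelihoods."""
    return {
        "version": "toy-1",
        "findings": {
            "f_vomit": {"label": "vomiting", "synonyms": ["emesis"]},
            "f_fever": {"label": "fever", "synonyms": []},
            "f_rlq": {"label": "right lower quadrant pain", "synonyms": []},
            "f_diarrhoea": {"label": "diarrhoea", "synonyms": []},
            "f_exertional": {"label": "pain on exertion", "synonyms": []},
            "f_pleuritic": {"label": "pleuritic pain", "synonyms": []},
            "f_syncope": {"label": "syncope", "synonyms": ["fainting"]},
            "f_wheeze": {"label": "wheeze", "synonyms": []},
            "f_smoker": {"label": "current smoker", "synonyms": []},
        },
        "rfes": {
            "abdominal_pain": [
                {
                    "dx_id": "gastroenteritis",
                    "label": "Gastroenteritis",
                    "incidence": 300.0,
                    "sex": "both",
                    "age_min": 0,
                    "age_max": 110,
                    "associations": [
                        {"finding_id": "f_vomit", "p_given_dx": 0.8, "p_given_not_dx": 0.2},
                        {"finding_id": "f_diarrhoea", "p_given_dx": 0.7, "p_given_not_dx": 0.1},
                        {"finding_id": "f_fever", "p_given_dx": 0.5, "p_given_not_dx": 0.2},
                    ],
                },
                {
                    "dx_id": "appendicitis",
                    "label": "Acute appendicitis",
                    "incidence": 30.0,
                    "sex": "both",
                    "age_min": 0,
                    "age_max": 110,
                    "associations": [
                        {"finding_id": "f_rlq", "p_given_dx": 0.85, "p_given_not_dx": 0.1},
                        {"finding_id": "f_fever", "p_given_dx": 0.6, "p_given_not_dx": 0.2},
                        {"finding_id": "f_vomit", "p_given_dx": 0.5, "p_given_not_dx": 0.25},
                    ],
                },
                {
                    "dx_id": "ovarian_torsion",
                    "label": "Ovarian torsion",
                    "incidence": 2.0,
                    "sex": "female",
                    "age_min": 12,
                    "age_max": 50,
                    "associations": [
                        {"finding_id": "f_vomit", "p_given_dx": 0.6, "p_given_not_dx": 0.25},
                    ],
                },
                {
                    "dx_id": "mesenteric_ischaemia",
                    "label": "Mesenteric ischaemia",
                    "incidence": 5.0,
                    "sex": "both",
                    "age_min": 60,
                    "age_max": 110,
                    "associations": [
                        {"finding_id": "f_vomit", "p_given_dx": 0.4, "p_given_not_dx": 0.25},
                    ],
                },
            ],
            "chest_pain": [
                {
                    "dx_id": "angina",
                    "label": "Stable angina",
                    "incidence": 80.0,
                    "sex": "both",
                    "age_min": 30,
                    "age_max": 110,
                    "associations": [
                        {"finding_id": "f_exertional", "p_given_dx": 0.9, "p_given_not_dx": 0.2},
                        {"finding_id": "f_smoker", "p_given_dx": 0.6, "p_given_not_dx": 0.3},
                    ],
                },
                {
                    "dx_id": "pulmonary_embolism",
                    "label": "Pulmonary embolism",
                    "incidence": 20.0,
                    "sex": "both",
                    "age_min": 16,
                    "age_max": 110,
                    "associations": [
                        {"finding_id": "f_pleuritic", "p_given_dx": 0.7, "p_given_not_dx": 0.15},
                    ],
                },
                {
                    "dx_id": "aortic_stenosis",
                    "label": "Aortic stenosis",
                    "incidence": 8.0,
                    "sex": "both",
                    "age_min": 50,
                    "age_max": 110,
                    "associations": [
                        {"finding_id": "f_syncope", "p_given_dx": 0.5, "p_given_not_dx": 0.05},
                        {"finding_id": "f_exertional", "p_given_dx": 0.7, "p_given_not_dx": 0.2},
                    ],
                },
            ],
            "dyspnoea": [
                {
                    "dx_id": "asthma",
                    "label": "Asthma",
                    "incidence": 150.0,
                    "sex": "both",
                    "age_min": 0,
                    "age_max": 110,
                    "associations": [
                        {"finding_id": "f_wheeze", "p_given_dx": 0.85, "p_given_not_dx": 0.2},
                    ],
                },
                {
                    "dx_id": "copd",
                    "label": "COPD",
                    "incidence": 60.0,
                    "sex": "both",
                    "age_min": 40,
                    "age_max": 110,
                    "associations": [
                        {"finding_id": "f_wheeze", "p_given_dx": 0.7, "p_given_not_dx": 0.25},
                        {"finding_id": "f_smoker", "p_given_dx": 0.9, "p_given_not_dx": 0.3},
                    ],
                },
            ],
        },
    }


@pytest.fixture()
def toy_eb() -> EvidenceBase:
    return parse_evidence_base(toy_document())


@pytest.fixture()
def toy_eb_file(tmp_path):
    path = tmp_path / "toy_eb.json"
    path.write_text(json.dumps(toy_document()), encoding="utf-8")
    return path


@pytest.fixture()
def abdo_ctx() -> PatientContext:
    return PatientContext(age=30, sex="female", rfe="abdominal_pain")


def coded(finding_id: str, status: str = "present", seq: int = 1) -> CodedFinding:
    return CodedFinding(finding_id=finding_id, status=status, seq=seq)
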