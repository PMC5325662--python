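"""Sequence-ordered coded consultation records and their episode-of-care export.

During a consultation the clinician codes findings present or absent, in any
order, optionally with a free-text note.  The record keeps every coded entry
with a 1-based sequence number (``seq``) — the canonical entry order; there
are no timestamps because a simulated consultation has no wall clock.
Re-coding a finding replaces its status in place (a checkbox has one state)
but preserves the original ``seq``.

At the end, the record is finalized with a working diagnosis, an optional
differential, a certainty rating (0 "not at all certain" to 10 "absolutely
certain"), one or more management actions (prescribe / refer / follow-up /
return if symptoms persist), and any tests ordered.  A finalized record is
immutable and can be exported as a JSON-compatible structured document that
round-trips losslessly through :func:`import_record`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .errors import DomainError, FinalizedRecordError, ReferenceLookupError, SchemaError
from .evidence import EvidenceBase, PatientContext

__all__ = [
    "CodedFinding",
    "ManagementAction",
    "ConsultationRecord",
    "code_finding",
    "finalize",
    "export_record",
    "import_record",
    "MANAGEMENT_ACTIONS",
]

MANAGEMENT_ACTIONS = ("prescribe", "refer", "follow_up", "return_if_persists")


@dataclass(frozen=True)
class CodedFinding:
    """One coded observation: a finding marked present or absent."""

    finding_id: str
    status: str  # "present" | "absent"
    seq: int  # 1-based entry order within the record
    note: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status not in ("present", "absent"):
            raise DomainError(f"status must be present/absent, got {self.status!r}")
        if self.seq < 1:
            raise DomainError(f"seq must be >= 1, got {self.seq}")

    @property
    def present(self) -> bool:
        return self.status == "present"


@dataclass(frozen=True)
class ManagementAction:
    action: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.action not in MANAGEMENT_ACTIONS:
            raise DomainError(
                f"action must be one of {MANAGEMENT_ACTIONS}, got {self.action!r}"
            )


@dataclass
class ConsultationRecord:
    """Audit of one consultation: the coded findings plus the recorded outcome."""

    patient: PatientContext
    coded: list[CodedFinding] = field(default_factory=list)
    working_dx: Optional[str] = None
    differential: tuple[str, ...] = ()
    certainty: Optional[int] = None
    management: tuple[ManagementAction, ...] = ()
    tests_ordered: tuple[str, ...] = ()
    finalized: bool = False

    @property
    def coded_count(self) -> int:
        return len(self.coded)

    def coded_status(self, finding_id: str) -> Optional[str]:
        for cf in self.coded:
            if cf.finding_id == finding_id:
                return cf.status
        return None


def code_finding(
    rec: ConsultationRecord,
    finding_id: str,
    status: str,
    note: Optional[str] = None,
    *,
    eb: Optional[EvidenceBase] = None,
) -> ConsultationRecord:
    """Append a coded finding (or replace the status of a re-coded one).

    When ``eb`` is given, ``finding_id`` must resolve in it.  Returns the
    record (mutated in place) for chaining.
    """
    if rec.finalized:
        raise FinalizedRecordError("cannot code findings on a finalized record")
    if eb is not None and finding_id not in eb.findings:
        raise ReferenceLookupError(f"unknown finding {finding_id!r}")
    for i, existing in enumerate(rec.coded):
        if existing.finding_id == finding_id:
            # re-code: replace status/note, keep original seq
            rec.coded[i] = replace(existing, status=status, note=note)
            return rec
    rec.coded.append(
        CodedFinding(finding_id=finding_id, status=status, seq=len(rec.coded) + 1, note=note)
    )
    return rec


def finalize(
    rec: ConsultationRecord,
    working_dx: str,
    differential: Iterable[str] = (),
    certainty: int = 5,
    management: Iterable[ManagementAction] = (),
    tests_ordered: Iterable[str] = (),
) -> ConsultationRecord:
    """Record the consultation outcome and freeze the record."""
    if rec.finalized:
        raise FinalizedRecordError("record already finalized")
    differential = tuple(differential)
    management = tuple(management)
    if not 0 <= certainty <= 10:
        raise DomainError(f"certainty must be within [0, 10], got {certainty}")
    if not management:
        raise DomainError("at least one management action is required")
    if working_dx in differential:
        raise DomainError(
            f"working diagnosis {working_dx!r} must not also appear in the differential"
        )
    rec.working_dx = working_dx
    rec.differential = differential
    rec.certainty = certainty
    rec.management = management
    rec.tests_ordered = tuple(tests_ordered)
    rec.finalized = True
    return rec


# ---------------------------------------------------------------------------
# episode-of-care document export / import


def export_record(rec: ConsultationRecord) -> dict:
    """Serialize a finalized record to its structured JSON-compatible document.

    The export is lossless: ``import_record(export_record(rec)) == rec``
    field for field, including the coded sequence order.
    """
    if not rec.finalized:
        raise FinalizedRecordError("only finalized records can be exported")
    return {
        "patient": {
            "age": rec.patient.age,
            "sex": rec.patient.sex,
            "rfe": rec.patient.rfe,
            "risk_factors": list(rec.patient.risk_factors),
        },
        "coded": [
            {"finding_id": cf.finding_id, "status": cf.status, "seq": cf.seq, "note": cf.note}
            for cf in rec.coded
        ],
        "coded_count": len(rec.coded),
        "working_dx": rec.working_dx,
        "differential": list(rec.differential),
        "certainty": rec.certainty,
        "management": [{"action": m.action, "detail": m.detail} for m in rec.management],
        "tests_ordered": list(rec.tests_ordered),
    }


def import_record(doc: Mapping) -> ConsultationRecord:
    """Rebuild a finalized :class:`ConsultationRecord` from its document form."""
    try:
        pat = doc["patient"]
        patient = PatientContext(
            age=pat["age"],
            sex=pat["sex"],
            rfe=pat["rfe"],
            risk_factors=tuple(pat.get("risk_factors", ())),
        )
        coded = [
            CodedFinding(
                finding_id=c["finding_id"],
                status=c["status"],
                seq=c["seq"],
                note=c.get("note"),
            )
            for c in doc["coded"]
        ]
        rec = ConsultationRecord(
            patient=patient,
            coded=coded,
            working_dx=doc["working_dx"],
            differential=tuple(doc["differential"]),
            certainty=doc["certainty"],
            management=tuple(
                ManagementAction(action=m["action"], detail=m.get("detail", ""))
                for m in doc["management"]
            ),
            tests_ordered=tuple(doc["tests_ordered"]),
            finalized=True,
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"consultation record document: missing or malformed field ({exc})") from None
    seqs = [c.seq for c in rec.coded]
    if seqs != sorted(seqs) or len(set(seqs)) != len(seqs):
        raise SchemaError("consultation record document: coded seq values must be strictly increasing")
    fids = [c.finding_id for c in rec.coded]
    if len(set(fids)) != len(fids):
        raise SchemaError("consultation record document: duplicate coded finding_id")
    return rec


def write_record(rec: ConsultationRecord, path: str | Path) -> None:
    Path(path).write_text(json.dumps(export_record(rec), indent=2) + "\n", encoding="utf-8")


def read_record(path: str | Path) -> ConsultationRecord:
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON: {exc}") from None
    return import_record(doc)
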