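"""Evidence base: the declarative knowledge model behind diagnosis suggestion.

An evidence base maps each reason for encounter (RfE) — the presenting
complaint, e.g. ``chest_pain`` — to candidate diagnoses.  Each diagnosis
carries a published annual incidence (per 100,000 per annum), age/sex
applicability, and a set of associated findings (symptoms or signs) with
conditional occurrence probabilities: ``p_given_dx`` is the probability the
finding is present when the diagnosis is true, ``p_given_not_dx`` when it is
false.  These probabilities drive the likelihood-ratio re-ranking in
:mod:`dxearly.ranking`.

Diagnoses are grouped into incidence tiers for initial display:

* common:   incidence > 50 / 100,000 p.a.
* uncommon: 10 <= incidence <= 50 (both boundaries inclusive)
* rare:     incidence < 10

The on-disk format is a UTF-8 JSON document::

    {
      "version": "1",
      "findings": {
        "f_nausea": {"label": "nausea", "synonyms": ["feeling sick"]}
      },
      "rfes": {
        "abdominal_pain": [
          {"dx_id": "gastritis", "label": "Gastritis", "incidence": 120.0,
           "sex": "both", "age_min": 0, "age_max": 110,
           "associations": [
             {"finding_id": "f_nausea", "p_given_dx": 0.7, "p_given_not_dx": 0.2}
           ]}
        ]
      }
    }

``load_evidence_base`` validates the document and raises :class:`SchemaError`
naming the offending path, or :class:`ReferenceLookupError` for a dangling
``finding_id``.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import DomainError, ReferenceLookupError, SchemaError

__all__ = [
    "Finding",
    "FindingAssociation",
    "DiagnosisEntry",
    "EvidenceBase",
    "PatientContext",
    "IncidenceTier",
    "tier_of",
    "load_evidence_base",
    "parse_evidence_base",
    "candidate_diagnoses",
    "search_findings",
]

# Tier thresholds, per 100,000 per annum.  Both boundaries belong to the
# uncommon tier (closed interval [10, 50]).
COMMON_THRESHOLD = 50.0
RARE_THRESHOLD = 10.0


class IncidenceTier(enum.Enum):
    """Incidence tier of a diagnosis; display order common -> uncommon -> rare."""

    COMMON = "common"
    UNCOMMON = "uncommon"
    RARE = "rare"

    @property
    def order(self) -> int:
        return {"common": 0, "uncommon": 1, "rare": 2}[self.value]


def tier_of(incidence: float) -> IncidenceTier:
    """Classify a positive annual incidence (per 100,000) into its tier.

    Exactly 50 and exactly 10 both map to ``UNCOMMON``.
    """
    if not incidence > 0:
        raise DomainError(f"incidence must be positive, got {incidence!r}")
    if incidence > COMMON_THRESHOLD:
        return IncidenceTier.COMMON
    if incidence >= RARE_THRESHOLD:
        return IncidenceTier.UNCOMMON
    return IncidenceTier.RARE


@dataclass(frozen=True)
class Finding:
    """A symptom or sign that can be coded present or absent."""

    finding_id: str
    label: str
    synonyms: tuple[str, ...] = ()
    polarity_supported: bool = True

    def __post_init__(self) -> None:
        if not self.label:
            raise DomainError(f"finding {self.finding_id!r}: label must be non-empty")


@dataclass(frozen=True)
class FindingAssociation:
    """Conditional occurrence probabilities linking a finding to a diagnosis.

    Probabilities are strictly inside (0, 1) so likelihood ratios stay finite.
    """

    finding_id: str
    p_given_dx: float
    p_given_not_dx: float

    def __post_init__(self) -> None:
        for name in ("p_given_dx", "p_given_not_dx"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise DomainError(
                    f"association {self.finding_id!r}: {name} must be strictly "
                    f"between 0 and 1, got {p!r}"
                )


@dataclass(frozen=True)
class DiagnosisEntry:
    """A candidate diagnosis for one reason for encounter."""

    dx_id: str
    label: str
    incidence: float  # per 100,000 per annum
    sex_applicability: str  # "male", "female" or "both"
    age_range: tuple[int, int]  # inclusive [min_years, max_years]
    associations: tuple[FindingAssociation, ...]

    def __post_init__(self) -> None:
        if not self.incidence > 0:
            raise DomainError(f"diagnosis {self.dx_id!r}: incidence must be > 0")
        if self.sex_applicability not in ("male", "female", "both"):
            raise DomainError(
                f"diagnosis {self.dx_id!r}: sex_applicability must be "
                f"male/female/both, got {self.sex_applicability!r}"
            )
        lo, hi = self.age_range
        if lo > hi:
            raise DomainError(
                f"diagnosis {self.dx_id!r}: age_range min {lo} exceeds max {hi}"
            )
        if not self.associations:
            raise DomainError(f"diagnosis {self.dx_id!r}: at least one association required")

    @property
    def tier(self) -> IncidenceTier:
        return tier_of(self.incidence)

    def applies_to(self, age: int, sex: str) -> bool:
        """True when the entry's age range contains ``age`` and the sex matches."""
        lo, hi = self.age_range
        return (lo <= age <= hi) and self.sex_applicability in ("both", sex)


@dataclass(frozen=True)
class EvidenceBase:
    """Validated catalogue of findings and per-RfE diagnosis lists."""

    rfes: Mapping[str, tuple[DiagnosisEntry, ...]]
    findings: Mapping[str, Finding]
    version: str = "1"

    def __post_init__(self) -> None:
        for fid, f in self.findings.items():
            if fid != f.finding_id:
                raise SchemaError(
                    f"findings[{fid!r}]: key does not match finding_id {f.finding_id!r}"
                )
        for rfe, entries in self.rfes.items():
            seen: set[str] = set()
            for entry in entries:
                if entry.dx_id in seen:
                    raise SchemaError(f"rfes[{rfe!r}]: duplicate dx_id {entry.dx_id!r}")
                seen.add(entry.dx_id)
                for assoc in entry.associations:
                    if assoc.finding_id not in self.findings:
                        raise ReferenceLookupError(
                            f"rfes[{rfe!r}][{entry.dx_id!r}]: association refers to "
                            f"undeclared finding {assoc.finding_id!r}"
                        )

    def diagnoses_for(self, rfe: str) -> tuple[DiagnosisEntry, ...]:
        try:
            return self.rfes[rfe]
        except KeyError:
            raise ReferenceLookupError(f"unknown reason for encounter {rfe!r}") from None

    def diagnosis(self, rfe: str, dx_id: str) -> DiagnosisEntry:
        for entry in self.diagnoses_for(rfe):
            if entry.dx_id == dx_id:
                return entry
        raise ReferenceLookupError(f"unknown diagnosis {dx_id!r} under RfE {rfe!r}")

    def to_document(self) -> dict:
        """Serialize back to the JSON-compatible document form."""
        return {
            "version": self.version,
            "findings": {
                fid: {"label": f.label, "synonyms": list(f.synonyms)}
                for fid, f in self.findings.items()
            },
            "rfes": {
                rfe: [
                    {
                        "dx_id": e.dx_id,
                        "label": e.label,
                        "incidence": e.incidence,
                        "sex": e.sex_applicability,
                        "age_min": e.age_range[0],
                        "age_max": e.age_range[1],
                        "associations": [
                            {
                                "finding_id": a.finding_id,
                                "p_given_dx": a.p_given_dx,
                                "p_given_not_dx": a.p_given_not_dx,
                            }
                            for a in e.associations
                        ],
                    }
                    for e in entries
                ]
                for rfe, entries in self.rfes.items()
            },
        }


@dataclass(frozen=True)
class PatientContext:
    """The consultation trigger context: age, sex, risk factors and RfE.

    Risk factors are finding ids pre-coded as present so they participate in
    ranking from the start of the consultation.
    """

    age: int
    sex: str
    rfe: str
    risk_factors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.age < 0:
            raise DomainError(f"age must be non-negative, got {self.age}")
        if self.sex not in ("male", "female"):
            raise DomainError(f"sex must be male or female, got {self.sex!r}")


# ---------------------------------------------------------------------------
# document parsing / validation


def _require(obj: Mapping, key: str, typ, path: str):
    if key not in obj:
        raise SchemaError(f"{path}: missing required field {key!r}")
    val = obj[key]
    if typ is float:
        if not isinstance(val, (int, float)) or isinstance(val, bool):
            raise SchemaError(f"{path}.{key}: expected a number, got {type(val).__name__}")
        return float(val)
    if typ is int:
        if not isinstance(val, int) or isinstance(val, bool):
            raise SchemaError(f"{path}.{key}: expected an integer, got {type(val).__name__}")
        return val
    if not isinstance(val, typ):
        raise SchemaError(f"{path}.{key}: expected {typ.__name__}, got {type(val).__name__}")
    return val


def parse_evidence_base(doc: Mapping) -> EvidenceBase:
    """Validate a parsed JSON document and build an :class:`EvidenceBase`."""
    if not isinstance(doc, Mapping):
        raise SchemaError("document root: expected a JSON object")
    version = str(doc.get("version", "1"))
    raw_findings = _require(doc, "findings", Mapping, "document root")
    findings: dict[str, Finding] = {}
    for fid, fdoc in raw_findings.items():
        path = f"findings[{fid!r}]"
        if not isinstance(fdoc, Mapping):
            raise SchemaError(f"{path}: expected an object")
        label = _require(fdoc, "label", str, path)
        synonyms = fdoc.get("synonyms", [])
        if not isinstance(synonyms, list) or not all(isinstance(s, str) for s in synonyms):
            raise SchemaError(f"{path}.synonyms: expected a list of strings")
        try:
            findings[fid] = Finding(
                finding_id=fid,
                label=label,
                synonyms=tuple(synonyms),
                polarity_supported=bool(fdoc.get("polarity_supported", True)),
            )
        except DomainError as exc:
            raise SchemaError(f"{path}: {exc}") from None

    raw_rfes = _require(doc, "rfes", Mapping, "document root")
    rfes: dict[str, tuple[DiagnosisEntry, ...]] = {}
    for rfe, entries in raw_rfes.items():
        path = f"rfes[{rfe!r}]"
        if not isinstance(entries, list):
            raise SchemaError(f"{path}: expected a list of diagnosis objects")
        parsed: list[DiagnosisEntry] = []
        for i, edoc in enumerate(entries):
            epath = f"{path}[{i}]"
            if not isinstance(edoc, Mapping):
                raise SchemaError(f"{epath}: expected an object")
            raw_assocs = _require(edoc, "associations", list, epath)
            assocs = []
            for j, adoc in enumerate(raw_assocs):
                apath = f"{epath}.associations[{j}]"
                if not isinstance(adoc, Mapping):
                    raise SchemaError(f"{apath}: expected an object")
                try:
                    assocs.append(
                        FindingAssociation(
                            finding_id=_require(adoc, "finding_id", str, apath),
                            p_given_dx=_require(adoc, "p_given_dx", float, apath),
                            p_given_not_dx=_require(adoc, "p_given_not_dx", float, apath),
                        )
                    )
                except DomainError as exc:
                    raise SchemaError(f"{apath}: {exc}") from None
            try:
                parsed.append(
                    DiagnosisEntry(
                        dx_id=_require(edoc, "dx_id", str, epath),
                        label=_require(edoc, "label", str, epath),
                        incidence=_require(edoc, "incidence", float, epath),
                        sex_applicability=_require(edoc, "sex", str, epath),
                        age_range=(
                            _require(edoc, "age_min", int, epath),
                            _require(edoc, "age_max", int, epath),
                        ),
                        associations=tuple(assocs),
                    )
                )
            except DomainError as exc:
                raise SchemaError(f"{epath}: {exc}") from None
        rfes[rfe] = tuple(parsed)

    return EvidenceBase(rfes=rfes, findings=findings, version=version)


def load_evidence_base(source: str | Path) -> EvidenceBase:
    """Load and validate an evidence-base JSON document from ``source``."""
    path = Path(source)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON: {exc}") from None
    return parse_evidence_base(doc)


# ---------------------------------------------------------------------------
# queries


def candidate_diagnoses(eb: EvidenceBase, ctx: PatientContext) -> list[DiagnosisEntry]:
    """Diagnoses under the patient's RfE applicable to their age and sex.

    Order is the evidence-base document order; display ordering is the
    ranking engine's job.
    """
    return [e for e in eb.diagnoses_for(ctx.rfe) if e.applies_to(ctx.age, ctx.sex)]


def _match_position(f: Finding, needle: str) -> int | None:
    best: int | None = None
    for text in (f.label, *f.synonyms):
        pos = text.lower().find(needle)
        if pos >= 0 and (best is None or pos < best):
            best = pos
    return best


def search_findings(eb: EvidenceBase, rfe: str, query: str) -> list[Finding]:
    """Context-sensitive finding search, as used by the coding search box.

    Case-insensitive substring match against label and synonyms, restricted
    to findings associated with at least one diagnosis of ``rfe``.  Results
    are ordered by (earliest match position, label); an empty result is not
    an error.
    """
    needle = query.strip().lower()
    if not needle:
        raise DomainError("search query must be non-empty")
    reachable: set[str] = set()
    for entry in eb.diagnoses_for(rfe):
        reachable.update(a.finding_id for a in entry.associations)
    hits: list[tuple[int, str, Finding]] = []
    for fid in reachable:
        f = eb.findings[fid]
        pos = _match_position(f, needle)
        if pos is not None:
            hits.append((pos, f.label, f))
    hits.sort(key=lambda t: (t[0], t[1]))
    return [f for _, _, f in hits]
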