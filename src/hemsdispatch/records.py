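"""Domain types for HEMS dispatch analysis.

An AMPDS (Advanced Medical Priority Dispatch System) code is the
"number-letter-number" descriptor produced during the initial emergency
call: a two-digit incident *category* (e.g. ``09`` cardiac/respiratory
arrest), a single-letter *determinant* grading the required response
(``A``-``E``), a two-digit *subtype*, and an optional single-letter
suffix (e.g. ``17-D-02P``).  Codes with suffixes are distinct dispatch
criteria in their own right.

A *tasking* is one HEMS (Helicopter Emergency Medical Service) dispatch.
It either results in *patient contact* or the team is *stood down*.  For
attended patients we record whether they received an HLIDD - a
HEMS-level intervention, drug or diagnostic beyond standard paramedic
scope (prehospital anaesthesia, thoracostomy, ...), with helicopter
conveyance itself counting as one by convention.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass, field

__all__ = [
    "AmpdsCode",
    "AmpdsParseError",
    "PatientOutcome",
    "DispatchRecord",
    "EmsReferenceRecord",
    "HliddRegistry",
    "DEFAULT_REGISTRY",
    "HELICOPTER_CONVEYANCE",
    "parse_code",
    "classify_hlidd",
    "assign_shift",
]

_DETERMINANTS = frozenset("ABCDEX")  # X = unknown/unsupported determinant

_CODE_RE = re.compile(
    r"""^\s*
        (\d{1,2})          # category
        \s*-?\s*
        ([A-EX])           # determinant (severity)
        \s*-?\s*
        (\d{1,2})          # subtype
        (?:\s*-?\s*([A-Z]))?   # optional suffix letter, possibly detached
        \s*$""",
    re.VERBOSE,
)


class AmpdsParseError(ValueError):
    """Raised when a text token cannot be parsed as an AMPDS code."""

    def __init__(self, token: str):
        self.token = token
        super().__init__(f"not a valid AMPDS code: {token!r}")


@dataclass(frozen=True, slots=True)
class AmpdsCode:
    """A normalized AMPDS dispatch code (category-determinant-subtype[suffix])."""

    category: str
    determinant: str
    subtype: str
    suffix: str | None = None

    def __post_init__(self) -> None:
        if not (len(self.category) == 2 and self.category.isdigit()):
            raise ValueError(f"category must be two digits, got {self.category!r}")
        if self.determinant not in _DETERMINANTS:
            raise ValueError(f"determinant must be A-E or X, got {self.determinant!r}")
        if not (len(self.subtype) == 2 and self.subtype.isdigit()):
            raise ValueError(f"subtype must be two digits, got {self.subtype!r}")
        if self.suffix is not None and not (
            len(self.suffix) == 1 and self.suffix.isalpha() and self.suffix.isupper()
        ):
            raise ValueError(f"suffix must be a single capital letter, got {self.suffix!r}")

    @property
    def canonical_text(self) -> str:
        """Normalized rendering, e.g. ``09-E-01`` or ``17-D-02P``."""
        return f"{self.category}-{self.determinant}-{self.subtype}{self.suffix or ''}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_text


def parse_code(text: str) -> AmpdsCode:
    """Parse free text into a normalized :class:`AmpdsCode`.

    Tolerant of case, spacing, missing hyphens, and a space-separated
    suffix letter (``"29-D-06 V"`` and ``"09e01"`` both parse).  Single
    digit category/subtype tokens are zero-padded.

    Raises
    ------
    AmpdsParseError
        If the text is not recognizably an AMPDS code.
    """
    if not isinstance(text, str) or not text.strip():
        raise AmpdsParseError(text)
    m = _CODE_RE.match(text.upper())
    if m is None:
        raise AmpdsParseError(text)
    cat, det, sub, suf = m.groups()
    return AmpdsCode(
        category=cat.zfill(2), determinant=det, subtype=sub.zfill(2), suffix=suf
    )


HELICOPTER_CONVEYANCE = "helicopter_conveyance"

# The frequent HLIDD identifiers (those received by >400 patients in the
# source system); the full clinical list is site-configurable.
_DEFAULT_HLIDD_ENTRIES = (
    "endotracheal_tube",
    "advanced_analgesia",
    HELICOPTER_CONVEYANCE,
    "phea",
    "pocus_cardiac",
    "gastric_tube",
    "procedural_sedation",
    "oesophageal_temperature_probe",
    "intravenous_antimicrobial",
    "thoracostomy",
    "intravenous_electrolyte",
    "splintage",
    "pocus_fast",
    "pocus_lung",
    "radial_arterial_line",
)


@dataclass(frozen=True, slots=True)
class HliddRegistry:
    """The set of intervention identifiers that count as HLIDD.

    ``includes_helicopter_conveyance`` toggles whether conveyance by
    helicopter alone makes a patient HLIDD-positive.
    """

    entries: frozenset[str] = frozenset(_DEFAULT_HLIDD_ENTRIES)
    includes_helicopter_conveyance: bool = True

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("HLIDD registry must be non-empty")

    @property
    def active_entries(self) -> frozenset[str]:
        if self.includes_helicopter_conveyance:
            return self.entries
        return self.entries - {HELICOPTER_CONVEYANCE}

    @classmethod
    def default(cls, extra: tuple[str, ...] = (), *, helicopter_conveyance: bool = True
                ) -> "HliddRegistry":
        return cls(
            entries=frozenset(_DEFAULT_HLIDD_ENTRIES) | frozenset(extra),
            includes_helicopter_conveyance=helicopter_conveyance,
        )


DEFAULT_REGISTRY = HliddRegistry()


def classify_hlidd(interventions: frozenset[str] | set[str],
                   registry: HliddRegistry = DEFAULT_REGISTRY) -> bool:
    """True iff any performed intervention is in the HLIDD registry."""
    return bool(set(interventions) & registry.active_entries)


def assign_shift(local_time: datetime.time | datetime.datetime) -> str:
    """Map a local clock time to ``"day"`` or ``"night"``.

    The day window is half-open [07:00, 19:00): 07:00 is day, 19:00 is
    night, avoiding double counting at the boundaries.
    """
    if isinstance(local_time, datetime.datetime):
        local_time = local_time.time()
    return "day" if datetime.time(7) <= local_time < datetime.time(19) else "night"


@dataclass(frozen=True, slots=True)
class PatientOutcome:
    """One attended patient: demographics, interventions, derived HLIDD flag."""

    age_years: float | None
    sex: str | None  # "male" | "female" | "transgender" | None (missing)
    interventions: frozenset[str]
    hlidd: bool

    @classmethod
    def from_interventions(
        cls,
        age_years: float | None,
        sex: str | None,
        interventions: frozenset[str] | set[str],
        registry: HliddRegistry = DEFAULT_REGISTRY,
    ) -> "PatientOutcome":
        ivs = frozenset(interventions)
        return cls(age_years, sex, ivs, classify_hlidd(ivs, registry))


@dataclass(frozen=True, slots=True)
class DispatchRecord:
    """One HEMS tasking with its code, outcome and covariates."""

    tasking_id: str
    code: AmpdsCode | None
    dispatch_type: str  # "immediate" | "interrogate" | "crew_request"
    contact: bool
    platform: str  # "helicopter" | "rrv"
    shift: str  # "day" | "night"
    desk_ccp: bool
    n_patients: int = 0
    patients: tuple[PatientOutcome, ...] = ()

    def __post_init__(self) -> None:
        if not self.contact and (self.n_patients != 0 or self.patients):
            raise ValueError("stand-down tasking cannot carry patients")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")

    @property
    def hlidd(self) -> bool:
        """Tasking-level HLIDD: true iff any attended patient received one."""
        return any(p.hlidd for p in self.patients)


@dataclass(frozen=True, slots=True)
class EmsReferenceRecord:
    """One whole-system EMS tasking: its code and whether HEMS was dispatched."""

    code: AmpdsCode
    hems_dispatched: bool
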