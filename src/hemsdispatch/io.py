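"""Delimited-text I/O for dispatch and EMS-reference record tables.

Canonical dispatch columns (rename via ``column_map``): ``tasking_id``,
``ampds_code``, ``dispatch_type``, ``contact``, ``platform``,
``desk_ccp``, and either ``tasking_datetime`` (shift derived from the
07:00-19:00 day window) or ``shift``.  Patient fields are optional:
``n_patients``, ``patient_age``, ``patient_sex``, ``interventions``.
Multi-patient taskings pack per-patient values with ``|`` and join
interventions within a patient with ``;`` (``"a;b|c"`` = patient 1 had
a and b, patient 2 had c).

Rows whose code fails to parse are retained with ``code=None`` and
counted in the attrition log; downstream analysis excludes them, which
mirrors the study flow's exclusion of non-coded dispatches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .records import (
    DEFAULT_REGISTRY,
    AmpdsParseError,
    DispatchRecord,
    EmsReferenceRecord,
    HliddRegistry,
    PatientOutcome,
    assign_shift,
    parse_code,
)

__all__ = [
    "ConfigError",
    "ReadResult",
    "read_dispatch_records",
    "write_dispatch_records",
    "read_ems_reference",
    "write_ems_reference",
]


class ConfigError(ValueError):
    """Raised when a table is missing mandatory columns."""


_MANDATORY = ("tasking_id", "ampds_code", "dispatch_type", "contact",
              "platform", "desk_ccp")

_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n", ""}


@dataclass
class ReadResult:
    """Parsed records plus an attrition log of rows needing attention."""

    records: list[DispatchRecord]
    attrition: dict[str, int] = field(default_factory=dict)

    @property
    def n_coded(self) -> int:
        return sum(1 for r in self.records if r.code is not None)

    @property
    def coded_fraction(self) -> float:
        return self.n_coded / len(self.records) if self.records else float("nan")


def _parse_bool(value: str, column: str) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ConfigError(f"cannot interpret {value!r} as boolean in column {column!r}")


def _split_field(value: str) -> list[str]:
    return str(value).split("|") if str(value).strip() != "" else []


def read_dispatch_records(
    source,
    *,
    column_map: dict[str, str] | None = None,
    registry: HliddRegistry = DEFAULT_REGISTRY,
    sep: str = ",",
) -> ReadResult:
    """Read a dispatch table from ``source`` (path or file-like).

    Raises :class:`ConfigError` when mandatory columns are absent.
    """
    frame = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    if column_map:
        frame = frame.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in _MANDATORY if c not in frame.columns]
    if missing:
        raise ConfigError(f"missing mandatory columns: {missing}")
    if "tasking_datetime" not in frame.columns and "shift" not in frame.columns:
        raise ConfigError("need either 'tasking_datetime' or 'shift' column")

    attrition: dict[str, int] = {}
    records: list[DispatchRecord] = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        code = None
        raw_code = d["ampds_code"].strip()
        if raw_code:
            try:
                code = parse_code(raw_code)
            except AmpdsParseError:
                attrition["unparseable_code"] = attrition.get("unparseable_code", 0) + 1
        else:
            attrition["missing_code"] = attrition.get("missing_code", 0) + 1

        if "shift" in d and str(d.get("shift", "")).strip():
            shift = str(d["shift"]).strip().lower()
            if shift not in ("day", "night"):
                raise ConfigError(f"shift must be day/night, got {shift!r}")
        else:
            shift = assign_shift(pd.Timestamp(d["tasking_datetime"]).to_pydatetime())

        contact = _parse_bool(d["contact"], "contact")
        patients: tuple[PatientOutcome, ...] = ()
        n_patients = 0
        if contact:
            ages = _split_field(d.get("patient_age", ""))
            sexes = _split_field(d.get("patient_sex", ""))
            ivs = _split_field(d.get("interventions", ""))
            n_patients = int(d["n_patients"]) if str(d.get("n_patients", "")).strip() else max(
                len(ages), len(sexes), len(ivs), 1
            )
            built = []
            for i in range(n_patients):
                age_s = ages[i].strip() if i < len(ages) else ""
                sex_s = sexes[i].strip().lower() if i < len(sexes) else ""
                iv_s = ivs[i] if i < len(ivs) else ""
                age = float(age_s) if age_s else None
                sex = sex_s if sex_s in ("male", "female", "transgender") else None
                iv = frozenset(t.strip() for t in iv_s.split(";") if t.strip())
                built.append(PatientOutcome.from_interventions(age, sex, iv, registry))
            patients = tuple(built)

        records.append(
            DispatchRecord(
                tasking_id=str(d["tasking_id"]),
                code=code,
                dispatch_type=str(d["dispatch_type"]).strip().lower(),
                contact=contact,
                platform=str(d["platform"]).strip().lower(),
                shift=shift,
                desk_ccp=_parse_bool(d["desk_ccp"], "desk_ccp"),
                n_patients=n_patients,
                patients=patients,
            )
        )
    return ReadResult(records=records, attrition=attrition)


def write_dispatch_records(records: Iterable[DispatchRecord], target, *, sep: str = ",") -> None:
    """Write records in the canonical dispatch-table dialect (round-trips)."""
    rows = []
    for r in records:
        rows.append(
            {
                "tasking_id": r.tasking_id,
                "ampds_code": r.code.canonical_text if r.code else "",
                "dispatch_type": r.dispatch_type,
                "contact": str(r.contact).lower(),
                "platform": r.platform,
                "shift": r.shift,
                "desk_ccp": str(r.desk_ccp).lower(),
                "n_patients": r.n_patients,
                "patient_age": "|".join(
                    "" if p.age_years is None else repr(float(p.age_years)) for p in r.patients
                ),
                "patient_sex": "|".join(p.sex or "" for p in r.patients),
                "interventions": "|".join(
                    ";".join(sorted(p.interventions)) for p in r.patients
                ),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "tasking_id", "ampds_code", "dispatch_type", "contact", "platform",
            "shift", "desk_ccp", "n_patients", "patient_age", "patient_sex",
            "interventions",
        ],
    ).to_csv(target, sep=sep, index=False)


def read_ems_reference(source, *, sep: str = ",") -> list[EmsReferenceRecord]:
    """Read the whole-system EMS reference stream (ampds_code, hems_dispatched)."""
    frame = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    for col in ("ampds_code", "hems_dispatched"):
        if col not in frame.columns:
            raise ConfigError(f"missing mandatory column: {col}")
    out = []
    for code_text, flag in zip(frame["ampds_code"], frame["hems_dispatched"]):
        out.append(
            EmsReferenceRecord(
                code=parse_code(code_text),
                hems_dispatched=_parse_bool(flag, "hems_dispatched"),
            )
        )
    return out


def write_ems_reference(records: Iterable[EmsReferenceRecord], target, *, sep: str = ",") -> None:
    records = list(records)
    pd.DataFrame(
        {
            "ampds_code": [r.code.canonical_text for r in records],
            "hems_dispatched": [str(r.hems_dispatched).lower() for r in records],
        }
    ).to_csv(target, sep=sep, index=False)
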