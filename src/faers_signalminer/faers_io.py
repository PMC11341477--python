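"""Reading, writing and joining FAERS-style quarterly ASCII tables.

The public quarterly extracts of the FDA Adverse Event Reporting System
(FAERS) ship as ``$``-delimited text files -- DEMO (one row per report
version, with demographics), DRUG (one row per reported drug), REAC (one
row per coded reaction, a MedDRA Preferred Term), THER (therapy dates) --
with a single header line and dates written as 8-digit YYYYMMDD strings
that degrade to 6 (YYYYMM) or 4 (YYYY) digits when the reporter supplied
only a partial date.

This module parses that dialect into typed records, writes it back, and
joins the per-table records into case-level :class:`CaseReport` objects
keyed on PRIMARYID.  Columns are resolved by header name
(case-insensitive), never by position, because the public layouts gained
and reordered columns over the years.  Empty fields, literal ``NULL`` and
whitespace-only fields all mean "absent".
"""

from __future__ import annotations

import datetime
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence, Union

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "NULL"}

ROLE_CODES = ("PS", "SS", "C", "I")  # primary suspect / secondary suspect / concomitant / interacting


class SchemaError(ValueError):
    """A table file does not carry the columns its schema requires."""


class ParseError(ValueError):
    """A data line could not be interpreted; the message carries the line number."""


class DatePrecision(str, enum.Enum):
    DAY = "day"
    MONTH = "month"
    YEAR = "year"
    ABSENT = "absent"


@dataclass(frozen=True)
class PartialDate:
    """A FAERS date with explicit precision.

    ``raw`` keeps the verbatim field so that writing a table back out
    reproduces the input byte-for-byte even for malformed dates.
    """

    raw: Optional[str]
    year: Optional[int]
    month: Optional[int]
    day: Optional[int]
    precision: DatePrecision

    @property
    def is_absent(self) -> bool:
        return self.precision is DatePrecision.ABSENT

    @property
    def sort_key(self) -> tuple:
        """Chronological key; an absent date sorts below every present one."""
        if self.is_absent:
            return (0, 0, 0, 0)
        return (1, self.year or 0, self.month or 0, self.day or 0)

    def to_date(self) -> datetime.date:
        if self.precision is not DatePrecision.DAY:
            raise ValueError(f"date {self.raw!r} has {self.precision.value} precision, not day")
        return datetime.date(self.year, self.month, self.day)

    def to_field(self) -> str:
        return self.raw or ""


ABSENT_DATE = PartialDate(None, None, None, None, DatePrecision.ABSENT)


def parse_date(raw: Optional[str]) -> PartialDate:
    """Parse the 8/6/4-digit partial-date dialect, leniently.

    8 digits -> day precision, 6 -> month, 4 -> year.  Anything else --
    including calendar-invalid values such as ``20200230`` -- maps to
    absent rather than raising: dirty dates are endemic in spontaneous
    reports and must not abort a bulk load.
    """
    if raw is None:
        return ABSENT_DATE
    token = raw.strip()
    if token in _MISSING_TOKENS:
        return ABSENT_DATE
    if not token.isdigit():
        return PartialDate(raw, None, None, None, DatePrecision.ABSENT)
    if len(token) == 8:
        try:
            d = datetime.date(int(token[:4]), int(token[4:6]), int(token[6:8]))
        except ValueError:
            return PartialDate(raw, None, None, None, DatePrecision.ABSENT)
        return PartialDate(raw, d.year, d.month, d.day, DatePrecision.DAY)
    if len(token) == 6:
        year, month = int(token[:4]), int(token[4:6])
        if not 1 <= month <= 12:
            return PartialDate(raw, None, None, None, DatePrecision.ABSENT)
        return PartialDate(raw, year, month, None, DatePrecision.MONTH)
    if len(token) == 4:
        return PartialDate(raw, int(token), None, None, DatePrecision.YEAR)
    return PartialDate(raw, None, None, None, DatePrecision.ABSENT)


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DemoRecord:
    primaryid: str
    caseid: str
    fda_dt: PartialDate = ABSENT_DATE
    event_dt: PartialDate = ABSENT_DATE
    sex: Optional[str] = None
    age: Optional[float] = None
    age_cod: Optional[str] = None
    wt: Optional[float] = None
    wt_cod: Optional[str] = None
    reporter_country: Optional[str] = None


@dataclass(frozen=True)
class DrugRecord:
    primaryid: str
    drug_seq: str
    role_cod: Optional[str] = None
    drugname: Optional[str] = None
    prod_ai: Optional[str] = None


@dataclass(frozen=True)
class ReacRecord:
    primaryid: str
    pt: str = ""


@dataclass(frozen=True)
class TherRecord:
    primaryid: str
    dsg_drug_seq: str
    start_dt: PartialDate = ABSENT_DATE


@dataclass
class CaseReport:
    """One report version with its linked drug, reaction and therapy rows."""

    demo: DemoRecord
    drugs: list[DrugRecord] = field(default_factory=list)
    reactions: list[ReacRecord] = field(default_factory=list)
    therapies: list[TherRecord] = field(default_factory=list)

    @property
    def primaryid(self) -> str:
        return self.demo.primaryid

    @property
    def caseid(self) -> str:
        return self.demo.caseid


# ---------------------------------------------------------------------------
# schemas
# ---------------------------------------------------------------------------


def _number(token: Optional[str], column: str) -> Optional[float]:
    if token is None:
        return None
    try:
        value = float(token)
    except ValueError as exc:
        raise ValueError(f"column {column}: {token!r} is not a number") from exc
    if value < 0:
        raise ValueError(f"column {column}: negative value {token!r}")
    return value


def _fmt_number(value: Optional[float]) -> str:
    if value is None:
        return ""
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))


def _build_demo(row: dict) -> DemoRecord:
    if not row.get("primaryid"):
        raise ValueError("empty primaryid")
    if not row.get("caseid"):
        raise ValueError("empty caseid")
    return DemoRecord(
        primaryid=row["primaryid"],
        caseid=row["caseid"],
        fda_dt=parse_date(row.get("fda_dt")),
        event_dt=parse_date(row.get("event_dt")),
        sex=row.get("sex"),
        age=_number(row.get("age"), "age"),
        age_cod=row.get("age_cod"),
        wt=_number(row.get("wt"), "wt"),
        wt_cod=row.get("wt_cod"),
        reporter_country=row.get("reporter_country"),
    )


def _build_drug(row: dict) -> DrugRecord:
    if not row.get("primaryid"):
        raise ValueError("empty primaryid")
    role = row.get("role_cod")
    if role is not None and role.upper() not in ROLE_CODES:
        raise ValueError(f"unknown role_cod {role!r}")
    return DrugRecord(
        primaryid=row["primaryid"],
        drug_seq=row.get("drug_seq") or "1",
        role_cod=role.upper() if role else None,
        drugname=row.get("drugname"),
        prod_ai=row.get("prod_ai"),
    )


def _build_reac(row: dict) -> ReacRecord:
    if not row.get("primaryid"):
        raise ValueError("empty primaryid")
    if not row.get("pt"):
        raise ValueError("empty pt")
    return ReacRecord(primaryid=row["primaryid"], pt=row["pt"])


def _build_ther(row: dict) -> TherRecord:
    if not row.get("primaryid"):
        raise ValueError("empty primaryid")
    return TherRecord(
        primaryid=row["primaryid"],
        dsg_drug_seq=row.get("dsg_drug_seq") or "1",
        start_dt=parse_date(row.get("start_dt")),
    )


@dataclass(frozen=True)
class _Schema:
    name: str
    required: tuple[str, ...]
    columns: tuple[str, ...]  # canonical write order
    build: Callable[[dict], object]
    to_row: Callable[[object], list[str]]


SCHEMAS: dict[str, _Schema] = {
    "DEMO": _Schema(
        "DEMO",
        required=("primaryid", "caseid"),
        columns=(
            "primaryid", "caseid", "fda_dt", "event_dt", "sex",
            "age", "age_cod", "wt", "wt_cod", "reporter_country",
        ),
        build=_build_demo,
        to_row=lambda r: [
            r.primaryid, r.caseid, r.fda_dt.to_field(), r.event_dt.to_field(),
            r.sex or "", _fmt_number(r.age), r.age_cod or "",
            _fmt_number(r.wt), r.wt_cod or "", r.reporter_country or "",
        ],
    ),
    "DRUG": _Schema(
        "DRUG",
        required=("primaryid", "drugname"),
        columns=("primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"),
        build=_build_drug,
        to_row=lambda r: [
            r.primaryid, r.drug_seq, r.role_cod or "", r.drugname or "", r.prod_ai or "",
        ],
    ),
    "REAC": _Schema(
        "REAC",
        required=("primaryid", "pt"),
        columns=("primaryid", "pt"),
        build=_build_reac,
        to_row=lambda r: [r.primaryid, r.pt],
    ),
    "THER": _Schema(
        "THER",
        required=("primaryid", "dsg_drug_seq"),
        columns=("primaryid", "dsg_drug_seq", "start_dt"),
        build=_build_ther,
        to_row=lambda r: [r.primaryid, r.dsg_drug_seq, r.start_dt.to_field()],
    ),
}


def _clean(token: str) -> Optional[str]:
    token = token.strip()
    if token in _MISSING_TOKENS:
        return None
    return token


def parse_table(path: Union[str, Path], schema: str) -> list:
    """Parse one ``$``-delimited table file into typed records.

    Fields are mapped through the header line, case-insensitively; columns
    the schema does not know are ignored.  UTF-8 is tried first with a
    Latin-1 fallback (older FAERS quarters are not valid UTF-8).
    """
    schema = schema.upper()
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    spec = SCHEMAS[schema]
    path = Path(path)
    data = path.read_bytes()
    try:
        text = data.decode("utf-8")
    except UnicodeDecodeError:
        text = data.decode("latin-1")
    lines = text.splitlines()
    if not lines:
        raise SchemaError(f"{path}: empty file")
    header = [h.strip().lower() for h in lines[0].split("$")]
    for col in spec.required:
        if col not in header:
            raise SchemaError(f"{path}: missing required column {col!r} for schema {schema}")
    ncol = len(header)
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("$")
        if len(fields) != ncol:
            raise ParseError(f"{path} line {lineno}: expected {ncol} fields, got {len(fields)}")
        row = {name: _clean(value) for name, value in zip(header, fields)}
        try:
            records.append(spec.build(row))
        except ValueError as exc:
            raise ParseError(f"{path} line {lineno}: {exc}") from exc
    return records


def write_table(records: Sequence, path: Union[str, Path], schema: str) -> None:
    """Write records in the same dialect :func:`parse_table` reads."""
    schema = schema.upper()
    spec = SCHEMAS[schema]
    path = Path(path)
    out = ["$".join(spec.columns)]
    for record in records:
        out.append("$".join(spec.to_row(record)))
    path.write_text("\n".join(out) + "\n", encoding="utf-8")


def table_filename(schema: str, year: int, quarter: int) -> str:
    """Conventional quarterly file name, e.g. ``DEMO23Q1.txt``."""
    return f"{schema.upper()}{year % 100:02d}Q{quarter}.txt"


def read_quarter(directory: Union[str, Path]) -> dict[str, list]:
    """Read every recognized table file in a quarter directory.

    Files are matched on the leading schema token of their name
    (``DEMO*.txt`` etc.); several files per schema concatenate.
    """
    directory = Path(directory)
    tables: dict[str, list] = {name: [] for name in SCHEMAS}
    found = False
    for path in sorted(directory.glob("*.txt")):
        for name in SCHEMAS:
            if path.name.upper().startswith(name):
                tables[name].extend(parse_table(path, name))
                found = True
                break
    if not found:
        raise SchemaError(f"{directory}: no FAERS table files (DEMO*/DRUG*/REAC*/THER*.txt) found")
    return tables


# ---------------------------------------------------------------------------
# joining
# ---------------------------------------------------------------------------


@dataclass
class JoinResult:
    cases: list[CaseReport]
    orphans: dict[str, int]  # table name -> child rows with no DEMO parent


def join_cases(
    demo: Sequence[DemoRecord],
    drug: Sequence[DrugRecord] = (),
    reac: Sequence[ReacRecord] = (),
    ther: Sequence[TherRecord] = (),
) -> JoinResult:
    """Attach child rows to their DEMO parent by primaryid.

    One :class:`CaseReport` per DEMO row; child rows whose primaryid has
    no DEMO parent are counted as orphans (logged, never attached), so
    attached + orphaned always equals the input row count per table.
    """
    by_pid: dict[str, CaseReport] = {}
    cases: list[CaseReport] = []
    for d in demo:
        report = CaseReport(demo=d)
        by_pid[d.primaryid] = report
        cases.append(report)
    orphans = {"DRUG": 0, "REAC": 0, "THER": 0}
    for name, rows, attach in (
        ("DRUG", drug, lambda case, r: case.drugs.append(r)),
        ("REAC", reac, lambda case, r: case.reactions.append(r)),
        ("THER", ther, lambda case, r: case.therapies.append(r)),
    ):
        for row in rows:
            case = by_pid.get(row.primaryid)
            if case is None:
                orphans[name] += 1
            else:
                attach(case, row)
    total_orphans = sum(orphans.values())
    if total_orphans:
        logger.warning("join_cases: %d orphan child rows (%s)", total_orphans, orphans)
    return JoinResult(cases=cases, orphans=orphans)
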