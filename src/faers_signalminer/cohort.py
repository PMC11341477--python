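"""Target-drug cohort identification and drug-event pair expansion.

A report belongs to the drug cohort when one of its drug rows matches a
configured synonym on the normalized DRUGNAME or PROD_AI string and (by
default) that row's role code is PS, the primary suspect.  Matching is
exact on normalized strings, never substring-based: spontaneous-report
drug names are free text and substring matching would capture unrelated
combination products.

Counting happens at the level of drug-event *pairs*: each distinct
reaction Preferred Term (PT) within a kept report contributes one pair,
so a report contributes at most one count to any term's cell.  Pairs
carry the PT's System Organ Class (SOC) through a user-supplied two-column
mapping (the licensed MedDRA dictionary itself is out of scope).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .faers_io import CaseReport, DrugRecord

logger = logging.getLogger(__name__)

UNMAPPED_SOC = "unmapped"

#: Name strings under which the IGF-1R antibody teprotumumab appears in
#: FAERS drug rows: trade names, the investigational Roche identifiers,
#: and dose/formulation variants.
DEFAULT_TARGET_SYNONYMS: tuple[str, ...] = (
    "TEPROTUMUMAB TRBW",
    "TEPEZZA",
    "TEPEZZA INJ",
    "TEPEZZA 2000 MG IV IN 250 ML 0 9 NACL",
    "RO4858696 INVESTIGATIONAL IGF 1R ANTAGONIST",
    "RO4858696 PLACEBO",
    "RO4858696",
    "RO4858696 INJECTION FOR INFUSION",
    "RO4858696 IGF 1R ANTAGONIST",
    "RO4858696 R1507",
    "R1507 R04858696",
)

_NON_ALNUM_RE = re.compile(r"[^0-9A-Z ]+")


def normalize_name(raw: str) -> str:
    """Normalize a free-text drug (or term) name for exact matching.

    Uppercase; punctuation and trademark glyphs become spaces; runs of
    whitespace collapse; the result is stripped.  ``"  tepezza®"`` and
    ``"Tepezza  Inj."`` normalize to ``"TEPEZZA"`` / ``"TEPEZZA INJ"``.
    """
    s = _NON_ALNUM_RE.sub(" ", raw.upper())
    return " ".join(s.split())


@dataclass(frozen=True)
class SynonymList:
    """Normalized name variants identifying one drug."""

    label: str
    names: frozenset[str]

    def __post_init__(self):
        if not self.names:
            raise ValueError("synonym list must not be empty")

    @classmethod
    def from_names(cls, names: Iterable[str], label: str = "target") -> "SynonymList":
        return cls(label=label, names=frozenset(normalize_name(n) for n in names))

    @classmethod
    def default(cls) -> "SynonymList":
        return cls.from_names(DEFAULT_TARGET_SYNONYMS, label="teprotumumab")

    @classmethod
    def from_file(cls, path: Union[str, Path], label: str = "target") -> "SynonymList":
        """One synonym per line; blank lines and ``#`` comments ignored."""
        names = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                names.append(line)
        return cls.from_names(names, label=label)

    def matches(self, name: Optional[str]) -> bool:
        return name is not None and normalize_name(name) in self.names


@dataclass(frozen=True)
class PtSocMap:
    """Total PT -> SOC function over the PTs it contains (normalized keys)."""

    mapping: dict  # normalized PT -> SOC name

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "PtSocMap":
        return cls(mapping={normalize_name(pt): soc for pt, soc in pairs})

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "PtSocMap":
        """Two-column CSV ``pt,soc`` with a header line."""
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"pt", "soc"} <= {f.lower() for f in reader.fieldnames}:
                raise ValueError(f"{path}: expected columns 'pt' and 'soc'")
            pairs = []
            for row in reader:
                row = {k.lower(): v for k, v in row.items()}
                pairs.append((row["pt"], row["soc"]))
        return cls.from_pairs(pairs)

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["pt", "soc"])
            for pt in sorted(self.mapping):
                writer.writerow([pt, self.mapping[pt]])

    def soc_of(self, pt: str) -> str:
        return self.mapping.get(normalize_name(pt), UNMAPPED_SOC)


@dataclass(frozen=True)
class PairRecord:
    """One (kept report, distinct reaction PT) unit of counting."""

    caseid: str
    pt: str  # normalized
    soc: str
    is_target: bool


def target_drug_records(
    report: CaseReport, synonyms: SynonymList, ps_only: bool = True
) -> list[DrugRecord]:
    """Drug rows of ``report`` matching the synonym list (role-filtered)."""
    hits = []
    for drug in report.drugs:
        if synonyms.matches(drug.drugname) or synonyms.matches(drug.prod_ai):
            if not ps_only or drug.role_cod == "PS":
                hits.append(drug)
    return hits


def is_target_report(report: CaseReport, synonyms: SynonymList, ps_only: bool = True) -> bool:
    """True iff the report carries the target drug (as primary suspect, by default)."""
    return bool(target_drug_records(report, synonyms, ps_only=ps_only))


def expand_pairs(
    reports: Sequence[CaseReport],
    synonyms: SynonymList,
    pt_soc_map: PtSocMap,
    ps_only: bool = True,
) -> list[PairRecord]:
    """Expand deduplicated reports into drug-event pair records.

    Duplicate PT mentions within one report collapse to a single pair.
    The target flag is decided once per report and inherited by all of its
    pairs.  PTs missing from the map are tagged ``unmapped`` and counted
    in the log.
    """
    pairs: list[PairRecord] = []
    n_unmapped = 0
    for report in reports:
        target = is_target_report(report, synonyms, ps_only=ps_only)
        seen: set[str] = set()
        for reac in report.reactions:
            pt = normalize_name(reac.pt)
            if not pt or pt in seen:
                continue
            seen.add(pt)
            soc = pt_soc_map.soc_of(pt)
            if soc == UNMAPPED_SOC:
                n_unmapped += 1
            pairs.append(PairRecord(caseid=report.caseid, pt=pt, soc=soc, is_target=target))
    if n_unmapped:
        logger.warning("expand_pairs: %d pairs with unmapped PT", n_unmapped)
    return pairs
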