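"""Time-to-onset (TTO) of adverse events after therapy start.

TTO for a target report is the whole-day interval from the earliest
therapy start date (START_DT, THER table) of a matching target-drug row
to the event onset date (EVENT_DT, DEMO table).  Both dates must carry
full day precision; reports with partial or missing dates, or with an
onset before the therapy start, are excluded with an explicit reason so
that included + excluded always equals the cohort size.  Same-day onset
(TTO = 0) is included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .cohort import SynonymList, target_drug_records
from .faers_io import CaseReport, DatePrecision

REASON_MISSING_DATE = "missing_date"
REASON_EVENT_BEFORE_START = "event_before_start"

#: Cumulative bin edges (days) reported for onset-delay distributions.
TTO_BIN_EDGES = (30, 60, 180)


@dataclass(frozen=True)
class TTORecord:
    caseid: str
    onset_days: int


@dataclass(frozen=True)
class TTOExclusion:
    caseid: str
    reason: str


@dataclass(frozen=True)
class TTOSummary:
    n: int
    median_days: float
    q1_days: float
    q3_days: float
    #: cumulative shares at <=30, <=60, <=180 days, plus the >180 remainder
    bin_shares: dict


def compute_tto(
    report: CaseReport, synonyms: SynonymList, ps_only: bool = True
) -> Union[TTORecord, TTOExclusion]:
    """One TTO per report: earliest qualifying therapy start to event onset."""
    event = report.demo.event_dt
    target_seqs = {d.drug_seq for d in target_drug_records(report, synonyms, ps_only=ps_only)}
    starts = [
        t.start_dt
        for t in report.therapies
        if t.dsg_drug_seq in target_seqs and t.start_dt.precision is DatePrecision.DAY
    ]
    if event.precision is not DatePrecision.DAY or not starts:
        return TTOExclusion(report.caseid, REASON_MISSING_DATE)
    start = min(starts, key=lambda d: d.sort_key)
    delta = (event.to_date() - start.to_date()).days
    if delta < 0:
        return TTOExclusion(report.caseid, REASON_EVENT_BEFORE_START)
    return TTORecord(report.caseid, delta)


def collect_tto(
    reports: Sequence[CaseReport], synonyms: SynonymList, ps_only: bool = True
) -> tuple[list[TTORecord], list[TTOExclusion]]:
    """Compute TTO for every report, partitioning into included / excluded."""
    included, excluded = [], []
    for report in reports:
        result = compute_tto(report, synonyms, ps_only=ps_only)
        if isinstance(result, TTORecord):
            included.append(result)
        else:
            excluded.append(result)
    return included, excluded


def summarize_tto(records: Sequence[TTORecord]) -> TTOSummary:
    """Median, quartiles (linear interpolation) and cumulative bin shares."""
    if not records:
        raise ValueError("no TTO records to summarize")
    days = np.array([r.onset_days for r in records], dtype=float)
    q1, med, q3 = np.percentile(days, [25, 50, 75], method="linear")
    n = len(days)
    shares = {}
    for edge in TTO_BIN_EDGES:
        shares[f"<={edge}"] = float(np.sum(days <= edge)) / n
    shares[f">{TTO_BIN_EDGES[-1]}"] = 1.0 - shares[f"<={TTO_BIN_EDGES[-1]}"]
    return TTOSummary(
        n=n, median_days=float(med), q1_days=float(q1), q3_days=float(q3), bin_shares=shares
    )
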