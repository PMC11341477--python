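"""FDA-recommended deduplication of spontaneous-report versions.

A FAERS case (CASEID) accumulates several report versions (PRIMARYID) as
follow-up information arrives.  The FDA-recommended reduction keeps, per
CASEID, the version with the largest FDA_DT (most recently received); ties
on FDA_DT are broken by the largest PRIMARYID.  The survivor is
deterministic regardless of input order.
"""

from __future__ import annotations

from dataclasses import dataclass

from .faers_io import CaseReport

REASON_OLDER_FDA_DT = "older_fda_dt"
REASON_SMALLER_PRIMARYID = "smaller_primaryid"


class IntegrityError(ValueError):
    """Two versions share caseid, fda_dt and primaryid -- the data is corrupt."""


@dataclass
class DedupResult:
    kept: list[CaseReport]
    removed_count: int
    rule_trace: dict[str, str]  # removed primaryid -> reason

    @property
    def kept_caseids(self) -> set[str]:
        return {r.caseid for r in self.kept}


def _pid_key(primaryid: str) -> tuple:
    # FAERS primaryids are numeric; compare numerically when they are,
    # lexicographically otherwise, without ever crashing on dirty data.
    if primaryid.isdigit():
        return (1, int(primaryid), "")
    return (0, 0, primaryid)


def _version_key(report: CaseReport) -> tuple:
    return (report.demo.fda_dt.sort_key, _pid_key(report.primaryid))


def deduplicate(reports: list[CaseReport]) -> DedupResult:
    """Reduce report versions to one survivor per caseid.

    The survivor maximizes (fda_dt, primaryid); an absent fda_dt loses to
    any present one, and two absents fall through to the primaryid rule.
    Each removed version is traced with the rule that removed it.
    """
    groups: dict[str, list[CaseReport]] = {}
    for report in reports:
        if not report.caseid or not report.primaryid:
            raise IntegrityError(f"report with empty caseid/primaryid: {report.demo}")
        groups.setdefault(report.caseid, []).append(report)

    kept: list[CaseReport] = []
    trace: dict[str, str] = {}
    for caseid in sorted(groups, key=_pid_key):
        versions = sorted(groups[caseid], key=_version_key)
        for earlier, later in zip(versions, versions[1:]):
            if _version_key(earlier) == _version_key(later):
                raise IntegrityError(
                    f"case {caseid}: duplicate primaryid {earlier.primaryid} "
                    f"with identical fda_dt"
                )
        survivor = versions[-1]
        kept.append(survivor)
        for loser in versions[:-1]:
            if loser.demo.fda_dt.sort_key < survivor.demo.fda_dt.sort_key:
                trace[loser.primaryid] = REASON_OLDER_FDA_DT
            else:
                trace[loser.primaryid] = REASON_SMALLER_PRIMARYID
    return DedupResult(kept=kept, removed_count=len(trace), rule_trace=trace)
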