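"""End-to-end orchestration: parse -> join -> dedup -> cohort -> reports.

The stage order is fixed and every stage's row counts are logged in the
style of a study-flowchart (raw report versions -> unique cases -> target
cohort -> drug-event pairs), so a run on real quarters is auditable.  All
outputs are plain CSV/JSON; the whole bundle is deterministic on fixed
inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import descriptives as _descriptives
from .case_dedup import deduplicate
from .cohort import PtSocMap, SynonymList, expand_pairs, is_target_report
from .disproportionality import SignalCriteria, signal_table
from .faers_io import join_cases, read_quarter
from .tto import collect_tto, summarize_tto
from .util import round_half_up

logger = logging.getLogger(__name__)

_ROUND_COLS = (
    "pct", "ror", "ror_lo", "ror_hi", "prr", "chi2", "ic", "ic025", "ebgm", "ebgm05",
)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    quarter_dirs: list
    pt_soc_map: Union[str, Path, PtSocMap]
    out_dir: Union[str, Path]
    synonyms: Optional[SynonymList] = None  # default: the teprotumumab list
    ps_only: bool = True
    criteria: SignalCriteria = field(default_factory=SignalCriteria)
    soc_counting: str = "report"
    ebgm_z: float = 1.645
    continuity: bool = False
    #: subset name -> list of PTs (or a path to a one-PT-per-line file)
    term_subsets: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RunConfig":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        synonyms = payload.pop("synonyms", None)
        if synonyms is not None:
            synonyms = SynonymList.from_names(synonyms)
        criteria = SignalCriteria(**payload.pop("criteria", {}))
        return cls(
            quarter_dirs=payload.pop("quarters"),
            pt_soc_map=payload.pop("map"),
            out_dir=payload.pop("out"),
            synonyms=synonyms,
            criteria=criteria,
            **payload,
        )


@dataclass
class ReportBundle:
    out_dir: Path
    demographics: Path
    annual_counts: Path
    signals_pt: Path
    signals_soc: Path
    subset_signals: dict
    tto_summary: Path
    tto_bins: Path
    run_log: Path
    counts: dict


def _rounded(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in _ROUND_COLS:
        if col in df.columns:
            df[col] = df[col].map(lambda x: round_half_up(x, 2))
    return df


def _terms_of(subset) -> list:
    if isinstance(subset, (str, Path)):
        return [
            line.strip()
            for line in Path(subset).read_text(encoding="utf-8").splitlines()
            if line.strip() and not line.strip().startswith("#")
        ]
    return list(subset)


def run_all(config: RunConfig) -> ReportBundle:
    """Run every stage and write the report bundle; see module docstring."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    synonyms = config.synonyms or SynonymList.default()
    counts: dict = {}

    stage = "parse"
    try:
        tables = {name: [] for name in ("DEMO", "DRUG", "REAC", "THER")}
        for quarter in config.quarter_dirs:
            loaded = read_quarter(quarter)
            for name in tables:
                tables[name].extend(loaded[name])
        counts["raw_reports"] = len(tables["DEMO"])
        if not tables["DEMO"]:
            raise StageError("parse: no DEMO records found")

        stage = "join"
        joined = join_cases(tables["DEMO"], tables["DRUG"], tables["REAC"], tables["THER"])
        counts["orphans"] = joined.orphans

        stage = "dedup"
        dedup = deduplicate(joined.cases)
        counts["unique_cases"] = len(dedup.kept)
        counts["removed_versions"] = dedup.removed_count

        stage = "cohort"
        pt_soc = (
            config.pt_soc_map
            if isinstance(config.pt_soc_map, PtSocMap)
            else PtSocMap.from_csv(config.pt_soc_map)
        )
        target_reports = [
            r for r in dedup.kept if is_target_report(r, synonyms, ps_only=config.ps_only)
        ]
        counts["target_cases"] = len(target_reports)
        pairs = expand_pairs(dedup.kept, synonyms, pt_soc, ps_only=config.ps_only)
        counts["pairs_total"] = len(pairs)
        counts["target_pairs"] = sum(1 for p in pairs if p.is_target)

        stage = "descriptives"
        demo_df = _descriptives.demographics(target_reports)
        demo_path = out_dir / "demographics.csv"
        demo_df.to_csv(demo_path, index=False)
        years, missing_years = _descriptives.annual_counts(target_reports)
        annual_path = out_dir / "annual_counts.csv"
        pd.DataFrame(
            [{"year": y, "count": n} for y, n in years.items()]
            + ([{"year": "missing", "count": missing_years}] if missing_years else [])
        ).to_csv(annual_path, index=False)

        stage = "signals"
        kwargs = dict(
            criteria=config.criteria,
            soc_counting=config.soc_counting,
            ebgm_z=config.ebgm_z,
            continuity=config.continuity,
        )
        pt_path = out_dir / "signals_pt.csv"
        _rounded(signal_table(pairs, level="PT", **kwargs)).to_csv(pt_path, index=False)
        soc_path = out_dir / "signals_soc.csv"
        _rounded(signal_table(pairs, level="SOC", **kwargs)).to_csv(soc_path, index=False)
        subset_paths = {}
        for name, subset in sorted(config.term_subsets.items()):
            path = out_dir / f"signals_{name}.csv"
            _rounded(
                signal_table(pairs, level="PT", terms=_terms_of(subset), **kwargs)
            ).to_csv(path, index=False)
            subset_paths[name] = path

        stage = "tto"
        included, excluded = collect_tto(target_reports, synonyms, ps_only=config.ps_only)
        counts["tto_included"] = len(included)
        counts["tto_excluded"] = {}
        for exc in excluded:
            counts["tto_excluded"][exc.reason] = counts["tto_excluded"].get(exc.reason, 0) + 1
        tto_path = out_dir / "tto_summary.json"
        bins_path = out_dir / "tto_bins.csv"
        if included:
            summary = summarize_tto(included)
            tto_path.write_text(
                json.dumps(dataclasses.asdict(summary), indent=1), encoding="utf-8"
            )
            pd.DataFrame(
                [{"bin": k, "cumulative_share": round_half_up(v, 4)}
                 for k, v in summary.bin_shares.items()]
            ).to_csv(bins_path, index=False)
        else:
            tto_path.write_text(json.dumps({"n": 0}), encoding="utf-8")
            pd.DataFrame(columns=["bin", "cumulative_share"]).to_csv(bins_path, index=False)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"{stage}: {exc}") from exc

    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(counts, indent=1, sort_keys=True), encoding="utf-8")
    for key, value in sorted(counts.items()):
        logger.info("run_all %s = %s", key, value)
    return ReportBundle(
        out_dir=out_dir,
        demographics=demo_path,
        annual_counts=annual_path,
        signals_pt=pt_path,
        signals_soc=soc_path,
        subset_signals=subset_paths,
        tto_summary=tto_path,
        tto_bins=bins_path,
        run_log=log_path,
        counts=counts,
    )
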