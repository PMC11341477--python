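"""Synthetic FAERS quarters with known ground truth.

Real spontaneous-report extracts cannot ship with a package, so every
pipeline stage is exercised against generated quarters that emulate the
structural quirks of the FAERS public files: multi-version cases (same
CASEID, several PRIMARYIDs with increasing FDA_DT), one-to-many
report->drug and report->reaction links, role codes, partial and missing
dates, mixed-case and decorated drug-name strings, and a skewed
background reaction spectrum with injected drug-event associations of
chosen strength.

Reaction model
--------------
Each case includes background Preferred Term *j* independently with
probability ``p_j``; for target-drug cases, injected PTs have their
probability multiplied by the configured strength (capped below 1).  A
case that draws no reaction receives a single categorical draw with the
same relative weights, which rescales every PT's expected pair count in
that stratum by a common factor and therefore leaves the pair-level odds
unchanged.  Consequently the population reporting odds ratio of PT *j*
has the closed form

    OR_j = [p'_j / (E_t - p'_j)] / [p_j / (E_b - p_j)]

where primes denote target-case probabilities and ``E`` the expected
pairs per case in each stratum.  :func:`population_odds_ratio` returns
this value; parameter-recovery tests measure interval coverage of it.

Every generated quarter comes with a :class:`GroundTruth` ledger holding
the unique-case count, the true per-PT 2x2 cells, the true onset delays
and per-version link counts, so downstream results can be checked for
exact agreement rather than plausibility.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .cohort import DEFAULT_TARGET_SYNONYMS, PtSocMap, normalize_name
from .disproportionality import ContingencyTable
from .faers_io import (
    CaseReport,
    DemoRecord,
    DrugRecord,
    ReacRecord,
    TherRecord,
    parse_date,
    table_filename,
    write_table,
)

PROB_CAP = 0.95


class ConfigError(ValueError):
    """The generator configuration is internally inconsistent."""


@dataclass(frozen=True)
class PtSpec:
    pt: str
    soc: str
    prob: float


@dataclass(frozen=True)
class InjectedSignal:
    pt: str
    multiplier: float


#: Background reaction spectrum: a skewed mix of common complaints and
#: rare terms across the major organ classes, with per-case inclusion
#: probabilities summing to ~1.4 (so a background report carries one to
#: a few distinct reactions, as real spontaneous reports do).
DEFAULT_BACKGROUND: tuple[PtSpec, ...] = (
    PtSpec("Nausea", "Gastrointestinal disorders", 0.115),
    PtSpec("Diarrhoea", "Gastrointestinal disorders", 0.085),
    PtSpec("Vomiting", "Gastrointestinal disorders", 0.060),
    PtSpec("Abdominal pain", "Gastrointestinal disorders", 0.040),
    PtSpec("Constipation", "Gastrointestinal disorders", 0.025),
    PtSpec("Headache", "Nervous system disorders", 0.105),
    PtSpec("Dizziness", "Nervous system disorders", 0.065),
    PtSpec("Somnolence", "Nervous system disorders", 0.030),
    PtSpec("Dysgeusia", "Nervous system disorders", 0.008),
    PtSpec("Fatigue", "General disorders and administration site conditions", 0.120),
    PtSpec("Pain", "General disorders and administration site conditions", 0.070),
    PtSpec("Asthenia", "General disorders and administration site conditions", 0.050),
    PtSpec("Infusion related reaction", "General disorders and administration site conditions", 0.012),
    PtSpec("Arthralgia", "Musculoskeletal and connective tissue disorders", 0.060),
    PtSpec("Back pain", "Musculoskeletal and connective tissue disorders", 0.040),
    PtSpec("Myalgia", "Musculoskeletal and connective tissue disorders", 0.035),
    PtSpec("Muscle spasms", "Musculoskeletal and connective tissue disorders", 0.009),
    PtSpec("Tinnitus", "Ear and labyrinth disorders", 0.004),
    PtSpec("Hypoacusis", "Ear and labyrinth disorders", 0.003),
    PtSpec("Deafness", "Ear and labyrinth disorders", 0.0012),
    PtSpec("Ear discomfort", "Ear and labyrinth disorders", 0.0009),
    PtSpec("Rash", "Skin and subcutaneous tissue disorders", 0.075),
    PtSpec("Pruritus", "Skin and subcutaneous tissue disorders", 0.045),
    PtSpec("Alopecia", "Skin and subcutaneous tissue disorders", 0.011),
    PtSpec("Dry skin", "Skin and subcutaneous tissue disorders", 0.007),
    PtSpec("Weight decreased", "Investigations", 0.030),
    PtSpec("Blood pressure increased", "Investigations", 0.020),
    PtSpec("Blood glucose increased", "Investigations", 0.006),
    PtSpec("Decreased appetite", "Metabolism and nutrition disorders", 0.035),
    PtSpec("Hyperglycaemia", "Metabolism and nutrition disorders", 0.004),
    PtSpec("Vision blurred", "Eye disorders", 0.012),
    PtSpec("Eye pain", "Eye disorders", 0.010),
    PtSpec("Diplopia", "Eye disorders", 0.002),
    PtSpec("Amenorrhoea", "Reproductive system and breast disorders", 0.0008),
    PtSpec("Insomnia", "Psychiatric disorders", 0.050),
    PtSpec("Anxiety", "Psychiatric disorders", 0.040),
    PtSpec("Dyspnoea", "Respiratory, thoracic and mediastinal disorders", 0.045),
    PtSpec("Cough", "Respiratory, thoracic and mediastinal disorders", 0.040),
)

#: Injected association strengths shaping the target-drug reaction
#: profile after the hallmark IGF-1R-inhibitor adverse-event pattern:
#: strong ototoxicity and muscle-spasm signals, moderate glycaemic,
#: infusion-reaction, alopecia and menstrual signals.
DEFAULT_INJECTED: tuple[InjectedSignal, ...] = (
    InjectedSignal("Muscle spasms", 20.0),
    InjectedSignal("Fatigue", 3.5),
    InjectedSignal("Tinnitus", 38.0),
    InjectedSignal("Headache", 3.5),
    InjectedSignal("Deafness", 100.0),
    InjectedSignal("Nausea", 2.2),
    InjectedSignal("Blood glucose increased", 17.0),
    InjectedSignal("Infusion related reaction", 9.5),
    InjectedSignal("Diarrhoea", 2.0),
    InjectedSignal("Alopecia", 6.0),
    InjectedSignal("Ear discomfort", 58.0),
    InjectedSignal("Hypoacusis", 17.0),
    InjectedSignal("Amenorrhoea", 54.0),
    InjectedSignal("Dry skin", 8.0),
    InjectedSignal("Diplopia", 20.0),
    InjectedSignal("Hyperglycaemia", 12.0),
    InjectedSignal("Blood pressure increased", 4.5),
    InjectedSignal("Dizziness", 1.7),
    InjectedSignal("Weight decreased", 2.2),
)

BACKGROUND_DRUGS = (
    "ASPIRIN", "METFORMIN", "LISINOPRIL", "ATORVASTATIN", "IBUPROFEN",
    "OMEPRAZOLE", "LEVOTHYROXINE", "ADALIMUMAB", "METHOTREXATE", "PREDNISONE",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the generator.

    Probabilities are per-case inclusion probabilities; distributions are
    category -> probability dicts (an empty-string country means the
    field is left blank).  Onset delays are log-normal, parameterized by
    their median in days and the log-scale standard deviation.
    """

    seed: int = 0
    n_cases: int = 2000
    target_share: float = 0.05
    duplication_rate: float = 0.15
    dup_tie_rate: float = 0.25  # duplicate versions sharing the survivor's FDA_DT
    background_pts: tuple[PtSpec, ...] = DEFAULT_BACKGROUND
    injected: tuple[InjectedSignal, ...] = DEFAULT_INJECTED
    sex_dist: dict = field(default_factory=lambda: {"F": 0.78, "M": 0.22})
    age_bin_dist: dict = field(
        default_factory=lambda: {"<18": 0.01, "18~64.9": 0.70, "65~85": 0.283, ">85": 0.007}
    )
    missing_age_rate: float = 0.10
    weight_bin_dist: dict = field(
        default_factory=lambda: {"<50": 0.045, "50~100": 0.81, ">100": 0.145}
    )
    country_dist: dict = field(default_factory=lambda: {"United States": 0.985, "": 0.015})
    year_dist: dict = field(
        default_factory=lambda: {"2020": 0.40, "2021": 0.27, "2022": 0.19, "2023": 0.14}
    )
    conco_mean: float = 0.7  # Poisson mean of concomitant drugs per report
    nontarget_target_role_rate: float = 0.01  # target drug appears with a non-PS role
    tto_median_days: float = 48.0
    tto_log_sd: float = 1.17
    missing_date_rate: float = 0.10

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ConfigError("n_cases must be >= 1")
        if not 0.0 <= self.target_share <= 1.0:
            raise ConfigError("target_share must lie in [0, 1]")
        for rate_name in ("duplication_rate", "dup_tie_rate", "missing_date_rate",
                          "missing_age_rate", "nontarget_target_role_rate"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{rate_name} must lie in [0, 1]")
        known = {normalize_name(s.pt) for s in self.background_pts}
        for spec in self.background_pts:
            if not 0.0 <= spec.prob <= 1.0:
                raise ConfigError(f"probability of {spec.pt!r} outside [0, 1]")
        for inj in self.injected:
            if normalize_name(inj.pt) not in known:
                raise ConfigError(f"injected PT {inj.pt!r} not in background spectrum")
            if inj.multiplier <= 0:
                raise ConfigError(f"multiplier for {inj.pt!r} must be positive")
        for dist_name in ("sex_dist", "age_bin_dist", "weight_bin_dist", "country_dist", "year_dist"):
            dist = getattr(self, dist_name)
            if not math.isclose(sum(dist.values()), 1.0, abs_tol=1e-9):
                raise ConfigError(f"{dist_name} probabilities must sum to 1")

    def to_json(self, path: Union[str, Path]) -> None:
        payload = dataclasses.asdict(self)
        payload["background_pts"] = [list(dataclasses.astuple(s)) for s in self.background_pts]
        payload["injected"] = [list(dataclasses.astuple(s)) for s in self.injected]
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SyntheticConfig":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        payload["background_pts"] = tuple(PtSpec(*row) for row in payload["background_pts"])
        payload["injected"] = tuple(InjectedSignal(*row) for row in payload["injected"])
        config = cls(**payload)
        config.validate()
        return config


def paper_scale_config(seed: int = 0) -> SyntheticConfig:
    """A demo-sized quarter mirroring a small real drug cohort.

    10,000 cases with a 2% target share give ~200 target reports
    contributing ~690 drug-event pairs, a 78%-female cohort, and
    log-normal onset delays with median 48 days.
    """
    return SyntheticConfig(seed=seed, n_cases=10_000, target_share=0.02)


def pt_soc_map_from_config(config: SyntheticConfig) -> PtSocMap:
    """The PT -> SOC mapping implied by the configured spectrum."""
    return PtSocMap.from_pairs((s.pt, s.soc) for s in config.background_pts)


# ---------------------------------------------------------------------------
# probability vectors and population quantities
# ---------------------------------------------------------------------------


def _prob_vectors(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """(background probs, target-case probs, normalized-PT index)."""
    p_bg = np.array([spec.prob for spec in config.background_pts], dtype=float)
    index = {normalize_name(spec.pt): i for i, spec in enumerate(config.background_pts)}
    p_tgt = p_bg.copy()
    for inj in config.injected:
        i = index[normalize_name(inj.pt)]
        p_tgt[i] = min(p_tgt[i] * inj.multiplier, PROB_CAP)
    return p_bg, p_tgt, index


def population_odds_ratio(config: SyntheticConfig, pt: str) -> float:
    """Exact pair-level reporting odds ratio implied by the configuration."""
    p_bg, p_tgt, index = _prob_vectors(config)
    i = index[normalize_name(pt)]
    e_bg, e_tgt = p_bg.sum(), p_tgt.sum()
    return (p_tgt[i] / (e_tgt - p_tgt[i])) / (p_bg[i] / (e_bg - p_bg[i]))


def _draw_reactions(rng: np.random.Generator, n: int, probs: np.ndarray) -> np.ndarray:
    """Boolean n x J inclusion matrix; empty rows get one categorical draw."""
    m = rng.random((n, probs.size)) < probs
    empty = np.flatnonzero(~m.any(axis=1))
    if empty.size:
        j = rng.choice(probs.size, size=empty.size, p=probs / probs.sum())
        m[empty, j] = True
    return m


@dataclass
class TrueCells:
    """Per-PT true 2x2 cells of one simulated database (normalized PT keys)."""

    pts: list[str]
    a: np.ndarray
    c: np.ndarray
    target_pair_total: int
    grand_pair_total: int

    def table(self, pt: str) -> ContingencyTable:
        i = self.pts.index(normalize_name(pt))
        a, c = int(self.a[i]), int(self.c[i])
        return ContingencyTable(
            a=a,
            b=self.target_pair_total - a,
            c=c,
            d=self.grand_pair_total - self.target_pair_total - c,
        )


def simulate_true_cells(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> TrueCells:
    """Draw only the reaction layer and return the true per-PT cells.

    A count-level fast path through the identical reaction model used by
    :func:`generate_cases`, for simulation studies (e.g. interval
    coverage) that need hundreds of replicates without file plumbing.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p_bg, p_tgt, index = _prob_vectors(config)
    n_target = round(config.n_cases * config.target_share)
    m_tgt = _draw_reactions(rng, n_target, p_tgt)
    m_bg = _draw_reactions(rng, config.n_cases - n_target, p_bg)
    a = m_tgt.sum(axis=0)
    c = m_bg.sum(axis=0)
    return TrueCells(
        pts=list(index),
        a=a,
        c=c,
        target_pair_total=int(a.sum()),
        grand_pair_total=int(a.sum() + c.sum()),
    )


# ---------------------------------------------------------------------------
# full case generation
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Generator bookkeeping: what the pipeline must recover exactly."""

    n_raw_reports: int
    n_unique_cases: int
    n_target_cases: int
    target_pair_total: int
    grand_pair_total: int
    pt_cells: dict  # normalized PT -> {"a": int, "c": int}
    tto_days: dict  # caseid -> onset days (target cases with full dates)
    year_counts: dict  # realized FDA_DT year -> target-case count
    link_counts: dict  # primaryid -> {"drug": n, "reac": n, "ther": n}

    def table(self, pt: str) -> ContingencyTable:
        cell = self.pt_cells[normalize_name(pt)]
        return ContingencyTable(
            a=cell["a"],
            b=self.target_pair_total - cell["a"],
            c=cell["c"],
            d=self.grand_pair_total - self.target_pair_total - cell["c"],
        )

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "GroundTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        payload["year_counts"] = {int(k): v for k, v in payload["year_counts"].items()}
        return cls(**payload)


def _choose(rng: np.random.Generator, dist: dict):
    keys = list(dist)
    return keys[rng.choice(len(keys), p=np.array([dist[k] for k in keys], dtype=float))]


_AGE_RANGES = {"<18": (1, 17), "18~64.9": (18, 64), "65~85": (65, 85), ">85": (86, 99)}
_WT_RANGES = {"<50": (35, 49), "50~100": (50, 100), ">100": (101, 140)}


def _decorate_name(rng: np.random.Generator, name: str) -> str:
    """Case/punctuation noise that normalization must undo."""
    style = rng.integers(0, 5)
    if style == 1:
        return name.lower()
    if style == 2:
        return name.title()
    if style == 3:
        return name + "®"  # registered-trademark glyph
    if style == 4:
        return name.replace(" ", "-")
    return name


def _random_date(rng: np.random.Generator, year: int) -> datetime.date:
    return datetime.date(year, 1, 1) + datetime.timedelta(days=int(rng.integers(0, 365)))


def _fmt(d: datetime.date) -> str:
    return f"{d.year:04d}{d.month:02d}{d.day:02d}"


@dataclass
class _Version:
    """One report version destined for the quarterly files."""

    demo: DemoRecord
    drugs: list[DrugRecord]
    reactions: list[ReacRecord]
    therapies: list[TherRecord]


def generate_cases(config: SyntheticConfig) -> tuple[list[CaseReport], GroundTruth]:
    """Generate the survivor report of every case, plus the truth ledger.

    Duplicate versions (and files) are the concern of :func:`generate`;
    this function produces what the pipeline should see *after*
    deduplication, which is also what the ledger describes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    n_target = round(n * config.target_share)
    p_bg, p_tgt, index = _prob_vectors(config)
    pts = list(index)
    pt_display = [spec.pt for spec in config.background_pts]

    is_target = np.zeros(n, dtype=bool)
    is_target[rng.permutation(n)[:n_target]] = True
    m_tgt = _draw_reactions(rng, n_target, p_tgt)
    m_bg = _draw_reactions(rng, n - n_target, p_bg)

    a_cells = np.zeros(len(pts), dtype=int)
    c_cells = np.zeros(len(pts), dtype=int)
    tto_days: dict = {}
    year_counts: dict = {}
    cases: list[CaseReport] = []
    i_tgt = i_bg = 0
    for cid in range(1, n + 1):
        caseid = str(cid)
        target = bool(is_target[cid - 1])
        if target:
            row = m_tgt[i_tgt]
            i_tgt += 1
            a_cells += row
        else:
            row = m_bg[i_bg]
            i_bg += 1
            c_cells += row

        sex = _choose(rng, config.sex_dist)
        if rng.random() < config.missing_age_rate:
            age = None
        else:
            lo, hi = _AGE_RANGES[_choose(rng, config.age_bin_dist)]
            age = float(rng.integers(lo, hi + 1))
        lo, hi = _WT_RANGES[_choose(rng, config.weight_bin_dist)]
        wt = float(rng.integers(lo, hi + 1))
        country = _choose(rng, config.country_dist) or None
        year = int(_choose(rng, config.year_dist))

        start = _random_date(rng, year)
        onset = int(round(float(rng.lognormal(math.log(config.tto_median_days), config.tto_log_sd))))
        event = start + datetime.timedelta(days=onset)
        fda = event + datetime.timedelta(days=int(rng.integers(5, 61)))
        start_raw, event_raw = _fmt(start), _fmt(event)
        dates_complete = True
        if rng.random() < config.missing_date_rate:
            dates_complete = False
            if rng.random() < 0.5:
                event_raw = ""
            else:
                start_raw = start_raw[:6]  # month precision only

        pid = str(cid * 100 + 9)  # survivor; duplicates get smaller ids
        drugs: list[DrugRecord] = []
        therapies: list[TherRecord] = []
        if target:
            variant = DEFAULT_TARGET_SYNONYMS[rng.integers(0, len(DEFAULT_TARGET_SYNONYMS))]
            prod_ai = "TEPROTUMUMAB TRBW" if rng.random() < 0.5 else None
            drugs.append(
                DrugRecord(pid, "1", "PS", _decorate_name(rng, variant), prod_ai)
            )
        else:
            name = BACKGROUND_DRUGS[rng.integers(0, len(BACKGROUND_DRUGS))]
            drugs.append(DrugRecord(pid, "1", "PS", name, None))
        therapies.append(TherRecord(pid, "1", parse_date(start_raw)))
        n_conco = int(rng.poisson(config.conco_mean))
        for k in range(n_conco):
            name = BACKGROUND_DRUGS[rng.integers(0, len(BACKGROUND_DRUGS))]
            role = "C" if rng.random() < 0.7 else "SS"
            drugs.append(DrugRecord(pid, str(2 + k), role, name, None))
        if not target and rng.random() < config.nontarget_target_role_rate:
            variant = DEFAULT_TARGET_SYNONYMS[rng.integers(0, len(DEFAULT_TARGET_SYNONYMS))]
            drugs.append(DrugRecord(pid, str(2 + n_conco), "SS", variant, None))

        reactions = [ReacRecord(pid, pt_display[j]) for j in np.flatnonzero(row)]
        demo = DemoRecord(
            primaryid=pid,
            caseid=caseid,
            fda_dt=parse_date(_fmt(fda)),
            event_dt=parse_date(event_raw),
            sex=sex,
            age=age,
            age_cod="YR" if age is not None else None,
            wt=wt,
            wt_cod="KG",
            reporter_country=country,
        )
        cases.append(CaseReport(demo=demo, drugs=drugs, reactions=reactions, therapies=therapies))
        if target:
            year_counts[fda.year] = year_counts.get(fda.year, 0) + 1
            if dates_complete:
                tto_days[caseid] = onset

    truth = GroundTruth(
        n_raw_reports=n,  # updated by generate() once duplicates exist
        n_unique_cases=n,
        n_target_cases=n_target,
        target_pair_total=int(a_cells.sum()),
        grand_pair_total=int(a_cells.sum() + c_cells.sum()),
        pt_cells={pt: {"a": int(a_cells[j]), "c": int(c_cells[j])} for j, pt in enumerate(pts)},
        tto_days=tto_days,
        year_counts=year_counts,
        link_counts={},
    )
    return cases, truth


def _duplicate_versions(
    rng: np.random.Generator, case: CaseReport, config: SyntheticConfig
) -> list[_Version]:
    """Earlier, superseded versions of a case (possibly none)."""
    if rng.random() >= config.duplication_rate:
        return []
    cid = int(case.caseid)
    pid = str(cid * 100 + 1)
    survivor_fda = case.demo.fda_dt
    if rng.random() < config.dup_tie_rate:
        fda = survivor_fda  # tie: the larger primaryid must win
    else:
        earlier = survivor_fda.to_date() - datetime.timedelta(days=int(rng.integers(10, 201)))
        fda = parse_date(_fmt(earlier))
    demo = dataclasses.replace(case.demo, primaryid=pid, fda_dt=fda)
    reactions = [
        dataclasses.replace(r, primaryid=pid)
        for r in case.reactions[: max(1, len(case.reactions) - 1)]
    ]
    drugs = [dataclasses.replace(d, primaryid=pid) for d in case.drugs]
    therapies = [dataclasses.replace(t, primaryid=pid) for t in case.therapies]
    return [_Version(demo=demo, drugs=drugs, reactions=reactions, therapies=therapies)]


def generate(config: SyntheticConfig, out_dir: Union[str, Path]) -> GroundTruth:
    """Write one synthetic quarter (DEMO/DRUG/REAC/THER + ledger JSON).

    Deterministic under a fixed seed: two calls with the same config are
    byte-identical.  Duplicate versions share the CASEID of their case,
    with the survivor carrying the largest FDA_DT (or, on ties, the
    largest PRIMARYID), so deduplication must recover exactly the
    survivors that :func:`generate_cases` returned.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cases, truth = generate_cases(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    versions: list[_Version] = []
    for case in cases:
        versions.extend(_duplicate_versions(rng, case, config))
        versions.append(
            _Version(demo=case.demo, drugs=case.drugs, reactions=case.reactions,
                     therapies=case.therapies)
        )
    versions.sort(key=lambda v: int(v.demo.primaryid))
    truth.n_raw_reports = len(versions)
    truth.link_counts = {
        v.demo.primaryid: {
            "drug": len(v.drugs), "reac": len(v.reactions), "ther": len(v.therapies)
        }
        for v in versions
    }

    year = min(int(y) for y in config.year_dist)
    write_table([v.demo for v in versions], out_dir / table_filename("DEMO", year, 1), "DEMO")
    write_table(
        [d for v in versions for d in v.drugs], out_dir / table_filename("DRUG", year, 1), "DRUG"
    )
    write_table(
        [r for v in versions for r in v.reactions], out_dir / table_filename("REAC", year, 1), "REAC"
    )
    write_table(
        [t for v in versions for t in v.therapies], out_dir / table_filename("THER", year, 1), "THER"
    )
    truth.to_json(out_dir / "ground_truth.json")
    pt_soc_map_from_config(config).to_csv(out_dir / "pt_soc_map.csv")
    return truth
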