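"""Disproportionality statistics over 2x2 reporting tables.

For one term t (a MedDRA PT or SOC) versus one drug, the pair records of
the whole deduplicated database cross-classify as

    =============  ============  ============
                   AE of interest   all other AEs
    target drug          a               b
    other drugs          c               d
    =============  ============  ============

with N = a+b+c+d the grand pair total.  Four classical signal statistics
are computed on this table:

* ROR  = ad/(bc), with the log-scale Wald 95% interval
  exp(ln ROR +/- 1.96*sqrt(1/a+1/b+1/c+1/d));
* PRR  = a(c+d)/(c(a+b)), paired with the Pearson chi-square
  (ad-bc)^2 N / ((a+b)(c+d)(a+c)(b+d)), no continuity correction;
* IC   = log2(aN/((a+c)(a+b))), the BCPNN information component, with the
  lower credibility bound IC025 = IC - 2*sqrt(V(IC)) where V(IC) is the
  closed-form posterior variance of the early BCPNN with symmetric unit
  priors;
* EBGM = aN/((a+c)(a+b)) -- the observed/expected relative reporting
  ratio, identical to 2^IC -- with the one-sided 5th-percentile bound
  EBGM05 = exp(ln EBGM - 1.645*sqrt(1/a+1/b+1/c+1/d)).

Note this EBGM is the *unshrunk* ratio: no gamma-mixture empirical-Bayes
fit (DuMouchel's MGPS shrinkage) is performed here.  With these
definitions IC and EBGM are the same quantity on different scales, an
identity the test-suite exploits.

Zero cells leave an estimate undefined (NaN marker) rather than raising;
an optional +0.5 continuity mode is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Optional, Sequence

from .cohort import PairRecord
from .util import percent, round_half_up

NAN = float("nan")


class InfeasibleAnchorError(ValueError):
    """A printed-aggregate anchor implies an impossible cell count."""


@dataclass(frozen=True)
class ContingencyTable:
    """The a, b, c, d cells for one term versus one drug (pair counts)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in {self}")
        if self.n_total == 0:
            raise ValueError("empty contingency table")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self, continuity: bool = False) -> tuple[float, float, float, float]:
        if continuity:
            return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)
        return (float(self.a), float(self.b), float(self.c), float(self.d))


@dataclass(frozen=True)
class RorEstimate:
    ror: float
    lo: float
    hi: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ror)


@dataclass(frozen=True)
class PrrEstimate:
    prr: float
    chi2: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.prr)


@dataclass(frozen=True)
class IcEstimate:
    ic: float
    ic025: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ic)


@dataclass(frozen=True)
class EbgmEstimate:
    ebgm: float
    ebgm05: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ebgm)


def ror(table: ContingencyTable, continuity: bool = False) -> RorEstimate:
    """Reporting odds ratio with the 95% log-scale Wald interval."""
    a, b, c, d = table.cells(continuity)
    if min(a, b, c, d) <= 0:
        return RorEstimate(NAN, NAN, NAN)
    point = a * d / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RorEstimate(
        ror=point,
        lo=math.exp(math.log(point) - 1.96 * se),
        hi=math.exp(math.log(point) + 1.96 * se),
    )


def prr_chi2(table: ContingencyTable, continuity: bool = False) -> PrrEstimate:
    """Proportional reporting ratio and Pearson chi-square (no Yates correction)."""
    a, b, c, d = table.cells(continuity)
    n = a + b + c + d
    if a <= 0 or c <= 0 or (a + b) <= 0:
        return PrrEstimate(NAN, NAN)
    prr = a * (c + d) / (c * (a + b))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = NAN if denom == 0 else (a * d - b * c) ** 2 * n / denom
    return PrrEstimate(prr=prr, chi2=chi2)


def _ic_variance(a: float, ab: float, ac: float, n: float) -> float:
    """Closed-form BCPNN posterior variance of IC (bits^2), unit priors.

    The symmetric-prior closed form of the early BCPNN: cell prior
    gamma11 = 1, margin priors alpha1 = beta1 = 1 with totals
    alpha = beta = 2, and gamma chosen so the prior IC expectation is 0.
    """
    alpha1 = beta1 = gamma11 = 1.0
    alpha = beta = 2.0
    gamma = gamma11 * (n + alpha) * (n + beta) / ((ab + alpha1) * (ac + beta1))
    v = (
        (n - a + gamma - gamma11) / ((a + gamma11) * (1 + n + gamma))
        + (n - ab + alpha - alpha1) / ((ab + alpha1) * (1 + n + alpha))
        + (n - ac + beta - beta1) / ((ac + beta1) * (1 + n + beta))
    )
    return v / (math.log(2.0) ** 2)


def bcpnn_ic(table: ContingencyTable, continuity: bool = False) -> IcEstimate:
    """BCPNN information component with its lower credibility bound.

    The point estimate is the observed/expected log2 ratio; IC025 is
    IC - 2*sqrt(V(IC)) with the closed-form posterior variance above.
    """
    a, b, c, d = table.cells(continuity)
    n = a + b + c + d
    if a <= 0 or (a + b) <= 0 or (a + c) <= 0:
        return IcEstimate(NAN, NAN)
    ic = math.log2(a * n / ((a + c) * (a + b)))
    v = _ic_variance(a, a + b, a + c, n)
    return IcEstimate(ic=ic, ic025=ic - 2.0 * math.sqrt(v))


def mgps_ebgm(table: ContingencyTable, z: float = 1.645, continuity: bool = False) -> EbgmEstimate:
    """Observed/expected relative reporting ratio with a lower bound.

    ``z`` defaults to 1.645, the one-sided 5th percentile, which is what
    published EBGM05 columns correspond to; pass 1.96 for a two-sided
    97.5% lower bound.
    """
    a, b, c, d = table.cells(continuity)
    n = a + b + c + d
    if a <= 0 or (a + b) <= 0 or (a + c) <= 0:
        return EbgmEstimate(NAN, NAN)
    ebgm = a * n / ((a + c) * (a + b))
    if min(a, b, c, d) <= 0:
        return EbgmEstimate(ebgm=ebgm, ebgm05=NAN)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EbgmEstimate(ebgm=ebgm, ebgm05=math.exp(math.log(ebgm) - z * se))


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------


def build_tables(
    pairs: Sequence[PairRecord],
    level: str = "PT",
    soc_counting: str = "report",
) -> dict[str, ContingencyTable]:
    """Build one contingency table per term from the full pair list.

    ``pairs`` must come from the complete deduplicated database -- target
    and non-target reports alike -- because cells c and d are the
    background.  At SOC level the counting unit is, by default, one per
    (report, SOC) (``soc_counting="report"``); ``"pairs"`` instead sums
    the PT pairs falling in each SOC.
    """
    if not pairs:
        raise ValueError("empty pair list")
    if level not in ("PT", "SOC"):
        raise ValueError(f"level must be 'PT' or 'SOC', got {level!r}")
    if level == "PT":
        units = {(p.caseid, p.pt, p.is_target) for p in pairs}
        keyed = [(pt, tgt) for (_, pt, tgt) in units]
    elif soc_counting == "report":
        units = {(p.caseid, p.soc, p.is_target) for p in pairs}
        keyed = [(soc, tgt) for (_, soc, tgt) in units]
    elif soc_counting == "pairs":
        keyed = [(p.soc, p.is_target) for p in pairs]
    else:
        raise ValueError(f"soc_counting must be 'report' or 'pairs', got {soc_counting!r}")

    target_total = sum(1 for _, tgt in keyed if tgt)
    grand_total = len(keyed)
    counts: dict[str, list[int]] = {}
    for term, tgt in keyed:
        cell = counts.setdefault(term, [0, 0])
        cell[0 if tgt else 1] += 1
    tables = {}
    for term, (a, c) in sorted(counts.items()):
        tables[term] = ContingencyTable(
            a=a, b=target_total - a, c=c, d=grand_total - target_total - c
        )
    return tables


def reconstruct_cells(
    a: int,
    target_total: int,
    grand_total: int,
    *,
    prr: Optional[float] = None,
    ebgm: Optional[float] = None,
) -> ContingencyTable:
    """Rebuild a full 2x2 table from published aggregates.

    Signal tables print only the a cell, the target pair total and a few
    statistics; given one anchor statistic (PRR or EBGM) the background
    cell c is solvable in closed form and rounded to the nearest count:

    * PRR anchor:   c = a(c+d) / (PRR * (a+b))      with c+d fixed
    * EBGM anchor:  a+c = a*N / ((a+b) * EBGM)

    The reconstructed table lets every other printed column be recomputed
    and cross-checked.
    """
    if not (1 <= a <= target_total < grand_total):
        raise ValueError("require 1 <= a <= target_total < grand_total")
    if (prr is None) == (ebgm is None):
        raise ValueError("provide exactly one anchor: prr= or ebgm=")
    b = target_total - a
    cd = grand_total - target_total
    if prr is not None:
        if prr <= 0:
            raise ValueError("anchor must be positive")
        c = round(a * cd / (prr * target_total))
    else:
        if ebgm <= 0:
            raise ValueError("anchor must be positive")
        c = round(a * grand_total / (target_total * ebgm)) - a
    d = cd - c
    if c < 1 or d < 1:
        raise InfeasibleAnchorError(
            f"anchor implies c={c}, d={d}; not a feasible background cell"
        )
    return ContingencyTable(a=a, b=b, c=c, d=d)


# ---------------------------------------------------------------------------
# criteria and combined evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignalCriteria:
    """Field-standard signal thresholds; each rule individually switchable."""

    min_a: int = 3
    ror_enabled: bool = True
    ror_ci_lower_gt: float = 1.0
    prr_enabled: bool = True
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic_enabled: bool = True
    ic025_gt: float = 0.0
    ebgm_enabled: bool = True
    ebgm05_gt: float = 2.0

    def __post_init__(self):
        if self.min_a < 1:
            raise ValueError("min_a must be >= 1")


@dataclass
class SignalEstimates:
    """All four algorithms for one term, plus per-algorithm signal flags."""

    term: str
    level: str
    n: int
    pct: float
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    flags: dict = field(default_factory=dict)


def evaluate(
    table: ContingencyTable,
    criteria: SignalCriteria = SignalCriteria(),
    term: str = "",
    level: str = "PT",
    target_total: Optional[int] = None,
    ebgm_z: float = 1.645,
    continuity: bool = False,
) -> SignalEstimates:
    """Run all four algorithms on one table and apply the signal criteria.

    Undefined estimates (NaN) always yield a False flag, as does an
    a-cell below ``criteria.min_a``.
    """
    r = ror(table, continuity)
    p = prr_chi2(table, continuity)
    i = bcpnn_ic(table, continuity)
    e = mgps_ebgm(table, z=ebgm_z, continuity=continuity)
    count_ok = table.a >= criteria.min_a
    flags = {
        "ror": bool(
            criteria.ror_enabled and count_ok and r.defined
            and not math.isnan(r.lo) and r.lo > criteria.ror_ci_lower_gt
        ),
        "prr": bool(
            criteria.prr_enabled and count_ok and p.defined
            and not math.isnan(p.chi2)
            and p.prr >= criteria.prr_min and p.chi2 >= criteria.chi2_min
        ),
        "ic": bool(
            criteria.ic_enabled and count_ok and i.defined
            and not math.isnan(i.ic025) and i.ic025 > criteria.ic025_gt
        ),
        "ebgm": bool(
            criteria.ebgm_enabled and count_ok and e.defined
            and not math.isnan(e.ebgm05) and e.ebgm05 > criteria.ebgm05_gt
        ),
    }
    denom = target_total if target_total else table.a + table.b
    return SignalEstimates(
        term=term,
        level=level,
        n=table.a,
        pct=percent(table.a, denom) if denom else NAN,
        ror=r.ror, ror_lo=r.lo, ror_hi=r.hi,
        prr=p.prr, chi2=p.chi2,
        ic=i.ic, ic025=i.ic025,
        ebgm=e.ebgm, ebgm05=e.ebgm05,
        flags=flags,
    )


def signal_table(
    pairs: Sequence[PairRecord],
    level: str = "PT",
    criteria: SignalCriteria = SignalCriteria(),
    soc_counting: str = "report",
    ebgm_z: float = 1.645,
    continuity: bool = False,
    terms: Optional[Iterable[str]] = None,
):
    """Signal estimates for every term, as a pandas DataFrame.

    Rows sort by n (descending) then term; ``terms`` restricts the output
    to an allow-list (normalized) for subset reports.  Estimates are
    unrounded; rounding half-up to 2 decimals is applied by the report
    writer.
    """
    import pandas as pd

    from .cohort import normalize_name

    tables = build_tables(pairs, level=level, soc_counting=soc_counting)
    target_total = next(iter(tables.values())).a + next(iter(tables.values())).b
    allow = {normalize_name(t) for t in terms} if terms is not None else None
    rows = []
    for term, table in tables.items():
        if allow is not None and term not in allow:
            continue
        est = evaluate(
            table, criteria, term=term, level=level,
            target_total=target_total, ebgm_z=ebgm_z, continuity=continuity,
        )
        row = {f.name: getattr(est, f.name) for f in fields(SignalEstimates) if f.name != "flags"}
        for name, value in est.flags.items():
            row[f"sig_{name}"] = value
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["n", "term"], ascending=[False, True], kind="mergesort")
        df = df.reset_index(drop=True)
    return df
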