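"""The four signal algorithms, table building and aggregate reconstruction."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faers_signalminer.cohort import PairRecord
from faers_signalminer.disproportionality import (
    ContingencyTable,
    InfeasibleAnchorError,
    SignalCriteria,
    bcpnn_ic,
    build_tables,
    evaluate,
    mgps_ebgm,
    prr_chi2,
    reconstruct_cells,
    ror,
)

BALANCED = ContingencyTable(5, 5, 5, 5)
SKEWED = ContingencyTable(10, 90, 100, 9900)

cells = st.integers(min_value=1, max_value=5000)
tables = st.builds(ContingencyTable, cells, cells, cells, cells)


def test_balanced_table_is_null_for_every_algorithm():
    assert ror(BALANCED).ror == pytest.approx(1.0)
    p = prr_chi2(BALANCED)
    assert p.prr == pytest.approx(1.0) and p.chi2 == pytest.approx(0.0)
    assert bcpnn_ic(BALANCED).ic == pytest.approx(0.0)
    assert mgps_ebgm(BALANCED).ebgm == pytest.approx(1.0)


def test_skewed_table_frozen_values():
    # closed forms evaluated independently: ROR = 10*9900/(90*100) = 11,
    # CI = exp(ln 11 -/+ 1.96*sqrt(1/10+1/90+1/100+1/9900)); PRR = 10;
    # chi2 = 90000^2*10100/(100*10000*110*9990); IC = log2(10*10100/(110*100)).
    r = ror(SKEWED)
    assert r.ror == pytest.approx(11.0)
    assert r.lo == pytest.approx(5.5598, abs=1e-3)
    assert r.hi == pytest.approx(21.7654, abs=1e-3)
    p = prr_chi2(SKEWED)
    assert p.prr == pytest.approx(10.0)
    assert p.chi2 == pytest.approx(74.4472, abs=1e-3)
    assert bcpnn_ic(SKEWED).ic == pytest.approx(math.log2(9.181818), abs=1e-5)
    assert mgps_ebgm(SKEWED).ebgm == pytest.approx(9.181818, abs=1e-5)


def test_zero_cells_give_undefined_markers_not_exceptions():
    t = ContingencyTable(3, 0, 7, 90)
    assert math.isnan(ror(t).ror)
    assert not math.isnan(prr_chi2(t).prr)  # PRR needs a,c >= 1 only
    assert math.isnan(prr_chi2(ContingencyTable(3, 7, 0, 90)).prr)
    assert math.isnan(bcpnn_ic(ContingencyTable(0, 3, 7, 90)).ic)
    assert math.isnan(mgps_ebgm(t).ebgm05) and not math.isnan(mgps_ebgm(t).ebgm)


def test_continuity_mode_defines_zero_cell_tables():
    t = ContingencyTable(3, 0, 7, 90)
    r = ror(t, continuity=True)
    assert r.defined and r.lo < r.ror < r.hi


def test_interval_cross_check_against_statsmodels():
    """Dual route: the log-scale Wald interval vs statsmodels' Table2x2."""
    sm = pytest.importorskip("statsmodels.api")
    for t in (SKEWED, ContingencyTable(44, 643, 21023, 6681700)):
        table = sm.stats.Table2x2([[t.a, t.b], [t.c, t.d]])
        r = ror(t)
        assert r.ror == pytest.approx(table.oddsratio, rel=1e-12)
        # statsmodels uses z = 1.959964; the conventional printed formula
        # uses 1.96 exactly, so the bounds agree only to ~2e-5 relative
        lo, hi = table.oddsratio_confint(0.05)
        assert r.lo == pytest.approx(lo, rel=1e-4)
        assert r.hi == pytest.approx(hi, rel=1e-4)


def test_chi2_cross_check_against_scipy():
    stats = pytest.importorskip("scipy.stats")
    for t in (SKEWED, ContingencyTable(44, 643, 21023, 6681700)):
        expected = stats.chi2_contingency(
            [[t.a, t.b], [t.c, t.d]], correction=False
        ).statistic
        assert prr_chi2(t).chi2 == pytest.approx(expected, rel=1e-12)


@given(tables)
@settings(derandomize=True, max_examples=200)
def test_ic_is_log2_of_ebgm(t):
    assert bcpnn_ic(t).ic == pytest.approx(math.log2(mgps_ebgm(t).ebgm), abs=1e-12)


@given(tables)
@settings(derandomize=True, max_examples=200)
def test_prr_ebgm_ratio_identity(t):
    # PRR = EBGM * (c+d)(a+c) / (c*N): both are a-share ratios with
    # different denominators; the identity pins the implementations together.
    prr = prr_chi2(t).prr
    ebgm = mgps_ebgm(t).ebgm
    assert prr == pytest.approx(
        ebgm * (t.c + t.d) * (t.a + t.c) / (t.c * t.n_total), rel=1e-12
    )


@given(tables)
@settings(derandomize=True, max_examples=200)
def test_ror_dominates_prr_dominates_ebgm_for_elevated_terms(t):
    # when the target's term share exceeds the background share
    if t.a / (t.a + t.b) <= t.c / (t.c + t.d):
        return
    r, p, e = ror(t).ror, prr_chi2(t).prr, mgps_ebgm(t).ebgm
    assert r >= p - 1e-12
    assert p >= e - 1e-12


@given(tables, st.integers(1, 50))
@settings(derandomize=True, max_examples=100)
def test_point_estimates_increase_with_a_at_fixed_margins(t, bump):
    # move `bump` reports from cell b to cell a and from d to c's complement:
    # increasing a while holding row/column margins requires a -= from b and
    # c -= into d, i.e. the classic diagonal shift.
    if t.b <= bump or t.c <= bump:
        return
    shifted = ContingencyTable(t.a + bump, t.b - bump, t.c - bump, t.d + bump)
    assert ror(shifted).ror > ror(t).ror
    assert prr_chi2(shifted).prr > prr_chi2(t).prr
    assert bcpnn_ic(shifted).ic > bcpnn_ic(t).ic
    assert mgps_ebgm(shifted).ebgm > mgps_ebgm(t).ebgm


@given(tables)
@settings(derandomize=True, max_examples=200)
def test_interval_ordering_invariants(t):
    r = ror(t)
    assert r.lo <= r.ror <= r.hi
    i = bcpnn_ic(t)
    assert i.ic025 <= i.ic
    e = mgps_ebgm(t)
    assert e.ebgm05 <= e.ebgm


# ---------------------------------------------------------------------------
# table building
# ---------------------------------------------------------------------------


def _pair(caseid, pt, soc, target):
    return PairRecord(caseid=caseid, pt=pt, soc=soc, is_target=target)


def test_build_tables_exhaustive_enumeration():
    pairs = [
        _pair("1", "X", "S1", True),
        _pair("1", "Y", "S1", True),
        _pair("2", "X", "S2", False),
        _pair("2", "Z", "S2", False),
    ]
    tables = build_tables(pairs, level="PT")
    assert tables["X"] == ContingencyTable(1, 1, 1, 1)
    assert tables["Y"] == ContingencyTable(1, 1, 0, 2)
    assert tables["Z"] == ContingencyTable(0, 2, 1, 1)
    # every table shares the same grand total
    assert {t.n_total for t in tables.values()} == {4}


def test_soc_level_counts_once_per_report_by_default():
    pairs = [
        _pair("1", "X", "S1", True),
        _pair("1", "Y", "S1", True),  # same report, same SOC
        _pair("2", "Z", "S2", False),
    ]
    report_level = build_tables(pairs, level="SOC", soc_counting="report")
    assert report_level["S1"].a == 1
    pair_level = build_tables(pairs, level="SOC", soc_counting="pairs")
    assert pair_level["S1"].a == 2


def test_empty_pairs_is_an_error():
    with pytest.raises(ValueError):
        build_tables([], level="PT")


# ---------------------------------------------------------------------------
# reconstruction from printed aggregates
# ---------------------------------------------------------------------------


def test_reconstruct_from_prr_anchor_solves_background_cell():
    t = reconstruct_cells(44, 687, 6_703_410, prr=20.42)
    assert (t.a, t.b, t.c) == (44, 643, 21023)
    assert t.n_total == 6_703_410
    # anchor consistency: the reconstructed table reproduces the anchor
    assert prr_chi2(t).prr == pytest.approx(20.42, abs=0.005)


def test_reconstruct_from_ebgm_anchor():
    t = reconstruct_cells(44, 687, 6_703_410, ebgm=20.35)
    assert t.a + t.c == 21097
    assert mgps_ebgm(t).ebgm == pytest.approx(20.35, abs=0.005)


def test_infeasible_anchor_raises():
    with pytest.raises(InfeasibleAnchorError):
        reconstruct_cells(44, 687, 6_703_410, prr=1e9)


# ---------------------------------------------------------------------------
# criteria
# ---------------------------------------------------------------------------


def test_balanced_table_raises_no_flags():
    est = evaluate(BALANCED, SignalCriteria())
    assert est.flags == {"ror": False, "prr": False, "ic": False, "ebgm": False}


def test_strong_reconstructed_signal_flags_all_four():
    t = reconstruct_cells(44, 687, 6_703_410, prr=20.42)
    est = evaluate(t, SignalCriteria())
    assert est.flags == {"ror": True, "prr": True, "ic": True, "ebgm": True}


def test_min_count_gate_suppresses_small_n_signals():
    strong_but_tiny = ContingencyTable(2, 98, 10, 99890)
    est = evaluate(strong_but_tiny, SignalCriteria(min_a=3))
    assert est.flags == {"ror": False, "prr": False, "ic": False, "ebgm": False}
    est2 = evaluate(strong_but_tiny, SignalCriteria(min_a=1))
    assert est2.flags["ror"] and est2.flags["prr"]
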