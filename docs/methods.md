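# Methods

## Counting model

The analysis unit is the **drug–event pair**: one record per
(deduplicated report, distinct reaction PT). A report therefore
contributes at most one count to any term's a-cell, matching the
"number of reports" semantics of published 2×2 definitions, while the
grand total N is the pair total of the whole database. At SOC level the
default unit is one per (report, SOC) (`soc_counting="report"`);
summing PT pairs within a SOC is available as `soc_counting="pairs"`.
Published SOC tables are consistent with the report-level convention
(their SOC n-column can exceed the PT pair total by only the few
reports spanning multiple SOCs).

A report joins the drug cohort when a drug row matches a configured
synonym on the normalized DRUGNAME or PROD_AI **exactly** — uppercase,
punctuation/trademark glyphs to spaces, whitespace collapsed — and, by
default, that row's role code is PS. Exact matching is deliberate:
synonym lists enumerate the name variants, and substring matching on
free-text drug fields captures unrelated combination products. The
flag is decided per report and inherited by all its pairs.

## Deduplication

Per CASEID the survivor maximizes (FDA_DT, PRIMARYID): the most
recently received version wins, ties go to the larger PRIMARYID
(compared numerically when all digits, lexicographically otherwise — a
crash-free total order on dirty identifiers). An absent FDA_DT loses
to any present one; two absents fall through to the PRIMARYID rule.
Identical (CASEID, FDA_DT, PRIMARYID) triples raise an integrity error
rather than picking arbitrarily. The operation is idempotent and
permutation-invariant, which the property tests assert. Cross-quarter
deleted-case lists are not applied.

## The four statistics

Formulas as in the package README. Numerical decisions:

- **Zero cells** leave an estimate undefined (NaN marker, never an
  exception, and always a `False` signal flag); no Haldane correction
  by default because published tables never contain zero-cell terms.
  An optional `continuity=True` adds +0.5 to every cell.
- **χ²** is Pearson's statistic without Yates continuity correction,
  exactly the classical closed form; it agrees with
  `scipy.stats.chi2_contingency(..., correction=False)` to 1e-12.
- **ROR/EBGM intervals** use the conventional printed z-values (1.96;
  1.645 for EBGM05). `ebgm_z` is configurable; 1.645 is the default
  because published EBGM05 columns correspond to the one-sided 5th
  percentile — recomputing published rows with 1.645 reproduces them,
  while 1.96 does not.
- **EBGM here is the unshrunk observed/expected ratio** aN/((a+c)(a+b)),
  i.e. the relative reporting ratio, identical to 2^IC. A full
  gamma-Poisson empirical-Bayes shrinkage (DuMouchel's MGPS) is *not*
  implemented; for the small-n terms where shrinkage matters most, the
  EBGM column here will exceed a shrunk EBGM. This is stated loudly
  because the column name invites confusion.
- **IC025** is IC − 2√V(IC) with the closed-form posterior variance of
  the early BCPNN under symmetric unit priors (cell prior γ₁₁ = 1,
  margin priors α₁ = β₁ = 1, totals α = β = 2, γ chosen so the prior
  expectation of IC is 0). Published IC025 columns in the validation
  source show a near-constant offset from IC that no count-dependent
  variance reproduces, so IC025 values are documented as this
  package's own convention and are not compared against printed ones.
- **Rounding for report output** is half-up to 2 decimals (`Decimal`
  based), the convention of printed signal tables; all in-memory
  estimates stay unrounded.

### Reconstruction from published aggregates

`reconstruct_cells(a, target_total, grand_total, prr=…|ebgm=…)` solves
the background cell from one anchor statistic (c = a(c+d)/(PRR·(a+b)),
or a+c = aN/((a+b)·EBGM)), rounds to the nearest integer and returns
the full table, raising if the anchor implies c < 1 or d < 1. This
turns printed rows into complete, recomputable tables: the validation
suite rebuilds a published muscle-spasms row (a = 44, 687 target pairs,
N = 6,703,410, PRR 20.42 → c = 21,023) and recovers the published ROR
21.75 (16.02–29.53) to the printed precision. One note on the printed
aggregates: the source describes N ≈ 6.7 M as AE counts "related to"
the drug while also reporting 687 drug pairs; only the reading of N as
the grand pair total of the deduplicated database makes the printed
ROR/PRR/CI columns internally consistent, and that reading is used.

## Signal criteria

Defaults: a ≥ 3, ROR CI lower bound > 1, PRR ≥ 2 with χ² ≥ 4,
IC025 > 0, EBGM05 > 2 — the field-standard thresholds; each rule is
individually switchable and every threshold configurable. These are
screening thresholds, not causal claims; no multiple-testing
adjustment is applied (none is conventional in this screening setting).

## Time to onset

TTO = EVENT_DT (DEMO) − earliest START_DT (THER) among the report's
matching target-drug rows, in whole days. Both dates must have full
day precision; otherwise the report is excluded with reason
`missing_date`, and negative intervals with `event_before_start`, so
included + excluded = cohort size. Same-day onset counts as 0 and is
included. One TTO per report (the earliest qualifying start), since
onset times are reported per report, not per therapy row. Quantiles
use linear interpolation between order statistics (the default of
mainstream statistical software); cumulative bins at ≤30/≤60/≤180 days
are upper-inclusive.

## Demographics

Ages convert to years via AGE_COD (DEC×10, MON÷12, WK÷52.143,
DY÷365.25, HR accordingly; absent code = years), weights to kg via
WT_COD (LBS×0.45359237). Bin edges: age <18, [18, 65), [65, 85], >85;
weight <50, [50, 100], >100 kg — the edge ownership (65, 85, 50, 100)
chosen to make the labels mutually exclusive in the conventional way.
Report year comes from FDA_DT (receipt), not EVENT_DT. Missing values
form their own category so counts always sum to the cohort size.

## Synthetic data generator

`synthetic_faers` emulates the structure of real quarterly extracts:
multi-version cases (a configurable fraction of cases gains an earlier
version with smaller PRIMARYID and earlier — or, with probability
`dup_tie_rate`, identical — FDA_DT, and a subset of the reactions),
one-to-many drug/reaction/therapy links, PS/SS/C roles with occasional
target-drug non-PS rows (exercising the PS-only rule), decorated drug
name strings (case changes, trademark glyphs, hyphens), partial and
missing dates, and categorical demographics.

Reactions follow a per-PT independent inclusion model: case *i*
includes PT *j* with probability p_j (background) or p′_j = min(m_j·p_j,
0.95) (target cases, with injected multipliers m_j); a case drawing no
reaction receives one categorical draw with the same relative weights.
That fallback rescales every PT's expected pair count within a stratum
by a common factor, so the pair-level population odds ratio has the
exact closed form

    OR_j = [p′_j/(E_t − p′_j)] / [p_j/(E_b − p_j)],   E = Σ p within stratum,

returned by `population_odds_ratio` and used as the truth in coverage
simulations. Two consequences worth knowing: with a single injected
rare PT, OR ≈ m; with many injected PTs, E_t grows and *weakly*
injected common terms can show pair-level ORs below 1 — not a bug but
the denominator competition inherent to pair-level disproportionality
(drug cohorts with rich AE profiles dilute their common-term shares).

Every run returns a `GroundTruth` ledger (unique-case and target-case
counts, true per-PT 2×2 cells, true onset days, per-version link
counts), and the integration tests assert *exact* equality between
pipeline-computed tables and the ledger — the pipeline is a
deterministic count, so any discrepancy is a bug. The default
configuration mirrors a small real cohort: 10,000 cases at 2% target
share (~200 target reports, ~650 pairs at ~3.3 pairs per target
report), 78% female, US-dominated, declining yearly counts over
2020–2023, log-normal onset with median 48 days and log-SD 1.17
(chosen so the IQR spans roughly 19–92 days), 10% missing/partial
dates. What the generator does **not** emulate: real FAERS drug-name
noise beyond simple decoration, indication/outcome tables, reporter
mix, secular reporting trends, and correlated reaction co-occurrence —
so passing tests demonstrate correctness of the counting and
statistics, not robustness to real-world name-mapping noise.

Determinism: all draws come from one `numpy` PCG64 generator seeded
from the config; file output is byte-identical across runs and
platforms for a fixed config.

## Problem sizes used in validation

Unit and integration tests run on a 600-case quarter with 30%
duplication; interval-coverage simulations use 200 replicates of
50,000-case databases per injected strength (2/5/20), drawing only the
reaction layer through the same model (`simulate_true_cells`) since
demographics are irrelevant to the 2×2 cells; the demo fixture uses
10,000 cases. These sizes make the full suite run in well under a
minute on one CPU while keeping every statistical tolerance meaningful
at ±2σ or better.

## Known limitations

- PT→SOC mapping is single-valued and user-supplied; MedDRA
  primary/secondary SOC multiplicity is not modelled.
- No FAERS XML (E2B) dialect; ASCII quarterly files only.
- No probabilistic duplicate detection across distinct CASEIDs.
- The EBGM column is unshrunk (see above); IC025 follows this
  package's documented variance, not any particular published table.
- Optional quarterly tables (INDI, OUTC, RPSR) are not ingested.
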