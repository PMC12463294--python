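# Methods

## Counting model

The unit of analysis is the drug–event **pair**: one (report, preferred
term) occurrence, after collapsing duplicate identical terms within a
report. Database totals (N) and drug margins (n_drug) are therefore pair
counts, matching how spontaneous-report "AE totals" are conventionally
quoted; report-level counting can be obtained by restricting each report
to its distinct terms and is not the default. All denominators derive from
one pair table per cohort, so every 2×2 table for a given cohort shares
the same N and n_drug.

Deduplication keeps, per case identifier, the report version with the
latest report date, ties broken by the largest primary id — the standard
practice for FAERS quarters, where a case accumulates versions across
quarters — and removes every report of a case listed in a DELETED table.
The operation is idempotent. Partial dates (YYYYMM, YYYY) are kept as
typed partial strings; they participate in dedup ordering (zero-padded)
but count as missing wherever day precision is required.

Drug selection is case-insensitive substring matching over normalised
(upper-cased, whitespace-collapsed) drug names against a synonym list; the
shipped default covers insulin glargine and its brand names. The default
role filter is primary suspect only; secondary suspect, concomitant and
interacting roles can be enabled per run. Both choices are configuration,
not code.

## Disproportionality statistics

ROR and PRR use the textbook closed forms with log-scale Wald 95%
intervals (Woolf variant for the ROR). χ² is **uncorrected** Pearson; a
Yates switch exists but is never the default — the uncorrected statistic
is the one that reproduces published signal tables in this domain. No
continuity correction is applied to zero cells: a statistic whose formula
requires a positive cell is returned as NaN with an `undefined` flag, and
a flagged component can never satisfy the joint criteria (consistent with
the a ≥ 3 floor, which already excludes all-zero numerators).

The BCPNN information component is reported in two forms, labelled
exactly this way in outputs:

- **IC**: the unshrunk log₂ observed/expected ratio, log₂(aN/(n_drug·n_event));
- **IC025**: the posterior expectation of the IC under Dirichlet
  pseudo-counts minus two posterior standard deviations.

The pseudo-count configuration is the classic one — marginal pseudo-counts
α₁ = β₁ = 1 with prior totals α = β = 2, joint pseudo-count γ₁₁ = 1 with
the joint total tied to the margins so the prior is centred on
independence. This configuration is pinned by tests: it reproduces
published IC025 values (3.30 bits at a = 34, 2.94 at a = 17) that the
large-count normal approximation (IC − 2/(ln2·√a), ≈ 3.94/4.65 there)
does not.

EBGM is reported as the observed/expected ratio itself and EBGM05 as
2^(IC − 2√V(IC)). This EBGM05 matches published values at large counts
but can deviate 1–2% on small-count rows; since the exact small-count
convention in circulation varies, EBGM05 is treated as a soft quantity:
it participates in the signal criteria but not in printed-row
verification. The full gamma-Poisson mixture shrinker (`pvsignals.mgps`)
fits a two-component gamma prior by maximum marginal likelihood
(negative-binomial mixture likelihood, L-BFGS-B over log/logit-scale
parameters, a fixed grid of starts plus seeded jitter, component labels
canonicalised low-mean-first) and provides posterior-geometric-mean
shrinkage as the principled alternative; it is optional because the
closed forms above are what published signal tables use.

Signal criteria are the conjunction a ≥ 3 ∧ ROR95lo > 1 ∧ PRR ≥ 2 ∧
χ² ≥ 4 ∧ IC025 > 0 ∧ EBGM05 > 2. Strength classes partition the IC025
axis with closed upper edges: none (≤ 0), weak (0, 1.5], medium (1.5, 3],
strong (> 3). No multiple-testing adjustment is applied — these are
hypothesis-generating alerts, and the run manifest says so explicitly.

## Published-row verification

Published signal tables print a, ROR (with CI) and the cohort margins but
not the comparator cell. Since ROR = ad/bc is monotone in c, the printed
ROR pins c = a(N − n_drug)/((n_drug − a)·ROR + a), rounded to the nearest
integer. Rebuilding the table and recomputing PRR, χ², IC, IC025 and EBGM
must then reproduce the printed values up to rounding propagation. The
tolerance is 0.5%, with one refinement: for printed values of magnitude
≤ 1 (small IC025 entries like 0.09) the comparison is absolute rather than
relative, because two-decimal printing alone can exceed 0.5% of such a
value. All 98 shipped rows pass with maximum deviation 0.46%.

## Pregnancy cohort

Candidates are the union of reports flagged by reaction terms (the
SMQ-derived pregnancy pool, which deliberately includes the paternal
terms) and reports whose indication text exactly matches a pregnancy
indication after normalisation. Exclusions then remove: any candidate
with a paternal-exposure reaction term; male reports, unless a
fetal/neonatal term set is configured and justifies retention (an infant
case reported under the child's sex); and reports with recorded age
outside [6, 55] years — a deliberately wide plausibility window for
pregnancy, configurable per run. A "review-recovered" hook can re-add
externally adjudicated ids; the default is no recovery. All steps are set
operations, so results are independent of record order, and the flow
counts (flagged, union, excluded, final) are emitted for audit.

MedDRA content is licensed: the shipped term file contains only publicly
printed PT codes plus a short starter list and is explicitly
non-exhaustive. Real analyses must supply their own SMQ expansions in the
same CSV format.

## Time to onset

TTO is event date minus the **earliest complete** therapy start among the
target drug's records on the report (when several therapy rows exist, the
first exposure is the pharmacologically relevant origin). Negative
intervals are excluded as outliers, day 0 is valid, and partial dates make
the record missing. Quartiles use inclusive linear interpolation (the
numpy/R type-7 default; the convention is stated because published tables
rarely state theirs). Calendar bins are 0–30, 31–60, 61–90, 91–120,
121–150, 151–180, 181–360 and > 360 days, closed on both ends with the
last bin open above; 0 falls in the first bin. The cumulative-incidence
curve is the empirical CDF over valid intervals.

## Synthetic quarter generator

The generator emulates the structural features the pipeline must survive:
multi-version duplicate cases (extra versions with earlier dates and
smaller primary ids), a DELETED list, demographic fields, a target drug
on a configurable share of reports (default 10%), a 250-term background
PT catalogue with Zipf weights, per-report PT multisets (1–5 terms,
truncated geometric) so pair collapsing is genuinely exercised, a
pregnancy stratum (default 3%) tagged via maternal-exposure reaction
terms and/or pregnancy indications with forced coverage (every stratum
report carries at least one tag), paternal and strictly-maternal male
decoys for the exclusion rules, and log-normal onset times (default
median 61 days overall and 186 days in pregnancy, σ = 1.2 on the log
scale — the onset profile of a long-acting basal insulin).

Injected signals multiply a PT's weight inside the target-drug multinomial
(renormalised). Two consequences worth knowing: the realised
observed/expected ratio equals the nominal multiplier only in the
small-share limit (with a 10% share, a 10× injection realises a/E ≈ 5–9,
still comfortably detectable); and the exact emitted pair counts — not
model expectations — are the ground truth (`GroundTruth.pairs`,
`expected_tables`), so oracle checks are equality checks. Deleted cases
and decoys are drawn disjointly from the pregnancy stratum so stratum
counts are exact. One `numpy` Generator keyed by the seed drives all
draws in a fixed order; the same seed yields byte-identical files.

What the generator does **not** emulate: drug co-prescription
correlations, free-text narratives, country/reporter biases correlated
with events, MedDRA hierarchy structure, and real-world duplicate
near-misses (duplicates are exact copies under another version id).
Passing tests therefore demonstrate correctness of the counting and
statistics, not robustness to every messiness of real FAERS text.

## Problem sizes and determinism

The test suite runs the pipeline at 2,000 cases for exact-oracle checks,
20,000 cases for null calibration (all multipliers 1: ≤ 2% of background
PTs may pass the joint criteria; observed 0%), and 50,000 cases for
signal recovery (five 10× injections: all five recovered at medium or
strong strength, no strong-class false positives among nulls). The MGPS
fit is validated by parameter recovery on 5,000 simulated PT counts
(≤ 15% relative error per parameter) and by the large-count limit
(shrunken EBGM within 1% of a/E for a ≥ 1000). All stochastic tests use
fixed seeds; hypothesis-based property tests are derandomised.

## Known limitations

- Drug-name matching is substring-based; misspellings and combination
  products need explicit synonyms.
- The EBGM05 closed form is a two-standard-deviation log-scale bound, not
  an exact posterior 5th percentile; small-count values differ slightly
  from some published tables (see above).
- The pregnancy age window and the male-retention rule are heuristics
  standing in for manual case review; the review-recovered hook exists
  precisely because no automated rule reproduces expert adjudication.
- Back-derived comparator cells inherit the printing precision of the
  published ROR; for a ≤ 5 the integer rounding of c dominates small
  deviations in recomputed statistics.
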