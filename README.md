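# pvsignals

Disproportionality signal detection for spontaneous adverse-event reports,
built around the insulin glargine safety question: which adverse events are
reported disproportionately often with the drug — in the population at
large, and specifically during pregnancy?

The package is aimed at pharmacovigilance analysts working with
FAERS-style quarterly ASCII data. It covers the full pipeline: parsing the
`$`-delimited quarterly tables (DEMO, DRUG, REAC, INDI, THER, OUTC,
DELETED), collapsing multi-version cases, selecting the drug of interest,
counting drug–event pairs, computing four disproportionality statistics
with joint signal criteria, assembling a pregnancy subcohort from
SMQ-derived term lists, and summarising time to onset. A synthetic report
generator with exact ground truth stands in for the (multi-gigabyte,
non-distributable) real download, so every stage is testable end to end.

## The statistics

For one drug–event pair, counts of *pairs* (one report × one preferred
term) form the 2×2 table

|                 | target event | other events |
|-----------------|--------------|--------------|
| target drug     | a            | b            |
| all other drugs | c            | d            |

with N = a+b+c+d. The four algorithms:

- **ROR** = ad/bc, Woolf 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`
- **PRR** = (a/(a+b)) / (c/(c+d)), with uncorrected Pearson **χ²**
- **BCPNN information component** IC = log₂(aN / ((a+b)(a+c))), with the
  credible lower bound IC025 computed from Dirichlet pseudo-counts
  (α₁=β₁=γ₁₁=1, prior totals α=β=2): posterior expectation minus two
  posterior standard deviations
- **EBGM** = aN/((a+b)(a+c)) (observed/expected) with EBGM05 =
  2^(IC − 2√V(IC)); a full DuMouchel-style gamma-mixture shrinkage fit is
  available in `pvsignals.mgps` as the principled alternative

A pair is a **signal** when all six criteria hold: a ≥ 3, ROR CI lower
bound > 1, PRR ≥ 2, χ² ≥ 4, IC025 > 0, EBGM05 > 2. Signal strength is
classed by IC025: weak (0–1.5], medium (1.5–3], strong (> 3).

## Worked example

Verify a published signal-table row without the source database. The row
for hypoglycaemia in the overall insulin-glargine cohort reports a = 3689
event pairs, ROR 22.04, against margins n_drug = 229,956 and
N = 53,352,754. Back-derive the comparator cell and recompute everything:

```python
from pvsignals import (ContingencyTable, compute_statistics,
                       solve_comparator_count)

a, ror, n_drug, N = 3689, 22.04, 229_956, 53_352_754
c = solve_comparator_count(a, ror, n_drug, N)   # -> 39268
t = ContingencyTable(a, n_drug - a, c, N - n_drug - c)
s = compute_statistics(t)
print(f"PRR {s.prr:.2f}  chi2 {s.chi2:.0f}  IC {s.ic:.2f} "
      f"(IC025 {s.ic025:.2f})  EBGM {s.ebgm:.2f}")
```

```
PRR 21.70  chi2 66649  IC 4.32 (IC025 4.26)  EBGM 19.92
```

matching the published 21.71 / 66661.2 / 4.32 (4.26) / 19.93 to printing
precision. `pvsignals verify` runs this check over all 98 shipped rows
(98/98 pass within 0.5%).

The synthetic end-to-end run (see `analysis/`): a 50,000-case quarter with
five events injected at 10× background reporting among target-drug
reports yields, after deduplication (49,500 reports) and pair counting
(93,632 pairs, 9,421 with the drug), exactly those five PTs as signals —
all medium strength, e.g. `PT_0030: a=489, ROR 9.75, IC025 2.17` — with
zero strong-class false positives among the 245 null terms, and onset
medians of 61 days overall versus 208 days in the 1,500-report pregnancy
cohort (population medians 61/186).

## Command line

```bash
pvsignals simulate --config cfg.yaml --out quarter/ --seed 1
pvsignals run --input quarter/ --cohort overall --out results/
pvsignals run --input quarter/ --cohort pregnancy --out results/
pvsignals verify            # re-verify the shipped published rows
```

The numbered scripts under `analysis/` run the same steps as a documented
narrative (simulate → overall signals → pregnancy signals → time to onset
→ published-row verification), writing tables under `results/`.

## What is (deliberately) out of scope

Absolute report counts of the real database (they require the actual
download), MedDRA dictionary content (licensed; term sets are
user-supplied CSVs, the shipped lists are starter sets), RxNorm-grade drug
name normalisation, and any causal interpretation: a disproportionality
signal is a statistical alert, not proof of a drug–event relationship.
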