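"""Pregnancy-subcohort analysis of the synthetic quarter.

Assembles the pregnancy cohort (SMQ-style reaction terms + indication
text, minus paternal/male/age exclusions), then runs the within-cohort
disproportionality contrast.  Writes results/pregnancy/ and checks the
cohort against the generator's ground-truth stratum.
"""

import pandas as pd

from common import QUARTER_DIR, RESULTS
from pvsignals import RunConfig, run_analysis
from pvsignals.datafiles import packaged_term_sets
from pvsignals.store import discover_quarter_files, parse_quarter

store = parse_quarter(discover_quarter_files(QUARTER_DIR))
config = RunConfig(term_sets=packaged_term_sets())
bundle = run_analysis(store, config, cohort="pregnancy", out_dir=RESULTS / "pregnancy")

flow = bundle["manifest"]["cohort_flow"]
print("cohort flow:", flow)

labels = pd.read_csv(QUARTER_DIR / "ground_truth_reports.csv", dtype={"primaryid": str})
truth_preg = set(labels.loc[(labels.stratum == "pregnancy") & ~labels.deleted, "primaryid"])
print(f"ground-truth pregnancy stratum: {len(truth_preg)}; "
      f"assembled cohort: {flow['final_cohort']}; "
      f"match: {flow['final_cohort'] == len(truth_preg)}")

sig = bundle["signal_table_view"]
print(f"\n{len(sig)} signals in the pregnancy cohort (all strengths kept):")
if len(sig):
    print(sig[["pt", "a", "ror", "ic025", "strength"]].head(10).round(2).to_string(index=False))
print(f"outputs in {RESULTS / 'pregnancy'}")
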