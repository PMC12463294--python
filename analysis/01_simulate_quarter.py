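"""Generate the synthetic study quarter and record its ground truth.

Writes FAERS-format files under scratch/quarter/ and a short simulation
summary (stratum sizes, injected signals, survivor counts) under results/.
"""

import pandas as pd

from common import INJECTED, QUARTER_DIR, RESULTS, STUDY_CONFIG
from pvsignals import generate_quarter

paths, truth = generate_quarter(STUDY_CONFIG, QUARTER_DIR)
labels = truth.report_labels

summary = pd.DataFrame(
    [
        ("cases simulated", STUDY_CONFIG.n_cases),
        ("reports surviving deduplication", truth.n_surviving_reports),
        ("target-drug reports", int((labels["exposed"] & ~labels["deleted"]).sum())),
        ("pregnancy stratum", len(truth.pregnancy_ids)),
        ("paternal decoys", len(truth.paternal_decoy_ids)),
        ("male decoys", len(truth.male_decoy_ids)),
        ("deleted cases", len(truth.deleted_case_ids)),
        ("drug-event pairs (ground truth)", len(truth.pairs)),
        ("injected signal PTs", ", ".join(sorted(INJECTED))),
    ],
    columns=["quantity", "value"],
)
RESULTS.mkdir(exist_ok=True)
summary.to_csv(RESULTS / "simulation_summary.csv", index=False)
truth.pairs.to_csv(QUARTER_DIR / "ground_truth_pairs.csv", index=False)
labels.to_csv(QUARTER_DIR / "ground_truth_reports.csv", index=False)

print(f"wrote quarter to {QUARTER_DIR}")
print(summary.to_string(index=False))
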