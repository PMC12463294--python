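"""Time-to-onset contrast: overall population versus pregnancy cohort.

Summarises onset intervals (median/IQR, calendar bins) and writes the
cumulative-incidence curves for both cohorts under results/tto/.
"""

from common import QUARTER_DIR, RESULTS
from pvsignals import RunConfig, deduplicate, run_analysis
from pvsignals.datafiles import packaged_term_sets
from pvsignals.store import discover_quarter_files, parse_quarter

store = deduplicate(parse_quarter(discover_quarter_files(QUARTER_DIR)))
config = RunConfig(term_sets=packaged_term_sets())

out = RESULTS / "tto"
out.mkdir(parents=True, exist_ok=True)
for cohort in ("overall", "pregnancy"):
    bundle = run_analysis(store, config, cohort=cohort)
    s = bundle["tto_summary"]
    s.as_frame().to_csv(out / f"{cohort}_tto_summary.csv", index=False)
    bundle["tto_curve"].to_csv(out / f"{cohort}_tto_curve.csv", index=False)
    if s.n_valid:
        print(f"{cohort}: n={s.n_valid} median {s.median:.0f} d "
              f"(IQR {s.q1:.0f}-{s.q3:.0f}), range {s.min:.0f}-{s.max:.0f}")
    else:
        print(f"{cohort}: no valid onset intervals")
print(f"outputs in {out}")
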