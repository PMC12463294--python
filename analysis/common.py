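"""Shared paths and the study configuration for the analysis scripts.

The synthetic quarter emulates the study conditions: a 50,000-case
database, ~10% of reports carrying the target drug as primary suspect,
a 250-term background event catalogue, five events injected at 10x
background reporting among target-drug reports, a 3% pregnancy stratum
with paternal/male decoys, and log-normal onset times (median 61 days
overall, 186 days in pregnancy).
"""

from pathlib import Path

from pvsignals import GeneratorConfig

ROOT = Path(__file__).resolve().parent.parent
QUARTER_DIR = ROOT / "scratch" / "quarter"
RESULTS = ROOT / "results"

INJECTED = {f"PT_{i:04d}": 10.0 for i in (30, 60, 100, 150, 200)}

STUDY_CONFIG = GeneratorConfig(
    n_cases=50_000,
    injected_signals=dict(INJECTED),
    seed=20_240_601,
)
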