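"""End-to-end orchestration of the two analyses (overall and pregnancy).

A run takes a report store (parsed from FAERS-style files or generated
synthetically), deduplicates it, selects the drug-of-interest reports,
builds the drug–event pair table, and writes the full artefact bundle:
a demographics summary, SOC-level counts/proportions and statistics, the
PT-level signal table ranked by IC025, the time-to-onset summary and
cumulative curve, and a YAML run manifest.

The pregnancy analysis first assembles the pregnancy cohort and restricts
both numerator and denominator to it, i.e. the disproportionality contrast
is the target drug versus all other drugs *within* pregnancy reports.

Presentation note: the overall-population report view keeps medium and
strong signals only, while the pregnancy view keeps weak signals as well
(pregnancy safety reporting conventionally surfaces weaker alerts); the
unfiltered tables are always written alongside.  No multiple-testing
adjustment is applied anywhere — signals are hypothesis-generating alerts,
not confirmatory tests — and the manifest records this.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .disprop import BcpnnPriors, signal_table, solve_comparator_count, ContingencyTable, compute_statistics
from .pregnancy import SmqTermSet, assemble_pregnancy_cohort, load_term_sets
from .store import (
    DEFAULT_DRUG_SYNONYMS,
    ReportStore,
    build_drug_event_pairs,
    deduplicate,
    select_drug_reports,
)
from .tto import cumulative_curve, summarize_tto, tto_records


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with the conventional defaults."""

    drug_synonyms: Sequence[str] = DEFAULT_DRUG_SYNONYMS
    roles: Sequence[str] = ("primary-suspect",)
    term_sets: Mapping[str, SmqTermSet] | None = None
    soc_map: Mapping[str, str] | None = None
    priors: BcpnnPriors = field(default_factory=BcpnnPriors)
    min_age: float = 6.0
    max_age: float = 55.0
    min_a: int = 1
    seed: int = 0

    @staticmethod
    def with_packaged_terms(**kwargs) -> "RunConfig":
        from .datafiles import packaged_term_sets

        return RunConfig(term_sets=packaged_term_sets(), **kwargs)


def demographics_summary(store: ReportStore) -> pd.DataFrame:
    """Sex / age-band / reporter / country / outcome roster with percentages."""
    demo = store.demo
    n = max(len(demo), 1)
    rows = []

    def add(block: str, series: pd.Series):
        for value, count in series.items():
            rows.append((block, value, int(count), round(100 * count / n, 2)))

    add("sex", demo["sex"].value_counts())
    age = demo["age_years"]
    bands = pd.cut(
        age,
        [0, 18, 45, 65, 75, np.inf],
        right=False,
        labels=["<18", "18-44", "45-64", "65-74", ">=75"],
    ).astype(object)
    bands = pd.Series(np.where(age.isna(), "unspecified", bands), index=demo.index)
    add("age", bands.value_counts())
    add("reporter", demo["reporter"].value_counts())
    add("country", demo["country"].replace("", "unspecified").value_counts())
    outc = store.outcomes[store.outcomes["primaryid"].isin(set(demo["primaryid"]))]
    add("outcome", outc["outcome"].value_counts())
    return pd.DataFrame(rows, columns=["block", "value", "count", "percent"])


def soc_summary(signal_df: pd.DataFrame, pairs: pd.DataFrame, soc_map: Mapping[str, str] | None) -> pd.DataFrame:
    """SOC-level pair counts and proportions among the drug's pairs."""
    exposed = pairs[pairs["exposed"]].copy()
    exposed["soc"] = exposed["pt_name"].map(soc_map or {}).fillna("UNMAPPED")
    counts = exposed["soc"].value_counts()
    total = max(len(exposed), 1)
    return pd.DataFrame(
        {
            "soc": counts.index,
            "n_pairs": counts.values,
            "proportion": np.round(counts.values / total, 4),
        }
    )


def run_analysis(
    store: ReportStore,
    config: RunConfig,
    cohort: str = "overall",
    out_dir: str | Path | None = None,
) -> dict:
    """Run one full analysis; returns (and optionally writes) the bundle.

    ``cohort`` is "overall" or "pregnancy".  The returned dict holds the
    signal table (full and presentation-filtered), demographics, SOC
    summaries, TTO summary/curve, cohort flow counts, and the manifest.
    """
    if cohort not in ("overall", "pregnancy"):
        raise ValueError("cohort must be 'overall' or 'pregnancy'")
    dedup = store if store.deduplicated else deduplicate(store)

    flow = None
    analysis_store = dedup
    if cohort == "pregnancy":
        ts = config.term_sets
        if not ts or "pregnancy-inclusion" not in ts:
            raise ValueError("pregnancy analysis requires pregnancy term sets")
        cohort_ids, flow = assemble_pregnancy_cohort(
            dedup,
            inclusion_terms=ts["pregnancy-inclusion"],
            indication_terms=ts.get(
                "indication-inclusion", SmqTermSet(role="indication-inclusion")
            ),
            paternal_terms=ts.get("paternal-exposure", SmqTermSet(role="paternal-exposure")),
            fetal_terms=ts.get("fetal-neonatal"),
            min_age=config.min_age,
            max_age=config.max_age,
        )
        analysis_store = dedup.restrict(cohort_ids)

    drug_store = select_drug_reports(analysis_store, config.drug_synonyms, config.roles)
    drug_ids = drug_store.report_ids
    pairs = build_drug_event_pairs(analysis_store, drug_ids)

    sig = signal_table(pairs, priors=config.priors, min_a=config.min_a, soc_map=config.soc_map)
    if cohort == "overall":
        sig_view = sig[sig["strength"].isin(["medium", "strong"]) & sig["is_signal"]]
    else:
        sig_view = sig[sig["is_signal"]]
    sig_view = sig_view.reset_index(drop=True)

    demographics = demographics_summary(drug_store)
    socs = soc_summary(sig, pairs, config.soc_map)

    records = tto_records(analysis_store, drug_ids, config.drug_synonyms)
    tto_summary = summarize_tto(records)
    curve = (
        cumulative_curve(records)
        if tto_summary.n_valid
        else pd.DataFrame(columns=["day", "cumulative_proportion"])
    )

    manifest = {
        "tool": f"pvsignals {__version__}",
        "cohort": cohort,
        "n_reports_store": int(analysis_store.n_reports),
        "n_reports_drug": int(len(drug_ids)),
        "n_pairs": int(len(pairs)),
        "n_pairs_drug": int(pairs["exposed"].sum()),
        "signal_criteria": "a>=3 & ROR95lo>1 & PRR>=2 & chi2>=4 & IC025>0 & EBGM05>2",
        "multiple_testing_adjustment": "none (disproportionality alerts are hypothesis-generating)",
        "roles": list(config.roles),
        "drug_synonyms": list(config.drug_synonyms),
        "seed": config.seed,
        "provenance": list(store.provenance),
        "config_hash": hashlib.sha256(
            repr((list(config.drug_synonyms), list(config.roles), config.priors, config.min_a)).encode()
        ).hexdigest()[:16],
    }
    if flow is not None:
        manifest["cohort_flow"] = flow.as_dict()

    bundle = {
        "signal_table": sig,
        "signal_table_view": sig_view,
        "demographics": demographics,
        "soc_summary": socs,
        "tto_summary": tto_summary,
        "tto_curve": curve,
        "cohort_flow": flow,
        "pairs": pairs,
        "manifest": manifest,
    }
    if out_dir is not None:
        _write_bundle(bundle, out_dir, cohort)
    return bundle


def _write_bundle(bundle: dict, out_dir: str | Path, cohort: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = f"{cohort}_"
    bundle["signal_table"].to_csv(out / f"{p}signal_table_full.csv", index=False)
    bundle["signal_table_view"].to_csv(out / f"{p}signal_table.csv", index=False)
    bundle["demographics"].to_csv(out / f"{p}demographics.csv", index=False)
    bundle["soc_summary"].to_csv(out / f"{p}soc_summary.csv", index=False)
    bundle["tto_summary"].as_frame().to_csv(out / f"{p}tto_summary.csv", index=False)
    bundle["tto_curve"].to_csv(out / f"{p}tto_curve.csv", index=False)
    if bundle["cohort_flow"] is not None:
        pd.Series(bundle["cohort_flow"].as_dict()).rename("count").to_csv(
            out / f"{p}cohort_flow.csv"
        )
    with open(out / f"{p}manifest.yaml", "w") as fh:
        yaml.safe_dump(bundle["manifest"], fh, sort_keys=False)


def verify_printed_rows(rows: pd.DataFrame, tolerance: float = 0.005) -> pd.DataFrame:
    """Re-verify published signal-table rows without the source database.

    Each row must supply pt, a, the published ROR and the cohort margins
    (n_drug, n_total).  The comparator cell c is back-derived from the
    published ROR, the 2x2 table reconstructed, and every other statistic
    recomputed; the report lists deviations against whichever published
    columns are present (prr, chi2, ic, ic025, ebgm).  Deviations are
    relative, except that for published values of magnitude <= 1 the
    comparison is absolute (the denominator is floored at 1): such values
    are dominated by their own two-decimal printing precision, where a
    relative criterion would be vacuous.  A row passes when all available
    deviations are within ``tolerance`` (default 0.5%, the slack implied
    by two-decimal rounding of the ROR).  Malformed rows are reported with
    an error, not fatal.
    """
    out_rows = []
    check_cols = ("ror", "ror_lo", "prr", "chi2", "ic", "ic025", "ebgm")
    for _, row in rows.iterrows():
        rec: dict = {"pt": row.get("pt", "?")}
        try:
            a = int(row["a"])
            n_drug = int(row["n_drug"])
            n_total = int(row["n_total"])
            ror = float(row["ror"])
            c = solve_comparator_count(a, ror, n_drug, n_total)
            t = ContingencyTable(a, n_drug - a, c, n_total - n_drug - c)
            s = compute_statistics(t)
            rec.update({"a": a, "c_derived": c})
            deviations = []
            for col in check_cols:
                if col in row and pd.notna(row[col]):
                    ref = float(row[col])
                    got = getattr(s, col)
                    dev = abs(got - ref) / max(abs(ref), 1.0)
                    rec[f"{col}_recomputed"] = got
                    rec[f"{col}_dev"] = dev
                    deviations.append(dev)
            rec["max_dev"] = max(deviations) if deviations else np.nan
            rec["pass"] = bool(deviations) and rec["max_dev"] <= tolerance
            rec["error"] = ""
        except Exception as exc:  # malformed row: reported, not fatal
            rec["pass"] = False
            rec["error"] = str(exc)
        out_rows.append(rec)
    return pd.DataFrame(out_rows)
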