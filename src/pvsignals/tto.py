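"""Time-to-onset (TTO) analysis: days from therapy start to event onset.

TTO for a report is the event date minus the earliest *complete* therapy
start date among the target drug's records on that report.  Negative
intervals (event before therapy) are excluded as outliers; partial or
missing dates make the record missing.  Summaries follow the conventional
spontaneous-report presentation: median (Q1, Q3), min/max, fixed calendar
bins, and the empirical cumulative-incidence curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .store import ReportStore, parse_faers_date

#: Calendar bins: (label, lower, upper) closed on both ends; last open above.
TTO_BINS: Sequence[tuple[str, int, float]] = (
    ("0-30d", 0, 30),
    ("31-60d", 31, 60),
    ("61-90d", 61, 90),
    ("91-120d", 91, 120),
    ("121-150d", 121, 150),
    ("151-180d", 151, 180),
    ("181-360d", 181, 360),
    (">360d", 361, np.inf),
)


@dataclass(frozen=True)
class TtoRecord:
    report_id: object
    tto_days: int | None
    status: str  # "valid" | "missing" | "negative-excluded"

    def __post_init__(self):
        if self.status == "valid" and (self.tto_days is None or self.tto_days < 0):
            raise ValueError("valid TTO records need tto_days >= 0")


@dataclass
class TtoSummary:
    n_valid: int
    n_missing_or_outlier: int
    mean: float | None = None
    sd: float | None = None
    median: float | None = None
    q1: float | None = None
    q3: float | None = None
    min: float | None = None
    max: float | None = None
    bin_counts: dict = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        rows = [("N", self.n_valid), ("Missing or outlier", self.n_missing_or_outlier)]
        for label, _, _ in TTO_BINS:
            rows.append((label, self.bin_counts.get(label, 0)))
        for name in ("mean", "sd", "median", "q1", "q3", "min", "max"):
            rows.append((name, getattr(self, name)))
        return pd.DataFrame(rows, columns=["statistic", "value"])


def compute_tto(therapy_start, event_date) -> tuple[int | None, str]:
    """(tto_days, status) between one start date and one event date.

    Both arguments are raw FAERS date strings; partial dates count as
    missing.  Day 0 (same-day onset) is valid.
    """
    start = parse_faers_date(therapy_start)
    event = parse_faers_date(event_date)
    if start is None or event is None:
        return None, "missing"
    days = (event - start).days
    if days < 0:
        return None, "negative-excluded"
    return days, "valid"


def tto_records(
    store: ReportStore,
    drug_report_ids: Iterable,
    name_patterns: Sequence[str] | None = None,
) -> list[TtoRecord]:
    """One TtoRecord per target-drug report in the store.

    The therapy start used is the earliest complete start date among the
    report's drug records (restricted to names matching ``name_patterns``
    when given).  Reports with no usable start or event date are missing.
    """
    ids = set(drug_report_ids)
    drugs = store.drugs[store.drugs["primaryid"].isin(ids)]
    if name_patterns:
        from .store import normalize_name

        pats = [normalize_name(p) for p in name_patterns]
        mask = pd.Series(False, index=drugs.index)
        for p in pats:
            mask |= drugs["drug_name"].str.contains(p, regex=False)
        drugs = drugs[mask]
    starts: dict = {}
    for rid, raw in zip(drugs["primaryid"], drugs["therapy_start_date"]):
        d = parse_faers_date(raw)
        if d is not None and (rid not in starts or d < starts[rid]):
            starts[rid] = d
    events = dict(zip(store.demo["primaryid"], store.demo["event_date"]))
    records = []
    for rid in sorted(ids, key=str):
        start = starts.get(rid)
        event = parse_faers_date(events.get(rid))
        if start is None or event is None:
            records.append(TtoRecord(rid, None, "missing"))
            continue
        days = (event - start).days
        if days < 0:
            records.append(TtoRecord(rid, None, "negative-excluded"))
        else:
            records.append(TtoRecord(rid, int(days), "valid"))
    return records


def summarize_tto(records: Iterable[TtoRecord]) -> TtoSummary:
    """Summary statistics and bin counts over the valid records.

    Quartiles use inclusive linear interpolation on the sorted sample.
    """
    records = list(records)
    valid = np.array([r.tto_days for r in records if r.status == "valid"], dtype=float)
    n_bad = sum(1 for r in records if r.status != "valid")
    if valid.size == 0:
        return TtoSummary(n_valid=0, n_missing_or_outlier=n_bad)
    q1, med, q3 = np.percentile(valid, [25, 50, 75])
    bins = {
        label: int(np.sum((valid >= lo) & (valid <= hi))) for label, lo, hi in TTO_BINS
    }
    return TtoSummary(
        n_valid=int(valid.size),
        n_missing_or_outlier=n_bad,
        mean=float(np.mean(valid)),
        sd=float(np.std(valid, ddof=1)) if valid.size > 1 else 0.0,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=float(valid.min()),
        max=float(valid.max()),
        bin_counts=bins,
    )


def cumulative_curve(records: Iterable[TtoRecord]) -> pd.DataFrame:
    """Empirical cumulative incidence: (day, cumulative_proportion) steps.

    Non-decreasing from the first step to exactly 1.0 at the last event day.
    """
    valid = sorted(r.tto_days for r in records if r.status == "valid")
    if not valid:
        raise ValueError("no valid TTO records for a cumulative curve")
    days, counts = np.unique(valid, return_counts=True)
    prop = np.cumsum(counts) / len(valid)
    return pd.DataFrame({"day": days.astype(int), "cumulative_proportion": prop})
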