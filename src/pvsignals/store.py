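"""Reading, deduplicating and indexing FAERS-style quarterly report files.

FAERS quarters arrive as eight ``$``-delimited ASCII tables (DEMO, DRUG,
REAC, INDI, THER, OUTC, RPSR, DELETED), one header row each.  This module
parses them into a :class:`ReportStore` of pandas DataFrames, collapses
multiple report versions of the same case to a single authoritative report,
selects the reports naming a drug of interest, and builds the drug–event
pair table that every disproportionality denominator is derived from.

Counting unit
-------------
The unit of counting is the drug–event *pair*: one (report, preferred term)
occurrence, with duplicate identical pairs within a report collapsed.
Database-wide totals (``N``) and drug margins (``n_drug``) are pair counts,
matching how spontaneous-report "AE" totals are conventionally quoted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: FAERS drug role codes -> canonical role names.
ROLE_CODES = {
    "PS": "primary-suspect",
    "SS": "secondary-suspect",
    "C": "concomitant",
    "I": "interacting",
}
ALL_ROLES = frozenset(ROLE_CODES.values())

#: The seven FAERS outcome codes (death, life-threatening, hospitalisation,
#: disability, congenital anomaly, required intervention, other).
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

SEX_MAP = {"F": "female", "M": "male"}
REPORTER_MAP = {
    "CN": "consumer",
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other-health-professional",
    "HP": "other-health-professional",
    "LW": "unspecified",
}

#: Default synonym list for the drug of interest (insulin glargine:
#: generic name plus marketed brand names).  Matching is case-insensitive
#: substring over normalised names; the list is configurable everywhere.
DEFAULT_DRUG_SYNONYMS = (
    "INSULIN GLARGINE",
    "LANTUS",
    "BASAGLAR",
    "TOUJEO",
    "SEMGLEE",
    "ABASAGLAR",
    "REZVOGLAR",
)

# Accepted header aliases per logical column (FAERS quarterly names first).
_DEMO_ALIASES: Mapping[str, Sequence[str]] = {
    "primaryid": ("primaryid", "primary_id", "isr"),
    "caseid": ("caseid", "case_id", "case"),
    "report_date": ("fda_dt", "report_date", "init_fda_dt"),
    "event_date": ("event_dt", "event_date"),
    "sex": ("sex", "gndr_cod"),
    "age": ("age",),
    "age_cod": ("age_cod",),
    "reporter": ("occp_cod", "reporter"),
    "country": ("occr_country", "reporter_country", "country"),
}
_DRUG_ALIASES: Mapping[str, Sequence[str]] = {
    "primaryid": ("primaryid", "primary_id", "isr"),
    "drug_seq": ("drug_seq", "dsg_drug_seq"),
    "role": ("role_cod", "role"),
    "drug_name": ("drugname", "drug_name", "prod_ai"),
}
_REAC_ALIASES: Mapping[str, Sequence[str]] = {
    "primaryid": ("primaryid", "primary_id", "isr"),
    "pt_name": ("pt", "pt_name"),
    "pt_code": ("pt_code", "pt_cod"),
}
_INDI_ALIASES: Mapping[str, Sequence[str]] = {
    "primaryid": ("primaryid", "primary_id", "isr"),
    "drug_seq": ("indi_drug_seq", "drug_seq"),
    "indication_pt": ("indi_pt", "indication_pt"),
}
_THER_ALIASES: Mapping[str, Sequence[str]] = {
    "primaryid": ("primaryid", "primary_id", "isr"),
    "drug_seq": ("dsg_drug_seq", "drug_seq"),
    "therapy_start_date": ("start_dt", "therapy_start_date"),
    "therapy_end_date": ("end_dt", "therapy_end_date"),
}
_OUTC_ALIASES: Mapping[str, Sequence[str]] = {
    "primaryid": ("primaryid", "primary_id", "isr"),
    "outcome": ("outc_cod", "outc_code", "outcome"),
}
_RPSR_ALIASES: Mapping[str, Sequence[str]] = {
    "primaryid": ("primaryid", "primary_id", "isr"),
    "source": ("rpsr_cod", "source"),
}
_DELETED_ALIASES: Mapping[str, Sequence[str]] = {
    "caseid": ("caseid", "case_id", "primaryid"),
}

_AGE_TO_YEARS = {
    "YR": 1.0,
    "": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}


class FaersParseError(ValueError):
    """A quarterly table is structurally unusable (e.g. no primary id column)."""


def normalize_name(name: object) -> str:
    """Upper-case, trim and collapse internal whitespace of a free-text name."""
    if name is None or (isinstance(name, float) and np.isnan(name)):
        return ""
    return " ".join(str(name).upper().split())


def parse_faers_date(raw: object) -> pd.Timestamp | None:
    """Parse a full-precision FAERS date (YYYYMMDD); partial dates -> None.

    FAERS dates may be truncated to YYYYMM or YYYY when the reporter did not
    supply the full date.  Computations that need day precision treat those
    as missing; the raw string is preserved on the store for ordering.
    """
    s = str(raw).strip() if raw is not None else ""
    if len(s) != 8 or not s.isdigit():
        return None
    try:
        return pd.Timestamp(year=int(s[:4]), month=int(s[4:6]), day=int(s[6:8]))
    except ValueError:
        return None


def _date_sort_key(raw: object) -> str:
    """Zero-pad a (possibly partial) YYYYMMDD date string for ordering."""
    s = str(raw).strip() if raw is not None else ""
    digits = "".join(ch for ch in s if ch.isdigit())
    return digits.ljust(8, "0")


@dataclass
class ReportStore:
    """Normalised container for one or more parsed FAERS quarters.

    Attributes
    ----------
    demo : DataFrame
        One row per report: primaryid, caseid, report_date, event_date
        (raw strings, possibly partial), sex, age_years, reporter, country.
    drugs : DataFrame
        primaryid, drug_seq, role, drug_name, therapy_start_date,
        therapy_end_date (therapy dates merged in from THER).
    reactions : DataFrame
        primaryid, pt_code (nullable integer), pt_name (normalised).
    indications : DataFrame
        primaryid, drug_seq, indication_pt (normalised).
    outcomes : DataFrame
        primaryid, outcome (one of the seven codes).
    deleted_cases : set of caseids listed in DELETED files.
    provenance : source file names, for the audit trail.
    deduplicated : True once :func:`deduplicate` has run.
    """

    demo: pd.DataFrame
    drugs: pd.DataFrame
    reactions: pd.DataFrame
    indications: pd.DataFrame
    outcomes: pd.DataFrame
    deleted_cases: set = field(default_factory=set)
    provenance: list = field(default_factory=list)
    deduplicated: bool = False

    @property
    def report_ids(self) -> set:
        return set(self.demo["primaryid"])

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    def counts(self) -> dict:
        return {
            "demo": len(self.demo),
            "drug": len(self.drugs),
            "reac": len(self.reactions),
            "indi": len(self.indications),
            "outc": len(self.outcomes),
            "deleted_cases": len(self.deleted_cases),
        }

    def restrict(self, report_ids: Iterable) -> "ReportStore":
        """Return the sub-store containing only the given reports."""
        ids = set(report_ids)
        return ReportStore(
            demo=self.demo[self.demo["primaryid"].isin(ids)].reset_index(drop=True),
            drugs=self.drugs[self.drugs["primaryid"].isin(ids)].reset_index(drop=True),
            reactions=self.reactions[self.reactions["primaryid"].isin(ids)].reset_index(drop=True),
            indications=self.indications[self.indications["primaryid"].isin(ids)].reset_index(drop=True),
            outcomes=self.outcomes[self.outcomes["primaryid"].isin(ids)].reset_index(drop=True),
            deleted_cases=set(self.deleted_cases),
            provenance=list(self.provenance),
            deduplicated=self.deduplicated,
        )

    def write_snapshot(self, out_dir: str | Path) -> None:
        """Write normalised per-table CSV snapshots (UTF-8) for audit."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.demo.to_csv(out / "demo.csv", index=False)
        self.drugs.to_csv(out / "drugs.csv", index=False)
        self.reactions.to_csv(out / "reactions.csv", index=False)
        self.indications.to_csv(out / "indications.csv", index=False)
        self.outcomes.to_csv(out / "outcomes.csv", index=False)
        pd.DataFrame({"caseid": sorted(self.deleted_cases, key=str)}).to_csv(
            out / "deleted_cases.csv", index=False
        )


def _read_dollar_table(
    path: str | Path, aliases: Mapping[str, Sequence[str]], required: Sequence[str]
) -> pd.DataFrame:
    """Read one $-delimited FAERS table, renaming headers to logical names.

    Unknown columns are dropped; unreadable rows (wrong field count) are
    skipped with a logged count.  A missing required column is a hard error
    naming the file and column.
    """
    path = Path(path)
    # FAERS is latin-1-ish and never quotes; '$' inside fields is unsupported.
    with open(path, encoding="latin-1", errors="replace") as fh:
        header = fh.readline().rstrip("\r\n")
        cols = [c.strip().lower() for c in header.split("$")]
        ncol = len(cols)
        rows: list[list[str]] = []
        skipped = 0
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("$")
            if len(parts) != ncol:
                skipped += 1
                continue
            rows.append(parts)
    if skipped:
        logger.warning("%s: skipped %d malformed rows", path.name, skipped)
    df = pd.DataFrame(rows, columns=cols, dtype=str)
    rename = {}
    for logical, options in aliases.items():
        for opt in options:
            if opt in df.columns and logical not in rename.values():
                rename[opt] = logical
                break
    df = df.rename(columns=rename)
    for col in required:
        if col not in df.columns:
            raise FaersParseError(
                f"{path.name}: required column {col!r} not found "
                f"(headers: {cols})"
            )
    keep = [c for c in aliases if c in df.columns]
    df = df[keep]
    logger.info("%s: %d rows", path.name, len(df))
    return df


def _empty(columns: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


def _convert_age(df: pd.DataFrame) -> pd.Series:
    age = pd.to_numeric(df.get("age", pd.Series(index=df.index, dtype=object)), errors="coerce")
    if "age_cod" in df.columns:
        factor = (
            df["age_cod"].fillna("").str.strip().str.upper().map(_AGE_TO_YEARS)
        ).astype(float)
        factor = factor.fillna(1.0)
        age = age * factor
    age[age < 0] = np.nan
    return age


def parse_quarter(
    file_paths: Mapping[str, str | Path],
    *,
    strict: bool = True,
) -> ReportStore:
    """Parse one FAERS quarter given a mapping of table name -> file path.

    Parameters
    ----------
    file_paths
        Keys among {"demo", "drug", "reac", "indi", "ther", "outc", "rpsr",
        "deleted"} (case-insensitive).  "demo", "drug" and "reac" are the
        analytically load-bearing tables; any other may be absent.
    strict
        If True, a missing DEMO table raises.

    Returns the raw (not yet deduplicated) :class:`ReportStore`.
    """
    paths = {k.lower(): Path(v) for k, v in file_paths.items()}
    provenance = [str(p) for p in paths.values()]

    if "demo" in paths:
        demo = _read_dollar_table(paths["demo"], _DEMO_ALIASES, ["primaryid", "caseid"])
    elif strict:
        raise FaersParseError("no DEMO table supplied")
    else:
        demo = _empty(list(_DEMO_ALIASES))
    for col in _DEMO_ALIASES:
        if col not in demo.columns:
            demo[col] = ""
    demo["age_years"] = _convert_age(demo)
    demo["sex"] = demo["sex"].fillna("").str.strip().str.upper().map(SEX_MAP).fillna("unspecified")
    demo["reporter"] = (
        demo["reporter"].fillna("").str.strip().str.upper().map(REPORTER_MAP).fillna("unspecified")
    )
    demo["country"] = demo["country"].fillna("").str.strip().str.upper()
    demo = demo[
        ["primaryid", "caseid", "report_date", "event_date", "sex", "age_years", "reporter", "country"]
    ]

    if "drug" in paths:
        drugs = _read_dollar_table(paths["drug"], _DRUG_ALIASES, ["primaryid"])
    else:
        drugs = _empty(list(_DRUG_ALIASES))
    for col in _DRUG_ALIASES:
        if col not in drugs.columns:
            drugs[col] = ""
    drugs["role"] = (
        drugs["role"].fillna("").str.strip().str.upper().map(ROLE_CODES).fillna("unspecified")
    )
    drugs["drug_name"] = drugs["drug_name"].map(normalize_name)

    if "ther" in paths:
        ther = _read_dollar_table(paths["ther"], _THER_ALIASES, ["primaryid"])
        drugs = drugs.merge(ther, on=["primaryid", "drug_seq"], how="left")
    for col in ("therapy_start_date", "therapy_end_date"):
        if col not in drugs.columns:
            drugs[col] = ""
        drugs[col] = drugs[col].fillna("")
    drugs = drugs[["primaryid", "drug_seq", "role", "drug_name", "therapy_start_date", "therapy_end_date"]]

    if "reac" in paths:
        reac = _read_dollar_table(paths["reac"], _REAC_ALIASES, ["primaryid", "pt_name"])
    else:
        reac = _empty(list(_REAC_ALIASES))
    if "pt_code" not in reac.columns:
        reac["pt_code"] = ""
    reac["pt_code"] = pd.to_numeric(reac["pt_code"], errors="coerce").astype("Int64")
    reac["pt_name"] = reac["pt_name"].map(normalize_name)
    reac = reac[reac["pt_name"] != ""].reset_index(drop=True)
    reac = reac[["primaryid", "pt_code", "pt_name"]]

    if "indi" in paths:
        indi = _read_dollar_table(paths["indi"], _INDI_ALIASES, ["primaryid"])
    else:
        indi = _empty(list(_INDI_ALIASES))
    for col in _INDI_ALIASES:
        if col not in indi.columns:
            indi[col] = ""
    indi["indication_pt"] = indi["indication_pt"].map(normalize_name)
    indi = indi[["primaryid", "drug_seq", "indication_pt"]]

    if "outc" in paths:
        outc = _read_dollar_table(paths["outc"], _OUTC_ALIASES, ["primaryid"])
    else:
        outc = _empty(list(_OUTC_ALIASES))
    if "outcome" not in outc.columns:
        outc["outcome"] = ""
    outc["outcome"] = outc["outcome"].fillna("").str.strip().str.upper()
    outc = outc[outc["outcome"].isin(OUTCOME_CODES)].reset_index(drop=True)
    outc = outc[["primaryid", "outcome"]]

    deleted: set = set()
    if "deleted" in paths:
        deld = _read_dollar_table(paths["deleted"], _DELETED_ALIASES, ["caseid"])
        deleted = set(deld["caseid"].astype(str).str.strip())

    return ReportStore(
        demo=demo,
        drugs=drugs,
        reactions=reac,
        indications=indi,
        outcomes=outc,
        deleted_cases=deleted,
        provenance=provenance,
    )


def discover_quarter_files(directory: str | Path) -> Mapping[str, Path]:
    """Map table names to files in a directory using FAERS naming (DEMOyyQq.txt)."""
    directory = Path(directory)
    found: dict[str, Path] = {}
    for prefix in ("demo", "drug", "reac", "indi", "ther", "outc", "rpsr", "deleted"):
        matches = sorted(directory.glob(f"{prefix.upper()}*.txt")) + sorted(
            directory.glob(f"{prefix}*.txt")
        )
        if matches:
            found[prefix] = matches[0]
    return found


def deduplicate(store: ReportStore) -> ReportStore:
    """Collapse report versions: one report per case, drop deleted cases.

    For each caseid the retained report is the one with the latest report
    date (partial dates compared zero-padded), ties broken by the largest
    primaryid.  Reports of cases listed in DELETED are removed entirely.
    Idempotent.
    """
    demo = store.demo
    if len(demo) == 0:
        return replace(store, deduplicated=True)
    demo = demo[~demo["caseid"].astype(str).str.strip().isin(store.deleted_cases)]
    key = demo["report_date"].map(_date_sort_key)
    # numeric primaryid tie-break where possible, falling back to string
    pid_num = pd.to_numeric(demo["primaryid"], errors="coerce")
    order = pd.DataFrame(
        {"k_date": key, "k_pid": pid_num.fillna(-1), "k_pid_s": demo["primaryid"].astype(str)}
    )
    idx = (
        demo.assign(**order)
        .sort_values(["k_date", "k_pid", "k_pid_s"], kind="mergesort")
        .groupby("caseid", sort=False)
        .tail(1)
        .index
    )
    demo = demo.loc[idx].reset_index(drop=True)
    keep_ids = set(demo["primaryid"])
    out = store.restrict(keep_ids)
    out.demo = demo
    out.deduplicated = True
    return out


def select_drug_reports(
    store: ReportStore,
    name_patterns: Sequence[str] = DEFAULT_DRUG_SYNONYMS,
    roles: Iterable[str] = ("primary-suspect",),
) -> ReportStore:
    """Keep reports with >=1 drug record matching a pattern in an allowed role.

    Matching is case-insensitive substring over the normalised drug name.
    """
    if not name_patterns:
        raise ValueError("name_patterns must not be empty")
    roles = set(roles)
    patterns = [normalize_name(p) for p in name_patterns]
    d = store.drugs
    mask = d["role"].isin(roles)
    name_hit = pd.Series(False, index=d.index)
    for pat in patterns:
        if pat == "*" or pat == "":
            name_hit |= True
        else:
            name_hit |= d["drug_name"].str.contains(pat, regex=False)
    hit_ids = set(d.loc[mask & name_hit, "primaryid"])
    return store.restrict(hit_ids)


def build_drug_event_pairs(store: ReportStore, drug_report_ids: Iterable) -> pd.DataFrame:
    """Build the drug–event pair table: unique (report, PT) with exposure flag.

    Returns a DataFrame with columns primaryid, pt_name, exposed (bool).
    ``N = len(table)``; ``n_drug = table.exposed.sum()``.
    """
    ids = set(drug_report_ids)
    pairs = (
        store.reactions[["primaryid", "pt_name"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    pairs["exposed"] = pairs["primaryid"].isin(ids)
    return pairs
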