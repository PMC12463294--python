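"""Synthetic FAERS-style quarter generator with exact ground truth.

Real spontaneous-report databases cannot be bundled, so every pipeline
stage is exercised against generated quarters whose structure mirrors the
real files: multi-version duplicate cases, a DELETED list, demographic
fields, a target drug carried by a configurable share of reports, a
long-tailed background catalogue of preferred terms, a set of PTs with
injected elevated relative reporting rates among target-drug reports, a
pregnancy stratum tagged through exposure PTs and indication text (plus
paternal and male decoys that the exclusion rules must remove), and
therapy-start/event dates giving controllable log-normal time-to-onset
distributions per stratum.

Reports are simulated at report level with per-report PT multisets (1–5
terms, truncated geometric) rather than as independent pairs, so pair
collapsing and deduplication are genuinely exercised.  A single
pseudo-random stream keyed by ``seed`` drives everything; the same seed
yields byte-identical files.

Injected signals multiply a PT's weight inside the target-drug multinomial
(renormalised), so the realised observed/expected ratio approaches the
configured multiplier only when the target-drug share of the database is
small; :class:`GroundTruth` carries the exact emitted pair counts, which
are the oracle the pipeline is checked against.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .disprop import ContingencyTable
from .store import DEFAULT_DRUG_SYNONYMS, ReportStore, parse_quarter

#: Maternal/fetal pregnancy-exposure preferred terms (public MedDRA codes).
MATERNAL_EXPOSURE_PTS = {
    10071407: "MATERNAL EXPOSURE DURING DELIVERY",
    10071409: "FOETAL EXPOSURE DURING DELIVERY",
    10071406: "MATERNAL EXPOSURE BEFORE PREGNANCY",
    10071408: "MATERNAL EXPOSURE DURING PREGNANCY",
    10071404: "FOETAL EXPOSURE DURING PREGNANCY",
    10073513: "EXPOSURE DURING PREGNANCY",
    10071415: "MATERNAL EXPOSURE TIMING UNSPECIFIED",
    10071405: "FOETAL EXPOSURE TIMING UNSPECIFIED",
    10026923: "MATERNAL DRUGS AFFECTING FOETUS",
    10064998: "DRUG EXPOSURE BEFORE PREGNANCY",
}

#: Paternal-exposure preferred terms (public MedDRA codes).
PATERNAL_EXPOSURE_PTS = {
    10050425: "PATERNAL DRUGS AFFECTING FOETUS",
    10071403: "EXPOSURE VIA FATHER",
    10080091: "PATERNAL EXPOSURE DURING PREGNANCY",
    10080092: "PATERNAL EXPOSURE TIMING UNSPECIFIED",
    10080093: "PATERNAL EXPOSURE BEFORE PREGNANCY",
    10084938: "MATERNAL EXPOSURE VIA PARTNER DURING PREGNANCY",
}

#: Starter pregnancy indication terms (non-exhaustive).
PREGNANCY_INDICATIONS = (
    "GESTATIONAL DIABETES",
    "PREGNANCY",
    "DIABETES MELLITUS IN PREGNANCY",
    "MATERNAL EXPOSURE DURING PREGNANCY",
)

_COUNTRIES = ("US", "GB", "DE", "FR", "JP", "BR", "CA", "IN")
_REPORTERS = ("CN", "MD", "PH", "OT", "")
_REPORTER_P = (0.6, 0.2, 0.05, 0.1, 0.05)
_OUTCOMES = ("OT", "HO", "LT", "DE", "DS", "CA", "RI")
_OUTCOME_P = (0.55, 0.25, 0.05, 0.06, 0.05, 0.02, 0.02)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic quarter; defaults describe the study conditions.

    ``injected_signals`` maps PT name -> relative reporting-rate multiplier
    (applied to that PT's weight among target-drug reports).  TTO medians
    default to the onset profile of a long-acting basal insulin: about two
    months in the overall population and about six months in the pregnancy
    stratum, log-normal with a wide spread.
    """

    n_cases: int = 20_000
    duplicate_rate: float = 0.10
    max_extra_versions: int = 3
    deleted_fraction: float = 0.01
    target_drug_share: float = 0.10
    n_background_pts: int = 250
    background_concentration: float = 1.0  # Zipf exponent of PT weights
    injected_signals: dict = field(default_factory=dict)
    pregnancy_fraction: float = 0.03
    p_reaction_tag: float = 0.8
    p_indication_tag: float = 0.4
    n_paternal_decoys: int = 5
    n_male_decoys: int = 3
    tto_median_days: float = 61.0
    tto_median_days_pregnancy: float = 186.0
    tto_sigma: float = 1.2
    p_event_date: float = 0.6
    p_start_date: float = 0.8
    p_negative_tto: float = 0.02
    date_start: str = "20150101"
    date_end: str = "20241231"
    seed: int = 0

    def validate(self) -> None:
        probs = (
            self.duplicate_rate, self.deleted_fraction, self.target_drug_share,
            self.pregnancy_fraction, self.p_reaction_tag, self.p_indication_tag,
            self.p_event_date, self.p_start_date, self.p_negative_tto,
        )
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all rate/probability parameters must lie in [0, 1]")
        if any(lam < 0 for lam in self.injected_signals.values()):
            raise ValueError("injected relative reporting rates must be >= 0")
        if self.n_background_pts < 1:
            raise ValueError("need at least one background PT")
        needed = self.n_paternal_decoys + self.n_male_decoys + int(
            round(self.n_cases * (self.pregnancy_fraction + self.deleted_fraction))
        )
        if self.n_cases and needed > self.n_cases:
            raise ValueError("strata (pregnancy + decoys + deleted) exceed n_cases")

    @staticmethod
    def from_yaml(path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return GeneratorConfig(**raw)


@dataclass
class GroundTruth:
    """Exact truth implied by the emitted files (not model expectations)."""

    pt_lambda: dict
    report_labels: pd.DataFrame  # primaryid, caseid, stratum, exposed, deleted
    pairs: pd.DataFrame  # surviving reports: primaryid, pt_name, exposed
    pregnancy_ids: set
    paternal_decoy_ids: set
    male_decoy_ids: set
    deleted_case_ids: set
    soc_map: dict
    tto_days: dict  # primaryid -> true TTO in days (valid records only)
    table_row_counts: dict  # raw rows written per table

    @property
    def n_surviving_reports(self) -> int:
        lbl = self.report_labels
        return int((~lbl["deleted"]).sum())


def _background_catalogue(config: GeneratorConfig) -> tuple[list[str], np.ndarray, dict]:
    names = [f"PT_{i:04d}" for i in range(1, config.n_background_pts + 1)]
    ranks = np.arange(1, config.n_background_pts + 1, dtype=float)
    w = ranks ** (-config.background_concentration)
    w /= w.sum()
    socs = {name: f"SOC_{(i % 20) + 1:02d}" for i, name in enumerate(names)}
    return names, w, socs


def _dates(rng: np.random.Generator, n: int, start: str, end: str) -> np.ndarray:
    t0 = pd.Timestamp(start)
    span = (pd.Timestamp(end) - t0).days
    offs = rng.integers(0, span + 1, size=n)
    return np.array([(t0 + pd.Timedelta(days=int(o))).strftime("%Y%m%d") for o in offs])


def build_quarter(config: GeneratorConfig) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Simulate one quarter; returns raw tables (as written) and ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    pt_names, pt_w, soc_map = _background_catalogue(config)
    lam = np.ones(len(pt_names))
    for pt, mult in config.injected_signals.items():
        if pt not in pt_names:
            raise ValueError(f"injected PT {pt!r} is not in the background catalogue")
        lam[pt_names.index(pt)] = mult
    pt_w_target = pt_w * lam
    pt_w_target /= pt_w_target.sum()
    pt_code = {name: 90_000_000 + i for i, name in enumerate(pt_names, start=1)}
    pt_code.update({v: k for k, v in MATERNAL_EXPOSURE_PTS.items()})
    pt_code.update({v: k for k, v in PATERNAL_EXPOSURE_PTS.items()})

    caseids = np.array([f"C{i:08d}" for i in range(1, n + 1)])
    primaryids = np.array([(i + 1) * 100 + 9 for i in range(n)])  # final version

    # --- strata assignment (disjoint; drawn from one permutation) ---
    perm = rng.permutation(n)
    n_preg = int(round(n * config.pregnancy_fraction))
    preg_idx = perm[:n_preg]
    pat_idx = perm[n_preg : n_preg + config.n_paternal_decoys]
    male_idx = perm[
        n_preg + config.n_paternal_decoys : n_preg + config.n_paternal_decoys + config.n_male_decoys
    ]
    n_del = int(round(n * config.deleted_fraction))
    del_idx = perm[len(perm) - n_del :] if n_del else np.array([], dtype=int)

    stratum = np.full(n, "background", dtype=object)
    stratum[preg_idx] = "pregnancy"
    stratum[pat_idx] = "paternal-decoy"
    stratum[male_idx] = "male-decoy"
    deleted = np.zeros(n, dtype=bool)
    deleted[del_idx] = True

    n_target = int(round(n * config.target_drug_share))
    exposed = np.zeros(n, dtype=bool)
    exposed[rng.permutation(n)[:n_target]] = True

    # --- demographics ---
    sex = np.where(
        rng.random(n) < 0.52, "F", np.where(rng.random(n) < 0.81, "M", "")
    ).astype(object)
    sex[preg_idx] = "F"
    sex[pat_idx] = "M"
    sex[male_idx] = "M"
    age = np.round(np.clip(rng.normal(55, 18, size=n), 1, 95), 0)
    age[preg_idx] = np.round(rng.uniform(18, 44, size=len(preg_idx)), 0)
    age_missing = rng.random(n) < 0.3
    age_missing[preg_idx] = rng.random(len(preg_idx)) < 0.1
    reporter = rng.choice(_REPORTERS, size=n, p=_REPORTER_P)
    country = rng.choice(_COUNTRIES, size=n, p=(0.7, 0.06, 0.05, 0.05, 0.05, 0.04, 0.03, 0.02))

    # --- dates and time to onset ---
    report_date = _dates(rng, n, config.date_start, config.date_end)
    start_ts = pd.to_datetime(
        _dates(rng, n, config.date_start, config.date_end), format="%Y%m%d"
    )
    median = np.where(
        stratum == "pregnancy", config.tto_median_days_pregnancy, config.tto_median_days
    ).astype(float)
    tto = np.round(np.exp(rng.normal(np.log(median), config.tto_sigma))).astype(int)
    has_event = rng.random(n) < config.p_event_date
    has_start = rng.random(n) < config.p_start_date
    negative = rng.random(n) < config.p_negative_tto
    signed_tto = np.where(negative, -np.maximum(tto, 1), tto)
    event_ts = start_ts + pd.to_timedelta(signed_tto, unit="D")
    event_date = np.where(has_event, event_ts.strftime("%Y%m%d"), "")
    start_date = np.where(has_start, start_ts.strftime("%Y%m%d"), "")

    # --- reactions: background multiset + stratum tag terms ---
    n_pts_per = 1 + np.minimum(rng.geometric(0.5, size=n) - 1, 4)
    total = int(n_pts_per.sum())
    flat = np.empty(total, dtype=object)
    is_exposed_row = np.repeat(exposed, n_pts_per)
    flat[is_exposed_row] = rng.choice(pt_names, size=int(is_exposed_row.sum()), p=pt_w_target)
    flat[~is_exposed_row] = rng.choice(pt_names, size=int((~is_exposed_row).sum()), p=pt_w)
    row_pid = np.repeat(primaryids, n_pts_per)

    reac_pid = list(row_pid)
    reac_pt = list(flat)
    maternal_names = list(MATERNAL_EXPOSURE_PTS.values())
    paternal_names = list(PATERNAL_EXPOSURE_PTS.values())
    preg_tagged_rx = rng.random(len(preg_idx)) < config.p_reaction_tag
    preg_tagged_ind = rng.random(len(preg_idx)) < config.p_indication_tag
    # every pregnancy report must carry at least one tag
    preg_tagged_rx |= ~preg_tagged_ind
    indi_extra: list[tuple[int, str]] = []
    for j, idx in enumerate(preg_idx):
        if preg_tagged_rx[j]:
            reac_pid.append(primaryids[idx])
            reac_pt.append(maternal_names[int(rng.integers(len(maternal_names)))])
        if preg_tagged_ind[j]:
            indi_extra.append(
                (primaryids[idx], PREGNANCY_INDICATIONS[int(rng.integers(len(PREGNANCY_INDICATIONS)))])
            )
    for idx in pat_idx:
        reac_pid.append(primaryids[idx])
        reac_pt.append(paternal_names[int(rng.integers(len(paternal_names)))])
    # male decoys carry strictly-maternal terms (never fetal/neonatal ones,
    # which would legitimately justify retaining a male infant report)
    strictly_maternal = [
        MATERNAL_EXPOSURE_PTS[c]
        for c in (10071407, 10071406, 10071408, 10073513, 10071415, 10064998)
    ]
    for idx in male_idx:
        reac_pid.append(primaryids[idx])
        reac_pt.append(strictly_maternal[int(rng.integers(len(strictly_maternal)))])

    reac = pd.DataFrame({"primaryid": reac_pid, "pt": reac_pt})
    reac["pt_code"] = reac["pt"].map(pt_code).astype("Int64")

    # --- drugs, therapy, indications ---
    synonyms = list(DEFAULT_DRUG_SYNONYMS)
    drug_rows = {"primaryid": [], "drug_seq": [], "role_cod": [], "drugname": []}
    ther_rows = {"primaryid": [], "dsg_drug_seq": [], "start_dt": [], "end_dt": []}
    indi_rows = {"primaryid": [], "indi_drug_seq": [], "indi_pt": []}
    n_conco = rng.integers(0, 3, size=n)
    conco_choice = rng.integers(0, 40, size=(n, 2))
    syn_choice = rng.integers(0, len(synonyms), size=n)
    for i in range(n):
        pid = primaryids[i]
        seq = 1
        if exposed[i]:
            drug_rows["primaryid"].append(pid)
            drug_rows["drug_seq"].append(seq)
            drug_rows["role_cod"].append("PS")
            drug_rows["drugname"].append(synonyms[syn_choice[i]])
            ther_rows["primaryid"].append(pid)
            ther_rows["dsg_drug_seq"].append(seq)
            ther_rows["start_dt"].append(start_date[i])
            ther_rows["end_dt"].append("")
            indi_rows["primaryid"].append(pid)
            indi_rows["indi_drug_seq"].append(seq)
            indi_rows["indi_pt"].append("DIABETES MELLITUS")
            seq += 1
        else:
            drug_rows["primaryid"].append(pid)
            drug_rows["drug_seq"].append(seq)
            drug_rows["role_cod"].append("PS")
            drug_rows["drugname"].append(f"DRUG_{conco_choice[i, 0]:02d}")
            seq += 1
        for k in range(n_conco[i]):
            drug_rows["primaryid"].append(pid)
            drug_rows["drug_seq"].append(seq)
            drug_rows["role_cod"].append("C")
            drug_rows["drugname"].append(f"DRUG_{conco_choice[i, k % 2]:02d}")
            seq += 1
    for pid, term in indi_extra:
        indi_rows["primaryid"].append(pid)
        indi_rows["indi_drug_seq"].append(1)
        indi_rows["indi_pt"].append(term)

    drug = pd.DataFrame(drug_rows)
    ther = pd.DataFrame(ther_rows)
    indi = pd.DataFrame(indi_rows)

    # --- outcomes ---
    n_outc = rng.integers(0, 2, size=n)
    outc_pid = np.repeat(primaryids, n_outc)
    outc_cod = rng.choice(_OUTCOMES, size=len(outc_pid), p=_OUTCOME_P)
    outc = pd.DataFrame({"primaryid": outc_pid, "outc_cod": outc_cod})

    demo = pd.DataFrame(
        {
            "primaryid": primaryids,
            "caseid": caseids,
            "fda_dt": report_date,
            "event_dt": event_date,
            "sex": sex,
            "age": np.where(age_missing, "", age.astype(int).astype(str)),
            "age_cod": np.where(age_missing, "", "YR"),
            "occp_cod": reporter,
            "occr_country": country,
        }
    )

    # --- duplicate versions: earlier primaryid, earlier-or-equal date ---
    n_dup = int(round(n * config.duplicate_rate))
    dup_idx = rng.permutation(n)[:n_dup]
    dup_frames_demo, dup_frames = [demo], {
        "drug": [drug], "ther": [ther], "reac": [reac], "indi": [indi], "outc": [outc]
    }
    extra_versions = rng.integers(1, config.max_extra_versions + 1, size=n_dup)
    for j, idx in enumerate(dup_idx):
        pid = primaryids[idx]
        for v in range(int(extra_versions[j])):
            old_pid = (idx + 1) * 100 + v  # < final pid (…09) for the same case
            old_date = (
                pd.Timestamp(str(report_date[idx]))
                - pd.Timedelta(days=int(rng.integers(0, 400)))
            ).strftime("%Y%m%d")
            drow = demo.iloc[[idx]].copy()
            drow["primaryid"] = old_pid
            drow["fda_dt"] = old_date
            dup_frames_demo.append(drow)
            for name, src in (("drug", drug), ("ther", ther), ("reac", reac), ("indi", indi), ("outc", outc)):
                sub = src[src["primaryid"] == pid].copy()
                if len(sub):
                    sub["primaryid"] = old_pid
                    dup_frames[name].append(sub)
    demo_all = pd.concat(dup_frames_demo, ignore_index=True)
    drug_all = pd.concat(dup_frames["drug"], ignore_index=True)
    ther_all = pd.concat(dup_frames["ther"], ignore_index=True)
    reac_all = pd.concat(dup_frames["reac"], ignore_index=True)
    indi_all = pd.concat(dup_frames["indi"], ignore_index=True)
    outc_all = pd.concat(dup_frames["outc"], ignore_index=True)
    deleted_df = pd.DataFrame({"caseid": caseids[del_idx]})

    tables = {
        "demo": demo_all,
        "drug": drug_all,
        "reac": reac_all,
        "indi": indi_all,
        "ther": ther_all,
        "outc": outc_all,
        "deleted": deleted_df,
    }

    # --- ground truth from the authoritative (final, non-deleted) versions ---
    surviving = ~deleted
    surv_pids = set(primaryids[surviving])
    pairs = reac[reac["primaryid"].isin(surv_pids)][["primaryid", "pt"]].drop_duplicates()
    pairs = pairs.rename(columns={"pt": "pt_name"}).reset_index(drop=True)
    exposed_map = dict(zip(primaryids, exposed))
    pairs["exposed"] = pairs["primaryid"].map(exposed_map).astype(bool)

    tto_days = {
        int(primaryids[i]): int(tto[i])
        for i in range(n)
        if surviving[i] and exposed[i] and has_event[i] and has_start[i] and not negative[i]
    }
    labels = pd.DataFrame(
        {
            "primaryid": primaryids,
            "caseid": caseids,
            "stratum": stratum,
            "exposed": exposed,
            "deleted": deleted,
        }
    )
    pt_lambda = {name: float(l) for name, l in zip(pt_names, lam)}
    truth = GroundTruth(
        pt_lambda=pt_lambda,
        report_labels=labels,
        pairs=pairs,
        pregnancy_ids=set(primaryids[preg_idx]) - set(primaryids[del_idx]),
        paternal_decoy_ids=set(primaryids[pat_idx]),
        male_decoy_ids=set(primaryids[male_idx]),
        deleted_case_ids=set(caseids[del_idx]),
        soc_map=soc_map,
        tto_days=tto_days,
        table_row_counts={k: len(v) for k, v in tables.items()},
    )
    return tables, truth


_FILE_STEMS = {
    "demo": "DEMO25Q1.txt",
    "drug": "DRUG25Q1.txt",
    "reac": "REAC25Q1.txt",
    "indi": "INDI25Q1.txt",
    "ther": "THER25Q1.txt",
    "outc": "OUTC25Q1.txt",
    "deleted": "DELETED25Q1.txt",
}


def write_quarter(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Serialise raw tables as $-delimited FAERS-style files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = out / _FILE_STEMS[name]
        with open(path, "w", encoding="latin-1", newline="\n") as fh:
            fh.write("$".join(df.columns) + "\n")
            for row in df.itertuples(index=False):
                fh.write("$".join("" if pd.isna(v) else str(v) for v in row) + "\n")
        paths[name] = path
    return paths


def generate_quarter(
    config: GeneratorConfig, out_dir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Simulate a quarter and write it as FAERS-format files.

    The config is validated (and the simulation completed) before any file
    is written; the same seed produces byte-identical output.
    """
    tables, truth = build_quarter(config)
    return write_quarter(tables, out_dir), truth


def generate_store(
    config: GeneratorConfig, out_dir: str | Path | None = None
) -> tuple[ReportStore, GroundTruth]:
    """Generate a quarter and parse it back through the reader.

    Routing the synthetic data through the file round-trip keeps the test
    surface identical to the real-data path.
    """
    if out_dir is None:
        with tempfile.TemporaryDirectory() as tmp:
            paths, truth = generate_quarter(config, tmp)
            return parse_quarter(paths), truth
    paths, truth = generate_quarter(config, out_dir)
    return parse_quarter(paths), truth


def expected_tables(truth: GroundTruth) -> dict[str, ContingencyTable]:
    """Exact per-PT 2x2 tables implied by the emitted files.

    This is the oracle for the reader and the disproportionality stage:
    the pipeline, run end to end on the generated files, must reproduce
    these tables exactly.
    """
    pairs = truth.pairs
    N = len(pairs)
    n_drug = int(pairs["exposed"].sum())
    a_counts = pairs[pairs["exposed"]]["pt_name"].value_counts()
    ev_counts = pairs["pt_name"].value_counts()
    out = {}
    for pt, ne in ev_counts.items():
        a = int(a_counts.get(pt, 0))
        out[pt] = ContingencyTable(a, n_drug - a, int(ne) - a, N - n_drug - int(ne) + a)
    return out
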