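"""Pregnancy-subcohort construction from a deduplicated report store.

Spontaneous-report databases have no pregnancy field, so the cohort is
assembled indirectly: reports are flagged when a reaction carries a
pregnancy/neonatal preferred term from user-supplied SMQ-derived term sets,
or when a drug's indication text names a pregnancy condition; flagged
reports are then filtered by exclusion rules (paternal-exposure terms,
male sex without a fetal/neonatal justification, implausible maternal age).

MedDRA content is licensed and never bundled: term sets are supplied as
CSV files keyed by SMQ code.  The package ships only the preferred-term
codes printed in public sources plus a small, explicitly non-exhaustive
starter list of PT names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .store import ReportStore, normalize_name

TERM_ROLES = (
    "pregnancy-inclusion",
    "indication-inclusion",
    "maternal-exposure",
    "paternal-exposure",
    "fetal-neonatal",
)


@dataclass(frozen=True)
class SmqTermSet:
    """A set of preferred terms (codes and/or names) with a matching role."""

    role: str
    pt_codes: frozenset = frozenset()
    pt_names: frozenset = frozenset()
    smq_codes: frozenset = frozenset()

    def __post_init__(self):
        if self.role not in TERM_ROLES:
            raise ValueError(f"unknown term-set role {self.role!r}")

    def __len__(self) -> int:
        return len(self.pt_codes) + len(self.pt_names)

    @staticmethod
    def from_frame(df: pd.DataFrame, role: str) -> "SmqTermSet":
        sub = df[df["role"] == role]
        codes = frozenset(
            int(c) for c in pd.to_numeric(sub.get("pt_code"), errors="coerce").dropna()
        )
        names = frozenset(
            normalize_name(n) for n in sub.get("pt_name", pd.Series(dtype=str)).dropna()
            if normalize_name(n)
        )
        smqs = frozenset(
            int(c) for c in pd.to_numeric(sub.get("smq_code"), errors="coerce").dropna()
        )
        return SmqTermSet(role=role, pt_codes=codes, pt_names=names, smq_codes=smqs)


def load_term_sets(path: str | Path) -> dict[str, SmqTermSet]:
    """Load all term sets from one CSV (columns smq_code, pt_code, pt_name, role)."""
    df = pd.read_csv(path, dtype={"pt_name": str, "role": str})
    return {role: SmqTermSet.from_frame(df, role) for role in df["role"].unique()}


@dataclass
class CohortAssignment:
    report_id: object
    label: str  # clearly-pregnancy | pregnancy-after-review | excluded | non-pregnancy
    reasons: list = field(default_factory=list)


@dataclass
class CohortFlowCounts:
    """Counts at each step of the cohort-assembly flow."""

    smq_flagged: int = 0
    indication_flagged: int = 0
    union_deduplicated: int = 0
    clearly_pregnancy: int = 0
    excluded: int = 0
    recovered_after_review: int = 0
    final_cohort: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _match_ids(records: pd.DataFrame, code_col: str, name_col: str, terms: SmqTermSet) -> set:
    hit = pd.Series(False, index=records.index)
    if terms.pt_codes and code_col in records.columns:
        codes = pd.to_numeric(records[code_col], errors="coerce")
        hit |= codes.isin(list(terms.pt_codes))
    if terms.pt_names:
        hit |= records[name_col].isin(list(terms.pt_names))
    return set(records.loc[hit, "primaryid"])


def flag_by_reaction_pts(store: ReportStore, terms: SmqTermSet) -> set:
    """Ids of reports with >=1 reaction PT in the pregnancy-inclusion set."""
    if len(terms) == 0:
        raise ValueError("empty pregnancy-inclusion term set")
    return _match_ids(store.reactions, "pt_code", "pt_name", terms)


def flag_by_indication(store: ReportStore, terms: SmqTermSet) -> set:
    """Ids of reports whose indication text exactly matches an inclusion term."""
    if len(terms) == 0:
        raise ValueError("empty indication-inclusion term set")
    hit = store.indications["indication_pt"].isin(list(terms.pt_names))
    return set(store.indications.loc[hit, "primaryid"])


def apply_exclusions(
    store: ReportStore,
    candidate_ids: set,
    paternal_terms: SmqTermSet,
    fetal_terms: SmqTermSet | None = None,
    min_age: float = 6.0,
    max_age: float = 55.0,
) -> tuple[list[CohortAssignment], set]:
    """Drop candidates flagged for paternal exposure, male sex, or age.

    A male report is retained only when a fetal/neonatal term set is given
    and every pregnancy-related reaction on the report belongs to it (a
    fetal case reported under the child's sex); otherwise male sex excludes.
    Age excludes when present and outside [min_age, max_age] years.
    Returns (exclusion assignments, kept id set).
    """
    demo = store.demo.set_index("primaryid")
    paternal_ids = _match_ids(store.reactions, "pt_code", "pt_name", paternal_terms)
    fetal_ids: set = set()
    if fetal_terms is not None and len(fetal_terms):
        fetal_ids = _match_ids(store.reactions, "pt_code", "pt_name", fetal_terms)

    excluded: list[CohortAssignment] = []
    kept: set = set()
    for rid in candidate_ids:
        reasons = []
        if rid in paternal_ids:
            reasons.append("paternal-exposure")
        row = demo.loc[rid] if rid in demo.index else None
        if row is not None:
            if row["sex"] == "male" and rid not in fetal_ids:
                reasons.append("gender-incompatibility")
            age = row["age_years"]
            if pd.notna(age) and not (min_age <= float(age) <= max_age):
                reasons.append("age")
        if reasons:
            excluded.append(CohortAssignment(rid, "excluded", reasons))
        else:
            kept.add(rid)
    return excluded, kept


def assemble_pregnancy_cohort(
    store: ReportStore,
    inclusion_terms: SmqTermSet,
    indication_terms: SmqTermSet,
    paternal_terms: SmqTermSet,
    fetal_terms: SmqTermSet | None = None,
    min_age: float = 6.0,
    max_age: float = 55.0,
    review_recovered: Iterable | None = None,
) -> tuple[set, CohortFlowCounts]:
    """Assemble the pregnancy cohort and the per-step flow counts.

    cohort = (reaction-flagged UNION indication-flagged) minus exclusions,
    plus any externally review-recovered ids (a hook for manual case review;
    default none).  Set semantics make the result independent of input
    record order.
    """
    flow = CohortFlowCounts()
    rx = flag_by_reaction_pts(store, inclusion_terms) if len(inclusion_terms) else set()
    ind = flag_by_indication(store, indication_terms) if len(indication_terms) else set()
    flow.smq_flagged = len(rx)
    flow.indication_flagged = len(ind)
    union = rx | ind
    flow.union_deduplicated = len(union)
    excluded, kept = apply_exclusions(
        store, union, paternal_terms, fetal_terms, min_age=min_age, max_age=max_age
    )
    flow.excluded = len(excluded)
    flow.clearly_pregnancy = len(kept)
    recovered = set(review_recovered or ()) & store.report_ids
    recovered -= kept
    flow.recovered_after_review = len(recovered)
    cohort = kept | recovered
    flow.final_cohort = len(cohort)
    return cohort, flow
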