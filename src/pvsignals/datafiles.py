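"""Loaders for the small data files shipped with the package.

* ``pregnancy_terms.csv`` — starter SMQ-derived term sets for pregnancy
  cohort construction: the publicly printed maternal/fetal and paternal
  exposure PT codes plus a short indication list.  Explicitly
  NON-EXHAUSTIVE: MedDRA is licensed, so full SMQ expansions must be
  supplied by the user as a CSV with the same columns
  (smq_code, pt_code, pt_name, role).
* ``published_signal_rows.csv`` — PT-level signal-table rows from a
  published FAERS insulin-glargine disproportionality analysis (overall
  population and pregnancy subcohort), with their cohort margins; used by
  the printed-row verification oracle.
* ``pt_soc_map.csv`` — PT -> System Organ Class assignments for the terms
  appearing in the published rows (a starter map; unmapped PTs fall into
  an explicit UNMAPPED bucket downstream).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .pregnancy import SmqTermSet
from .store import normalize_name


def _data_path(name: str):
    return resources.files("pvsignals.data").joinpath(name)


def published_signal_rows(cohort: str | None = None) -> pd.DataFrame:
    """Published signal-table rows; optionally one cohort ('overall'/'pregnancy')."""
    with resources.as_file(_data_path("published_signal_rows.csv")) as p:
        df = pd.read_csv(p)
    if cohort is not None:
        df = df[df["cohort"] == cohort].reset_index(drop=True)
    return df


def packaged_term_sets() -> dict[str, SmqTermSet]:
    """The starter pregnancy term sets keyed by role."""
    with resources.as_file(_data_path("pregnancy_terms.csv")) as p:
        df = pd.read_csv(p)
    return {role: SmqTermSet.from_frame(df, role) for role in df["role"].unique()}


def packaged_soc_map() -> dict[str, str]:
    """Starter PT -> SOC map (normalised PT names as keys)."""
    with resources.as_file(_data_path("pt_soc_map.csv")) as p:
        df = pd.read_csv(p)
    return {normalize_name(pt): soc for pt, soc in zip(df["pt_name"], df["soc"])}
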