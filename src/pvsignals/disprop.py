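"""Disproportionality statistics on 2x2 drug–event contingency tables.

Implements the four classic pharmacovigilance signal-detection statistics —
reporting odds ratio (ROR) with Woolf confidence interval, proportional
reporting ratio (PRR), the BCPNN information component (IC) with its
credible lower bound IC025, and the empirical-Bayes geometric mean (EBGM)
with its 5% bound — plus the joint signal criteria and the IC025-based
signal-strength classification.

The 2x2 table for one (drug, event) pair over a pair-count database:

    =====================  ============  ============
                           target event  other events
    target drug            a             b
    all other drugs        c             d
    =====================  ============  ============

with N = a+b+c+d, n_drug = a+b, n_event = a+c.

BCPNN closed forms follow the original formulation with marginal pseudo-
counts alpha1 = beta1 = 1 (prior totals alpha = beta = 2) and joint
pseudo-count gamma11 = 1, the joint prior total gamma being tied to the
margins so that the prior is centred on independence:

    gamma = gamma11 * (N+alpha)(N+beta) / ((n_drug+alpha1)(n_event+beta1))

The reported "IC" is the unshrunk log2 observed/expected ratio; "IC025" is
the prior-adjusted posterior expectation minus two posterior standard
deviations.  EBGM is the observed/expected ratio itself and EBGM05 its
two-standard-deviation lower bound on the log2 scale.  Chi-square is
uncorrected Pearson by default (a Yates switch exists for comparison).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd

Z95 = 1.96  # two-sided 95% normal quantile, as conventional in this field
_LN2_SQ_INV = 1.0 / math.log(2.0) ** 2


class SignalClass(str, Enum):
    NONE = "none"
    WEAK = "weak"
    MEDIUM = "medium"
    STRONG = "strong"


@dataclass(frozen=True)
class ContingencyTable:
    """Integer cell counts of one drug–event 2x2 table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_drug(self) -> int:
        return self.a + self.b

    @property
    def n_event(self) -> int:
        return self.a + self.c


@dataclass(frozen=True)
class BcpnnPriors:
    """Marginal and joint pseudo-counts of the BCPNN Dirichlet priors."""

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha, self.beta, self.gamma11) <= 0:
            raise ValueError("all BCPNN prior pseudo-counts must be strictly positive")


@dataclass
class SignalStatistics:
    """All four disproportionality statistics for one table.

    Any component whose formula is undefined for the table (a zero in a
    required cell) is NaN and the corresponding flag in ``undefined`` is
    set; such a table can never satisfy the joint signal criteria.
    """

    a: int
    ror: float = math.nan
    ror_lo: float = math.nan
    ror_hi: float = math.nan
    prr: float = math.nan
    prr_lo: float = math.nan
    prr_hi: float = math.nan
    chi2: float = math.nan
    ic: float = math.nan
    ic_expect: float = math.nan
    ic_var: float = math.nan
    ic025: float = math.nan
    ebgm: float = math.nan
    ebgm05: float = math.nan
    undefined: frozenset = frozenset()


def build_contingency(pairs: pd.DataFrame, event: str) -> ContingencyTable:
    """Tally the 2x2 table for one preferred term from the pair table.

    ``pairs`` is the output of :func:`pvsignals.store.build_drug_event_pairs`
    (columns primaryid, pt_name, exposed).
    """
    is_event = pairs["pt_name"] == event
    exposed = pairs["exposed"].to_numpy(dtype=bool)
    ev = is_event.to_numpy(dtype=bool)
    a = int((exposed & ev).sum())
    b = int((exposed & ~ev).sum())
    c = int((~exposed & ev).sum())
    d = int((~exposed & ~ev).sum())
    return ContingencyTable(a, b, c, d)


def reporting_odds_ratio(t: ContingencyTable) -> tuple[float, float, float]:
    """ROR = ad/bc with Woolf 95% CI; NaNs if any required cell is zero."""
    if t.a == 0 or t.b == 0 or t.c == 0 or t.d == 0:
        return (math.nan, math.nan, math.nan)
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return (ror, ror * math.exp(-Z95 * se), ror * math.exp(Z95 * se))


def proportional_reporting_ratio(t: ContingencyTable) -> tuple[float, float, float]:
    """PRR = (a/(a+b)) / (c/(c+d)) with its log-scale 95% CI."""
    if t.a == 0 or t.c == 0 or t.a + t.b == 0 or t.c + t.d == 0:
        return (math.nan, math.nan, math.nan)
    prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    se = math.sqrt(1 / t.a - 1 / (t.a + t.b) + 1 / t.c - 1 / (t.c + t.d))
    return (prr, prr * math.exp(-Z95 * se), prr * math.exp(Z95 * se))


def pearson_chi_square(t: ContingencyTable, yates: bool = False) -> float:
    """Pearson chi-square of the 2x2 table; uncorrected by default."""
    margins = (t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d)
    if any(m == 0 for m in margins):
        return math.nan
    diff = abs(t.a * t.d - t.b * t.c)
    if yates:
        diff = max(0.0, diff - t.n / 2.0)
    return t.n * diff * diff / (margins[0] * margins[1] * margins[2] * margins[3])


def bcpnn_ic(
    t: ContingencyTable, priors: BcpnnPriors = BcpnnPriors()
) -> tuple[float, float, float, float]:
    """BCPNN information component: (ic, ic_expect, ic_var, ic025).

    ``ic`` is the unshrunk log2(a N / (n_drug n_event)) and is NaN when
    a = 0; the posterior expectation, variance and IC025 remain defined
    for any table through the pseudo-counts.
    """
    N, nd, ne, a = t.n, t.n_drug, t.n_event, t.a
    p = priors
    gamma = p.gamma11 * (N + p.alpha) * (N + p.beta) / ((nd + p.alpha1) * (ne + p.beta1))
    ic_expect = math.log2(
        (a + p.gamma11) * (N + p.alpha) * (N + p.beta)
        / ((N + gamma) * (nd + p.alpha1) * (ne + p.beta1))
    )
    ic_var = _LN2_SQ_INV * (
        (N - a + gamma - p.gamma11) / ((a + p.gamma11) * (1 + N + gamma))
        + (N - nd + p.alpha - p.alpha1) / ((nd + p.alpha1) * (1 + N + p.alpha))
        + (N - ne + p.beta - p.beta1) / ((ne + p.beta1) * (1 + N + p.beta))
    )
    ic025 = ic_expect - 2.0 * math.sqrt(ic_var)
    if a == 0 or nd == 0 or ne == 0:
        ic = math.nan
    else:
        ic = math.log2(a * N / (nd * ne))
    return (ic, ic_expect, ic_var, ic025)


def relative_reporting_ebgm(t: ContingencyTable, ic_var: float) -> tuple[float, float]:
    """EBGM as the observed/expected reporting ratio, EBGM05 from the IC scale.

    ebgm05 = 2**(ic - 2*sqrt(ic_var)); both NaN when a = 0.
    """
    if t.a == 0 or t.n_drug == 0 or t.n_event == 0:
        return (math.nan, math.nan)
    ebgm = t.a * t.n / (t.n_drug * t.n_event)
    ebgm05 = 2.0 ** (math.log2(ebgm) - 2.0 * math.sqrt(ic_var))
    return (ebgm, ebgm05)


def compute_statistics(
    t: ContingencyTable,
    priors: BcpnnPriors = BcpnnPriors(),
    yates: bool = False,
) -> SignalStatistics:
    """Compute all statistics for one table, flagging undefined components."""
    undefined: set[str] = set()
    ror, ror_lo, ror_hi = reporting_odds_ratio(t)
    if math.isnan(ror):
        undefined.add("ror")
    prr, prr_lo, prr_hi = proportional_reporting_ratio(t)
    if math.isnan(prr):
        undefined.add("prr")
    chi2 = pearson_chi_square(t, yates=yates)
    if math.isnan(chi2):
        undefined.add("chi2")
    ic, ic_expect, ic_var, ic025 = bcpnn_ic(t, priors)
    if math.isnan(ic):
        undefined.add("ic")
    ebgm, ebgm05 = relative_reporting_ebgm(t, ic_var)
    if math.isnan(ebgm):
        undefined.add("ebgm")
    return SignalStatistics(
        a=t.a,
        ror=ror,
        ror_lo=ror_lo,
        ror_hi=ror_hi,
        prr=prr,
        prr_lo=prr_lo,
        prr_hi=prr_hi,
        chi2=chi2,
        ic=ic,
        ic_expect=ic_expect,
        ic_var=ic_var,
        ic025=ic025,
        ebgm=ebgm,
        ebgm05=ebgm05,
        undefined=frozenset(undefined),
    )


#: The joint signal criteria: all six must hold simultaneously.
SIGNAL_CRITERIA = (
    "a >= 3",
    "ROR 95% CI lower bound > 1",
    "PRR >= 2",
    "chi-square >= 4",
    "IC025 > 0",
    "EBGM05 > 2",
)


def evaluate_signal(stats: SignalStatistics) -> bool:
    """True iff the table satisfies all six joint signal criteria.

    Any undefined component fails the conjunction.
    """
    checks = (
        stats.a >= 3,
        stats.ror_lo > 1.0,
        stats.prr >= 2.0,
        stats.chi2 >= 4.0,
        stats.ic025 > 0.0,
        stats.ebgm05 > 2.0,
    )
    return all(bool(c) and not math.isnan(float(v)) for c, v in zip(
        checks, (stats.a, stats.ror_lo, stats.prr, stats.chi2, stats.ic025, stats.ebgm05)
    ))


def classify_strength(ic025: float) -> SignalClass:
    """Signal-strength class from IC025: none / weak / medium / strong.

    Bands: none (ic025 <= 0), weak (0 < ic025 <= 1.5),
    medium (1.5 < ic025 <= 3), strong (ic025 > 3).
    """
    if math.isnan(ic025) or ic025 <= 0.0:
        return SignalClass.NONE
    if ic025 <= 1.5:
        return SignalClass.WEAK
    if ic025 <= 3.0:
        return SignalClass.MEDIUM
    return SignalClass.STRONG


def solve_comparator_count(a: int, ror_printed: float, n_drug: int, N: int) -> int:
    """Back-derive the comparator cell c from a published ROR.

    Given a, the drug margin and the database total, the c consistent with
    ROR = ad/(bc) (b = n_drug - a, d = N - n_drug - c) is

        c = a (N - n_drug) / (b * ROR + a)

    rounded to the nearest integer.  This lets published signal-table rows
    be re-verified without the underlying database.
    """
    if ror_printed <= 0:
        raise ValueError("ror_printed must be positive")
    if not (a <= n_drug <= N):
        raise ValueError("need a <= n_drug <= N")
    b = n_drug - a
    c = a * (N - n_drug) / (b * ror_printed + a)
    c_int = int(round(c))
    if c_int < 0 or c_int > N - n_drug:
        raise ValueError("no admissible comparator count for these inputs")
    return c_int


def signal_table(
    pairs: pd.DataFrame,
    priors: BcpnnPriors = BcpnnPriors(),
    min_a: int = 1,
    soc_map: dict | None = None,
    yates: bool = False,
) -> pd.DataFrame:
    """Per-PT signal statistics over a pair table, sorted by IC025 descending.

    One row per preferred term with at least ``min_a`` exposed pairs;
    columns mirror the published signal-table layout plus the joint-criteria
    verdict and strength class.  PTs with no entry in ``soc_map`` fall into
    an explicit "UNMAPPED" bucket.
    """
    exposed = pairs[pairs["exposed"]]
    N = len(pairs)
    n_drug = len(exposed)
    a_counts = exposed["pt_name"].value_counts()
    event_counts = pairs["pt_name"].value_counts()
    rows = []
    for pt, a in a_counts.items():
        if a < min_a:
            continue
        ne = int(event_counts[pt])
        t = ContingencyTable(int(a), n_drug - int(a), ne - int(a), N - n_drug - ne + int(a))
        s = compute_statistics(t, priors, yates=yates)
        soc = (soc_map or {}).get(pt, "UNMAPPED")
        rows.append(
            {
                "soc": soc,
                "pt": pt,
                "a": int(a),
                "ror": s.ror,
                "ror_lo": s.ror_lo,
                "ror_hi": s.ror_hi,
                "prr": s.prr,
                "prr_lo": s.prr_lo,
                "prr_hi": s.prr_hi,
                "chi2": s.chi2,
                "ic": s.ic,
                "ic025": s.ic025,
                "ebgm": s.ebgm,
                "ebgm05": s.ebgm05,
                "is_signal": evaluate_signal(s),
                "strength": classify_strength(s.ic025).value,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "soc", "pt", "a", "ror", "ror_lo", "ror_hi", "prr", "prr_lo",
            "prr_hi", "chi2", "ic", "ic025", "ebgm", "ebgm05", "is_signal",
            "strength",
        ],
    )
    if len(df):
        df = df.sort_values(["ic025", "pt"], ascending=[False, True]).reset_index(drop=True)
    return df
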