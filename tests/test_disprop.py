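"""Disproportionality statistics against independent oracles and invariants."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignals import (
    BcpnnPriors,
    ContingencyTable,
    SignalClass,
    bcpnn_ic,
    build_contingency,
    classify_strength,
    compute_statistics,
    evaluate_signal,
    pearson_chi_square,
    proportional_reporting_ratio,
    relative_reporting_ebgm,
    reporting_odds_ratio,
    signal_table,
    solve_comparator_count,
)

cells = st.integers(min_value=1, max_value=5000)
tables = st.builds(ContingencyTable, cells, cells, cells, cells)


class TestPointEstimates:
    def test_against_direct_formula_evaluation(self):
        # independent brute-force evaluation for a small table
        t = ContingencyTable(3, 7, 12, 78)
        ror, lo, hi = reporting_odds_ratio(t)
        assert ror == pytest.approx((3 * 78) / (7 * 12))
        se = math.sqrt(1 / 3 + 1 / 7 + 1 / 12 + 1 / 78)
        assert lo == pytest.approx(ror * math.exp(-1.96 * se))
        assert hi == pytest.approx(ror * math.exp(1.96 * se))
        prr, plo, phi = proportional_reporting_ratio(t)
        assert prr == pytest.approx((3 / 10) / (12 / 90))
        # chi-square against the cell-sum oracle sum (obs-exp)^2/exp
        obs = np.array([[3, 7], [12, 78]])
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        assert pearson_chi_square(t) == pytest.approx(((obs - exp) ** 2 / exp).sum())

    def test_against_scipy_and_statsmodels(self):
        t = ContingencyTable(17, 229939, 76, 53122722)
        chi2_scipy = scipy.stats.chi2_contingency(
            [[t.a, t.b], [t.c, t.d]], correction=False
        ).statistic
        assert pearson_chi_square(t) == pytest.approx(chi2_scipy, rel=1e-10)
        chi2_yates = scipy.stats.chi2_contingency(
            [[t.a, t.b], [t.c, t.d]], correction=True
        ).statistic
        assert pearson_chi_square(t, yates=True) == pytest.approx(chi2_yates, rel=1e-10)
        import statsmodels.api as sm

        tab = sm.stats.Table2x2([[t.a, t.b], [t.c, t.d]])
        ror, lo, hi = reporting_odds_ratio(t)
        assert ror == pytest.approx(tab.oddsratio)
        assert (lo, hi) == pytest.approx(tab.oddsratio_confint(0.05), rel=1e-4)

    def test_symmetric_table_is_null(self):
        t = ContingencyTable(10, 10, 10, 10)
        assert reporting_odds_ratio(t)[0] == pytest.approx(1.0)
        assert proportional_reporting_ratio(t)[0] == pytest.approx(1.0)
        assert pearson_chi_square(t) == pytest.approx(0.0)
        ic, _, icv, _ = bcpnn_ic(t)
        assert ic == pytest.approx(0.0)
        assert relative_reporting_ebgm(t, icv)[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("a,b,c,d", [(4, 8, 7, 14), (20, 5, 80, 20), (9, 9, 33, 33)])
    def test_independence_implies_all_unity(self, a, b, c, d):
        # a*d == b*c by construction
        t = ContingencyTable(a, b, c, d)
        assert a * d == b * c
        s = compute_statistics(t)
        assert s.ror == pytest.approx(1.0)
        assert s.prr == pytest.approx(1.0)
        assert s.ebgm == pytest.approx(1.0)
        assert s.ic == pytest.approx(0.0)
        assert s.chi2 == pytest.approx(0.0)

    def test_zero_cells_flagged_and_never_signal(self):
        s = compute_statistics(ContingencyTable(0, 10, 5, 100))
        assert {"ror", "prr", "ic", "ebgm"} <= set(s.undefined)
        assert not evaluate_signal(s)


class TestBcpnn:
    def test_reference_values_pin_the_variant(self):
        """The closed form with Dirichlet pseudo-counts (1,1,1 over prior
        totals 2,2) must reproduce published IC025 values 3.30 and 2.94;
        the expectation-approximation variant gives ~3.94/~4.65 there and
        must not match."""
        N, nd = 53_352_754, 229_956
        for a, ror, want in [(34, 25.34, 3.30), (17, 51.68, 2.94)]:
            c = solve_comparator_count(a, ror, nd, N)
            t = ContingencyTable(a, nd - a, c, N - nd - c)
            ic, _, _, ic025 = bcpnn_ic(t)
            assert ic025 == pytest.approx(want, abs=0.02)
            # discriminator: the large-N approximation ic - 2/ln2 * 1/sqrt(a)
            ic025_approx = ic - 2.0 / math.log(2) * (1.0 / math.sqrt(a))
            assert abs(ic025_approx - want) > 0.1

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(tables)
    def test_ic025_below_ic_and_ebgm05_below_ebgm(self, t):
        ic, _, icv, ic025 = bcpnn_ic(t)
        assert ic025 < ic + 1e-12
        ebgm, ebgm05 = relative_reporting_ebgm(t, icv)
        assert ebgm05 < ebgm + 1e-12

    def test_ic025_strictly_increasing_in_a(self):
        # hold N, n_drug and n_event - a fixed
        N, nd, c = 100_000, 2_000, 50
        prev = -math.inf
        for a in range(1, 60, 5):
            t = ContingencyTable(a, nd - a, c, N - nd - c)
            ic025 = bcpnn_ic(t)[3]
            assert ic025 > prev
            prev = ic025


class TestCriteriaAndStrength:
    def _passing_stats(self):
        # a large obvious signal
        t = ContingencyTable(100, 900, 100, 98_900)
        return compute_statistics(t)

    def test_joint_conjunction(self):
        s = self._passing_stats()
        assert evaluate_signal(s)
        import dataclasses

        for field, bad in [("a", 2), ("prr", 1.5), ("chi2", 3.0), ("ic025", -0.1),
                           ("ebgm05", 1.9), ("ror_lo", 0.99)]:
            assert not evaluate_signal(dataclasses.replace(s, **{field: bad}))

    @pytest.mark.parametrize(
        "ic025,want",
        [
            (-0.2, SignalClass.NONE),
            (0.0, SignalClass.NONE),
            (1e-9, SignalClass.WEAK),
            (1.5, SignalClass.WEAK),
            (1.5 + 1e-9, SignalClass.MEDIUM),
            (3.0, SignalClass.MEDIUM),
            (3.0 + 1e-9, SignalClass.STRONG),
            (4.26, SignalClass.STRONG),
        ],
    )
    def test_strength_bands(self, ic025, want):
        assert classify_strength(ic025) is want

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(min_value=-10, max_value=10, allow_nan=False))
    def test_strength_partitions_the_line(self, x):
        assert classify_strength(x) in set(SignalClass)


class TestComparatorBackDerivation:
    def test_symmetric_identity(self):
        assert solve_comparator_count(10, 1.0, 20, 40) == 10

    @pytest.mark.parametrize(
        "a,ror,nd,N,c_want,prr_want",
        [
            (3689, 22.04, 229_956, 53_352_754, 39_268, 21.71),
            (73, 39.42, 2_748, 1_315_162, 908, 38.40),
        ],
    )
    def test_back_derivation_reproduces_published_prr(self, a, ror, nd, N, c_want, prr_want):
        c = solve_comparator_count(a, ror, nd, N)
        assert c == c_want
        t = ContingencyTable(a, nd - a, c, N - nd - c)
        prr = proportional_reporting_ratio(t)[0]
        assert prr == pytest.approx(prr_want, rel=0.005)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(tables)
    def test_roundtrip_recovers_c(self, t):
        ror = reporting_odds_ratio(t)[0]
        assert solve_comparator_count(t.a, ror, t.n_drug, t.n) == t.c

    def test_inadmissible_inputs_error(self):
        with pytest.raises(ValueError):
            solve_comparator_count(10, -1.0, 20, 40)
        with pytest.raises(ValueError):
            solve_comparator_count(30, 1.0, 20, 40)


class TestSignalTable:
    def test_build_contingency_direct_count(self):
        pairs = pd.DataFrame(
            {
                "primaryid": list(range(10)),
                "pt_name": ["X", "X", "Y", "Y", "Z", "X", "Z", "Z", "Y", "Z"],
                "exposed": [True] * 4 + [False] * 6,
            }
        )
        t = build_contingency(pairs, "X")
        assert (t.a, t.b, t.c, t.d) == (2, 2, 1, 5)
        absent = build_contingency(pairs, "W")
        assert (absent.a, absent.c) == (0, 0)
        assert absent.b == 4 and absent.d == 6

    def test_table_sorted_by_ic025_and_soc_mapped(self, small_dedup):
        from pvsignals import build_drug_event_pairs, select_drug_reports

        dd, truth = small_dedup
        pairs = build_drug_event_pairs(dd, select_drug_reports(dd).report_ids)
        sig = signal_table(pairs, soc_map=truth.soc_map)
        assert (sig["ic025"].diff().dropna() <= 1e-12).all()
        assert sig["soc"].notna().all()
        # maternal-exposure tag PTs are absent from the synthetic SOC map
        assert (sig["soc"] == "UNMAPPED").any()
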