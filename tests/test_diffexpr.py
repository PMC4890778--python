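"""Normalization, exact count test, call thresholds."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mircold import diffexpr as de


class TestNormalize:
    @pytest.mark.parametrize("x,n,expected", [
        (5, 1_000_000, 5.0),
        (0, 123_456, 0.01),
        (1_000_000, 1_000_000, 1_000_000.0),
    ])
    def test_values(self, x, n, expected):
        assert de.normalize(x, n) == pytest.approx(expected)

    def test_invalid_total(self):
        with pytest.raises(ValueError):
            de.normalize(1, 0)


class TestLog2FC:
    @pytest.mark.parametrize("t,c,expected", [
        (2.0, 1.0, 1.0), (1.0, 1.0, 0.0), (0.01, 10.0, math.log2(0.001))])
    def test_values(self, t, c, expected):
        assert de.log2fc(t, c) == pytest.approx(expected)


def _exact_ac(x, n1, n2, y):
    """Exact-rational two-sided AC p-value, same canonical orientation."""
    if (y, n2) < (x, n1):
        x, n1, y, n2 = y, n2, x, n1

    def pmf(k):
        num = Fraction(n1) ** (x + 1) * Fraction(n2) ** k * math.comb(x + k, k)
        return num / Fraction(n1 + n2) ** (x + k + 1)

    lower = sum(pmf(k) for k in range(y + 1))
    upper = 1 - sum(pmf(k) for k in range(y))
    return float(min(Fraction(1), 2 * min(lower, upper)))


class TestAcTest:
    def test_identical_zero_counts(self):
        assert de.ac_test(0, 10**6, 0, 10**6) == 1.0

    def test_identical_counts_capped_at_one(self):
        assert de.ac_test(5, 10**6, 5, 10**6) == 1.0

    def test_extreme_imbalance(self):
        assert de.ac_test(0, 10**6, 50, 10**6) < 1e-10

    def test_matches_exact_rational_summation(self):
        for x, y in [(0, 0), (0, 5), (3, 17), (10, 10), (25, 2), (30, 30)]:
            for n1, n2 in [(10**6, 10**6), (10**4, 10**6)]:
                assert de.ac_test(x, n1, y, n2) == pytest.approx(
                    _exact_ac(x, n1, n2, y), abs=1e-10)

    def test_matches_negative_binomial_tails(self):
        """The conditional is NB(x+1, N1/(N1+N2)): scipy as independent route."""
        for x, y, n1, n2 in [(4, 19, 10**5, 10**5), (0, 7, 10**4, 10**6),
                             (12, 3, 2 * 10**5, 10**5)]:
            cx, cn1, cy, cn2 = (x, n1, y, n2) if (x, n1) <= (y, n2) else (y, n2, x, n1)
            p_s = cn1 / (cn1 + cn2)
            lower = sps.nbinom.cdf(cy, cx + 1, p_s)
            upper = sps.nbinom.sf(cy - 1, cx + 1, p_s)
            expected = min(1.0, 2 * min(lower, upper))
            assert de.ac_test(x, n1, y, n2) == pytest.approx(expected, abs=1e-9)

    @given(x=st.integers(0, 200), y=st.integers(0, 200),
           n1=st.integers(10**3, 10**7), n2=st.integers(10**3, 10**7))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetry(self, x, y, n1, n2):
        assert de.ac_test(x, n1, y, n2) == pytest.approx(
            de.ac_test(y, n2, x, n1), abs=1e-12)

    def test_monotone_in_divergence(self):
        ps = [de.ac_test(8, 10**6, y, 10**6) for y in range(0, 40)]
        for y in range(8, 39):
            assert ps[y + 1] <= ps[y] + 1e-12
        for y in range(0, 8):
            assert ps[y] <= ps[y + 1] + 1e-12

    def test_large_counts_do_not_overflow(self):
        p = de.ac_test(4000, 90_000, 1000, 90_000)
        assert 0 <= p < 1e-100 or p == 0.0


class TestClassify:
    @pytest.mark.parametrize("lfc,p,call", [
        (0.4, 0.01, "ns"),       # fold change below threshold
        (1.2, 0.001, "up"),
        (-0.6, 0.2, "ns"),       # p criterion fails
        (-1.2, 0.001, "down"),
        (0.5, 0.001, "ns"),      # boundary lfc is ns
        (1.0, 0.05, "ns"),       # boundary p is ns
    ])
    def test_calls(self, lfc, p, call):
        assert de.classify(lfc, p) == call

    def test_monotone_in_evidence(self):
        """Raising the treat count never flips an up call to down."""
        n = 10**5
        calls = []
        for x_treat in range(0, 400, 25):
            lfc = de.log2fc(de.normalize(x_treat, n), de.normalize(100, n))
            calls.append(de.classify(lfc, de.ac_test(100, n, x_treat, n)))
        seen_up = False
        for c in calls:
            if c == "up":
                seen_up = True
            assert not (seen_up and c == "down")


class TestContrastTable:
    def _table(self):
        counts = pd.DataFrame(
            {"HCA": [100, 0, 50], "HSA": [400, 0, 52]},
            index=["m1", "m2", "m3"])
        totals = {"HCA": 10**5, "HSA": 10**5}
        return counts, totals

    def test_calls_and_partition(self):
        counts, totals = self._table()
        res = de.contrast_table(counts, totals, [("anther", "HSA", "HCA")])
        assert len(res) == 3
        calls = dict(zip(res.entity_id, res.call))
        assert calls["m1"] == "up" and calls["m2"] == "ns" and calls["m3"] == "ns"
        summary = de.summarize_calls(res)
        assert sum(summary["anther"].values()) == 3

    def test_all_zero_matrix_all_ns(self):
        counts = pd.DataFrame({"A": [0, 0], "B": [0, 0]}, index=["m1", "m2"])
        res = de.contrast_table(counts, {"A": 1000, "B": 1000}, [("c", "B", "A")])
        assert (res.call == "ns").all()

    def test_unknown_library_raises(self):
        counts, totals = self._table()
        with pytest.raises(KeyError):
            de.contrast_table(counts, totals, [("bad", "NOPE", "HCA")])

    def test_tpm_conservation_without_zero_replacement(self):
        """Library TPMs sum to 1e6 when every entity is observed."""
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 500, size=200)
        n = int(counts.sum())
        tpms = [de.normalize(int(c), n) for c in counts]
        assert sum(tpms) == pytest.approx(1e6, rel=1e-9)
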