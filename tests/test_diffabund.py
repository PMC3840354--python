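import math
import random

import numpy as np
import pytest
from scipy.stats import nbinom

from mpnpipe.diffabund import ac_test, bh_fdr, compare_libraries
from mpnpipe.functional import KOProfile
from mpnpipe.simulate import null_ko_profiles


def ac_oracle(x, y, n1, n2, sided="one"):
    """Direct finite summation of the conditional count distribution with
    plain floats and lgamma -- independent of the log-space tail
    implementation under test."""
    r = n2 / n1

    def pmf(k):
        return math.exp(
            k * math.log(r)
            + math.lgamma(x + k + 1) - math.lgamma(x + 1) - math.lgamma(k + 1)
            - (x + k + 1) * math.log1p(r)
        )

    if y / n2 == x / n1:
        p = 1.0
    else:
        lower = sum(pmf(k) for k in range(0, y + 1))
        p = lower if y / n2 < x / n1 else max(0.0, 1.0 - lower)
    p = min(p, 1.0)
    return min(1.0, 2.0 * p) if sided == "two" else p


class TestACTest:
    def test_equal_zero_counts_whole_tail(self):
        assert ac_test(0, 0, 1000, 1000, sided="one") == 1.0

    def test_five_vs_zero_closed_form(self):
        """x=5, y=0, equal sizes: lower tail = C(5,0)/2^6 = (1/2)^6."""
        assert ac_test(5, 0, 1000, 1000, sided="one") == pytest.approx(
            0.5 ** 6, abs=1e-12
        )

    def test_matches_direct_summation_oracle(self):
        for x in range(0, 51, 7):
            for y in range(0, 51, 5):
                for ratio in (0.5, 1.0, 2.0):
                    n1, n2 = 10000.0, 10000.0 * ratio
                    assert ac_test(x, y, n1, n2, sided="one") == pytest.approx(
                        ac_oracle(x, y, n1, n2), abs=1e-10
                    )

    def test_exchangeable_between_libraries(self):
        """p(x, y, N1, N2) = p(y, x, N2, N1) on random tuples."""
        rng = random.Random(42)
        for _ in range(50):
            x, y = rng.randint(0, 300), rng.randint(0, 300)
            n1, n2 = rng.uniform(1e3, 1e5), rng.uniform(1e3, 1e5)
            assert ac_test(x, y, n1, n2) == pytest.approx(
                ac_test(y, x, n2, n1), abs=1e-10
            )

    def test_lower_tail_is_negative_binomial_cdf(self):
        """Cross-check against scipy: y | x is NB(x+1, N1/(N1+N2))."""
        from mpnpipe.diffabund import _lower_tail

        for x in (0, 3, 17):
            for y in (0, 5, 40):
                got = _lower_tail(x, y, 1500.0, 3000.0)
                want = nbinom.cdf(y, x + 1, 1500.0 / 4500.0)
                assert got == pytest.approx(want, abs=1e-12)

    def test_upper_tail_p_decreases_beyond_expectation(self):
        """For fixed x, the p-value is non-increasing as y moves further
        above the matched expectation."""
        x, n1, n2 = 20, 10000.0, 10000.0
        ps = [ac_test(x, y, n1, n2, sided="one") for y in range(21, 80)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_two_sided_doubles_and_caps(self):
        p1 = ac_test(5, 0, 1000, 1000, sided="one")
        assert ac_test(5, 0, 1000, 1000, sided="two") == pytest.approx(2 * p1)
        assert ac_test(0, 0, 1000, 1000, sided="two") == 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ac_test(-1, 0, 100, 100)
        with pytest.raises(ValueError):
            ac_test(0, 0, 0, 100)
        with pytest.raises(ValueError):
            ac_test(0, 0, 100, 100, sided="three")


class TestBHFDR:
    def test_step_up_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_against_independent_step_up_oracle(self):
        rng = np.random.default_rng(3)
        p = rng.random(200)
        # literal step-up: q_(i) = min_{j>=i} p_(j) * m / j, mapped back
        order = np.argsort(p)
        m = len(p)
        q_sorted = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        expected = np.empty(m)
        expected[order] = np.clip(q_sorted, 0, 1)
        assert np.allclose(bh_fdr(p), expected)

    def test_monotone_in_p_order(self):
        rng = np.random.default_rng(4)
        p = rng.random(100)
        q = bh_fdr(p)
        idx = np.argsort(p)
        assert np.all(np.diff(q[idx]) >= -1e-12)
        assert np.all(q >= p - 1e-12)

    def test_never_more_discoveries_than_uncorrected(self):
        rng = np.random.default_rng(5)
        p = rng.random(500) ** 2
        q = bh_fdr(p)
        for alpha in (0.01, 0.05, 0.1):
            assert (q < alpha).sum() <= (p < alpha).sum()

    def test_rejects_bad_p(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestCompareLibraries:
    def test_identical_libraries_nothing_significant(self):
        prof = KOProfile("a", {"K1": 40.0, "K2": 10.0, "K3": 1.0}, 51)
        comp = compare_libraries(prof, KOProfile("b", dict(prof.weight), 51))
        assert comp.significant_fraction == 0.0
        assert (comp.results["p_value"] == 1.0).all()

    def test_absent_feature_counts_zero_and_fold_inf(self):
        a = KOProfile("a", {"K1": 30.0, "K2": 20.0}, 50)
        b = KOProfile("b", {"K2": 50.0}, 50)
        comp = compare_libraries(a, b)
        row = comp.results.set_index("feature").loc["K1"]
        assert row["y"] == 0
        assert np.isinf(row["fold"])

    def test_double_zero_features_skipped(self):
        a = KOProfile("a", {"K1": 10.0, "K2": 0.0}, 10)
        b = KOProfile("b", {"K2": 0.0, "K3": 5.0}, 5)
        comp = compare_libraries(a, b)
        assert set(comp.results["feature"]) == {"K1", "K3"}

    def test_fractional_weights_are_rounded(self):
        a = KOProfile("a", {"K1": 9.5}, 10)
        b = KOProfile("b", {"K1": 9.4}, 10)
        comp = compare_libraries(a, b, rounding="round")
        row = comp.results.iloc[0]
        assert (row["x"], row["y"]) == (10, 9)
        comp_floor = compare_libraries(a, b, rounding="floor")
        assert tuple(comp_floor.results.iloc[0][["x", "y"]]) == (9, 9)

    def test_null_multinomial_type_one_error_controlled(self):
        """Two draws from one 500-feature multinomial: the BH-significant
        fraction stays at or below 1.5x the nominal level."""
        a, b = null_ko_profiles(500, 20000, seed=8)
        comp = compare_libraries(a, b, alpha=0.05)
        assert comp.significant_fraction <= 0.075

    def test_mpn_arm_alkylphosphonate_kos_significant(self, rna_ko_profiles, default_sim):
        """At the MPn-arm endpoint every detected C-P lyase KO is significant
        with a large positive fold over the control."""
        comp = compare_libraries(
            rna_ko_profiles["GlcN_MPn_48h_RNA"], rna_ko_profiles["control_48h_RNA"]
        )
        phn_kos = {
            e.ko_id
            for e in default_sim.catalog.entries.values()
            if e.family and e.family.startswith("phn") and e.ko_id
            and e.family not in ("phnW", "phnX")
        }
        rows = comp.results[comp.results["feature"].isin(phn_kos)]
        assert len(rows) >= 10
        assert rows["significant"].all()
        assert (rows["fold"] > 10).all()
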