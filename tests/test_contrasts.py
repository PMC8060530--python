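import numpy as np
import pytest
from scipy import stats

from emarisk import contrasts as ct

# 2x2 tables reconstructed from the published period totals and prevalences
PUBLISHED_TABLES = {
    1: (413, 547, 113, 101),
    2: (171, 789, 22, 192),
    3: (256, 704, 74, 140),
    4: (113, 847, 5, 209),
}


def make_labels(table):
    a, b, c, d = table
    labels = np.array([1] * a + [2] * b + [1] * c + [2] * d)
    periods = np.array(["pre_lockdown"] * (a + b) + ["lockdown"] * (c + d))
    return labels, periods


class TestContingency:
    def test_reconstructed_profile1_table(self):
        labels, periods = make_labels(PUBLISHED_TABLES[1])
        tab = ct.contingency_table(labels, periods, 1)
        assert tab.tolist() == [[413, 547], [113, 101]]
        assert tab[0].sum() == 960 and tab[1].sum() == 214

    def test_missing_period_is_degenerate(self):
        labels = np.array([1, 2, 1])
        periods = np.array(["pre_lockdown"] * 3)
        with pytest.raises(ct.DegenerateTableError, match="degenerate margin"):
            ct.contingency_table(labels, periods, 1)

    def test_unknown_profile_rejected(self):
        labels, periods = make_labels(PUBLISHED_TABLES[1])
        with pytest.raises(ValueError, match="unknown profile"):
            ct.contingency_table(labels, periods, 99)

    def test_single_profile_gives_zero_column_and_degenerate_chi2(self):
        labels = np.array([1, 1, 1, 1])
        periods = np.array(["pre_lockdown", "pre_lockdown", "lockdown", "lockdown"])
        tab = ct.contingency_table(labels, periods, 1)
        assert tab[:, 1].sum() == 0
        with pytest.raises(ct.DegenerateTableError):
            ct.yates_chi_square(tab)


class TestYatesChiSquare:
    @pytest.mark.parametrize("pid,expected", [(1, 6.38), (2, 6.69), (3, 5.04), (4, 16.20)])
    def test_published_quadruple(self, pid, expected):
        a, b, c, d = PUBLISHED_TABLES[pid]
        chi2, _ = ct.yates_chi_square(np.array([[a, b], [c, d]]))
        assert round(chi2, 2) == expected

    def test_identical_proportions_floor_to_zero(self):
        chi2, p = ct.yates_chi_square(np.array([[50, 50], [50, 50]]))
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_agrees_with_scipy_continuity_correction(self, rng):
        for _ in range(200):
            tab = rng.integers(1, 80, size=(2, 2))
            chi2, p = ct.yates_chi_square(tab)
            ref_chi2, ref_p, _, _ = stats.chi2_contingency(tab, correction=True)
            assert chi2 == pytest.approx(ref_chi2, abs=1e-8)
            assert p == pytest.approx(ref_p, abs=1e-8)

    def test_row_swap_invariance(self, rng):
        tab = np.array([[30, 50], [10, 60]])
        assert ct.yates_chi_square(tab)[0] == pytest.approx(ct.yates_chi_square(tab[::-1])[0])

    def test_yates_never_exceeds_pearson(self, rng):
        for _ in range(300):
            tab = rng.integers(1, 100, size=(2, 2))
            assert ct.yates_chi_square(tab)[0] <= ct.pearson_chi_square(tab) + 1e-12


class TestPercentChange:
    @pytest.mark.parametrize(
        "pre,lock,expected",
        [(43.0, 52.8, 22.8), (17.8, 10.3, -42.1), (26.7, 34.6, 29.6), (5.0, 5.0, 0.0)],
    )
    def test_published_changes(self, pre, lock, expected):
        assert round(ct.percent_change(pre, lock), 1) == expected

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            ct.percent_change(0.0, 5.0)

    def test_direction_words(self):
        assert ct.format_percent_change(43.0, 52.8) == "22.8% increase"
        assert ct.format_percent_change(17.8, 10.3) == "42.1% decrease"
        assert "no change" in ct.format_percent_change(5.0, 5.0)


class TestClopperPearson:
    def test_published_rare_profile_interval(self):
        lo, hi = ct.clopper_pearson_ci(7, 960, 0.95)
        assert round(lo, 1) == 0.3
        assert round(hi, 1) == 1.5
        assert lo < 100 * 7 / 960 < hi

    def test_boundaries(self):
        assert ct.clopper_pearson_ci(0, 100)[0] == 0.0
        assert ct.clopper_pearson_ci(100, 100)[1] == 100.0

    def test_matches_binomial_tail_inversion(self):
        # independent oracle: root-find the binomial tail probabilities directly
        from scipy.optimize import brentq

        x, n, level = 7, 960, 0.95
        tail = (1 - level) / 2
        lo = brentq(lambda p: stats.binom.sf(x - 1, n, p) - tail, 1e-9, 1 - 1e-9)
        hi = brentq(lambda p: stats.binom.cdf(x, n, p) - tail, 1e-9, 1 - 1e-9)
        got_lo, got_hi = ct.clopper_pearson_ci(x, n, level)
        assert got_lo == pytest.approx(100 * lo, abs=1e-6)
        assert got_hi == pytest.approx(100 * hi, abs=1e-6)

    def test_matches_statsmodels_beta_method(self):
        from statsmodels.stats.proportion import proportion_confint

        for x, n in ((7, 960), (3, 50), (40, 60)):
            lo, hi = ct.clopper_pearson_ci(x, n)
            ref_lo, ref_hi = proportion_confint(x, n, alpha=0.05, method="beta")
            assert lo == pytest.approx(100 * ref_lo, abs=1e-8)
            assert hi == pytest.approx(100 * ref_hi, abs=1e-8)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ct.clopper_pearson_ci(8, 7)
        with pytest.raises(ValueError):
            ct.clopper_pearson_ci(1, 7, level=1.2)


class TestReconstruction:
    @pytest.mark.parametrize(
        "pct,total,expected",
        [(43.0, 960, 413), (52.8, 214, 113), (17.8, 960, 171), (10.3, 214, 22),
         (26.7, 960, 256), (34.6, 214, 74), (11.8, 960, 113), (2.3, 214, 5),
         (0.7, 960, 7)],
    )
    def test_round_half_away_from_zero(self, pct, total, expected):
        assert ct.reconstruct_count(pct, total) == expected


class TestReport:
    def test_report_structure_and_conservation(self, rng):
        n_pre, n_lock = 500, 200
        labels = np.concatenate([
            rng.choice([1, 2, 3, 4], size=n_pre, p=[0.45, 0.2, 0.25, 0.1]),
            rng.choice([1, 2, 3, 4], size=n_lock, p=[0.5, 0.1, 0.35, 0.05]),
        ])
        labels[:4] = [5, 5, 6, 7]  # a few rare rows
        periods = np.array(["pre_lockdown"] * n_pre + ["lockdown"] * n_lock)
        contrasts, table, text = ct.build_report(labels, periods, top=4)
        assert len(contrasts) == 4
        assert len(table) == 5 and table.iloc[-1]["profile"] == "rare_pooled"
        for col in ("prev_pre_pct", "prev_lock_pct"):
            assert table[col].sum() == pytest.approx(100.0, abs=0.1)
        assert "chi2" in text

    def test_single_period_rejected(self):
        with pytest.raises(ct.DegenerateTableError):
            ct.build_report(np.array([1, 2]), np.array(["lockdown", "lockdown"]))

    def test_p_value_formatting(self):
        assert ct.format_p(0.0004) == "<0.001"
        assert ct.format_p(0.0123) == "0.012"
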