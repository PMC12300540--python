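"""Split-plot ANOVA, LSD mean separation, letters, contrasts, correlation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ratoonlight import splitplot
from ratoonlight.errors import DesignError, InvalidParameterError
from ratoonlight.splitplot import (
    SplitPlotAnova,
    correlate,
    letter_display,
    pct_contrast,
)


def make_layout(r, a, b, rng=None, effects=None):
    """Balanced layout; optional dict of effect callables on (rep, w, s)."""
    rows = []
    for rep, wi, si in itertools.product(range(1, r + 1), range(a), range(b)):
        y = 0.0
        if effects:
            y = effects(rep, wi, si)
        if rng is not None:
            y += rng.normal()
        rows.append({"rep": rep, "stubble": f"W{wi}", "variety": f"S{si}", "y": y})
    return pd.DataFrame(rows)


def brute_force_ss(data):
    """Explicit deviation-sum oracle for the balanced decomposition."""
    y = data["y"].to_numpy()
    grand = y.mean()
    r = data.rep.nunique()
    a = data.stubble.nunique()
    b = data.variety.nunique()
    ss = {}
    ss["Rep"] = a * b * sum(
        (data[data.rep == rep].y.mean() - grand) ** 2 for rep in data.rep.unique()
    )
    ss["Whole"] = r * b * sum(
        (data[data.stubble == w].y.mean() - grand) ** 2 for w in data.stubble.unique()
    )
    ss["Error_a"] = b * sum(
        (
            data[(data.rep == rep) & (data.stubble == w)].y.mean()
            - data[data.rep == rep].y.mean()
            - data[data.stubble == w].y.mean()
            + grand
        ) ** 2
        for rep in data.rep.unique()
        for w in data.stubble.unique()
    )
    ss["Sub"] = r * a * sum(
        (data[data.variety == s].y.mean() - grand) ** 2 for s in data.variety.unique()
    )
    ss["Sub_x_Whole"] = r * sum(
        (
            data[(data.stubble == w) & (data.variety == s)].y.mean()
            - data[data.stubble == w].y.mean()
            - data[data.variety == s].y.mean()
            + grand
        ) ** 2
        for w in data.stubble.unique()
        for s in data.variety.unique()
    )
    ss["Total"] = float(((y - grand) ** 2).sum())
    ss["Error_b"] = ss["Total"] - sum(
        ss[k] for k in ("Rep", "Whole", "Error_a", "Sub", "Sub_x_Whole")
    )
    return ss


class TestAnova:
    def test_constant_response_gives_zero_ss_and_p_one(self):
        data = make_layout(3, 2, 2, effects=lambda rep, w, s: 5.0)
        res = SplitPlotAnova(data, "y").fit()
        for src in ("Rep", "Whole", "Sub", "Sub_x_Whole", "Error_a", "Error_b"):
            assert res.anova.loc[src, "ss"] == pytest.approx(0.0, abs=1e-12)
        for src in ("Whole", "Sub", "Sub_x_Whole"):
            assert math.isnan(res.anova.loc[src, "F"])
            assert res.anova.loc[src, "p"] == 1.0

    def test_matches_brute_force_oracle_small_design(self):
        rng = np.random.default_rng(0)
        data = make_layout(3, 2, 2, rng=rng,
                           effects=lambda rep, w, s: rep + 2.0 * w + 0.5 * s + w * s)
        res = SplitPlotAnova(data, "y").fit()
        want = brute_force_ss(data)
        for src, val in want.items():
            assert res.anova.loc[src, "ss"] == pytest.approx(val, abs=1e-9)

    def test_matches_statsmodels_ols_decomposition(self):
        """Independent route: fixed-effects OLS anova_lm on the same layout."""
        smf = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(5)
        data = make_layout(3, 2, 6, rng=rng,
                           effects=lambda rep, w, s: 0.3 * rep + w + 0.2 * s)
        res = SplitPlotAnova(data, "y").fit()
        fit = smf.ols(
            "y ~ C(rep) + C(stubble) + C(rep):C(stubble) + C(variety) "
            "+ C(variety):C(stubble)",
            data=data,
        ).fit()
        tab = anova_lm(fit, typ=1)
        pairs = {
            "Rep": "C(rep)",
            "Whole": "C(stubble)",
            "Error_a": "C(rep):C(stubble)",
            "Sub": "C(variety)",
            "Sub_x_Whole": "C(variety):C(stubble)",
            "Error_b": "Residual",
        }
        for ours, theirs in pairs.items():
            assert res.anova.loc[ours, "ss"] == pytest.approx(
                tab.loc[theirs, "sum_sq"], rel=1e-9
            )
            assert res.anova.loc[ours, "df"] == tab.loc[theirs, "df"]

    def test_f_tests_use_correct_error_strata(self):
        rng = np.random.default_rng(1)
        data = make_layout(3, 2, 6, rng=rng, effects=lambda rep, w, s: w + s)
        res = SplitPlotAnova(data, "y").fit()
        t = res.anova
        assert t.loc["Whole", "F"] == pytest.approx(
            t.loc["Whole", "ms"] / t.loc["Error_a", "ms"]
        )
        assert t.loc["Sub", "F"] == pytest.approx(
            t.loc["Sub", "ms"] / t.loc["Error_b", "ms"]
        )
        assert t.loc["Error_a", "df"] == 2
        assert t.loc["Error_b", "df"] == 2 * 2 * 5  # a(r-1)(b-1)
        assert t.loc["Whole", "p"] == pytest.approx(
            float(stats.f.sf(t.loc["Whole", "F"], 1, 2))
        )

    def test_permuting_rows_leaves_ss_unchanged(self):
        rng = np.random.default_rng(9)
        data = make_layout(3, 2, 4, rng=rng, effects=lambda rep, w, s: w * s)
        res1 = SplitPlotAnova(data, "y").fit()
        res2 = SplitPlotAnova(data.sample(frac=1, random_state=4), "y").fit()
        pd.testing.assert_frame_equal(res1.anova, res2.anova)

    def test_unbalanced_layout_lists_missing_cells(self):
        data = make_layout(3, 2, 2, effects=lambda rep, w, s: 1.0).iloc[:-1]
        with pytest.raises(DesignError, match="missing cells"):
            SplitPlotAnova(data, "y")

    def test_single_level_factor_rejected(self):
        data = make_layout(3, 1, 3, effects=lambda rep, w, s: s)
        with pytest.raises(DesignError):
            SplitPlotAnova(data, "y")


class TestLsd:
    @pytest.fixture()
    def fitted(self):
        rng = np.random.default_rng(2)
        data = make_layout(3, 2, 6, rng=rng, effects=lambda rep, w, s: w + 0.5 * s)
        return SplitPlotAnova(data, "y").fit()

    def test_formulas_match_hand_computation(self, fitted):
        r, a, b = 3, 2, 6
        ms_a = fitted.anova.loc["Error_a", "ms"]
        ms_b = fitted.anova.loc["Error_b", "ms"]
        df_a = int(fitted.anova.loc["Error_a", "df"])
        df_b = int(fitted.anova.loc["Error_b", "df"])
        want_sub = stats.t.ppf(0.975, df_b) * math.sqrt(2 * ms_b / (r * a))
        want_whole = stats.t.ppf(0.975, df_a) * math.sqrt(2 * ms_a / (r * b))
        sed = math.sqrt(2 * ((b - 1) * ms_b + ms_a) / (r * b))
        t_w = (
            (b - 1) * ms_b * stats.t.ppf(0.975, df_b)
            + ms_a * stats.t.ppf(0.975, df_a)
        ) / ((b - 1) * ms_b + ms_a)
        assert fitted.lsd("sub") == pytest.approx(want_sub, abs=1e-9)
        assert fitted.lsd("whole") == pytest.approx(want_whole, abs=1e-9)
        assert fitted.lsd("whole_within_sub") == pytest.approx(t_w * sed, abs=1e-9)

    def test_scaling_response_scales_lsd_linearly(self, fitted):
        data = fitted.model.data.copy()
        data["y"] = data["y"] * math.sqrt(2)
        doubled_ms = SplitPlotAnova(data, "y").fit()
        for scope in ("sub", "whole", "whole_within_sub"):
            assert doubled_ms.lsd(scope) == pytest.approx(
                fitted.lsd(scope) * math.sqrt(2), rel=1e-9
            )

    def test_zero_subplot_error_gives_zero_lsd(self):
        data = make_layout(3, 2, 3, effects=lambda rep, w, s: float(s))
        res = SplitPlotAnova(data, "y").fit()
        assert res.lsd("sub") == pytest.approx(0.0, abs=1e-12)
        letters = res.letters("sub")
        assert letters["letters"].nunique() == 3  # all means separated

    def test_unknown_scope_rejected(self, fitted):
        with pytest.raises(InvalidParameterError):
            fitted.lsd("pairwise")


class TestLetterDisplay:
    @pytest.mark.parametrize(
        "means,lsd,expected",
        [
            ({"A": 10.0, "B": 9.9}, 0.5, {"A": "a", "B": "a"}),
            ({"A": 10.0, "B": 8.0, "C": 6.0}, 1.0, {"A": "a", "B": "b", "C": "c"}),
            ({"A": 10.0, "B": 9.5, "C": 9.0}, 0.7, {"A": "a", "B": "ab", "C": "b"}),
        ],
    )
    def test_examples(self, means, lsd, expected):
        out = letter_display(means, lsd)
        got = dict(zip(out["level"], out["letters"]))
        assert got == expected

    def test_boundary_tie_is_not_significant(self):
        out = letter_display({"A": 10.0, "B": 9.0}, 1.0)
        assert set(out["letters"]) == {"a"}

    def test_invariant_to_input_ordering(self):
        rng = np.random.default_rng(12)
        means = {f"v{i}": float(v) for i, v in enumerate(rng.uniform(0, 10, 8))}
        base = letter_display(means, 1.5)
        shuffled = dict(reversed(list(means.items())))
        again = letter_display(shuffled, 1.5)
        pd.testing.assert_frame_equal(
            base.sort_values("level").reset_index(drop=True),
            again.sort_values("level").reset_index(drop=True),
        )

    def test_sharing_constraints_on_random_means(self):
        """Pairs within the LSD share a letter; pairs beyond it share none."""
        rng = np.random.default_rng(77)
        for _ in range(25):
            vals = rng.uniform(0, 10, rng.integers(2, 9))
            means = {f"m{i}": float(v) for i, v in enumerate(vals)}
            lsd = float(rng.uniform(0.1, 5.0))
            out = letter_display(means, lsd)
            lookup = dict(zip(out["level"], out["letters"]))
            mv = dict(zip(out["level"], out["mean"]))
            for x, yv in itertools.combinations(lookup, 2):
                share = bool(set(lookup[x]) & set(lookup[yv]))
                nonsig = abs(mv[x] - mv[yv]) <= lsd
                assert share == nonsig

    def test_letters_start_at_a_for_largest_mean(self):
        out = letter_display({"lo": 1.0, "hi": 50.0}, 2.0)
        assert out.iloc[0]["level"] == "hi" and out.iloc[0]["letters"] == "a"


class TestContrast:
    @pytest.mark.parametrize(
        "hs,ls,expected",
        [(1010.9, 780.8, 29.5), (247.1, 192.0, 28.7), (5.0, 5.0, 0.0)],
    )
    def test_examples_round_to_published_values(self, hs, ls, expected):
        assert round(pct_contrast(hs, ls), 1) == pytest.approx(expected)

    def test_forward_and_reverse_contrasts_compose_to_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = rng.uniform(0.5, 100, 2)
            c1, c2 = pct_contrast(a, b), pct_contrast(b, a)
            assert (1 + c1 / 100) * (1 + c2 / 100) == pytest.approx(1.0, rel=1e-12)

    def test_zero_baseline_flags_nan(self):
        with pytest.warns(UserWarning, match="zero baseline"):
            assert math.isnan(pct_contrast(1.0, 0.0))


class TestCorrelate:
    def test_perfect_linear_relationship(self):
        x = np.arange(10, dtype=float)
        out = correlate(x, 2 * x + 1)
        assert out.r == pytest.approx(1.0)
        assert out.slope == pytest.approx(2.0)
        assert out.intercept == pytest.approx(1.0)
        assert out.p < 1e-10

    def test_independent_samples_have_near_zero_r(self):
        rng = np.random.default_rng(123)
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        assert abs(correlate(x, y).r) < 0.03

    def test_sign_equivariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        a, b = correlate(x, y), correlate(-x, y)
        assert b.r == pytest.approx(-a.r)
        assert abs(b.r) == pytest.approx(abs(a.r))

    def test_zero_variance_flags_nan(self):
        with pytest.warns(UserWarning, match="zero variance"):
            out = correlate(np.ones(5), np.arange(5.0))
        assert math.isnan(out.r)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidParameterError):
            correlate([1.0, 2.0], [1.0, 2.0])


def test_significance_codes_follow_table_footnote_convention():
    assert splitplot.significance_code(0.005) == "**"
    assert splitplot.significance_code(0.03) == "*"
    assert splitplot.significance_code(0.2) == "ns"


def test_tiny_p_prints_as_bounded_string():
    assert splitplot.format_p(1e-20) == "<1e-15"
    assert splitplot.format_p(0.0123) == "0.0123"
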