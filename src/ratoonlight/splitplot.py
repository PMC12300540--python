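"""Split-plot ANOVA with LSD mean separation and compact letter display.

The layout is the textbook balanced split-plot: a hard-to-randomise
whole-plot factor (stubble height) applied to main plots within blocks
(replicates), and a sub-plot factor (variety) randomised within them.
Blocks are treated as random; the block × whole-plot interaction is the
whole-plot error (Error a) and the residual is the sub-plot error
(Error b):

    F(whole)   = MS_whole / MS_Ea,   df (a−1, (r−1)(a−1))
    F(sub)     = MS_sub   / MS_Eb,   df (b−1, a(r−1)(b−1))
    F(sub×w)   = MS_int   / MS_Eb

Mean separation uses the unadjusted least significant difference (LSD)
at a chosen alpha, with the comparison-scope-specific standard errors of
a balanced split-plot; whole-plot comparisons within a sub-plot level
use the combined error with a Satterthwaite-weighted t critical value.

The API follows the statsmodels convention: build a
:class:`SplitPlotAnova` model from a tidy DataFrame, call ``fit()`` to
obtain a :class:`SplitPlotResults` carrying the ANOVA table, LSD values,
letter groupings and a ``summary()`` text table.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import string
import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, InvalidParameterError

_SOURCES = ("Rep", "Whole", "Error_a", "Sub", "Sub_x_Whole", "Error_b", "Total")


class SplitPlotAnova:
    """Balanced split-plot ANOVA model.

    Parameters
    ----------
    data
        Tidy observations, one row per plot.
    response
        Column holding the numeric response.
    whole_plot, sub_plot, block
        Columns holding the whole-plot factor (default ``"stubble"``),
        sub-plot factor (default ``"variety"``) and replicate block
        (default ``"rep"``).

    The design must be balanced: exactly one observation per
    (block, whole, sub) cell, with at least 2 levels of each factor.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        whole_plot: str = "stubble",
        sub_plot: str = "variety",
        block: str = "rep",
    ):
        for col in (response, whole_plot, sub_plot, block):
            if col not in data.columns:
                raise DesignError(f"column {col!r} not in data")
        self.data = data[[block, whole_plot, sub_plot, response]].copy()
        self.response = response
        self.whole_plot = whole_plot
        self.sub_plot = sub_plot
        self.block = block

        self.blocks = sorted(self.data[block].unique(), key=str)
        self.whole_levels = sorted(self.data[whole_plot].unique(), key=str)
        self.sub_levels = sorted(self.data[sub_plot].unique(), key=str)
        r, a, b = len(self.blocks), len(self.whole_levels), len(self.sub_levels)
        if r < 2 or a < 2 or b < 2:
            raise DesignError(
                f"need >= 2 levels of every factor, got r={r}, a={a}, b={b}"
            )

        counts = self.data.groupby([block, whole_plot, sub_plot], sort=True).size()
        expected = set(itertools.product(self.blocks, self.whole_levels, self.sub_levels))
        missing = sorted(expected - set(counts.index), key=str)
        extra = counts[counts > 1]
        if missing or len(extra):
            parts = []
            if missing:
                parts.append(f"missing cells: {missing}")
            if len(extra):
                parts.append(f"duplicated cells: {list(extra.index)}")
            raise DesignError("unbalanced layout; " + "; ".join(parts))
        if self.data[response].isna().any():
            raise DesignError(f"response {response!r} contains missing values")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, **kwargs) -> "SplitPlotAnova":
        return cls(data, response, **kwargs)

    @property
    def r(self) -> int:
        return len(self.blocks)

    @property
    def a(self) -> int:
        return len(self.whole_levels)

    @property
    def b(self) -> int:
        return len(self.sub_levels)

    def fit(self) -> "SplitPlotResults":
        """Compute the ANOVA decomposition and return the results object."""
        d = self.data
        y = d[self.response].to_numpy(dtype=float)
        r, a, b = self.r, self.a, self.b
        grand = y.mean()

        m_rep = d.groupby(self.block, sort=True)[self.response].mean()
        m_w = d.groupby(self.whole_plot, sort=True)[self.response].mean()
        m_s = d.groupby(self.sub_plot, sort=True)[self.response].mean()
        m_rw = d.groupby([self.block, self.whole_plot], sort=True)[self.response].mean()
        m_sw = d.groupby([self.whole_plot, self.sub_plot], sort=True)[self.response].mean()

        ss_total = float(((y - grand) ** 2).sum())
        ss_rep = a * b * float(((m_rep - grand) ** 2).sum())
        ss_w = r * b * float(((m_w - grand) ** 2).sum())
        # whole-plot error: block x whole interaction of main-plot means
        dev_rw = (
            m_rw
            - m_rep.reindex(m_rw.index.get_level_values(0)).to_numpy()
            - m_w.reindex(m_rw.index.get_level_values(1)).to_numpy()
            + grand
        )
        ss_ea = b * float((dev_rw**2).sum())
        ss_s = r * a * float(((m_s - grand) ** 2).sum())
        dev_sw = (
            m_sw
            - m_w.reindex(m_sw.index.get_level_values(0)).to_numpy()
            - m_s.reindex(m_sw.index.get_level_values(1)).to_numpy()
            + grand
        )
        ss_sw = r * float((dev_sw**2).sum())
        ss_eb = ss_total - (ss_rep + ss_w + ss_ea + ss_s + ss_sw)
        ss_eb = max(ss_eb, 0.0)  # guard tiny negative round-off

        df = {
            "Rep": r - 1,
            "Whole": a - 1,
            "Error_a": (r - 1) * (a - 1),
            "Sub": b - 1,
            "Sub_x_Whole": (a - 1) * (b - 1),
            "Error_b": a * (r - 1) * (b - 1),
            "Total": r * a * b - 1,
        }
        ss = {
            "Rep": ss_rep,
            "Whole": ss_w,
            "Error_a": ss_ea,
            "Sub": ss_s,
            "Sub_x_Whole": ss_sw,
            "Error_b": ss_eb,
            "Total": ss_total,
        }
        ms = {k: (ss[k] / df[k] if df[k] > 0 else math.nan) for k in ss}

        def f_and_p(num: str, den: str) -> tuple[float, float]:
            ms_n, ms_d = ms[num], ms[den]
            if ss[num] <= 0 and ms_d == 0:
                return math.nan, 1.0
            if ms_d == 0:
                warnings.warn(
                    f"zero {den} mean square with nonzero {num} effect; F is infinite",
                    stacklevel=3,
                )
                return math.inf, 0.0
            if ms_d != ms_d:  # NaN df guard
                return math.nan, 1.0
            f = ms_n / ms_d
            if ss[num] <= 0:
                return (0.0 if f == 0 else f), 1.0
            p = float(stats.f.sf(f, df[num], df[den]))
            return f, p

        fvals: dict[str, float] = {}
        pvals: dict[str, float] = {}
        fvals["Rep"], pvals["Rep"] = f_and_p("Rep", "Error_a")
        fvals["Whole"], pvals["Whole"] = f_and_p("Whole", "Error_a")
        fvals["Sub"], pvals["Sub"] = f_and_p("Sub", "Error_b")
        fvals["Sub_x_Whole"], pvals["Sub_x_Whole"] = f_and_p("Sub_x_Whole", "Error_b")

        table = pd.DataFrame(
            {
                "ss": [ss[k] for k in _SOURCES],
                "df": [df[k] for k in _SOURCES],
                "ms": [ms[k] for k in _SOURCES],
                "F": [fvals.get(k, math.nan) for k in _SOURCES],
                "p": [pvals.get(k, math.nan) for k in _SOURCES],
            },
            index=list(_SOURCES),
        )
        return SplitPlotResults(self, table, grand)


@dataclasses.dataclass
class SplitPlotResults:
    """Fitted split-plot ANOVA: table, LSDs, letters, summary."""

    model: SplitPlotAnova
    anova: pd.DataFrame
    grand_mean: float

    def _ms(self, source: str) -> float:
        return float(self.anova.loc[source, "ms"])

    def _df(self, source: str) -> int:
        return int(self.anova.loc[source, "df"])

    def lsd(self, scope: str = "sub", alpha: float = 0.05) -> float:
        """Least significant difference for a comparison scope.

        ``"sub"``: sub-plot (variety) means pooled over the whole-plot
        factor; ``"whole"``: whole-plot (stubble) means pooled over
        sub-plots; ``"whole_within_sub"``: whole-plot levels compared
        within one sub-plot level, using the combined Error a / Error b
        variance with a Satterthwaite-weighted t (the standard balanced
        split-plot formula).
        """
        if not 0 < alpha < 1:
            raise InvalidParameterError(f"alpha must be in (0, 1), got {alpha}")
        r, a, b = self.model.r, self.model.a, self.model.b
        ms_a, ms_b = self._ms("Error_a"), self._ms("Error_b")
        df_a, df_b = self._df("Error_a"), self._df("Error_b")
        if scope == "sub":
            if df_b <= 0:
                raise DesignError("no sub-plot error degrees of freedom")
            t = stats.t.ppf(1 - alpha / 2, df_b)
            return float(t * math.sqrt(2.0 * ms_b / (r * a)))
        if scope == "whole":
            if df_a <= 0:
                raise DesignError("no whole-plot error degrees of freedom")
            t = stats.t.ppf(1 - alpha / 2, df_a)
            return float(t * math.sqrt(2.0 * ms_a / (r * b)))
        if scope == "whole_within_sub":
            if df_a <= 0 or df_b <= 0:
                raise DesignError("insufficient replication for combined error")
            sed = math.sqrt(2.0 * ((b - 1) * ms_b + ms_a) / (r * b))
            wsum = (b - 1) * ms_b + ms_a
            if wsum == 0:
                return 0.0
            t_a = stats.t.ppf(1 - alpha / 2, df_a)
            t_b = stats.t.ppf(1 - alpha / 2, df_b)
            t_w = ((b - 1) * ms_b * t_b + ms_a * t_a) / wsum
            return float(t_w * sed)
        raise InvalidParameterError(f"unknown comparison scope {scope!r}")

    def means(self, scope: str = "sub") -> pd.Series:
        d, m = self.model.data, self.model
        if scope == "sub":
            return d.groupby(m.sub_plot, sort=True)[m.response].mean()
        if scope == "whole":
            return d.groupby(m.whole_plot, sort=True)[m.response].mean()
        raise InvalidParameterError(f"unknown means scope {scope!r}")

    def letters(self, scope: str = "sub", alpha: float = 0.05) -> pd.DataFrame:
        """Compact letter display for the means of a comparison scope."""
        means = self.means(scope)
        return letter_display(means, self.lsd(scope, alpha))

    def whole_within_sub_letters(self, alpha: float = 0.05) -> pd.DataFrame:
        """Whole-plot letters within each sub-plot level (the lowercase
        letters of a field-trial table), one block per sub-plot level."""
        m = self.model
        lsd_val = self.lsd("whole_within_sub", alpha)
        cell = m.data.groupby([m.sub_plot, m.whole_plot], sort=True)[m.response].mean()
        out = []
        for sub in m.sub_levels:
            block = letter_display(cell.loc[sub], lsd_val)
            block.insert(0, m.sub_plot, sub)
            out.append(block)
        return pd.concat(out, ignore_index=True)

    def summary(self, alpha: float = 0.05) -> str:
        """Human-readable ANOVA and mean-separation summary."""
        m = self.model
        lines = [
            f"Split-plot ANOVA: {m.response}",
            f"  blocks ({m.block}): {m.r}; whole-plot ({m.whole_plot}): {m.a} levels; "
            f"sub-plot ({m.sub_plot}): {m.b} levels",
            "",
            f"{'source':<14}{'SS':>14}{'df':>5}{'MS':>14}{'F':>10}{'p':>12}  sig",
        ]
        display = {
            "Rep": m.block,
            "Whole": m.whole_plot,
            "Error_a": "Error (a)",
            "Sub": m.sub_plot,
            "Sub_x_Whole": f"{m.sub_plot} x {m.whole_plot}",
            "Error_b": "Error (b)",
            "Total": "Total",
        }
        for src in _SOURCES:
            row = self.anova.loc[src]
            fstr = "" if math.isnan(row["F"]) else f"{row['F']:.3f}"
            pstr = "" if math.isnan(row["p"]) else format_p(row["p"])
            sig = "" if math.isnan(row["p"]) else significance_code(row["p"])
            lines.append(
                f"{display[src]:<14}{row['ss']:>14.4f}{int(row['df']):>5}"
                f"{row['ms']:>14.4f}{fstr:>10}{pstr:>12}  {sig}"
            )
        lines.append("")
        lines.append(f"LSD({alpha}) {m.sub_plot}: {self.lsd('sub', alpha):.4f}; "
                     f"{m.whole_plot}: {self.lsd('whole', alpha):.4f}; "
                     f"{m.whole_plot} within {m.sub_plot}: "
                     f"{self.lsd('whole_within_sub', alpha):.4f}")
        for scope in ("sub", "whole"):
            tab = self.letters(scope, alpha)
            lines.append(f"  {scope} means: " + "; ".join(
                f"{row['level']}={row['mean']:.3f} {row['letters']}"
                for _, row in tab.iterrows()
            ))
        return "\n".join(lines)


def letter_display(means: pd.Series | Mapping[str, float], lsd_value: float) -> pd.DataFrame:
    """Compact letter display from labelled means and a single LSD.

    Means are sorted descending; two means differing by strictly more
    than ``lsd_value`` are significantly different (ties exactly at the
    LSD are non-significant).  Letters are assigned by insert-and-absorb
    on the induced significance graph, starting at ``a`` for the largest
    mean; the result is invariant to input ordering.
    """
    if lsd_value < 0:
        raise InvalidParameterError(f"LSD must be >= 0, got {lsd_value}")
    s = pd.Series(dict(means)) if not isinstance(means, pd.Series) else means
    s = s.sort_values(ascending=False, kind="mergesort")
    labels, vals = list(s.index), s.to_numpy(dtype=float)
    k = len(vals)
    # With a common LSD the non-significance graph over sorted means is an
    # interval graph: each maximal run with spread <= LSD is one letter.
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and vals[i] - vals[j + 1] <= lsd_value:
            j += 1
        intervals.append((i, j))
    maximal = [
        (i, j)
        for (i, j) in intervals
        if not any((p <= i and j <= q) and (p, q) != (i, j) for p, q in intervals)
    ]
    # dedupe while keeping order
    seen: list[tuple[int, int]] = []
    for iv in maximal:
        if iv not in seen:
            seen.append(iv)
    alphabet = string.ascii_lowercase
    letters = ["" for _ in range(k)]
    for idx, (i, j) in enumerate(seen):
        if idx >= len(alphabet):
            raise InvalidParameterError("more letter groups than letters available")
        for pos in range(i, j + 1):
            letters[pos] += alphabet[idx]
    return pd.DataFrame({"level": labels, "mean": vals, "letters": letters})


def pct_contrast(mean_hs: float, mean_ls: float) -> float:
    """Percent change of the treatment mean relative to the baseline.

    ``100 · (mean_hs − mean_ls) / mean_ls`` on unrounded means; the
    reporting layer rounds to one decimal.  A zero baseline yields NaN
    with a warning (flagged undefined contrast).
    """
    if mean_ls == 0:
        warnings.warn("percent contrast undefined for zero baseline", stacklevel=2)
        return math.nan
    return 100.0 * (mean_hs - mean_ls) / mean_ls


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    slope: float
    intercept: float
    n: int


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with the OLS fit line for a trait scatter.

    Returns r, the two-sided t-test p-value (n − 2 df), and the
    least-squares slope and intercept.  Zero variance in either variable
    yields a flagged NaN result rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("x and y must be 1-D and equal length")
    if x.size < 3:
        raise InvalidParameterError(f"need at least 3 points, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InvalidParameterError("x and y must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance; correlation undefined", stacklevel=2)
        return CorrelationResult(math.nan, math.nan, math.nan, math.nan, int(x.size))
    fit = stats.linregress(x, y)
    return CorrelationResult(
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=int(x.size),
    )


def significance_code(p: float) -> str:
    """``**`` for p < 0.01, ``*`` for p < 0.05, else ``ns``."""
    if math.isnan(p):
        return "ns"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def format_p(p: float) -> str:
    """p below machine precision prints as '<1e-15', never 0."""
    if math.isnan(p):
        return "nan"
    if p < 1e-15:
        return "<1e-15"
    return f"{p:.4g}"
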