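"""Inference layer: balanced two-way fixed-effects ANOVA with interaction,
gatekept Tukey HSD, pooled-variance Student's t, and a Pearson correlation
matrix.

Everything is computed from first principles — explicit sums of squares and
a numerically integrated studentized-range distribution — so each piece can
be checked against an independent oracle.  Only the classical F and t
distributions come from scipy.

The analysis unit is the biological replicate: multiple imaged fields are
averaged per replicate before any test, which avoids pseudo-replication.
Designs must be balanced and complete; unbalanced input is an error (the
caller should pre-aggregate per replicate), not a silent fallback to
Type-III sums of squares.

Gatekeeping follows the factorial-ANOVA-then-Tukey convention: when the
interaction is significant, Tukey runs on the individual cell means; else,
for each significant main effect, Tukey runs on that factor's marginal
(collapsed-over-the-other-factor) means.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field
from math import lgamma, log, sqrt

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sps

__all__ = [
    "AnovaTable",
    "TukeyResult",
    "CorrelationMatrix",
    "two_way_anova",
    "tukey_hsd",
    "gatekept_posthoc",
    "students_t",
    "pearson_matrix",
    "studentized_range_cdf",
]


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaTable:
    """Fixed-effects decomposition for a balanced a x b design.

    Rows (``sources``): factor A, factor B, the A x B interaction, and the
    residual.  Sums of squares add up to the total on balanced designs.
    """

    sources: list[str]
    ss: dict[str, float]
    df: dict[str, int]
    ms: dict[str, float]
    f: dict[str, float]
    p: dict[str, float]
    ss_total: float
    n_obs: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": s,
                "sum_sq": self.ss[s],
                "df": self.df[s],
                "mean_sq": self.ms[s],
                "F": self.f.get(s, float("nan")),
                "p": self.p.get(s, float("nan")),
            }
            for s in self.sources + ["residual"]
        ]
        return pd.DataFrame(rows)


def _check_balanced(values, factor_a, factor_b):
    values = np.asarray(values, dtype=float)
    factor_a = np.asarray(factor_a)
    factor_b = np.asarray(factor_b)
    if not (len(values) == len(factor_a) == len(factor_b)):
        raise ValueError("values and factors must have equal length")
    a_levels = list(dict.fromkeys(factor_a.tolist()))
    b_levels = list(dict.fromkeys(factor_b.tolist()))
    counts = {}
    for a in a_levels:
        for b in b_levels:
            n = int(np.sum((factor_a == a) & (factor_b == b)))
            counts[(a, b)] = n
    ns = set(counts.values())
    if 0 in ns:
        missing = [k for k, v in counts.items() if v == 0]
        raise ValueError(f"design incomplete: empty cells {missing}")
    if len(ns) != 1:
        raise ValueError(
            f"unbalanced design (cell sizes {sorted(ns)}); aggregate to one "
            "value per replicate per cell first"
        )
    n = ns.pop()
    if n < 2:
        raise ValueError("need >= 2 observations per cell")
    return values, factor_a, factor_b, a_levels, b_levels, n


def two_way_anova(values, factor_a, factor_b) -> AnovaTable:
    """Balanced two-way fixed-effects ANOVA with interaction.

    Classical mean-based decomposition: SS_A from factor-A marginal means,
    SS_B likewise, SS_AB from cell means minus the additive part, SS_resid
    within cells.  F statistics are tested against the residual mean
    square with exact F-distribution p-values.
    """
    values, fa, fb, a_levels, b_levels, n = _check_balanced(
        values, factor_a, factor_b
    )
    a, b = len(a_levels), len(b_levels)
    grand = values.mean()
    mean_a = {lv: values[fa == lv].mean() for lv in a_levels}
    mean_b = {lv: values[fb == lv].mean() for lv in b_levels}
    mean_cell = {
        (la, lb): values[(fa == la) & (fb == lb)].mean()
        for la in a_levels
        for lb in b_levels
    }

    ss_a = b * n * sum((mean_a[lv] - grand) ** 2 for lv in a_levels)
    ss_b = a * n * sum((mean_b[lv] - grand) ** 2 for lv in b_levels)
    ss_cells = n * sum(
        (mean_cell[(la, lb)] - grand) ** 2 for la in a_levels for lb in b_levels
    )
    ss_ab = ss_cells - ss_a - ss_b
    resid = values - np.array([mean_cell[(la, lb)] for la, lb in zip(fa, fb)])
    ss_e = float(np.sum(resid**2))
    ss_t = float(np.sum((values - grand) ** 2))

    df = {
        "factor_a": a - 1,
        "factor_b": b - 1,
        "interaction": (a - 1) * (b - 1),
        "residual": a * b * (n - 1),
    }
    ss = {
        "factor_a": float(ss_a),
        "factor_b": float(ss_b),
        "interaction": float(ss_ab),
        "residual": ss_e,
    }
    ms = {s: (ss[s] / df[s] if df[s] > 0 else float("nan")) for s in ss}
    f_stats, p_vals = {}, {}
    for s in ("factor_a", "factor_b", "interaction"):
        if ms["residual"] > 0:
            f_stats[s] = ms[s] / ms["residual"]
            p_vals[s] = float(sps.f.sf(f_stats[s], df[s], df["residual"]))
        else:
            # zero within-cell variance: any between-cell variation is
            # infinitely significant, none at all is p = 1
            f_stats[s] = float("inf") if ms[s] > 0 else 0.0
            p_vals[s] = 0.0 if ms[s] > 0 else 1.0
    return AnovaTable(
        sources=["factor_a", "factor_b", "interaction"],
        ss=ss,
        df=df,
        ms=ms,
        f=f_stats,
        p=p_vals,
        ss_total=ss_t,
        n_obs=len(values),
    )


# ---------------------------------------------------------------------------
# studentized range and Tukey HSD
# ---------------------------------------------------------------------------


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(160)


def _gl_grid(lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    half = 0.5 * (hi - lo)
    return lo + half * (_GL_NODES + 1.0), half * _GL_WEIGHTS


def _srange_cdf_given_scale(q: float, k: int, u: np.ndarray) -> np.ndarray:
    """P(range of k standard normals <= q*u), vectorized over scales u.

    Inner integral k * int phi(z) [Phi(z) - Phi(z - q u)]^{k-1} dz over a
    fixed 160-point Gauss-Legendre grid (the integrand is smooth and the
    tails below -8 / above 8 + q*u are < 1e-15).
    """
    qu = np.atleast_1d(q * u)  # (m,)
    z, w = _gl_grid(-8.0, 8.0 + float(qu.max()))  # (n,)
    phi = sps.norm.pdf(z)
    big_phi = sps.norm.cdf(z)
    inner = big_phi[None, :] - sps.norm.cdf(z[None, :] - qu[:, None])
    vals = k * np.sum((w * phi)[None, :] * np.clip(inner, 0.0, None) ** (k - 1), axis=1)
    return np.clip(vals, 0.0, 1.0)


def studentized_range_cdf(q: float, k: int, df: float) -> float:
    """CDF of the studentized range Q_{k,df} by direct numerical integration.

    The scale u = s/sigma follows the distribution of sqrt(chi2_df/df); the
    CDF integrates the conditional range probability over that density on a
    fixed Gauss-Legendre grid.  Absolute accuracy is well below 1e-8 for
    the df encountered in practice.
    """
    if q <= 0:
        return 0.0
    if k < 2:
        raise ValueError("k must be >= 2")
    if df <= 0:
        raise ValueError("df must be > 0")
    if np.isinf(df):
        return float(_srange_cdf_given_scale(q, k, np.array([1.0]))[0])
    # density of u = sqrt(chi2_df/df):
    #   f(u) = df^{df/2} u^{df-1} exp(-df u^2/2) / (Gamma(df/2) 2^{df/2-1})
    log_c = 0.5 * df * log(df) - lgamma(df / 2.0) - (df / 2.0 - 1.0) * log(2.0)
    # u concentrates around 1 with sd ~ 1/sqrt(2 df); pad generously
    hi = 1.0 + 12.0 / sqrt(2.0 * df)
    u, w = _gl_grid(1e-12, hi)
    log_fu = log_c + (df - 1.0) * np.log(u) - df * u * u / 2.0
    val = float(np.sum(w * np.exp(log_fu) * _srange_cdf_given_scale(q, k, u)))
    return min(max(val, 0.0), 1.0)


@dataclass
class TukeyResult:
    """All-pairs Tukey HSD comparisons for one family.

    ``family`` names the comparison set (a factor for marginal means,
    "cells" for cell means); each row of ``to_frame()`` is one pair with
    its mean difference, studentized-range q, adjusted p, and significance
    at ``alpha``.
    """

    family: str
    comparisons: list[dict] = dc_field(default_factory=list)
    alpha: float = 0.05
    ms_within: float = float("nan")
    df_within: int = 0
    note: str = ""

    def to_frame(self) -> pd.DataFrame:
        if not self.comparisons:
            return pd.DataFrame(
                columns=["family", "group_1", "group_2", "mean_diff", "q", "p_adj", "significant"]
            )
        return pd.DataFrame(
            [{"family": self.family, **c} for c in self.comparisons]
        )


def tukey_hsd(
    group_values: dict[str, "np.ndarray | list[float]"],
    alpha: float = 0.05,
    ms_within: float | None = None,
    df_within: int | None = None,
    family: str = "groups",
) -> TukeyResult:
    """Tukey (Tukey-Kramer for unequal n) all-pairs comparisons.

    q = |mean_i - mean_j| / sqrt(MS_within/2 * (1/n_i + 1/n_j)); the
    adjusted p is the studentized-range survival probability with
    parameters (k groups, residual df).  ``ms_within``/``df_within``
    default to the pooled within-group variance of the supplied groups but
    can be overridden with a surrounding model's residual mean square
    (as the gatekept factorial procedure does).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in group_values.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for name, g in groups.items():
        if g.size < 2:
            raise ValueError(f"group {name!r} has n < 2")
    k = len(groups)
    if ms_within is None:
        sse = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups.values())
        dfe = sum(g.size - 1 for g in groups.values())
        ms_within = sse / dfe
        df_within = dfe
    if df_within is None or df_within <= 0:
        raise ValueError("df_within must be > 0")

    comparisons = []
    for (na, ga), (nb, gb) in itertools.combinations(groups.items(), 2):
        diff = float(ga.mean() - gb.mean())
        if ms_within > 0:
            se = sqrt(ms_within / 2.0 * (1.0 / ga.size + 1.0 / gb.size))
            q = abs(diff) / se
            p = 1.0 - studentized_range_cdf(q, k, df_within)
        else:
            q = float("inf") if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        comparisons.append(
            {
                "group_1": na,
                "group_2": nb,
                "mean_diff": diff,
                "q": q,
                "p_adj": min(max(p, 0.0), 1.0),
                "significant": p < alpha,
            }
        )
    return TukeyResult(
        family=family,
        comparisons=comparisons,
        alpha=alpha,
        ms_within=float(ms_within),
        df_within=int(df_within),
    )


def gatekept_posthoc(
    anova_table: AnovaTable,
    data: pd.DataFrame,
    alpha: float = 0.05,
    value_col: str = "value",
    a_col: str = "factor_a",
    b_col: str = "factor_b",
) -> list[TukeyResult]:
    """ANOVA-gatekept Tukey comparisons.

    Significant interaction -> Tukey on the a x b cell means.  Otherwise,
    each significant main effect gets Tukey on its marginal means (the
    other factor collapsed), using the factorial model's residual mean
    square and df.  Nothing significant -> an empty result carrying a note.
    """
    ms_w = anova_table.ms["residual"]
    df_w = anova_table.df["residual"]
    out: list[TukeyResult] = []
    if anova_table.p["interaction"] < alpha:
        cells = {
            f"{la}:{lb}": grp[value_col].to_numpy()
            for (la, lb), grp in data.groupby([a_col, b_col], sort=False)
        }
        out.append(
            tukey_hsd(cells, alpha, ms_within=ms_w, df_within=df_w, family="cells")
        )
        return out
    for src, col in (("factor_a", a_col), ("factor_b", b_col)):
        if anova_table.p[src] < alpha:
            marg = {
                str(lv): grp[value_col].to_numpy()
                for lv, grp in data.groupby(col, sort=False)
            }
            if len(marg) >= 2:
                out.append(
                    tukey_hsd(
                        marg, alpha, ms_within=ms_w, df_within=df_w, family=col
                    )
                )
    if not out:
        out.append(
            TukeyResult(
                family="none",
                alpha=alpha,
                ms_within=ms_w,
                df_within=df_w,
                note="no significant ANOVA source; no comparisons performed",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Student's t and Pearson
# ---------------------------------------------------------------------------


def students_t(group, control, welch: bool = False) -> tuple[float, float, float]:
    """Two-sided independent-samples t-test of group vs control.

    Pooled-variance (classical Student) by default; ``welch=True`` drops
    the equal-variance assumption.  Returns (t, df, p).
    """
    x = np.asarray(group, dtype=float)
    y = np.asarray(control, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need n >= 2")
    if welch:
        res = sps.ttest_ind(x, y, equal_var=False)
        return float(res.statistic), float(res.df), float(res.pvalue)
    nx, ny = x.size, y.size
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0:
        if diff == 0:
            return 0.0, float(df), 1.0
        return float(np.sign(diff)) * float("inf"), float(df), 0.0
    t = diff / sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), float(df), p


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations with p-values and per-pair n."""

    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        out = []
        for i, a in enumerate(self.variables):
            for b in self.variables[i + 1:]:
                if np.isfinite(self.p.loc[a, b]) and self.p.loc[a, b] < alpha:
                    out.append((a, b))
        return out


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        return float("nan"), float("nan"), n
    xd = x - x.mean()
    yd = y - y.mean()
    sxx = float(np.sum(xd * xd))
    syy = float(np.sum(yd * yd))
    if sxx == 0 or syy == 0:
        return float("nan"), float("nan"), n  # constant variable: undefined
    r = float(np.sum(xd * yd)) / sqrt(sxx * syy)
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return r, p, n


def pearson_matrix(variable_table: pd.DataFrame) -> CorrelationMatrix:
    """Product-moment correlation matrix over a table of variables.

    Missing values are handled pairwise-complete; p-values come from the
    exact t transform t = r sqrt((n-2)/(1-r^2)), two-sided.  Pairs
    involving a constant variable are NaN (flagged by omission from
    ``significant_pairs``).
    """
    cols = [c for c in variable_table.columns if pd.api.types.is_numeric_dtype(variable_table[c])]
    if len(cols) < 2:
        raise ValueError("need >= 2 numeric variables")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    n = pd.DataFrame(0, index=cols, columns=cols)
    for c in cols:
        n.loc[c, c] = int(variable_table[c].notna().sum())
        p.loc[c, c] = 0.0
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            ri, pi, ni = _pearson(
                variable_table[a].to_numpy(dtype=float),
                variable_table[b].to_numpy(dtype=float),
            )
            r.loc[a, b] = r.loc[b, a] = ri
            p.loc[a, b] = p.loc[b, a] = pi
            n.loc[a, b] = n.loc[b, a] = ni
    return CorrelationMatrix(variables=cols, r=r, p=p, n=n)
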