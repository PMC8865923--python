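"""Statistical primitives: Kruskal-Wallis, paired t, Benjamini-Hochberg FDR,
and linear / random-intercept models for diversity responses.

The rank and t statistics are computed from their defining formulas (ranking
delegated to scipy's tie-aware rankdata; tail probabilities to scipy
distributions) so that they can be cross-checked against independent
reference implementations in the test suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

FLAG_TIES = "ties"
FLAG_ZERO_VARIANCE = "zero_variance"
FLAG_SINGULAR_FIT = "singular_fit"
FLAG_TWO_SAMPLE_FALLBACK = "degenerate_two_sample"


@dataclass
class TestResult:
    statistic: float
    statistic_name: str
    p_value: float
    n: int
    q_value: float | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not np.isnan(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")
        if (
            self.q_value is not None
            and not np.isnan(self.q_value)
            and self.q_value < self.p_value - 1e-12
        ):
            raise ValueError("q-value below p-value")


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from chi-square (k-1 df).

    H = 12/(N(N+1)) * sum R_j^2/n_j - 3(N+1), divided by
    1 - sum(t^3 - t)/(N^3 - N) over tie groups.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    n_total = pooled.size
    if n_total < 3:
        raise ValueError("need total n >= 3")
    ranks = sps.rankdata(pooled)
    flags: list[str] = []
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(((counts**3) - counts).sum())
    denom = 1.0 - tie_sum / (n_total**3 - n_total)
    if denom <= 0.0:
        # every observation identical: no variation at all
        return TestResult(
            statistic=0.0,
            statistic_name="H",
            p_value=1.0,
            n=n_total,
            flags=(FLAG_TIES, FLAG_ZERO_VARIANCE),
        )
    if tie_sum > 0:
        flags.append(FLAG_TIES)
    h /= denom
    df = len(groups) - 1
    p = float(sps.chi2.sf(h, df))
    return TestResult(
        statistic=float(h), statistic_name="H", p_value=p, n=n_total,
        flags=tuple(flags),
    )


def paired_t(x, y) -> TestResult:
    """Two-sided paired t test: t = mean(d) / (sd(d)/sqrt(n)), d = x - y,
    p from the t distribution with n-1 df. Zero-variance differences yield
    a flagged result with missing p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        return TestResult(
            statistic=float("nan"), statistic_name="t", p_value=float("nan"),
            n=n, flags=(FLAG_ZERO_VARIANCE,),
        )
    t = d.mean() / (sd / np.sqrt(n))
    p = float(2 * sps.t.sf(abs(t), n - 1))
    return TestResult(statistic=float(t), statistic_name="t", p_value=p, n=n)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, capped at 1.
    NaN entries propagate as NaN and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    qv = np.empty(m)
    qv[order] = ranked
    q[ok] = qv
    return q


def _design_matrix(df: pd.DataFrame, fixed: list[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded dummies / centered numeric columns."""
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for term in fixed:
        v = df[term]
        if pd.api.types.is_numeric_dtype(v) and v.nunique() > 2:
            cols.append(v.to_numpy(dtype=float))
            names.append(term)
        else:
            levels = sorted(v.astype(str).unique())
            for lev in levels[1:]:
                cols.append((v.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{term}[{lev}]")
    return np.column_stack(cols), names


def diversity_model(
    data: pd.DataFrame,
    response: str,
    fixed: list[str],
    random_intercept: str | None = None,
) -> pd.DataFrame:
    """Fit a Gaussian linear model (or random-intercept mixed model) of a
    per-sample diversity response on design factors.

    Returns a coefficient table (term, estimate, se, statistic, p_value,
    flags). Aliased design columns are dropped and reported; a degenerate
    random-intercept fit (one observation per group, or singular variance)
    falls back to least squares with a ``singular_fit`` flag.
    """
    import statsmodels.api as sm

    df = data.dropna(subset=[response] + fixed).copy()
    x, names = _design_matrix(df, fixed)
    y = df[response].to_numpy(dtype=float)
    # drop aliased columns by QR rank
    flags: list[str] = []
    r = np.linalg.qr(x, mode="r")
    diag = np.abs(np.diag(r))
    tol = max(x.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    keep = []
    for j in range(x.shape[1]):
        xj = x[:, keep + [j]]
        if np.linalg.matrix_rank(xj, tol=None) == len(keep) + 1:
            keep.append(j)
    if len(keep) < x.shape[1]:
        dropped = [names[j] for j in range(x.shape[1]) if j not in keep]
        logger.warning("dropping aliased design columns: %s", dropped)
        flags.append("aliased_columns_dropped")
        x = x[:, keep]
        names = [names[j] for j in keep]

    if np.allclose(y, y[0]):
        # constant response: all slopes exactly zero
        out = pd.DataFrame(
            {
                "term": names,
                "estimate": [y[0]] + [0.0] * (len(names) - 1),
                "se": 0.0,
                "statistic": np.nan,
                "p_value": np.nan,
            }
        )
        out["flags"] = FLAG_ZERO_VARIANCE
        return out

    use_mixed = random_intercept is not None
    if use_mixed:
        grp = df[random_intercept].astype(str)
        if grp.value_counts().max() == 1:
            logger.warning(
                "one observation per %s: random-intercept variance "
                "unidentifiable; falling back to least squares",
                random_intercept,
            )
            flags.append(FLAG_SINGULAR_FIT)
            use_mixed = False

    if use_mixed:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = sm.MixedLM(y, x, groups=df[random_intercept].astype(str))
            fit = model.fit(reml=False)
        singular = any("singular" in str(w.message).lower() for w in caught) or (
            float(np.asarray(fit.cov_re).ravel()[0]) < 1e-10
        )
        if singular:
            flags.append(FLAG_SINGULAR_FIT)
        params = fit.params[: len(names)]
        ses = fit.bse[: len(names)]
        stat = params / ses
        pvals = fit.pvalues[: len(names)]
    else:
        fit = sm.OLS(y, x).fit()
        params, ses, stat, pvals = fit.params, fit.bse, fit.tvalues, fit.pvalues

    out = pd.DataFrame(
        {
            "term": names,
            "estimate": np.asarray(params, dtype=float),
            "se": np.asarray(ses, dtype=float),
            "statistic": np.asarray(stat, dtype=float),
            "p_value": np.asarray(pvals, dtype=float),
        }
    )
    out["flags"] = ",".join(flags)
    return out
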