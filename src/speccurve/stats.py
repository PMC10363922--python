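"""Rank-based correlation and two-sample statistics.

Conventions, fixed package-wide:

* Spearman's rho is the Pearson correlation of average ranks, with
  pairwise-complete deletion; p comes from the t approximation with
  n−2 degrees of freedom; the 95% CI from Fisher's z transform with
  standard error 1/sqrt(n−3) (Bonett–Wright SE selectable).
* The partial Spearman correlation rank-transforms every variable on the
  listwise-complete cases, residualizes the x- and y-ranks on the
  covariate ranks by least squares, and correlates the residuals; p uses
  n−2−k df and the CI standard error 1/sqrt(n−3−k) for k covariates.
* The Wilcoxon rank-sum test uses the normal approximation with tie
  correction and a 0.5 continuity correction; the reported statistic is
  U of the first sample (the first sample's rank sum minus
  n_a(n_a+1)/2), the convention R's ``wilcox.test`` prints as W.  Effect
  size r = |Z|/sqrt(N) with a percentile-bootstrap CI.
* Welch's t test uses the unequal-variance statistic with
  Welch–Satterthwaite degrees of freedom.

Fewer complete pairs than the minimum (4, plus one per covariate) give a
missing-marked result rather than an exception, so multiverse cells with
too little data are counted, not fatal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats as sps

#: Fewest complete pairs for a valid plain correlation.
MIN_COMPLETE_PAIRS = 4


def average_ranks(a: np.ndarray) -> np.ndarray:
    """Average (midrank) ranks, 1-based; ties share their mean rank.

    Equivalent to ``scipy.stats.rankdata(a, method="average")`` but
    cheap enough for the million-correlation permutation loops.
    """
    a = np.asarray(a)
    n = len(a)
    order = np.argsort(a, kind="stable")
    sa = a[order]
    change = np.empty(n, dtype=bool)
    change[0] = True
    np.not_equal(sa[1:], sa[:-1], out=change[1:])
    gid = np.cumsum(change) - 1
    starts = np.flatnonzero(change)
    counts = np.diff(np.append(starts, n))
    avg = starts + (counts + 1) / 2.0
    ranks = np.empty(n)
    ranks[order] = avg[gid]
    return ranks


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation with its t-approximation p and Fisher-z 95% CI."""

    rho: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int
    n_covariates: int = 0

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.rho)


@dataclass(frozen=True)
class TwoSampleResult:
    """A two-sample test with effect size r and its bootstrap CI."""

    statistic: float
    p_value: float
    effect_r: float
    effect_r_ci_low: float
    effect_r_ci_high: float
    n_x: int
    n_y: int
    method: str = ""

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.statistic)


def _missing_corr(n: int, k: int = 0) -> CorrelationResult:
    return CorrelationResult(np.nan, np.nan, np.nan, np.nan, int(n), k)


def _as_float(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def _fisher_ci(rho: float, se: float) -> tuple[float, float]:
    if not np.isfinite(se) or se <= 0 or abs(rho) >= 1:
        # CI collapses at |rho| = 1 (zero-width on the z scale's limit)
        return (rho, rho) if abs(rho) >= 1 else (np.nan, np.nan)
    z = np.arctanh(rho)
    half = 1.959963984540054 * se
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def _corr_of(xr: np.ndarray, yr: np.ndarray) -> float:
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return np.nan
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _t_p_value(rho: float, df: int) -> float:
    if df <= 0 or not np.isfinite(rho):
        return np.nan
    if abs(rho) >= 1:
        return 0.0
    t = rho * np.sqrt(df / (1.0 - rho * rho))
    return float(2.0 * special.stdtr(df, -abs(t)))


def spearman(x, y, *, min_n: int = MIN_COMPLETE_PAIRS,
             ci_method: str = "fisher") -> CorrelationResult:
    """Spearman correlation with pairwise-complete deletion.

    ``ci_method`` is ``"fisher"`` (SE = 1/sqrt(n−3)) or
    ``"bonett-wright"`` (SE = sqrt((1 + rho²/2)/(n−3))).
    """
    x, y = _as_float(x), _as_float(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < min_n:
        return _missing_corr(n)
    xr = average_ranks(x[mask])
    yr = average_ranks(y[mask])
    rho = _corr_of(xr, yr)
    if not np.isfinite(rho):
        return _missing_corr(n)
    p = _t_p_value(rho, n - 2)
    if ci_method == "bonett-wright":
        se = np.sqrt((1.0 + rho * rho / 2.0) / (n - 3)) if n > 3 else np.nan
    elif ci_method == "fisher":
        se = 1.0 / np.sqrt(n - 3) if n > 3 else np.nan
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    lo, hi = _fisher_ci(rho, se)
    return CorrelationResult(rho, p, lo, hi, n, 0)


def partial_spearman(x, y, covariates, *,
                     min_n: int | None = None,
                     ci_method: str = "fisher") -> CorrelationResult:
    """Partial Spearman correlation, covariates removed on the rank scale.

    Listwise-complete deletion over x, y and all covariates.  Constant
    covariates (on the complete cases) are dropped with a warning.
    """
    x, y = _as_float(x), _as_float(y)
    covs = [_as_float(c) for c in covariates]
    for c in covs:
        if c.shape != x.shape:
            raise ValueError("covariates must match x/y length")
    if not covs:
        return spearman(x, y, min_n=min_n or MIN_COMPLETE_PAIRS,
                        ci_method=ci_method)
    mask = np.isfinite(x) & np.isfinite(y)
    for c in covs:
        mask &= np.isfinite(c)
    n = int(mask.sum())
    kept = []
    for i, c in enumerate(covs):
        if n > 0 and np.ptp(c[mask]) == 0:
            warnings.warn(f"covariate {i} is constant on the complete "
                          "cases; dropped", stacklevel=2)
        else:
            kept.append(c)
    k = len(kept)
    if k == 0:
        return spearman(np.where(mask, x, np.nan), np.where(mask, y, np.nan),
                        min_n=min_n or MIN_COMPLETE_PAIRS, ci_method=ci_method)
    need = (MIN_COMPLETE_PAIRS + k) if min_n is None else min_n
    if n < need:
        return _missing_corr(n, k)
    xr = average_ranks(x[mask])
    yr = average_ranks(y[mask])
    design = np.column_stack(
        [np.ones(n)] + [average_ranks(c[mask]) for c in kept])
    coef, *_ = np.linalg.lstsq(design, np.column_stack([xr, yr]),
                               rcond=None)
    resid = np.column_stack([xr, yr]) - design @ coef
    rx, ry = resid[:, 0], resid[:, 1]
    # a variable fully explained by the covariates has no remaining rank
    # variance: report zero partial association, not numerical noise
    tss = ((xr - xr.mean()) @ (xr - xr.mean())) * \
        ((yr - yr.mean()) @ (yr - yr.mean()))
    if (rx @ rx) * (ry @ ry) < 1e-16 * max(tss, 1.0):
        return CorrelationResult(0.0, 1.0, np.nan, np.nan, n, k)
    rho = _corr_of(rx, ry)
    if not np.isfinite(rho):
        return _missing_corr(n, k)
    p = _t_p_value(rho, n - 2 - k)
    if ci_method == "bonett-wright":
        se = (np.sqrt((1.0 + rho * rho / 2.0) / (n - 3 - k))
              if n > 3 + k else np.nan)
    elif ci_method == "fisher":
        se = 1.0 / np.sqrt(n - 3 - k) if n > 3 + k else np.nan
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    lo, hi = _fisher_ci(rho, se)
    return CorrelationResult(rho, p, lo, hi, n, k)


# ---------------------------------------------------------------------------
# Two-sample tests
# ---------------------------------------------------------------------------

def _rank_sum_z(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(U of the first sample, continuity-corrected |Z|) or (U, nan)."""
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = average_ranks(pooled)
    r_a = ranks[:n_a].sum()
    u = r_a - n_a * (n_a + 1) / 2.0
    mu = n_a * n_b / 2.0
    n = n_a + n_b
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts.astype(float) ** 3 - counts).sum()
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    if var <= 0:
        return float(u), np.nan
    z = max(abs(u - mu) - 0.5, 0.0) / np.sqrt(var)
    return float(u), float(z)


def wilcoxon_rank_sum_cc(a, b, *, bootstrap_reps: int = 2000,
                         rng=None) -> TwoSampleResult:
    """Two-sided Wilcoxon rank-sum test with continuity correction.

    The statistic is U of the first sample (R's W).  effect_r = |Z|/sqrt(N)
    with a seeded percentile-bootstrap 95% CI (``bootstrap_reps`` = 0
    skips the CI).
    """
    a = _as_float(a)
    b = _as_float(b)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must contain non-missing values")
    u, z = _rank_sum_z(a, b)
    if np.isfinite(z):
        p = float(min(2.0 * special.ndtr(-z), 1.0))
        r = z / np.sqrt(len(a) + len(b))
    else:  # all pooled values identical: no evidence of a shift
        p, r = 1.0, 0.0
    lo = hi = np.nan
    if bootstrap_reps > 0:
        rng = np.random.default_rng(rng)
        rs = np.empty(bootstrap_reps)
        n = len(a) + len(b)
        for i in range(bootstrap_reps):
            ra = rng.choice(a, size=len(a), replace=True)
            rb = rng.choice(b, size=len(b), replace=True)
            _, zb = _rank_sum_z(ra, rb)
            rs[i] = zb / np.sqrt(n) if np.isfinite(zb) else 0.0
        lo, hi = np.percentile(rs, [2.5, 97.5])
    return TwoSampleResult(u, p, r, float(lo), float(hi),
                           len(a), len(b), "wilcoxon_rank_sum_cc")


def welch_t(a, b, *, bootstrap_reps: int = 0, rng=None) -> TwoSampleResult:
    """Welch's unequal-variance t test, two-sided.

    effect_r = sqrt(t² / (t² + df)); the bootstrap CI is optional and off
    by default.
    """
    a = _as_float(a)
    b = _as_float(b)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch_t needs at least 2 non-missing values "
                         "per sample")
    res = sps.ttest_ind(a, b, equal_var=False)
    t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    if np.isfinite(t):
        r = np.sqrt(t * t / (t * t + df))
    else:  # zero variance in both samples
        t, p, r = 0.0, 1.0, 0.0
    lo = hi = np.nan
    if bootstrap_reps > 0:
        rng = np.random.default_rng(rng)
        rs = np.empty(bootstrap_reps)
        for i in range(bootstrap_reps):
            ra = rng.choice(a, size=len(a), replace=True)
            rb = rng.choice(b, size=len(b), replace=True)
            if ra.std() == 0 and rb.std() == 0:
                rs[i] = 0.0
                continue
            rr = sps.ttest_ind(ra, rb, equal_var=False)
            tb, dfb = float(rr.statistic), float(rr.df)
            rs[i] = (np.sqrt(tb * tb / (tb * tb + dfb))
                     if np.isfinite(tb) else 0.0)
        lo, hi = np.percentile(rs, [2.5, 97.5])
    return TwoSampleResult(t, p, float(r), float(lo), float(hi),
                           len(a), len(b), "welch_t")
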