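"""Second-order contrasts across arms of the multiverse.

These compare sets of specification coefficients with each other rather
than with a permutation null: group-vs-group (Welch t on the rho
distributions), within- vs between-category comparisons on the combined
sample (Wilcoxon rank sum with continuity correction), the same split
per OxMET metric category, and the with- vs without-covariates contrast.

Category contrasts use the combined sample *without* covariates by
default; the group contrast pools both covariate conditions.  The
covariate contrast is unpaired by default (matching the named rank-sum
test) even though its design is paired; a paired signed-rank alternative
is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .engine import MultiverseResult, SpecResult
from .metrics import CATEGORIES
from .stats import TwoSampleResult, welch_t, wilcoxon_rank_sum_cc

_MISSING_TEST = TwoSampleResult(np.nan, np.nan, np.nan, np.nan, np.nan,
                                0, 0, "missing")


@dataclass(frozen=True)
class CategoryContrast:
    """Within- vs between-category split for one OxMET metric category."""

    oxmet_category: str
    median_between: float
    median_within: float
    n_between: int
    n_within: int
    test: TwoSampleResult


@dataclass(frozen=True)
class CovariateContrast:
    """Unadjusted vs age/education-adjusted coefficient distributions."""

    median_without: float
    median_with: float
    test: TwoSampleResult


def _rhos(mv: MultiverseResult, **conditions) -> np.ndarray:
    def keep(r: SpecResult) -> bool:
        for key, value in conditions.items():
            if key == "within_category":
                if r.within_category != value:
                    return False
            elif key == "x_category":
                if r.x_category != value:
                    return False
            elif getattr(r.spec, key) != value:
                return False
        return True

    vals = np.array([r.corr.rho for r in mv.results if keep(r)], dtype=float)
    return vals[np.isfinite(vals)]


def group_contrast(mv: MultiverseResult, group_a: str,
                   group_b: str) -> TwoSampleResult:
    """Welch t between two groups' coefficient distributions.

    Both covariate conditions are pooled per group.
    """
    a = _rhos(mv, group=group_a)
    b = _rhos(mv, group=group_b)
    if len(a) == 0:
        raise ValueError(f"group {group_a!r} absent from the multiverse")
    if len(b) == 0:
        raise ValueError(f"group {group_b!r} absent from the multiverse")
    return welch_t(a, b)


def within_between_contrast(mv: MultiverseResult, *,
                            covariate_condition: str = "none",
                            bootstrap_reps: int = 2000,
                            rng=None) -> TwoSampleResult:
    """Wilcoxon rank sum, within-category vs between-category coefficients.

    Restricted to the combined sample; the within side is the first
    sample.
    """
    within = _rhos(mv, group="combined",
                   covariate_condition=covariate_condition,
                   within_category=True)
    between = _rhos(mv, group="combined",
                    covariate_condition=covariate_condition,
                    within_category=False)
    if len(within) == 0 or len(between) == 0:
        raise ValueError("within/between partition has an empty side")
    return wilcoxon_rank_sum_cc(within, between,
                                bootstrap_reps=bootstrap_reps, rng=rng)


def category_contrasts(mv: MultiverseResult, *,
                       covariate_condition: str = "none",
                       bootstrap_reps: int = 2000,
                       rng=None) -> list[CategoryContrast]:
    """One within/between contrast per OxMET metric category."""
    rng = np.random.default_rng(rng)
    out = []
    for cat in CATEGORIES:
        within = _rhos(mv, group="combined",
                       covariate_condition=covariate_condition,
                       x_category=cat, within_category=True)
        between = _rhos(mv, group="combined",
                        covariate_condition=covariate_condition,
                        x_category=cat, within_category=False)
        if len(within) == 0 or len(between) == 0:
            import warnings
            warnings.warn(f"category {cat!r}: empty within/between side; "
                          "test missing-marked", stacklevel=2)
            test = _MISSING_TEST
        else:
            test = wilcoxon_rank_sum_cc(within, between,
                                        bootstrap_reps=bootstrap_reps,
                                        rng=rng)
        out.append(CategoryContrast(
            cat,
            float(np.median(between)) if len(between) else np.nan,
            float(np.median(within)) if len(within) else np.nan,
            len(between), len(within), test))
    return out


def covariate_contrast(mv: MultiverseResult, *,
                       paired: bool = False,
                       bootstrap_reps: int = 2000,
                       rng=None) -> CovariateContrast:
    """Unadjusted vs adjusted coefficients on the combined sample.

    Default is the unpaired rank-sum test (first sample = without
    covariates); ``paired=True`` runs a Wilcoxon signed-rank on the
    per-spec differences instead (the spec universe is identical across
    the two conditions).
    """
    without = _rhos(mv, group="combined", covariate_condition="none")
    with_cov = _rhos(mv, group="combined",
                     covariate_condition="age_education")
    if len(without) == 0:
        raise ValueError("covariate condition 'none' absent for the "
                         "combined sample")
    if len(with_cov) == 0:
        raise ValueError("covariate condition 'age_education' absent for "
                         "the combined sample")
    if paired:
        if len(without) != len(with_cov):
            raise ValueError("paired contrast requires equal-length "
                             "condition vectors")
        res = sps.wilcoxon(without, with_cov, correction=True,
                           zero_method="wilcox")
        n = len(without)
        z = abs(sps.norm.isf(min(res.pvalue, 1.0) / 2.0)) if res.pvalue < 1 \
            else 0.0
        test = TwoSampleResult(float(res.statistic), float(res.pvalue),
                               z / np.sqrt(n), np.nan, np.nan, n, n,
                               "wilcoxon_signed_rank")
    else:
        test = wilcoxon_rank_sum_cc(without, with_cov,
                                    bootstrap_reps=bootstrap_reps, rng=rng)
    return CovariateContrast(float(np.median(without)),
                             float(np.median(with_cov)), test)


def round_for_display(value: float, dp: int = 2) -> float:
    """Display rounding (2 dp medians), separated from computation."""
    return float(np.round(value, dp))
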