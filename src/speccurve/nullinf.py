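"""Permutation-null inference for the specification curve.

The null model re-runs the whole multiverse B times (default 500) on
cohorts whose x–y association has been destroyed by shuffling, and
collects each null multiverse's median coefficient and share of
significant specifications.  The observed curve is then tested with the
median-of-curve rule: both medians are rounded to two decimal places, the
proportion of null medians greater than or equal to the observed median
is halved, and a zero count is reported as the bound p < 1/B.

Permutation schemes (``scheme``):

* ``task_blocks_within_group`` (default) — for each comparator task
  (Trails, rule finding) the task's raw observations are shuffled as
  whole participant blocks across participants *within each sample
  group*.  This is the weakest intervention that removes every x–y
  association while preserving each variable's marginal distribution,
  the within-task dependence between a task's metrics, the group
  structure, and the covariates.
* ``task_blocks_pooled`` — same block shuffle, ignoring group membership.
* ``fields_within_group`` — every comparator raw field shuffled
  independently within group (breaks within-task dependence too).

The x-side observations, group labels, ages and educations are never
touched by any scheme.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics as met
from .engine import (MultiverseResult, Specification, run_multiverse,
                     specs_digest, _cohort_frame)

COMPARATOR_TASKS = ("trails", "rulefinding")
SCHEMES = ("task_blocks_within_group", "task_blocks_pooled",
           "fields_within_group")


@dataclass(frozen=True)
class NullModel:
    """B permutation replicates of the multiverse summaries."""

    B: int
    null_medians: tuple[float, ...]
    null_sig_shares: tuple[float, ...]
    seed: int
    scheme: str
    spec_digest: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(1, self.B + 1),
            "median_rho": self.null_medians,
            "significant_share": self.null_sig_shares,
        })


@dataclass(frozen=True)
class CurveTest:
    """Observed-vs-null comparison of the curve summaries."""

    observed_median: float
    observed_sig_share: float
    p_median: float
    p_median_is_bound: bool
    p_sig_share: float
    p_sig_share_is_bound: bool
    p_floor: float


def _task_fields(task: str) -> list[str]:
    schema = met.raw_schema()
    return list(schema.loc[schema["task"] == task, "field"])


def permute_comparators(frame: pd.DataFrame, rng: np.random.Generator,
                        scheme: str = "task_blocks_within_group"
                        ) -> pd.DataFrame:
    """Return a copy of the cohort with comparator observations shuffled."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; valid: {SCHEMES}")
    out = frame.copy()
    group = frame["group"].to_numpy()
    if scheme == "task_blocks_pooled":
        blocks = [np.arange(len(frame))]
    else:
        blocks = [np.flatnonzero(group == g) for g in ("healthy", "stroke")]
    for task in COMPARATOR_TASKS:
        fields = _task_fields(task)
        for idx in blocks:
            if len(idx) == 0:
                continue
            if scheme == "fields_within_group":
                for f in fields:
                    perm = rng.permutation(idx)
                    out.iloc[idx, out.columns.get_indexer([f])] = (
                        frame.iloc[perm][f].to_numpy())
            else:
                perm = rng.permutation(idx)
                out.iloc[idx, out.columns.get_indexer(fields)] = (
                    frame.iloc[perm][fields].to_numpy())
    return out


def permute_null_once(records, specs: Sequence[Specification],
                      alpha: float, rng: np.random.Generator, *,
                      scheme: str = "task_blocks_within_group",
                      ci_method: str = "fisher") -> tuple[float, float]:
    """One permuted multiverse; returns (median rho, significant share)."""
    frame = _cohort_frame(records)
    permuted = permute_comparators(frame, rng, scheme)
    mv = run_multiverse(permuted, specs, alpha, ci_method=ci_method,
                        compute_digest=False)
    return mv.median_rho, mv.significant_share


def build_null(records, specs: Sequence[Specification], alpha: float,
               B: int = 500, seed: int = 0, *,
               scheme: str = "task_blocks_within_group",
               ci_method: str = "fisher") -> NullModel:
    """B independent permuted multiverses, reproducibly seeded."""
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    frame = _cohort_frame(records)
    rng = np.random.default_rng(seed)
    medians = np.empty(B)
    shares = np.empty(B)
    for i in range(B):
        medians[i], shares[i] = permute_null_once(
            frame, specs, alpha, rng, scheme=scheme, ci_method=ci_method)
    return NullModel(B, tuple(medians), tuple(shares), seed, scheme,
                     specs_digest(specs))


def _round_decimal(value: float, dp: int) -> float:
    """Half-up decimal rounding on the shortest repr, so .195 -> .20.

    Plain float rounding sees 0.195 as 0.19499999...; the comparison rule
    is stated in decimal, so ties at the printed precision round up
    (away from zero for negatives).
    """
    if not np.isfinite(value):
        return value
    from decimal import ROUND_HALF_UP, Decimal
    q = Decimal(1).scaleb(-dp)
    return float(Decimal(repr(float(value))).quantize(
        q, rounding=ROUND_HALF_UP))


def _halved_upper_p(observed: float, nulls: np.ndarray, B: int,
                    round_dp: int | None) -> tuple[float, bool]:
    if round_dp is not None:
        observed = _round_decimal(observed, round_dp)
        nulls = np.array([_round_decimal(v, round_dp) for v in nulls])
    count = int((nulls >= observed).sum())
    if count == 0:
        return 1.0 / B, True
    return (count / B) / 2.0, False


def two_sided_permutation_p(observed: float, nulls: Sequence[float]) -> float:
    """Standard two-sided permutation p: (1 + #{|null| >= |obs|}) / (B+1)."""
    nulls = np.asarray(nulls, dtype=float)
    count = int((np.abs(nulls) >= abs(observed)).sum())
    return (1 + count) / (len(nulls) + 1)


def test_curve(observed: MultiverseResult, null: NullModel, *,
               halve_sig_share: bool = True,
               round_dp: int | None = 2) -> CurveTest:
    """Median-of-curve and significance-share tests against the null.

    Both sides are rounded to ``round_dp`` decimals (default 2) before
    the >= comparison; the proportion of qualifying null replicates is
    divided by two; a zero count reports the bound 1/B with the
    ``*_is_bound`` flag set.  ``halve_sig_share=False`` skips the halving
    for the significance-share comparison only.
    """
    if null.spec_digest != specs_digest([r.spec for r in observed.results]):
        raise ValueError("null model was built on a different specification "
                         "set than the observed multiverse")
    meds = np.asarray(null.null_medians, dtype=float)
    shares = np.asarray(null.null_sig_shares, dtype=float)
    p_med, med_bound = _halved_upper_p(observed.median_rho, meds,
                                       null.B, round_dp)
    if halve_sig_share:
        p_share, share_bound = _halved_upper_p(
            observed.significant_share, shares, null.B, round_dp)
    else:
        obs = observed.significant_share
        sh = shares
        if round_dp is not None:
            obs = _round_decimal(obs, round_dp)
            sh = np.array([_round_decimal(v, round_dp) for v in sh])
        count = int((sh >= obs).sum())
        share_bound = count == 0
        p_share = 1.0 / null.B if share_bound else count / null.B
    return CurveTest(observed.median_rho, observed.significant_share,
                     p_med, med_bound, p_share, share_bound, 1.0 / null.B)
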