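"""Multiverse enumeration and evaluation.

A *specification* is one fully resolved analysis cell: an OxMET metric on
the x side, a comparator metric (Trails or rule finding) on the y side, a
sample group (healthy, stroke, or both combined), and a covariate
condition (plain correlation, or partial correlation with age and
education factored out).  The full catalogue gives
10 × 37 × 3 × 2 = 2,220 specifications.

``run_multiverse`` evaluates every specification on a cohort and returns
the per-spec results together with the curve summaries the inference
stage needs: the median coefficient and the share of specifications
significant at alpha.  Specifications with too few complete cases are
missing-marked, excluded from the summaries, and counted.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics as met
from .records import records_to_frame
from .stats import CorrelationResult, partial_spearman, spearman

GROUP_ARMS = ("healthy", "stroke", "combined")
COVARIATE_CONDITIONS = ("none", "age_education")
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class Specification:
    x_metric: str
    y_metric: str
    group: str
    covariate_condition: str
    spec_id: int


@dataclass(frozen=True)
class SpecResult:
    spec: Specification
    corr: CorrelationResult
    significant: bool
    x_category: str
    y_category: str

    @property
    def within_category(self) -> bool:
        return self.x_category == self.y_category


@dataclass(frozen=True)
class MultiverseResult:
    results: tuple[SpecResult, ...]
    alpha: float
    median_rho: float
    significant_share: float
    n_missing: int
    config_digest: str

    def to_frame(self) -> pd.DataFrame:
        """One row per specification, ready for CSV export."""
        rows = []
        for r in self.results:
            s, c = r.spec, r.corr
            rows.append((s.spec_id, s.x_metric, s.y_metric, r.x_category,
                         r.y_category, s.group, s.covariate_condition, c.n,
                         c.rho, c.p_value, c.ci_low, c.ci_high,
                         r.significant, r.within_category))
        return pd.DataFrame(rows, columns=[
            "spec_id", "x_metric", "y_metric", "x_category", "y_category",
            "group", "covariate_condition", "n", "rho", "p_value",
            "ci_low", "ci_high", "significant", "within_category"])


def default_x_metrics() -> list[str]:
    return met.metric_names("oxmet")


def default_y_metrics() -> list[str]:
    return met.metric_names("trails") + met.metric_names("rulefinding")


def enumerate_specs(x_metrics: Sequence[str] | None = None,
                    y_metrics: Sequence[str] | None = None,
                    groups: Sequence[str] = GROUP_ARMS,
                    covariate_conditions: Sequence[str] = COVARIATE_CONDITIONS,
                    ) -> list[Specification]:
    """Full Cartesian product in deterministic order (x, y, group, cond).

    spec_ids run 1..N and are stable across runs for a fixed request.
    """
    x_metrics = default_x_metrics() if x_metrics is None else list(x_metrics)
    y_metrics = default_y_metrics() if y_metrics is None else list(y_metrics)
    if not x_metrics or not y_metrics or not groups or not covariate_conditions:
        raise ValueError("all specification dimensions must be non-empty")
    for name in itertools.chain(x_metrics, y_metrics):
        met.metric(name)  # raises with valid names on a miss
    for g in groups:
        if g not in GROUP_ARMS:
            raise ValueError(f"unknown group {g!r}; valid: {GROUP_ARMS}")
    for c in covariate_conditions:
        if c not in COVARIATE_CONDITIONS:
            raise ValueError(
                f"unknown covariate condition {c!r}; "
                f"valid: {COVARIATE_CONDITIONS}")
    specs = []
    for i, (x, y, g, c) in enumerate(
            itertools.product(x_metrics, y_metrics, groups,
                              covariate_conditions), start=1):
        specs.append(Specification(x, y, g, c, i))
    return specs


def specs_digest(specs: Sequence[Specification]) -> str:
    h = hashlib.sha1()
    for s in specs:
        h.update(f"{s.spec_id}|{s.x_metric}|{s.y_metric}|{s.group}|"
                 f"{s.covariate_condition}\n".encode())
    return h.hexdigest()


def _cohort_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records, met.RAW_FIELDS)


def _summaries(results: Sequence[SpecResult]) -> tuple[float, float, int]:
    rhos = np.array([r.corr.rho for r in results], dtype=float)
    valid = np.isfinite(rhos)
    n_missing = int((~valid).sum())
    if valid.sum() == 0:
        return np.nan, np.nan, n_missing
    median = float(np.median(rhos[valid]))
    share = float(np.mean([r.significant for r, ok in zip(results, valid)
                           if ok]))
    return median, share, n_missing


def run_multiverse(records, specs: Sequence[Specification],
                   alpha: float = DEFAULT_ALPHA, *,
                   ci_method: str = "fisher",
                   compute_digest: bool = True) -> MultiverseResult:
    """Evaluate every specification on a cohort.

    Derivation happens once per group arm; each spec then applies a plain
    or age/education-partial Spearman correlation.  Fully deterministic
    given the inputs.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    frame = _cohort_frame(records)
    if frame.empty:
        raise ValueError("records must be non-empty")
    needed = sorted({s.x_metric for s in specs} | {s.y_metric for s in specs})
    derived = met.derive(frame, needed)
    values = {n: derived[n].to_numpy() for n in needed}
    group_col = frame["group"].to_numpy()
    masks = {
        "healthy": group_col == "healthy",
        "stroke": group_col == "stroke",
        "combined": np.ones(len(frame), dtype=bool),
    }
    age = frame["age"].to_numpy(dtype=float)
    edu = frame["education"].to_numpy(dtype=float)

    cats = {n: met.metric(n).category for n in needed}
    results = []
    for s in specs:
        m = masks[s.group]
        x = values[s.x_metric][m]
        y = values[s.y_metric][m]
        if s.covariate_condition == "age_education":
            corr = partial_spearman(x, y, [age[m], edu[m]],
                                    ci_method=ci_method)
        else:
            corr = spearman(x, y, ci_method=ci_method)
        sig = bool(np.isfinite(corr.p_value) and corr.p_value < alpha)
        results.append(SpecResult(s, corr, sig,
                                  cats[s.x_metric], cats[s.y_metric]))

    median, share, n_missing = _summaries(results)
    digest = ""
    if compute_digest:
        h = hashlib.sha1()
        h.update(frame.to_csv(index=False).encode())
        h.update(specs_digest(specs).encode())
        h.update(f"{alpha}|{ci_method}".encode())
        digest = h.hexdigest()
    return MultiverseResult(tuple(results), alpha, median, share,
                            n_missing, digest)


def subset_multiverse(mv: MultiverseResult,
                      predicate) -> MultiverseResult:
    """A MultiverseResult over the specs satisfying ``predicate``.

    Summaries (median, significant share) are recomputed on the subset.
    """
    kept = tuple(r for r in mv.results if predicate(r))
    median, share, n_missing = _summaries(kept)
    return MultiverseResult(kept, mv.alpha, median, share, n_missing,
                            mv.config_digest)


def order_curve(mv: MultiverseResult) -> pd.DataFrame:
    """Specification curve: valid specs sorted ascending by rho.

    Ties are broken by spec_id; a ``rank`` column runs 1..N over the
    retained rows.  Missing-rho specs are excluded; the excluded count is
    in ``frame.attrs['n_excluded']``.
    """
    frame = mv.to_frame()
    valid = frame[np.isfinite(frame["rho"].to_numpy(dtype=float))].copy()
    valid = valid.sort_values(["rho", "spec_id"], kind="mergesort")
    valid.insert(0, "rank", np.arange(1, len(valid) + 1))
    valid = valid.reset_index(drop=True)
    valid.attrs["n_excluded"] = len(frame) - len(valid)
    return valid
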