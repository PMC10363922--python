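"""Outcome-metric catalogue and derivation.

Three tests contribute candidate convergent-validity metrics:

* **OxMET** (Oxford Digital Multiple Errands Test): completion time, total
  accuracy, a six-way error taxonomy, a derived total-error count, and an
  accuracy-per-time composite — 10 metrics.
* **OCS-Plus Trails** (shape-based Trail Making Test with Trail A circles,
  Trail A squares, and a switching Trail B): per-condition completion and
  thinking times, accuracies, errors, their Trail-A means, and the classic
  family of B−A / B/A composites — 30 metrics.
* **OCS-Plus rule finding**: time, accuracy, rules learned, errors, and the
  three per-time composites — 7 metrics.

Unlabelled Trails subtraction/ratio composites operate on completion
*time* (the classic TMT B−A and B/A are time scores).  Two rows are
accuracy-based by name or by definition: the per-condition
accuracy-per-time ratios, and the OCS-Plus executive ratio score
``trails_exec_ratio`` = Trail B accuracy / (Trail A circles accuracy +
Trail A squares accuracy) as a percentage.  "Median Trail A" over the two
baseline conditions equals their mean.  The nominal time-over-itself ratio
(Trail B time / Trail B time ≡ 1) is degenerate and is not in the
catalogue; see the raw-schema documentation.

Zero denominators yield missing values, never infinities, so downstream
rank statistics stay well defined.  Direction metadata is informational
only — values are never sign-flipped before correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .records import ParticipantRecord, records_to_frame

TASKS = ("oxmet", "trails", "rulefinding")
CATEGORIES = ("time", "accuracy", "error", "composite")

# ---------------------------------------------------------------------------
# Raw-schema registry: every raw observation a task stores, with units.
# Columns: field, task, category, unit, description.
# ---------------------------------------------------------------------------

_RAW_SCHEMA_ROWS = [
    ("oxmet_time_completion", "oxmet", "time", "s", "OxMET time to completion"),
    ("oxmet_accuracy", "oxmet", "accuracy", "count", "OxMET total task accuracy within rule constraints"),
    ("oxmet_rules_broken", "oxmet", "error", "count", "number of rules broken (of 3)"),
    ("oxmet_rule_break_freq", "oxmet", "error", "count", "frequency of rule breaks"),
    ("oxmet_omissions", "oxmet", "error", "count", "non-attempted tasks"),
    ("oxmet_partial_omissions", "oxmet", "error", "count", "incomplete tasks"),
    ("oxmet_perseverations", "oxmet", "error", "count", "perseverative errors"),
    ("oxmet_commissions", "oxmet", "error", "count", "wrong items bought"),
    ("trails_time_a_circles", "trails", "time", "s", "Trail A circles completion time"),
    ("trails_think_a_circles", "trails", "time", "s", "Trail A circles thinking time"),
    ("trails_time_a_squares", "trails", "time", "s", "Trail A squares completion time"),
    ("trails_think_a_squares", "trails", "time", "s", "Trail A squares thinking time"),
    ("trails_time_b", "trails", "time", "s", "Trail B completion time"),
    ("trails_think_b", "trails", "time", "s", "Trail B thinking time"),
    ("trails_acc_a_circles", "trails", "accuracy", "count", "Trail A circles connections accuracy"),
    ("trails_acc_a_squares", "trails", "accuracy", "count", "Trail A squares connections accuracy"),
    ("trails_acc_b", "trails", "accuracy", "count", "Trail B connections accuracy"),
    ("trails_err_a_circles", "trails", "error", "count", "Trail A circles errors"),
    ("trails_err_a_squares", "trails", "error", "count", "Trail A squares errors"),
    ("trails_err_b", "trails", "error", "count", "Trail B errors"),
    ("rule_time", "rulefinding", "time", "s", "rule finding time to completion"),
    ("rule_accuracy", "rulefinding", "accuracy", "count", "rule finding total accuracy"),
    ("rule_rules_learned", "rulefinding", "accuracy", "count", "number of rules learned"),
    ("rule_errors", "rulefinding", "error", "count", "rule finding total errors"),
]

RAW_FIELDS: tuple[str, ...] = tuple(r[0] for r in _RAW_SCHEMA_ROWS)


def raw_schema() -> pd.DataFrame:
    """Machine-readable raw-field registry (field, task, category, unit)."""
    return pd.DataFrame(
        _RAW_SCHEMA_ROWS,
        columns=["field", "task", "category", "unit", "description"],
    )


# ---------------------------------------------------------------------------
# Formula registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FormulaRule:
    """A documented scoring rule: raw inputs, unit, and the computation."""

    formula_id: str
    inputs: tuple[str, ...]
    unit: str
    description: str
    fn: Callable[[pd.DataFrame], pd.Series]


@dataclass(frozen=True)
class MetricDefinition:
    """A catalogue entry: named derived score with category metadata."""

    name: str
    task: str
    category: str
    formula_id: str
    direction: str  # higher_better | higher_worse | neutral


def _identity(field: str) -> Callable[[pd.DataFrame], pd.Series]:
    return lambda raw: raw[field].astype(float)


def _safe_div(num: pd.Series, den: pd.Series) -> pd.Series:
    out = num / den.where(den != 0, np.nan)
    return out


def _build_registry() -> dict[str, FormulaRule]:
    rules: dict[str, FormulaRule] = {}

    def add(fid, inputs, unit, desc, fn):
        rules[fid] = FormulaRule(fid, tuple(inputs), unit, desc, fn)

    # --- OxMET -------------------------------------------------------------
    for fid, field, unit, desc in [
        ("oxmet_time", "oxmet_time_completion", "s", "time to completion"),
        ("oxmet_accuracy", "oxmet_accuracy", "count", "total accuracy within rule constraints"),
        ("oxmet_rules_broken", "oxmet_rules_broken", "count", "number of rules broken"),
        ("oxmet_rule_break_freq", "oxmet_rule_break_freq", "count", "frequency of rule breaks"),
        ("oxmet_omissions", "oxmet_omissions", "count", "task omissions"),
        ("oxmet_partial_omissions", "oxmet_partial_omissions", "count", "partial task omissions"),
        ("oxmet_perseverations", "oxmet_perseverations", "count", "perseverative errors"),
        ("oxmet_commissions", "oxmet_commissions", "count", "task commissions"),
    ]:
        add(fid, [field], unit, desc, _identity(field))
    add("oxmet_total_errors",
        ["oxmet_rules_broken", "oxmet_omissions", "oxmet_commissions"],
        "count", "total errors = rule breaks + omissions + commissions",
        lambda r: r["oxmet_rules_broken"] + r["oxmet_omissions"] + r["oxmet_commissions"])
    add("oxmet_accuracy_per_time",
        ["oxmet_accuracy", "oxmet_time_completion"],
        "count/s", "total accuracy / time to completion",
        lambda r: _safe_div(r["oxmet_accuracy"], r["oxmet_time_completion"]))

    # --- Trails: simple times / accuracies / errors -------------------------
    for field in ["trails_time_a_circles", "trails_think_a_circles",
                  "trails_time_a_squares", "trails_think_a_squares",
                  "trails_time_b", "trails_think_b",
                  "trails_acc_a_circles", "trails_acc_a_squares", "trails_acc_b",
                  "trails_err_a_circles", "trails_err_a_squares", "trails_err_b"]:
        unit = "s" if ("time" in field or "think" in field) else "count"
        add(field, [field], unit, field.replace("_", " "), _identity(field))
    add("trails_time_a_mean", ["trails_time_a_circles", "trails_time_a_squares"],
        "s", "mean completion time of Trail A circles and squares",
        lambda r: (r["trails_time_a_circles"] + r["trails_time_a_squares"]) / 2.0)
    add("trails_think_a_mean", ["trails_think_a_circles", "trails_think_a_squares"],
        "s", "mean thinking time of Trail A circles and squares",
        lambda r: (r["trails_think_a_circles"] + r["trails_think_a_squares"]) / 2.0)
    add("trails_acc_a_mean", ["trails_acc_a_circles", "trails_acc_a_squares"],
        "count", "mean connections accuracy of Trail A circles and squares",
        lambda r: (r["trails_acc_a_circles"] + r["trails_acc_a_squares"]) / 2.0)
    add("trails_err_a_mean", ["trails_err_a_circles", "trails_err_a_squares"],
        "count", "mean errors of Trail A circles and squares",
        lambda r: (r["trails_err_a_circles"] + r["trails_err_a_squares"]) / 2.0)

    # --- Trails: composites (time-based unless named otherwise) -------------
    add("trails_b_minus_a_circles", ["trails_time_b", "trails_time_a_circles"],
        "s", "time(Trail B) − time(Trail A circles)",
        lambda r: r["trails_time_b"] - r["trails_time_a_circles"])
    add("trails_b_minus_a_squares", ["trails_time_b", "trails_time_a_squares"],
        "s", "time(Trail B) − time(Trail A squares)",
        lambda r: r["trails_time_b"] - r["trails_time_a_squares"])
    add("trails_b_minus_a_mean",
        ["trails_time_b", "trails_time_a_circles", "trails_time_a_squares"],
        "s", "time(Trail B) − mean time(Trail A)",
        lambda r: r["trails_time_b"] - (r["trails_time_a_circles"] + r["trails_time_a_squares"]) / 2.0)
    add("trails_b_minus_a_sum",
        ["trails_time_b", "trails_time_a_circles", "trails_time_a_squares"],
        "s", "time(Trail B) − (time A circles + time A squares)",
        lambda r: r["trails_time_b"] - (r["trails_time_a_circles"] + r["trails_time_a_squares"]))
    add("trails_b_over_a_circles", ["trails_time_b", "trails_time_a_circles"],
        "ratio", "time(Trail B) / time(Trail A circles)",
        lambda r: _safe_div(r["trails_time_b"], r["trails_time_a_circles"]))
    add("trails_b_over_a_squares", ["trails_time_b", "trails_time_a_squares"],
        "ratio", "time(Trail B) / time(Trail A squares)",
        lambda r: _safe_div(r["trails_time_b"], r["trails_time_a_squares"]))
    add("trails_b_over_a_mean",
        ["trails_time_b", "trails_time_a_circles", "trails_time_a_squares"],
        "ratio", "time(Trail B) / mean time(Trail A)",
        lambda r: _safe_div(r["trails_time_b"],
                            (r["trails_time_a_circles"] + r["trails_time_a_squares"]) / 2.0))
    add("trails_b_over_a_median",
        ["trails_time_b", "trails_time_a_circles", "trails_time_a_squares"],
        "ratio", "time(Trail B) / median time(Trail A); the median of the two "
        "Trail A conditions equals their mean",
        lambda r: _safe_div(r["trails_time_b"],
                            (r["trails_time_a_circles"] + r["trails_time_a_squares"]) / 2.0))
    add("trails_exec_ratio",
        ["trails_acc_b", "trails_acc_a_circles", "trails_acc_a_squares"],
        "%", "OCS-Plus executive ratio score: Trail B accuracy / "
        "(Trail A circles accuracy + Trail A squares accuracy) as a percentage",
        lambda r: 100.0 * _safe_div(r["trails_acc_b"],
                                    r["trails_acc_a_circles"] + r["trails_acc_a_squares"]))
    add("trails_acc_a_circles_per_time",
        ["trails_acc_a_circles", "trails_time_a_circles"],
        "count/s", "Trail A circles accuracy / Trail A circles time",
        lambda r: _safe_div(r["trails_acc_a_circles"], r["trails_time_a_circles"]))
    add("trails_acc_a_squares_per_time",
        ["trails_acc_a_squares", "trails_time_a_squares"],
        "count/s", "Trail A squares accuracy / Trail A squares time",
        lambda r: _safe_div(r["trails_acc_a_squares"], r["trails_time_a_squares"]))
    add("trails_err_a_circles_per_time",
        ["trails_err_a_circles", "trails_time_a_circles"],
        "count/s", "Trail A circles errors / Trail A circles time",
        lambda r: _safe_div(r["trails_err_a_circles"], r["trails_time_a_circles"]))
    add("trails_err_a_squares_per_time",
        ["trails_err_a_squares", "trails_time_a_squares"],
        "count/s", "Trail A squares errors / Trail A squares time",
        lambda r: _safe_div(r["trails_err_a_squares"], r["trails_time_a_squares"]))
    # Pairing of Trail B errors with Trail A squares time follows the source
    # metric list verbatim; see docs for the flag on this row.
    add("trails_err_b_per_time_a_squares",
        ["trails_err_b", "trails_time_a_squares"],
        "count/s", "Trail B errors / Trail A squares time",
        lambda r: _safe_div(r["trails_err_b"], r["trails_time_a_squares"]))

    # --- Rule finding --------------------------------------------------------
    add("rule_time", ["rule_time"], "s", "time to completion", _identity("rule_time"))
    add("rule_accuracy", ["rule_accuracy"], "count", "total accuracy", _identity("rule_accuracy"))
    add("rule_rules_learned", ["rule_rules_learned"], "count",
        "number of rules learned", _identity("rule_rules_learned"))
    add("rule_errors", ["rule_errors"], "count", "total number of errors", _identity("rule_errors"))
    add("rule_accuracy_per_time", ["rule_accuracy", "rule_time"],
        "count/s", "total accuracy / time to completion",
        lambda r: _safe_div(r["rule_accuracy"], r["rule_time"]))
    add("rule_errors_per_time", ["rule_errors", "rule_time"],
        "count/s", "total errors / time to completion",
        lambda r: _safe_div(r["rule_errors"], r["rule_time"]))
    add("rule_rules_per_time", ["rule_rules_learned", "rule_time"],
        "count/s", "rules learned / time to completion",
        lambda r: _safe_div(r["rule_rules_learned"], r["rule_time"]))

    return rules


_REGISTRY = _build_registry()


def formula_registry() -> dict[str, FormulaRule]:
    """All registered scoring rules, keyed by formula id.

    Lookup of an unregistered id is a plain ``KeyError`` — never a silent
    default.
    """
    return dict(_REGISTRY)


# ---------------------------------------------------------------------------
# Catalogue
# ---------------------------------------------------------------------------

def _defs() -> list[MetricDefinition]:
    def d(name, task, category, direction):
        return MetricDefinition(name, task, category, name, direction)

    oxmet = [
        d("oxmet_time", "oxmet", "time", "higher_worse"),
        d("oxmet_accuracy", "oxmet", "accuracy", "higher_better"),
        d("oxmet_rules_broken", "oxmet", "error", "higher_worse"),
        d("oxmet_rule_break_freq", "oxmet", "error", "higher_worse"),
        d("oxmet_omissions", "oxmet", "error", "higher_worse"),
        d("oxmet_partial_omissions", "oxmet", "error", "higher_worse"),
        d("oxmet_perseverations", "oxmet", "error", "higher_worse"),
        d("oxmet_commissions", "oxmet", "error", "higher_worse"),
        d("oxmet_total_errors", "oxmet", "error", "higher_worse"),
        d("oxmet_accuracy_per_time", "oxmet", "composite", "higher_better"),
    ]
    trails = [
        d("trails_time_a_circles", "trails", "time", "higher_worse"),
        d("trails_think_a_circles", "trails", "time", "higher_worse"),
        d("trails_time_a_squares", "trails", "time", "higher_worse"),
        d("trails_think_a_squares", "trails", "time", "higher_worse"),
        d("trails_time_b", "trails", "time", "higher_worse"),
        d("trails_think_b", "trails", "time", "higher_worse"),
        d("trails_time_a_mean", "trails", "time", "higher_worse"),
        d("trails_think_a_mean", "trails", "time", "higher_worse"),
        d("trails_acc_a_circles", "trails", "accuracy", "higher_better"),
        d("trails_acc_a_squares", "trails", "accuracy", "higher_better"),
        d("trails_acc_b", "trails", "accuracy", "higher_better"),
        d("trails_acc_a_mean", "trails", "accuracy", "higher_better"),
        d("trails_err_a_circles", "trails", "error", "higher_worse"),
        d("trails_err_a_squares", "trails", "error", "higher_worse"),
        d("trails_err_b", "trails", "error", "higher_worse"),
        d("trails_err_a_mean", "trails", "error", "higher_worse"),
        d("trails_b_minus_a_circles", "trails", "composite", "higher_worse"),
        d("trails_b_minus_a_squares", "trails", "composite", "higher_worse"),
        d("trails_b_minus_a_mean", "trails", "composite", "higher_worse"),
        d("trails_b_minus_a_sum", "trails", "composite", "neutral"),
        d("trails_b_over_a_circles", "trails", "composite", "higher_worse"),
        d("trails_b_over_a_squares", "trails", "composite", "higher_worse"),
        d("trails_b_over_a_mean", "trails", "composite", "higher_worse"),
        d("trails_b_over_a_median", "trails", "composite", "higher_worse"),
        d("trails_exec_ratio", "trails", "composite", "higher_better"),
        d("trails_acc_a_circles_per_time", "trails", "composite", "higher_better"),
        d("trails_acc_a_squares_per_time", "trails", "composite", "higher_better"),
        d("trails_err_a_circles_per_time", "trails", "composite", "higher_worse"),
        d("trails_err_a_squares_per_time", "trails", "composite", "higher_worse"),
        d("trails_err_b_per_time_a_squares", "trails", "composite", "higher_worse"),
    ]
    rule = [
        d("rule_time", "rulefinding", "time", "higher_worse"),
        d("rule_accuracy", "rulefinding", "accuracy", "higher_better"),
        d("rule_rules_learned", "rulefinding", "accuracy", "higher_better"),
        d("rule_errors", "rulefinding", "error", "higher_worse"),
        d("rule_accuracy_per_time", "rulefinding", "composite", "higher_better"),
        d("rule_errors_per_time", "rulefinding", "composite", "higher_worse"),
        d("rule_rules_per_time", "rulefinding", "composite", "higher_better"),
    ]
    return oxmet + trails + rule


_CATALOGUE = _defs()
_BY_NAME = {m.name: m for m in _CATALOGUE}
assert len(_BY_NAME) == len(_CATALOGUE), "metric names must be unique"


def catalogue(task: str | None = None) -> list[MetricDefinition]:
    """The metric catalogue: 10 OxMET, 30 Trails, 7 rule-finding entries.

    Parameters
    ----------
    task
        Optional filter; one of ``oxmet``, ``trails``, ``rulefinding``.
    """
    if task is None:
        return list(_CATALOGUE)
    if task not in TASKS:
        raise KeyError(f"unknown task {task!r}; valid tasks: {TASKS}")
    return [m for m in _CATALOGUE if m.task == task]


def metric(name: str) -> MetricDefinition:
    """Catalogue lookup by name; raises with the valid names on a miss."""
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown metric {name!r}; valid names: {sorted(_BY_NAME)}"
        ) from None


def metric_names(task: str | None = None) -> list[str]:
    return [m.name for m in catalogue(task)]


def derive(records: Sequence[ParticipantRecord] | pd.DataFrame,
           requested: Iterable[str] | None = None) -> pd.DataFrame:
    """Derive requested metrics for every participant.

    Returns a DataFrame indexed by participant id with one column per
    requested metric (catalogue order is preserved for the default "all").
    A cell is NaN iff any raw ingredient is missing or a guarded
    denominator is zero; there is no imputation.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = records_to_frame(records, RAW_FIELDS)
    names = metric_names() if requested is None else list(requested)
    for n in names:
        metric(n)  # validate early, with the full name list in the error
    raw = frame[list(RAW_FIELDS)].astype(float)
    out = pd.DataFrame(index=pd.Index(frame["id"], name="id"))
    for n in names:
        rule = _REGISTRY[_BY_NAME[n].formula_id]
        out[n] = rule.fn(raw).to_numpy()
    return out


def registry_table() -> pd.DataFrame:
    """Machine-readable export of the formula registry for the docs."""
    rows = []
    for m in _CATALOGUE:
        rule = _REGISTRY[m.formula_id]
        rows.append((m.name, m.task, m.category, m.direction,
                     ";".join(rule.inputs), rule.unit, rule.description))
    return pd.DataFrame(rows, columns=[
        "metric", "task", "category", "direction", "inputs", "unit", "rule"])
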