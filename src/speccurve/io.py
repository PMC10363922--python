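"""File I/O, run configuration, and the end-to-end pipeline driver.

One run = one immutable output directory (named by the config digest plus
a timestamp) holding every table a report needs: the per-spec results
CSV, plot-ready curve tables per sample group, the sample-size view, the
permutation-null draws and curve tests, the contrast table, a JSON
summary with every headline number, and a log with per-stage counts.
Identical configs produce byte-identical CSV/JSON contents.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import contrasts as ctr
from . import engine, metrics as met, nullinf
from .records import GROUPS, ID_COLUMNS, ParticipantRecord, frame_to_records
from .synthetic import CohortParams, cohort_to_csv, generate_cohort

log = logging.getLogger("speccurve")


def read_participants(path: str | Path, *,
                      allow_extra: bool = False) -> list[ParticipantRecord]:
    """Read the canonical wide participant CSV.

    Empty cells are missing.  Unknown columns are rejected (naming them)
    unless ``allow_extra`` is set; a raw column absent from the file is
    missing for everyone.  Duplicate ids and malformed values are errors
    with the offending line number.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"id": str, "group": str},
                        float_precision="round_trip")
    for col in ID_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    known = set(ID_COLUMNS) | set(met.RAW_FIELDS)
    extra = [c for c in frame.columns if c not in known]
    if extra and not allow_extra:
        raise ValueError(f"{path}: unknown columns {extra}; pass "
                         "allow_extra=True to ignore them")
    dup = frame["id"][frame["id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate ids {sorted(set(dup))}")
    bad_group = ~frame["group"].isin(GROUPS)
    if bad_group.any():
        line = int(np.flatnonzero(bad_group)[0]) + 2  # header is line 1
        raise ValueError(f"{path}, line {line}: group must be one of "
                         f"{GROUPS}, got {frame['group'][bad_group].iloc[0]!r}")
    numeric = ["age", "education"] + [c for c in met.RAW_FIELDS
                                      if c in frame.columns]
    for col in numeric:
        try:
            frame[col] = pd.to_numeric(frame[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: non-numeric value in column "
                             f"{col!r}: {exc}") from None
    for f in met.RAW_FIELDS:
        if f not in frame.columns:
            frame[f] = np.nan
    return frame_to_records(frame, met.RAW_FIELDS)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

DEFAULT_OPTIONS: dict[str, Any] = {
    "permutation_scheme": "task_blocks_within_group",
    "ci_method": "fisher",
    "halve_sig_share": True,
    "paired_covariate": False,
}


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    input_path: str | None = None
    synthetic: CohortParams | None = None
    x_metrics: Sequence[str] | None = None
    y_metrics: Sequence[str] | None = None
    groups: Sequence[str] = engine.GROUP_ARMS
    covariate_conditions: Sequence[str] = engine.COVARIATE_CONDITIONS
    alpha: float = engine.DEFAULT_ALPHA
    B: int = 500
    bootstrap_reps: int = 2000
    seed: int = 0
    output_dir: str = "runs"
    options: Mapping[str, Any] = field(
        default_factory=lambda: dict(DEFAULT_OPTIONS))

    def validate(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_path / synthetic must "
                             "be set")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.B < 1:
            raise ValueError(f"B must be >= 1, got {self.B}")
        if self.synthetic is not None:
            self.synthetic.validate()

    def option(self, key: str):
        return self.options.get(key, DEFAULT_OPTIONS[key])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = list(self.groups)
        d["covariate_conditions"] = list(self.covariate_conditions)
        if self.x_metrics is not None:
            d["x_metrics"] = list(self.x_metrics)
        if self.y_metrics is not None:
            d["y_metrics"] = list(self.y_metrics)
        d["options"] = dict(self.options)
        return d

    def digest(self) -> str:
        """Digest of the analysis-relevant fields (output location excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic") is not None and not isinstance(
                d["synthetic"], CohortParams):
            d["synthetic"] = CohortParams(**d["synthetic"])
        options = dict(DEFAULT_OPTIONS)
        options.update(d.get("options") or {})
        d["options"] = options
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix == ".json"
                else yaml.safe_load(text))
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _test_to_dict(t) -> dict:
    return {"statistic": t.statistic, "p_value": t.p_value,
            "effect_r": t.effect_r, "effect_r_ci": [t.effect_r_ci_low,
                                                    t.effect_r_ci_high],
            "n_x": t.n_x, "n_y": t.n_y, "method": t.method}


def _curve_test_to_dict(ct: nullinf.CurveTest) -> dict:
    return dataclasses.asdict(ct)


def _write_curve_plot(curve: pd.DataFrame, median: float,
                      path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    x = curve["rank"].to_numpy()
    ax.fill_between(x, curve["ci_low"], curve["ci_high"],
                    color="0.85", label="95% CI")
    sig = curve["significant"].astype(bool).to_numpy()
    ax.scatter(x[~sig], curve["rho"].to_numpy()[~sig], s=4, c="firebrick",
               label="non-significant")
    ax.scatter(x[sig], curve["rho"].to_numpy()[sig], s=4, c="steelblue",
               label=f"significant (alpha={0.05})")
    ax.axhline(median, ls=":", c="k", lw=1, label="median rho")
    ax.set_xlabel("specification rank")
    ax.set_ylabel("Spearman rho")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: RunConfig, *, make_plot: bool = True) -> Path:
    """Execute the full analysis and write the run directory.

    Stages: cohort (read or simulate) → metric derivation → specification
    enumeration → multiverse evaluation → per-group permutation nulls and
    curve tests → contrasts → export.
    """
    config.validate()
    digest = config.digest()
    stamp = time.strftime("%Y%m%dT%H%M%S")
    run_dir = Path(config.output_dir) / f"run_{digest[:10]}_{stamp}"
    i = 0
    while run_dir.exists():
        i += 1
        run_dir = Path(config.output_dir) / f"run_{digest[:10]}_{stamp}.{i}"
    run_dir.mkdir(parents=True)

    lines = [f"config digest: {digest}", f"seed: {config.seed}"]

    if config.input_path is not None:
        records = read_participants(config.input_path)
        lines.append(f"cohort: read {len(records)} records from "
                     f"{config.input_path}")
    else:
        records = generate_cohort(config.synthetic)
        cohort_to_csv(records, run_dir / "cohort.csv")
        lines.append(f"cohort: simulated {len(records)} records "
                     f"(seed {config.synthetic.seed})")

    specs = engine.enumerate_specs(config.x_metrics, config.y_metrics,
                                   config.groups,
                                   config.covariate_conditions)
    lines.append(f"specifications enumerated: {len(specs)}")

    ci_method = config.option("ci_method")
    mv = engine.run_multiverse(records, specs, config.alpha,
                               ci_method=ci_method)
    lines.append(f"multiverse evaluated: {len(mv.results)} specs, "
                 f"{mv.n_missing} missing-marked")
    mv.to_frame().to_csv(run_dir / "specs.csv", index=False)

    # Sample-size view: every valid spec ordered by its n.
    spec_frame = mv.to_frame()
    size_view = spec_frame[np.isfinite(spec_frame["rho"])].sort_values(
        ["n", "spec_id"])[["spec_id", "group", "n", "rho", "significant"]]
    size_view.to_csv(run_dir / "sample_size_curve.csv", index=False)

    scheme = config.option("permutation_scheme")
    curve_tests = {}
    group_summaries = {}
    for k, g in enumerate(config.groups):
        sub = engine.subset_multiverse(mv, lambda r, g=g: r.spec.group == g)
        curve = engine.order_curve(sub)
        curve.to_csv(run_dir / f"curve_{g}.csv", index=False)
        null = nullinf.build_null(records,
                                  [r.spec for r in sub.results],
                                  config.alpha, config.B,
                                  seed=config.seed + k, scheme=scheme,
                                  ci_method=ci_method)
        null.to_frame().to_csv(run_dir / f"null_{g}.csv", index=False)
        ct = nullinf.test_curve(
            sub, null, halve_sig_share=config.option("halve_sig_share"))
        curve_tests[g] = _curve_test_to_dict(ct)
        group_summaries[g] = {
            "n_specs": len(sub.results),
            "n_missing": sub.n_missing,
            "median_rho": sub.median_rho,
            "significant_share": sub.significant_share,
        }
        lines.append(f"group {g}: median rho {sub.median_rho:.3f}, "
                     f"significant share {sub.significant_share:.3f}, "
                     f"null B={config.B}, p_median "
                     f"{'<' if ct.p_median_is_bound else '='} "
                     f"{ct.p_median:.4g}")
        if make_plot and g == "combined":
            _write_curve_plot(curve, sub.median_rho, run_dir / "curve.png")

    rng = np.random.default_rng(config.seed)
    config_dict = config.to_dict()
    config_dict.pop("output_dir", None)
    summary: dict[str, Any] = {
        "config": config_dict,
        "config_digest": digest,
        "n_records": len(records),
        "n_specifications": len(specs),
        "n_missing_specs": mv.n_missing,
        "alpha": config.alpha,
        "groups": group_summaries,
        "curve_tests": curve_tests,
    }

    contrast_rows = []
    if "healthy" in config.groups and "stroke" in config.groups:
        gt = ctr.group_contrast(mv, "healthy", "stroke")
        summary["group_contrast_healthy_vs_stroke"] = _test_to_dict(gt)
        contrast_rows.append(("healthy_vs_stroke", gt.n_x, gt.n_y,
                              np.nan, np.nan, gt))
    if "combined" in config.groups:
        wb = ctr.within_between_contrast(
            mv, bootstrap_reps=config.bootstrap_reps, rng=rng)
        summary["within_between_contrast"] = _test_to_dict(wb)
        contrast_rows.append(("within_vs_between", wb.n_x, wb.n_y,
                              np.nan, np.nan, wb))
        cats = ctr.category_contrasts(
            mv, bootstrap_reps=config.bootstrap_reps, rng=rng)
        summary["category_contrasts"] = [
            {"oxmet_category": c.oxmet_category,
             "median_between": c.median_between,
             "median_within": c.median_within,
             "n_between": c.n_between, "n_within": c.n_within,
             "test": _test_to_dict(c.test)} for c in cats]
        for c in cats:
            contrast_rows.append((f"category_{c.oxmet_category}",
                                  c.n_within, c.n_between,
                                  c.median_within, c.median_between, c.test))
        if ("none" in config.covariate_conditions
                and "age_education" in config.covariate_conditions):
            cc = ctr.covariate_contrast(
                mv, paired=config.option("paired_covariate"),
                bootstrap_reps=config.bootstrap_reps, rng=rng)
            summary["covariate_contrast"] = {
                "median_without": cc.median_without,
                "median_with": cc.median_with,
                "test": _test_to_dict(cc.test)}
            contrast_rows.append(("covariates_without_vs_with",
                                  cc.test.n_x, cc.test.n_y,
                                  cc.median_without, cc.median_with,
                                  cc.test))
    if contrast_rows:
        pd.DataFrame(
            [(name, nx, ny, m1, m2, t.statistic, t.p_value, t.effect_r,
              t.effect_r_ci_low, t.effect_r_ci_high, t.method)
             for name, nx, ny, m1, m2, t in contrast_rows],
            columns=["contrast", "n_first", "n_second", "median_first",
                     "median_second", "statistic", "p_value", "effect_r",
                     "effect_r_ci_low", "effect_r_ci_high", "method"],
        ).to_csv(run_dir / "contrasts.csv", index=False)
        lines.append(f"contrasts computed: {len(contrast_rows)}")

    (run_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, default=float) + "\n")
    (run_dir / "log.txt").write_text("\n".join(lines) + "\n")
    for line in lines:
        log.info(line)
    return run_dir
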