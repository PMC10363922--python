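"""Synthetic cohort generation.

Emulates the statistical structure the validation analysis assumes: two
sample groups (neurologically healthy adults, default n=88, and stroke
survivors, default n=117), a single latent "executive ability" factor
loading on every raw task observation, direction coding (accuracy-like
fields load positively, time- and error-like fields negatively), small
linear age and education effects on performance, and low-rate
missing-completely-at-random cells.

The generative model, per participant i:

    g_i   ~ Normal(shift_group, latent_sd)          latent ability
    p_i   = g_i + age_effect * (age_i − 70) + education_effect * (edu_i − 14)
    z_if  = loading(category of f) * p_i + Normal(0, noise_sd)

Each raw field f is a strictly increasing transform of z_if onto a
realistic scale — exponential for times and error counts (positive,
right-skewed), affine for accuracies — so rank correlations among raw
fields are exactly those of the latent z scores.  Demographics follow the
groupwise means/SDs of the study cohort (configurable).  All draws flow
from one seeded generator in a fixed documented order: ages, educations,
latent abilities, the noise matrix, the missingness mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .metrics import RAW_FIELDS, raw_schema
from .records import ParticipantRecord, records_to_frame

#: Groupwise demographic means/SDs (age years, education years).
DEFAULT_DEMOGRAPHICS = {
    "healthy": {"age_mean": 66.69, "age_sd": 11.67,
                "edu_mean": 15.56, "edu_sd": 3.63},
    "stroke": {"age_mean": 72.40, "age_sd": 12.47,
               "edu_mean": 12.89, "edu_sd": 3.51},
}

#: Per-field output scale: (transform, location, spread).  ``exp`` maps
#: z -> exp(loc + spread*z); ``linear`` maps z -> loc + spread*z.
_FIELD_SCALE = {
    "time": ("exp", 4.0, 0.35),        # ~55 s median times
    "error": ("exp", 0.7, 0.6),        # ~2 median error counts
    "accuracy": ("linear", 20.0, 4.0),  # ~20-point accuracy scores
}

DEFAULT_LOADINGS = {"accuracy": 0.7, "time": -0.7, "error": -0.7}


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the synthetic cohort generator.

    ``loading_by_category`` gives the signed loading of the latent factor
    on raw fields of each category (negative for fields where higher means
    worse).  ``group_shift`` is the latent decrement applied to the stroke
    group mean (negative = stroke performs worse).  ``age_effect`` and
    ``education_effect`` are in latent-SD units per year.
    """

    n_healthy: int = 88
    n_stroke: int = 117
    latent_sd: float = 1.0
    group_shift: float = -1.0
    loading_by_category: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOADINGS))
    noise_sd: float = 0.5
    age_effect: float = -0.02
    education_effect: float = 0.03
    missing_rate: float = 0.02
    seed: int = 0
    demographics: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v)
                                 for g, v in DEFAULT_DEMOGRAPHICS.items()})

    def validate(self) -> None:
        if self.n_healthy < 0:
            raise ValueError(f"n_healthy must be >= 0, got {self.n_healthy}")
        if self.n_stroke < 0:
            raise ValueError(f"n_stroke must be >= 0, got {self.n_stroke}")
        if not self.latent_sd > 0:
            raise ValueError(f"latent_sd must be > 0, got {self.latent_sd}")
        if not self.noise_sd > 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(
                f"missing_rate must be in [0, 1), got {self.missing_rate}")
        for cat, loading in self.loading_by_category.items():
            if not -1 <= loading <= 1:
                raise ValueError(
                    f"loading_by_category[{cat!r}] must be in [-1, 1], "
                    f"got {loading}")


def generate_cohort(params: CohortParams) -> list[ParticipantRecord]:
    """Draw a cohort of ``n_healthy + n_stroke`` participants.

    Healthy records come first (ids ``hc001``...), then stroke
    (``ss001``...).  Identical params, including the seed, give identical
    output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_healthy + params.n_stroke
    groups = np.array(["healthy"] * params.n_healthy
                      + ["stroke"] * params.n_stroke)

    age = np.empty(n)
    edu = np.empty(n)
    for g in ("healthy", "stroke"):
        demo = params.demographics[g]
        mask = groups == g
        age[mask] = rng.normal(demo["age_mean"], demo["age_sd"], mask.sum())
        edu[mask] = rng.normal(demo["edu_mean"], demo["edu_sd"], mask.sum())
    age = np.clip(age, 18.0, None)
    edu = np.clip(edu, 4.0, None)

    g_mean = np.where(groups == "stroke", params.group_shift, 0.0)
    latent = rng.normal(g_mean, params.latent_sd)
    ability = (latent
               + params.age_effect * (age - 70.0)
               + params.education_effect * (edu - 14.0))

    schema = raw_schema().set_index("field")
    noise = rng.normal(0.0, params.noise_sd, size=(n, len(RAW_FIELDS)))
    values = np.empty((n, len(RAW_FIELDS)))
    for j, f in enumerate(RAW_FIELDS):
        cat = schema.loc[f, "category"]
        loading = params.loading_by_category.get(cat, 0.0)
        z = loading * ability + noise[:, j]
        transform, loc, spread = _FIELD_SCALE[cat]
        if transform == "exp":
            values[:, j] = np.exp(loc + spread * z)
        else:
            values[:, j] = loc + spread * z

    missing = rng.random(size=(n, len(RAW_FIELDS))) < params.missing_rate

    records = []
    for i in range(n):
        prefix = "hc" if groups[i] == "healthy" else "ss"
        idx = i + 1 if groups[i] == "healthy" else i + 1 - params.n_healthy
        raw = {f: float(values[i, j]) for j, f in enumerate(RAW_FIELDS)
               if not missing[i, j]}
        records.append(ParticipantRecord(
            id=f"{prefix}{idx:03d}",
            group=str(groups[i]),
            age=float(age[i]),
            education=float(edu[i]),
            raw=raw,
        ))
    return records


def null_params(**overrides) -> CohortParams:
    """Params for a cohort with no latent structure (all loadings zero).

    Every metric is then independent noise, so the multiverse's share of
    significant correlations estimates the type-I rate.
    """
    base = CohortParams(loading_by_category={"accuracy": 0.0, "time": 0.0,
                                             "error": 0.0},
                        group_shift=0.0, age_effect=0.0,
                        education_effect=0.0, missing_rate=0.0)
    return replace(base, **overrides)


def cohort_to_csv(records: Sequence[ParticipantRecord],
                  path: str | Path) -> None:
    """Write the canonical wide CSV (missing raw fields as empty cells)."""
    if not records:
        raise ValueError("cannot write an empty cohort")
    frame = records_to_frame(records, RAW_FIELDS)
    frame.to_csv(path, index=False, na_rep="")


def expected_rank_correlation(loading_x: float, loading_y: float,
                              noise_sd: float,
                              latent_sd: float = 1.0) -> float:
    """Population Pearson correlation of two latent z scores.

    corr = l_x l_y Var(p) / sqrt((l_x^2 Var(p) + s^2)(l_y^2 Var(p) + s^2));
    the large-n Spearman correlation of the observed fields approaches
    this (rank statistics are invariant to the increasing output
    transforms, and the rank version of a bivariate-normal correlation
    deviates from the Pearson value by less than 0.02 over the relevant
    range).
    """
    v = latent_sd ** 2
    num = loading_x * loading_y * v
    den = np.sqrt((loading_x ** 2 * v + noise_sd ** 2)
                  * (loading_y ** 2 * v + noise_sd ** 2))
    return float(num / den)
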