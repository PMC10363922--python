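"""Permutation null model and the median-of-curve test."""

import numpy as np
import pytest

import speccurve as sc
from speccurve import metrics as met
from speccurve.engine import specs_digest
from speccurve.nullinf import NullModel, permute_comparators
from speccurve.records import records_to_frame


def make_null_model(observed, medians, shares=None, seed=0):
    medians = tuple(float(m) for m in medians)
    if shares is None:
        shares = tuple(0.05 for _ in medians)
    return NullModel(len(medians), medians, tuple(shares), seed,
                     "task_blocks_within_group",
                     specs_digest([r.spec for r in observed.results]))


@pytest.fixture(scope="module")
def cohort_frame(default_cohort):
    return records_to_frame(default_cohort, met.RAW_FIELDS)


class TestPermutationScheme:
    def test_marginals_groups_covariates_and_x_side_preserved(
            self, cohort_frame):
        rng = np.random.default_rng(3)
        perm = permute_comparators(cohort_frame, rng)
        for col in ("id", "group", "age", "education"):
            assert (perm[col] == cohort_frame[col]).all()
        oxmet_cols = [f for f in met.RAW_FIELDS if f.startswith("oxmet")]
        assert perm[oxmet_cols].equals(cohort_frame[oxmet_cols])
        schema = met.raw_schema()
        comparator_cols = schema.loc[schema["task"] != "oxmet", "field"]
        for g in ("healthy", "stroke"):
            mask = cohort_frame["group"] == g
            for col in comparator_cols:
                a = np.sort(cohort_frame.loc[mask, col].to_numpy())
                b = np.sort(perm.loc[mask, col].to_numpy())
                np.testing.assert_array_equal(a, b)

    def test_task_rows_move_as_blocks(self):
        """A participant's Trails observations stay together post-shuffle."""
        recs = sc.generate_cohort(sc.CohortParams(missing_rate=0.0, seed=8))
        frame = records_to_frame(recs, met.RAW_FIELDS)
        rng = np.random.default_rng(4)
        perm = permute_comparators(frame, rng)
        trails_cols = list(met.raw_schema().query(
            "task == 'trails'")["field"])
        original_rows = {tuple(r) for r in frame[trails_cols].to_numpy()}
        permuted_rows = {tuple(r) for r in perm[trails_cols].to_numpy()}
        assert original_rows == permuted_rows

    def test_association_destroyed(self, rng):
        recs = []
        for i in range(60):
            t = float(rng.uniform(10, 90))
            raw = {f: float(v) for f, v in
                   zip(met.RAW_FIELDS, rng.uniform(1, 50, len(met.RAW_FIELDS)))}
            raw["oxmet_time_completion"] = t
            raw["rule_time"] = t  # y identical to x before shuffling
            recs.append(sc.ParticipantRecord(f"p{i}", "healthy", 60.0, 12.0,
                                             raw))
        specs = sc.enumerate_specs(["oxmet_time"], ["rule_time"],
                                   ["healthy"], ["none"])
        assert sc.run_multiverse(recs, specs).median_rho == pytest.approx(1.0)
        med, _ = sc.permute_null_once(recs, specs, 0.05,
                                      np.random.default_rng(5))
        assert abs(med) < 0.5

    @pytest.mark.parametrize("scheme", ["task_blocks_pooled",
                                        "fields_within_group"])
    def test_alternative_schemes_preserve_marginals(self, cohort_frame,
                                                    scheme):
        rng = np.random.default_rng(6)
        perm = permute_comparators(cohort_frame, rng, scheme)
        a = np.sort(cohort_frame["trails_time_b"].to_numpy())
        b = np.sort(perm["trails_time_b"].to_numpy())
        np.testing.assert_array_equal(a, b)

    def test_unknown_scheme_rejected(self, cohort_frame):
        with pytest.raises(ValueError, match="scheme"):
            permute_comparators(cohort_frame, np.random.default_rng(0),
                                "telepathy")


class TestBuildNull:
    @pytest.fixture(scope="class")
    def small(self, default_cohort):
        specs = sc.enumerate_specs(
            ["oxmet_accuracy", "oxmet_time"],
            ["trails_acc_b", "trails_time_b", "rule_errors"],
            ["combined"], ["none"])
        return default_cohort, specs

    def test_vector_lengths_match_B(self, small):
        recs, specs = small
        null = sc.build_null(recs, specs, 0.05, B=7, seed=1)
        assert null.B == 7
        assert len(null.null_medians) == 7
        assert len(null.null_sig_shares) == 7
        assert null.to_frame().shape == (7, 3)

    def test_same_seed_reproduces(self, small):
        recs, specs = small
        a = sc.build_null(recs, specs, 0.05, B=4, seed=2)
        b = sc.build_null(recs, specs, 0.05, B=4, seed=2)
        c = sc.build_null(recs, specs, 0.05, B=4, seed=3)
        assert a == b
        assert a.null_medians != c.null_medians


class TestCurveTest:
    @pytest.fixture(scope="class")
    def observed(self, default_cohort):
        specs = sc.enumerate_specs(["oxmet_accuracy"], ["trails_acc_b"],
                                   ["combined"], ["none"])
        return sc.run_multiverse(default_cohort, specs)

    def test_zero_qualifying_reports_floor_bound(self, observed):
        null = make_null_model(observed,
                               np.full(500, observed.median_rho - 0.5))
        ct = sc.test_curve(observed, null)
        assert ct.p_median == pytest.approx(0.002)
        assert ct.p_median_is_bound
        assert ct.p_floor == pytest.approx(1 / 500)

    def test_halving_rule_arithmetic(self, observed):
        meds = np.full(500, observed.median_rho - 0.5)
        meds[:50] = observed.median_rho + 0.5  # 50 of 500 qualify
        ct = sc.test_curve(observed, make_null_model(observed, meds))
        assert ct.p_median == pytest.approx(0.05)
        assert not ct.p_median_is_bound

    def test_all_qualifying_gives_half(self, observed):
        null = make_null_model(observed,
                               np.full(20, observed.median_rho + 0.5))
        assert sc.test_curve(observed, null).p_median == pytest.approx(0.5)

    def test_two_dp_rounding_rule(self, observed):
        # .195 and .2049 both compare as .20 under the 2-dp rule
        from speccurve.nullinf import _halved_upper_p, _round_decimal
        assert _round_decimal(0.195, 2) == pytest.approx(0.20)
        assert _round_decimal(0.2049, 2) == pytest.approx(0.20)
        for obs in (0.2049, 0.195):
            # a null median of .195 also rounds to .20 and qualifies
            p, bound = _halved_upper_p(obs, np.array([0.195, 0.10]), 2, 2)
            assert not bound
            assert p == pytest.approx((1 / 2) / 2)
            # but a null median of .19 sits strictly below: zero qualify
            p, bound = _halved_upper_p(obs, np.array([0.19, 0.10]), 2, 2)
            assert bound and p == pytest.approx(1 / 2)

    def test_p_never_below_floor(self, observed):
        for shift in (-0.5, -0.1, 0.1, 0.5):
            null = make_null_model(
                observed, observed.median_rho + shift + np.zeros(40))
            ct = sc.test_curve(observed, null)
            assert ct.p_median >= 1 / 40 - 1e-12
            assert ct.p_sig_share >= 1 / 40 - 1e-12

    def test_p_monotone_in_observed_median(self, observed):
        rng = np.random.default_rng(9)
        meds = rng.normal(0, 0.1, 200)
        ps = []
        for margin in (-0.3, -0.1, 0.0, 0.1, 0.3):
            # larger margin = observed sits further above the null medians
            shifted = make_null_model(observed, meds - margin
                                      + observed.median_rho)
            ps.append(sc.test_curve(observed, shifted).p_median)
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_spec_mismatch_is_an_error(self, observed, default_cohort):
        other_specs = sc.enumerate_specs(["oxmet_time"], ["rule_time"],
                                         ["combined"], ["none"])
        other = sc.run_multiverse(default_cohort, other_specs)
        null = make_null_model(other, np.zeros(10))
        with pytest.raises(ValueError, match="specification"):
            sc.test_curve(observed, null)

    def test_unhalved_share_comparison_option(self, observed):
        shares = np.full(100, 1.0)  # every null replicate fully significant
        null = make_null_model(observed, np.zeros(100), shares)
        halved = sc.test_curve(observed, null)
        plain = sc.test_curve(observed, null, halve_sig_share=False)
        assert halved.p_sig_share == pytest.approx(0.5)
        assert plain.p_sig_share == pytest.approx(1.0)
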