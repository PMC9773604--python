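"""Statistical kernels and the stratified method-comparison report."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dentalage as da

from conftest import make_record


class TestMeanErrors:
    @pytest.mark.parametrize(
        "errors, expected",
        [
            ([1.0, -1.0], (0.0, math.sqrt(2))),
            ([0.3, 0.3, 0.3], (0.3, 0.0)),
            ([0.2, -0.1, 0.5, 0.0], (0.15, 0.2646)),
        ],
    )
    def test_mean_error(self, errors, expected):
        me, sd = da.mean_error(errors)
        assert me == pytest.approx(expected[0])
        assert sd == pytest.approx(expected[1], abs=1e-4)

    @pytest.mark.parametrize(
        "errors, expected",
        [
            ([1.0, -1.0], (1.0, 0.0)),
            ([0.0, 0.0, 0.0], (0.0, 0.0)),
            ([0.2, -0.1, 0.5, 0.0], (0.20, 0.2160)),
        ],
    )
    def test_mean_absolute_error(self, errors, expected):
        mae, sd = da.mean_absolute_error(errors)
        assert mae == pytest.approx(expected[0])
        assert sd == pytest.approx(expected[1], abs=1e-4)

    def test_single_value_has_no_sd(self):
        me, sd = da.mean_error([0.4])
        assert me == 0.4 and math.isnan(sd)

    def test_empty_input_rejected(self):
        for fn in (da.mean_error, da.mean_absolute_error, da.error_band_frequencies):
            with pytest.raises(da.ValidationError):
                fn([])

    @given(st.lists(st.floats(-3, 3), min_size=2, max_size=40))
    def test_mae_dominates_absolute_me(self, errors):
        me, _ = da.mean_error(errors)
        mae, _ = da.mean_absolute_error(errors)
        assert mae >= abs(me) - 1e-12
        # one-signed samples achieve equality
        if min(errors) >= 0 or max(errors) <= 0:
            assert mae == pytest.approx(abs(me))


class TestPairedT:
    def test_no_difference(self):
        res = da.paired_t_test([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_symmetric_differences_give_zero_t(self):
        res = da.paired_t_test([1, -1, 1, -1], [0, 0, 0, 0])
        assert res.statistic == 0.0

    def test_matches_closed_form_oracle(self):
        d = np.array([0.2, -0.1, 0.5, 0.0])
        res = da.paired_t_test(d, np.zeros(4))
        t_oracle = d.mean() / (d.std(ddof=1) / 2.0)
        assert res.statistic == pytest.approx(t_oracle, abs=1e-10)
        assert res.statistic == pytest.approx(1.1339, abs=1e-3)
        assert res.df == 3
        assert res.pvalue == pytest.approx(0.339, abs=1e-3)
        assert res.ci_low < d.mean() < res.ci_high

    def test_constant_nonzero_difference_flags_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = da.paired_t_test([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])
        assert math.isinf(res.statistic) and res.pvalue == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(da.ValidationError):
            da.paired_t_test([1.0, 2.0], [1.0])

    @given(
        st.lists(
            st.floats(-2, 2).map(lambda x: round(x, 3)), min_size=3, max_size=30
        ).filter(lambda d: np.std(d, ddof=1) > 1e-6)
    )
    def test_closed_form_on_random_fixtures(self, d):
        d = np.asarray(d)
        res = da.paired_t_test(d, np.zeros_like(d))
        expected = d.mean() * math.sqrt(d.size) / d.std(ddof=1)
        assert res.statistic == pytest.approx(expected, abs=1e-10)


class TestIndependentT:
    def test_identical_groups(self):
        res = da.independent_t_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.statistic == pytest.approx(0.0) and res.pvalue == pytest.approx(1.0)

    def test_zero_variance_groups_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = da.independent_t_test([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert math.isinf(res.statistic)

    def test_matches_welch_closed_form(self):
        a = np.array([0.1, 0.3, 0.2, 0.4])
        b = np.array([0.5, 0.7, 0.6, 0.8])
        res = da.independent_t_test(a, b)
        se = math.sqrt(a.var(ddof=1) / 4 + b.var(ddof=1) / 4)
        t_oracle = (a.mean() - b.mean()) / se
        num = (a.var(ddof=1) / 4 + b.var(ddof=1) / 4) ** 2
        den = (a.var(ddof=1) / 4) ** 2 / 3 + (b.var(ddof=1) / 4) ** 2 / 3
        assert res.statistic == pytest.approx(t_oracle, abs=1e-10)
        assert res.df == pytest.approx(num / den, abs=1e-10)
        assert 0.0 < res.pvalue < 0.01

    def test_small_group_rejected(self):
        with pytest.raises(da.ValidationError):
            da.independent_t_test([1.0], [1.0, 2.0])


class TestErrorBands:
    @pytest.mark.parametrize(
        "errors, expected",
        [
            ([0.5, 1.5, 2.5], (33.3, 33.3, 33.3)),
            ([0.99, 1.00], (50.0, 50.0, 0.0)),  # boundary goes upward
            ([0.2, 0.4, 1.1, 3.0], (50.0, 25.0, 25.0)),
            ([-0.5, 0.5], (100.0, 0.0, 0.0)),  # bands use |error|
        ],
    )
    def test_band_percentages(self, errors, expected):
        assert da.error_band_frequencies(errors) == expected

    @given(st.lists(st.floats(-4, 4), min_size=1, max_size=60))
    def test_bands_partition_to_100(self, errors):
        bands = da.error_band_frequencies(errors)
        assert sum(bands) == pytest.approx(100.0, abs=0.15)


class TestICC:
    def test_identical_channels_give_exactly_one(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0], [3.0, 3.0]])
        assert da.icc_agreement(x).value == 1.0

    def test_shrout_fleiss_worked_example(self):
        """Published two-way random/absolute-agreement oracle: ICC(2,1) = 0.29."""
        sf = np.array(
            [
                [9, 2, 5, 8],
                [6, 1, 3, 2],
                [8, 4, 6, 8],
                [7, 1, 2, 6],
                [10, 5, 6, 9],
                [6, 2, 4, 7],
            ],
            dtype=float,
        )
        assert da.icc_agreement(sf).value == pytest.approx(0.29, abs=0.005)

    def test_cross_check_against_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(3)
        x = rng.normal(12, 2, size=20)
        ratings = np.column_stack([x, x + rng.normal(0, 0.7, 20)])
        ours = da.icc_agreement(ratings).value
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(20), 2),
                "rater": np.tile(["r1", "r2"], 20),
                "score": ratings.ravel(),
            }
        )
        icc = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        # two-way random, absolute agreement, single rater: labelled ICC2 or
        # ICC(A,1) depending on pingouin version; it is always the second row
        mask = icc["Type"].isin(["ICC2", "ICC(A,1)"])
        theirs = float(icc.loc[mask, "ICC"].iloc[0]) if mask.any() else float(
            icc["ICC"].iloc[1]
        )
        assert ours == pytest.approx(theirs, abs=1e-9)

    def test_dominant_noise_drives_icc_down(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1.0, size=200)
        ratings = np.column_stack([x, x + rng.normal(0, 10.0, 200)])
        assert da.icc_agreement(ratings).value < 0.3

    def test_icc_decreases_with_misstaging(self, model):
        ds = da.simulate_cohort(da.CohortSpec(n=250, seed=31), model)
        values = []
        for p in (0.0, 0.1, 0.3):
            twin = da.simulate_repeat_ratings(ds, p, seed=41)
            da1 = [da.quick_estimate(r).da_years for r in ds]
            da2 = [da.quick_estimate(r).da_years for r in twin]
            values.append(da.icc_agreement(np.column_stack([da1, da2])).value)
        assert values[0] == 1.0
        assert values[0] > values[1] > values[2]

    def test_no_between_subject_variance_is_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            res = da.icc_agreement(np.full((4, 2), 3.0))
        assert math.isnan(res.value)

    def test_missing_cells_rejected(self):
        x = np.array([[1.0, np.nan], [2.0, 2.0]])
        with pytest.raises(da.ValidationError):
            da.icc_agreement(x)


@pytest.fixture(scope="module")
def report(model):
    ds = da.simulate_cohort(da.CohortSpec(n=400, seed=17), model)
    atlases = {
        s: da.build_atlas_from_model(model, s) for s in (da.Sex.MALE, da.Sex.FEMALE)
    }
    ests = da.estimate_dataset(
        ds, ("quick", "atlas"), quick_params=da.QuickParams(), atlas=atlases
    )
    return ds, ests, da.evaluate(ds, ests)


class TestEvaluate:
    def test_single_group_when_unstratified(self, model):
        ds = da.simulate_cohort(da.CohortSpec(n=30, seed=5), model)
        ests = da.estimate_dataset(ds, ("quick",), quick_params=da.QuickParams())
        rep = da.evaluate(ds, ests, stratify_by=())
        assert len(rep.stats) == 1
        assert rep.stats.loc[0, "n"] == 30

    def test_report_me_matches_kernel_per_stratum(self, report):
        ds, ests, rep = report
        by_id = {r.subject_id: r for r in ds}
        row = rep.stats.iloc[0]
        errors = [
            by_id[e.subject_id].ca_years - e.da_years
            for e in ests
            if e.method == row["method"]
            and by_id[e.subject_id].sex.value == row["sex"]
            and int(by_id[e.subject_id].ca_years) == row["bracket"]
        ]
        me, sd = da.mean_error(errors)
        assert row["me"] == pytest.approx(me)
        assert row["me_sd"] == pytest.approx(sd)
        bands = da.error_band_frequencies(errors)
        assert (row["pct_under_1"], row["pct_1_to_2"], row["pct_2_plus"]) == bands

    def test_mae_dominates_me_in_every_stratum(self, report):
        _, _, rep = report
        assert ((rep.stats["mae"] + 1e-12) >= rep.stats["me"].abs()).all()

    def test_overall_has_one_row_per_method(self, report):
        _, _, rep = report
        assert sorted(rep.overall["method"]) == ["atlas", "quick"]
        assert (rep.overall[["bracket", "sex"]] == "all").all().all()

    def test_sex_comparison_present_per_method(self, report):
        _, _, rep = report
        assert sorted(rep.sex_comparison["method"]) == ["atlas", "quick"]

    def test_orphan_estimate_is_join_error(self, model):
        ds = da.simulate_cohort(da.CohortSpec(n=10, seed=2), model)
        stray = da.Estimate("ghost", "quick", 12.0, 1.0)
        with pytest.raises(da.DentalAgeError, match="ghost"):
            da.evaluate(ds, [stray])

    def test_multi_observer_dataset_rejected(self, model):
        ds = da.simulate_cohort(da.CohortSpec(n=10, seed=2), model)
        both = da.Dataset(
            ds.records + da.simulate_repeat_ratings(ds, 0.0, 1).records
        )
        ests = [da.quick_estimate(r) for r in ds]
        with pytest.raises(da.ValidationError, match="observer"):
            da.evaluate(both, ests)

    def test_summary_and_json_render(self, report):
        _, _, rep = report
        text = rep.summary()
        assert "positive = underestimate" in text
        assert "multiple-testing" in text
        import json

        payload = json.loads(rep.to_json())
        assert payload["stratify_by"] == ["method", "bracket", "sex"]
        assert len(payload["overall"]) == 2
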