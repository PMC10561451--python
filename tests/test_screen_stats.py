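"""Well summaries, RPS, ranking, 4PL fitting, Mann-Whitney, QC tables."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu

import fociscreen as fs
from fociscreen.screen_stats import QC_BIN_WIDTH


LAYOUT_ROW = {"plate": "P1", "well": "B02", "role": "compound", "compound_id": "C1"}


def _records(n_pos, n_neg, n_nonsig):
    classes = (
        ["foci_positive"] * n_pos + ["foci_negative"] * n_neg + ["non_signaling"] * n_nonsig
    )
    return pd.DataFrame(
        {"plate": "P1", "well": "B02", "field": 0, "class": classes}
    )


class TestSummarizeWell:
    def test_percentage_formula(self):
        ws = fs.summarize_well(_records(30, 10, 5), LAYOUT_ROW)
        assert ws.pct_foci_positive == pytest.approx(75.0)
        assert ws.n_cells == 45

    def test_zero_positive(self):
        assert fs.summarize_well(_records(0, 40, 0), LAYOUT_ROW).pct_foci_positive == 0.0

    def test_only_nonsignaling_is_missing(self):
        ws = fs.summarize_well(_records(0, 0, 12), LAYOUT_ROW)
        assert ws.missing and np.isnan(ws.pct_foci_positive)

    def test_multi_well_records_rejected(self):
        rec = _records(1, 1, 0)
        rec.loc[0, "well"] = "C03"
        with pytest.raises(ValueError, match="span"):
            fs.summarize_well(rec, LAYOUT_ROW)


class TestComputeRps:
    def test_median_compound_gets_100(self):
        rps = fs.compute_rps(pd.Series({"a": 3.0, "b": 5.0, "c": 9.0}))
        assert rps["b"] == pytest.approx(100.0)

    def test_arithmetic(self):
        rps = fs.compute_rps(pd.Series({"a": 2.0, "b": 4.0, "c": 8.0}))
        assert list(rps) == [50.0, 100.0, 200.0]

    def test_all_equal_all_100(self):
        rps = fs.compute_rps(pd.Series({"a": 7.0, "b": 7.0, "c": 7.0}))
        assert (rps == 100.0).all()

    def test_missing_excluded_from_median_and_stay_missing(self):
        rps = fs.compute_rps(pd.Series({"a": 2.0, "b": np.nan, "c": 8.0}))
        assert np.isnan(rps["b"])
        assert rps["a"] == pytest.approx(100.0 * 2.0 / 5.0)

    def test_zero_median_rejected(self):
        with pytest.raises(ValueError, match="median"):
            fs.compute_rps(pd.Series({"a": 0.0, "b": 0.0, "c": 0.0}))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.5, 500.0), min_size=1, max_size=30),
    )
    def test_median_rps_is_100_property(self, values):
        s = pd.Series(values, index=[f"c{i}" for i in range(len(values))])
        rps = fs.compute_rps(s)
        assert float(rps.median()) == pytest.approx(100.0, abs=1e-9)
        assert (rps >= 0).all()


class TestAggregateAndRank:
    def test_selects_exactly_n(self):
        rng = np.random.default_rng(0)
        ids = [f"C{i:03d}" for i in range(315)]
        reps = [pd.Series(rng.uniform(50, 150, 315), index=ids) for _ in range(3)]
        out = fs.aggregate_and_rank(reps, n_select=12)
        assert out["selected"].sum() == 12
        assert sorted(out["rank"]) == list(range(1, 316))
        # selected are exactly the 12 smallest means
        assert out.nsmallest(12, "mean_rps")["selected"].all()

    def test_fewer_compounds_than_n_select_warns(self):
        reps = [pd.Series({"a": 90.0, "b": 110.0})]
        with pytest.warns(UserWarning, match="selecting all"):
            out = fs.aggregate_and_rank(reps, n_select=12)
        assert out["selected"].all()

    def test_tie_broken_by_compound_id(self):
        reps = [pd.Series({"b": 100.0, "a": 100.0, "c": 100.0})]
        out = fs.aggregate_and_rank(reps, n_select=1)
        assert list(out["compound_id"]) == ["a", "b", "c"]
        assert out.loc[out["selected"], "compound_id"].tolist() == ["a"]

    def test_duplicate_compound_rejected(self):
        dup = pd.Series([1.0, 2.0], index=["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            fs.aggregate_and_rank([dup])

    def test_missing_replicate_mean_over_available(self):
        reps = [pd.Series({"a": 80.0, "b": 120.0}), pd.Series({"a": 100.0})]
        out = fs.aggregate_and_rank(reps, n_select=1).set_index("compound_id")
        assert out.loc["a", "mean_rps"] == pytest.approx(90.0)
        assert out.loc["a", "n_reps"] == 2
        assert out.loc["b", "n_reps"] == 1


def _4pl(d, bottom, top, ic50, hill):
    return bottom + (top - bottom) / (1 + np.exp(hill * (np.log(d) - np.log(ic50))))


class TestFitDoseResponse:
    DOSES = np.array([1.0, 3.0, 10.0, 30.0, 60.0, 100.0, 200.0, 400.0])

    def test_noise_free_round_trip_within_1pct(self):
        y = _4pl(self.DOSES, 5.0, 95.0, 40.0, 1.5)
        fit = fs.fit_dose_response(self.DOSES, y)
        assert fit.converged
        assert fit.ic50 == pytest.approx(40.0, rel=0.01)
        assert fit.bottom <= fit.top

    def test_constant_responses_degenerate(self):
        fit = fs.fit_dose_response(self.DOSES, np.full(8, 50.0))
        assert not fit.converged and fit.ic50 is None

    def test_noise_monte_carlo_median_error(self):
        rng = np.random.default_rng(1)
        y = _4pl(self.DOSES, 10.0, 90.0, 40.0, 1.2)
        errors = []
        for _ in range(200):
            fit = fs.fit_dose_response(
                self.DOSES, y * (1 + 0.05 * rng.standard_normal(8))
            )
            if fit.ic50 is not None:
                errors.append(abs(fit.ic50 - 40.0) / 40.0)
        assert np.median(errors) <= 0.10
        assert len(errors) >= 190

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError, match="4"):
            fs.fit_dose_response([1.0, 10.0, 100.0], [90.0, 50.0, 10.0])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            fs.fit_dose_response(self.DOSES, [np.nan] * 8)

    def test_zero_dose_mapped_to_pseudo_dose(self):
        doses = np.array([0.0, 1.0, 10.0, 100.0, 1000.0])
        y = _4pl(np.where(doses == 0, 0.01, doses), 0.0, 100.0, 30.0, 1.0)
        fit = fs.fit_dose_response(doses, y)
        assert fit.ic50 == pytest.approx(30.0, rel=0.05)


class TestMannWhitney:
    def test_identical_samples_half_product(self):
        x = np.array([3.0, 1.0, 2.0])
        gc = fs.mann_whitney_u(x, x)
        assert gc.u == pytest.approx(len(x) ** 2 / 2)
        assert gc.direction == "x~y"

    def test_extreme_ordering_u_zero(self):
        gc = fs.mann_whitney_u([1.0, 2.0], [5.0, 6.0, 7.0])
        assert gc.u == 0.0 and gc.direction == "x<y"

    def test_u_matches_pair_counting_all_small_sizes(self):
        rng = np.random.default_rng(3)
        for n1, n2 in itertools.product(range(1, 7), range(1, 7)):
            for _ in range(3):
                x = rng.integers(0, 5, n1).astype(float)  # ties likely
                y = rng.integers(0, 5, n2).astype(float)
                gc = fs.mann_whitney_u(x, y)
                brute = sum(
                    (xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y
                )
                assert gc.u == pytest.approx(brute)
                assert 0.0 <= gc.u <= n1 * n2
                assert gc.method == "exact"

    def test_exact_p_matches_scipy_without_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(loc=0.5, size=6)
            gc = fs.mann_whitney_u(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert gc.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        y = rng.normal(loc=1.0, size=40)
        gc = fs.mann_whitney_u(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert gc.method == "normal"
        assert gc.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fs.mann_whitney_u([], [1.0])


@pytest.fixture(scope="module")
def qc_bundle():
    rng = np.random.default_rng(7)
    ids = [f"C{i:02d}" for i in range(40)]
    mean_rps = rng.uniform(60, 140, 40)
    mean_rps[:6] = rng.uniform(10, 30, 6)  # strong actives
    results = fs.aggregate_and_rank([pd.Series(mean_rps, index=ids)], n_select=6)
    rows = [
        {"role": "compound", "compound_id": cid, "rps": mean_rps[i]}
        for i, cid in enumerate(ids)
    ]
    for _ in range(10):
        rows.append({"role": "control", "compound_id": "", "rps": rng.uniform(90, 110)})
    return fs.screen_qc(results, pd.DataFrame(rows))


class TestScreenQc:
    def test_ecdf_reaches_one(self, qc_bundle):
        assert qc_bundle["ecdf"]["ecdf"].iloc[-1] == pytest.approx(1.0)
        assert qc_bundle["ecdf"]["mean_rps"].is_monotonic_increasing

    def test_histogram_counts_conserved(self, qc_bundle):
        hist = qc_bundle["histograms"]
        assert hist.loc[hist.group == "control", "count"].sum() == 10
        assert hist.loc[hist.group == "selected", "count"].sum() == 6
        assert (hist["bin_high"] - hist["bin_low"]).eq(QC_BIN_WIDTH).all()

    def test_control_vs_selected_comparison_present(self, qc_bundle):
        comparison = qc_bundle["control_vs_selected"]
        assert comparison.n1 == 10 and comparison.n2 == 6
        assert comparison.p_value < 0.01  # planted strong actives
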