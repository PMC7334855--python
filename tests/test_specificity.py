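"""The ±1-coded tissue-specificity model and its variants."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from epimark.exceptions import ValidationError
from epimark.signal_aggregation import FeatureWindow, SignalMatrix
from epimark.io_model import GenomicInterval
from epimark.specificity import (
    SpecificityModelSpec, fit_specificity_model, methylation_specificity,
    select_top_fraction, specificity_matrix, standardize_expression,
    weighted_methylation,
)


def make_matrix(values, tissues, classes=None, feature_ids=None, mark="H3K4me3"):
    values = np.asarray(values, dtype=float)
    return SignalMatrix(
        values=values,
        feature_ids=feature_ids or [f"g{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{i}" for i in range(values.shape[1])],
        tissue_labels=list(tissues),
        exclusion_class=list(classes or tissues),
        mark=mark,
    )


class TestFitSpecificityModel:
    def test_matches_pooled_two_sample_t_worked_example(self):
        fit = fit_specificity_model(
            np.array([4, 5, 6, 1, 2, 3], float),
            ["a"] * 3 + ["b"] * 3,
            SpecificityModelSpec("a"),
        )
        assert fit.b == pytest.approx(1.5)
        assert fit.t == pytest.approx(3 / math.sqrt(2 / 3), abs=1e-10)
        assert fit.n_used == 6

    def test_equal_means_give_zero_effect(self):
        fit = fit_specificity_model(
            np.array([1, 3, 2, 2], float), ["a", "a", "b", "b"],
            SpecificityModelSpec("a"),
        )
        assert fit.b == pytest.approx(0.0) and fit.t == pytest.approx(0.0)

    def test_constant_signal_uses_degenerate_rule(self):
        fit = fit_specificity_model(
            np.full(6, 7.0), ["a"] * 3 + ["b"] * 3, SpecificityModelSpec("a")
        )
        assert fit.t == 0.0

    def test_matches_scipy_pooled_t_over_random_partitions(self, rng):
        for _ in range(200):
            n1 = int(rng.integers(2, 8))
            n2 = int(rng.integers(2, 12))
            y = rng.normal(0, 1, n1 + n2)
            tissues = ["a"] * n1 + ["b"] * n2
            fit = fit_specificity_model(y, tissues, SpecificityModelSpec("a"))
            t_ref = sps.ttest_ind(y[:n1], y[n1:], equal_var=True).statistic
            assert fit.t == pytest.approx(t_ref, abs=1e-10)

    def test_matches_statsmodels_ols_with_covariates(self, rng):
        import statsmodels.api as sm

        n = 24
        y = rng.normal(0, 1, n)
        tissues = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        sex = rng.choice(["m", "f"], n)
        study = rng.choice(["s1", "s2", "s3"], n)
        cov = pd.DataFrame({"sex": sex, "study": study})
        fit = fit_specificity_model(
            y, tissues, SpecificityModelSpec("a", covariates=cov)
        )
        x = np.where(np.array(tissues) == "a", 1.0, -1.0)
        X = pd.concat(
            [pd.Series(x, name="tissue"),
             pd.get_dummies(cov.astype("category"), drop_first=True, dtype=float)],
            axis=1,
        )
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        assert fit.b == pytest.approx(ref.params["tissue"], abs=1e-10)
        assert fit.se == pytest.approx(ref.bse["tissue"], abs=1e-10)
        assert fit.t == pytest.approx(ref.tvalues["tissue"], abs=1e-10)

    def test_inverting_coding_negates_b_and_t_exactly(self, rng):
        y = rng.normal(0, 1, 12)
        tissues = ["a"] * 4 + ["b"] * 8
        std = fit_specificity_model(y, tissues, SpecificityModelSpec("a"))
        inv = fit_specificity_model(
            y, tissues, SpecificityModelSpec("a", coding="inverted")
        )
        assert inv.b == -std.b and inv.t == -std.t

    def test_excluding_confound_restores_original_fit(self, rng):
        y = rng.normal(0, 1, 10)
        tissues = ["a"] * 4 + ["b"] * 6
        base = fit_specificity_model(y, tissues, SpecificityModelSpec("a"))
        # append a same-class sample, then remove it through the exclusion set
        y2 = np.append(y, 99.0)
        tissues2 = tissues + ["a_like"]
        ids = [f"s{i}" for i in range(11)]
        spec = SpecificityModelSpec("a", exclusion={"s10"})
        restored = fit_specificity_model(y2, tissues2, spec, sample_ids=ids)
        assert restored.t == base.t and restored.b == base.b

    def test_empty_group_after_exclusion_is_error(self):
        spec = SpecificityModelSpec("a", exclusion={"s2", "s3"})
        with pytest.raises(ValidationError, match="nonempty"):
            fit_specificity_model(
                np.arange(4.0), ["a", "a", "b", "b"], spec,
                sample_ids=["s0", "s1", "s2", "s3"],
            )

    def test_collinear_covariate_is_named(self, rng):
        cov = pd.DataFrame({"dup1": ["x", "x", "y", "y"] * 3,
                            "dup2": ["x", "x", "y", "y"] * 3})
        with pytest.raises(ValidationError, match="collinear"):
            fit_specificity_model(
                rng.normal(0, 1, 12), ["a"] * 6 + ["b"] * 6,
                SpecificityModelSpec("a", covariates=cov),
            )


class TestSpecificityMatrix:
    def test_planted_feature_peaks_in_its_tissue(self, rng):
        tissues = sum([[f"t{i}"] * 3 for i in range(4)], [])
        V = rng.normal(0, 1, (20, 12))
        V[5, [0, 1, 2]] += 4.0  # plant feature 5 in tissue t0
        R = specificity_matrix(make_matrix(V, tissues))
        assert R.t.loc["g5"].idxmax() == "t0"

    def test_same_class_samples_removed_from_comparison(self):
        # B cell and T cell share the immune class; liver is separate.
        tissues = ["bcell"] * 2 + ["tcell"] * 2 + ["liver"] * 2
        classes = ["immune"] * 4 + ["gi"] * 2
        V = np.array([[5.1, 4.9, 5.0, 5.2, 1.0, 1.2]], float)
        M = make_matrix(V, tissues, classes)
        R = specificity_matrix(M)
        # with T cells excluded, testing B cells compares [5,5] vs [1,1]
        assert R.n_used["bcell"] == 4
        # without exclusion the elevated T cells join the comparison group
        R_no = specificity_matrix(M, class_exclusion=False)
        assert R_no.n_used["bcell"] == 6
        assert R.t.loc["g0", "bcell"] > R_no.t.loc["g0", "bcell"]

    def test_distinct_classes_mean_no_exclusion(self, rng):
        tissues = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        M = make_matrix(rng.normal(0, 1, (4, 9)), tissues)
        R = specificity_matrix(M)
        assert (R.n_used == 9).all()

    def test_too_few_outside_class_lists_tissue(self):
        tissues = ["a"] * 2 + ["b"] * 2
        classes = ["shared"] * 4
        with pytest.raises(ValidationError, match="a"):
            specificity_matrix(make_matrix(np.ones((2, 4)), tissues, classes))

    def test_inverted_coding_flips_sign_matrix_wide(self, rng):
        tissues = ["a"] * 3 + ["b"] * 3
        M = make_matrix(rng.normal(0, 1, (5, 6)), tissues)
        R = specificity_matrix(M)
        R_inv = specificity_matrix(M, coding="inverted")
        assert np.allclose(R_inv.t.to_numpy(), -R.t.to_numpy())

    def test_hypomethylated_promoter_scores_positive(self):
        # methylation 0.1 in the tissue, 0.8 elsewhere: inverted coding
        tissues = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        V = np.vstack([
            [0.1, 0.12, 0.11, 0.8, 0.82, 0.78, 0.79, 0.81, 0.8],
            np.full(9, 0.5),
        ])
        V[1, 2] = 0.55
        R = methylation_specificity(make_matrix(V, tissues, mark="WGBS"))
        assert R.t.loc["g0", "a"] > 5
        assert abs(R.t.loc["g1", "a"]) < abs(R.t.loc["g0", "a"])

    def test_nan_features_dropped_before_fit(self, rng):
        tissues = ["a"] * 3 + ["b"] * 3
        V = rng.normal(0, 1, (4, 6))
        V[2, 0] = np.nan
        R = specificity_matrix(make_matrix(V, tissues))
        assert list(R.t.index) == ["g0", "g1", "g3"]


class TestStandardizeExpression:
    def test_sample_column_centered_and_scaled(self):
        M = make_matrix([[1, 4], [2, 4.5], [3, 5]], ["a", "b"], mark="expression")
        S = standardize_expression(M)
        assert np.allclose(S.values[:, 0], [-1, 0, 1])
        assert S.values[:, 1] == pytest.approx([-1, 0, 1])

    def test_idempotent_on_standardized_input(self, rng):
        M = make_matrix(rng.normal(0, 1, (50, 3)), ["a", "b", "c"])
        once = standardize_expression(M)
        twice = standardize_expression(once)
        assert np.allclose(once.values, twice.values)

    def test_constant_sample_rejected(self):
        M = make_matrix([[1, 2], [1, 3]], ["a", "b"])
        with pytest.raises(ValidationError, match="zero-variance"):
            standardize_expression(M)

    def test_per_tissue_mode_pools_tissue_samples(self):
        M = make_matrix([[1, 1, 10], [3, 3, 20]], ["a", "a", "b"])
        S = standardize_expression(M, mode="per_tissue")
        # tissue a pooled values {1,1,3,3} -> mean 2; tissue b {10,20} -> mean 15
        assert S.values[:, 0] == pytest.approx([-0.866, 0.866], abs=1e-3)
        assert S.values[:, 2] == pytest.approx([-0.707, 0.707], abs=1e-3)


class TestWeightedMethylation:
    def test_pooled_read_ratio(self):
        df = pd.DataFrame({"meth_reads": [3, 7], "total_reads": [10, 10]})
        assert weighted_methylation(df) == pytest.approx(0.5)

    def test_weights_by_coverage_not_per_cpg_mean(self):
        df = pd.DataFrame({"meth_reads": [1, 0], "total_reads": [1, 9]})
        assert weighted_methylation(df) == pytest.approx(0.1)

    def test_single_fully_methylated_cpg(self):
        df = pd.DataFrame({"meth_reads": [5], "total_reads": [5]})
        assert weighted_methylation(df) == 1.0

    def test_empty_window_is_missing(self):
        df = pd.DataFrame({"meth_reads": [], "total_reads": []})
        assert math.isnan(weighted_methylation(df))


class TestSelectTopFraction:
    def _result(self, ts, ids=None):
        ids = ids or [f"g{i}" for i in range(len(ts))]
        idx = pd.Index(ids, name="feature_id")
        t = pd.DataFrame({"a": ts}, index=idx)
        from epimark.specificity import SpecificityResult

        return SpecificityResult(b=t * 0, se=t * 0 + 1, t=t,
                                 n_used=pd.Series({"a": 10}))

    def _windows(self, ids):
        return [
            FeatureWindow(g, GenomicInterval("chr1", 100 * i, 100 * i + 50), "promoter")
            for i, g in enumerate(ids)
        ]

    def test_takes_largest_t(self):
        R = self._result([3.1, 2.0, -1.0, 0.5])
        ts = select_top_fraction(R, "a", 0.5, self._windows(["g0", "g1", "g2", "g3"]))
        assert ts.feature_ids == ["g0", "g1"]

    def test_k_one_selects_everything(self):
        R = self._result([1.0, 2.0, 3.0])
        ts = select_top_fraction(R, "a", 1.0, self._windows(["g0", "g1", "g2"]))
        assert len(ts.feature_ids) == 3

    def test_ties_resolved_by_feature_id(self):
        R = self._result([1.0, 1.0, 0.0, 0.0], ids=["gB", "gA", "gC", "gD"])
        ts = select_top_fraction(R, "a", 0.25,
                                 self._windows(["gB", "gA", "gC", "gD"]))
        assert ts.feature_ids == ["gA"]

    def test_fraction_below_one_feature_is_error(self):
        R = self._result([1.0, 2.0])
        with pytest.raises(ValidationError, match="< 1"):
            select_top_fraction(R, "a", 0.2, self._windows(["g0", "g1"]))

    def test_regions_align_with_selection(self):
        R = self._result([3.0, 1.0])
        windows = self._windows(["g0", "g1"])
        ts = select_top_fraction(R, "a", 0.5, windows)
        assert ts.regions[0].start == 0


def test_planted_recovery_on_direct_matrix(rng):
    """Features planted at 3 within-group sd land in the top 5% set."""
    n_feat, tissues = 1000, [f"t{i}" for i in range(10) for _ in range(5)]
    V = rng.normal(0, 1, (n_feat, 50))
    planted = {f"t{i}": list(range(i * 20, i * 20 + 20)) for i in range(10)}
    for i, (tis, feats) in enumerate(planted.items()):
        cols = [j for j, t in enumerate(tissues) if t == tis]
        for f in feats:
            V[f, cols] += 3.0
    M = make_matrix(V, tissues)
    R = specificity_matrix(M)
    windows = [
        FeatureWindow(f"g{i}", GenomicInterval("chr1", 10 * i, 10 * i + 5), "promoter")
        for i in range(n_feat)
    ]
    hits = total = 0
    for tis, feats in planted.items():
        top = select_top_fraction(R, tis, 0.05, windows)
        hits += len(set(top.feature_ids) & {f"g{f}" for f in feats})
        total += len(feats)
    assert hits / total >= 0.9
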