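import numpy as np
import pandas as pd
import pytest
from scipy.stats import gaussian_kde

from octs.activity import (
    ActivityModel,
    ActivityThreshold,
    active_union,
    call_activity,
    fit_activity_model,
    sample_correlation,
)


class TestFitActivityModel:
    def test_mode_recovery_against_fine_grid_oracle(self, bimodal_sample):
        """The 4096-grid argmax agrees with a 10x-finer brute-force search
        of the same KDE, and both land near the planted active mode."""
        model = fit_activity_model(bimodal_sample, sample_id="s")

        positive = bimodal_sample[bimodal_sample > 0]
        log2v = np.log2(positive)
        bw_factor = positive.size ** (-1.0 / 5.0)
        kde = gaussian_kde(log2v, bw_method=bw_factor)
        bw = np.std(log2v, ddof=1) * bw_factor
        fine = np.linspace(log2v.min() - 3 * bw, log2v.max() + 3 * bw, 40960)
        oracle_mu = fine[np.argmax(kde(fine))]

        grid_step = (log2v.max() - log2v.min() + 6 * bw) / 4095
        assert abs(model.mu - oracle_mu) <= grid_step
        assert abs(model.mu - 5.0) <= 0.15

    def test_all_identical_positive_values_degenerate(self):
        values = np.full(200, 8.0)
        with pytest.raises(ValueError, match="degenerate"):
            fit_activity_model(values)

    def test_too_few_positive_values(self):
        values = np.concatenate([np.zeros(100), np.ones(10)])
        with pytest.raises(ValueError, match="positive"):
            fit_activity_model(values)

    def test_fpkm_threshold_closed_form(self):
        model = ActivityModel(sample_id="s", mu=3.0, sd=1.0, z_cutoff=-2.6)
        assert model.fpkm_threshold == pytest.approx(2.0 ** 0.4)

    def test_sd_must_be_positive(self):
        with pytest.raises(ValueError, match="sd"):
            ActivityModel(sample_id="s", mu=0.0, sd=0.0)


class TestZfpkmTransform:
    def test_direct_evaluation(self):
        model = ActivityModel(sample_id="s", mu=3.0, sd=2.0)
        assert model.zfpkm(np.array([32.0]))[0] == pytest.approx(1.0)
        assert model.zfpkm(np.array([8.0]))[0] == pytest.approx(0.0)

    def test_zero_fpkm_maps_to_minus_inf(self):
        model = ActivityModel(sample_id="s", mu=3.0, sd=2.0)
        z = model.zfpkm(np.array([0.0, 1e-300]))
        assert z[0] == -np.inf
        assert np.isfinite(z[1])

    def test_monotone_in_fpkm(self):
        model = ActivityModel(sample_id="s", mu=1.5, sd=0.8)
        fpkm = np.sort(np.random.default_rng(0).lognormal(1, 2, 100))
        assert (np.diff(model.zfpkm(fpkm)) >= 0).all()

    def test_missing_model_named(self, toy_fpkm):
        est = ActivityThreshold()
        est.models_ = {"s1": ActivityModel(sample_id="s1", mu=1.0, sd=1.0)}
        with pytest.raises(ValueError, match="s2"):
            est.transform(toy_fpkm)

    def test_threshold_identity(self, default_cohort):
        """{z > cutoff} must equal {fpkm > fpkm_threshold} in every sample."""
        est, matrix = default_cohort["est"], default_cohort["matrix"]
        zfpkm = default_cohort["zfpkm"]
        for sample, model in est.models_.items():
            above_z = zfpkm[sample].to_numpy() > model.z_cutoff
            above_f = matrix.values[sample].to_numpy() > model.fpkm_threshold
            np.testing.assert_array_equal(above_z, above_f)


class TestCallActivity:
    @pytest.fixture
    def z(self):
        # gA above everywhere; gB above in 1/3; gC below everywhere;
        # gD exactly at the cutoff once, above elsewhere
        return pd.DataFrame(
            {
                "r1": [0.0, 1.0, -5.0, -2.6],
                "r2": [1.0, -3.0, -4.0, 0.0],
                "r3": [2.0, -3.0, -np.inf, 1.0],
            },
            index=["gA", "gB", "gC", "gD"],
        )

    def test_three_way_classification(self, z):
        status = call_activity(z, {"grp": ["r1", "r2", "r3"]})
        assert status.loc["gA", "grp"] == "active"
        assert status.loc["gB", "grp"] == "variable"
        assert status.loc["gC", "grp"] == "inactive"

    def test_boundary_is_strict(self, z):
        """z exactly at the cutoff does not count as above."""
        status = call_activity(z, {"grp": ["r1", "r2", "r3"]})
        assert status.loc["gD", "grp"] == "variable"

    def test_partition(self, default_cohort):
        status = default_cohort["status"]
        for group in status.columns:
            counts = status[group].value_counts()
            assert counts.sum() == len(status)

    def test_empty_and_single_replicate_groups_rejected(self, z):
        with pytest.raises(ValueError, match="empty"):
            call_activity(z, {"grp": []})
        with pytest.raises(ValueError, match="replicate"):
            call_activity(z, {"grp": ["r1"]})


class TestActiveUnion:
    @pytest.fixture
    def status(self):
        return pd.DataFrame(
            {
                "tibia": ["inactive", "variable", "active"],
                "femur": ["active", "variable", "inactive"],
                "humerus": ["inactive", "variable", "inactive"],
            },
            index=["gA", "gB", "gC"],
        )

    def test_union_semantics(self, status):
        assert active_union(status) == {"gA", "gC"}
        assert active_union(status, ["humerus"]) == set()

    def test_variable_everywhere_excluded(self, status):
        assert "gB" not in active_union(status)

    def test_unknown_group(self, status):
        with pytest.raises(ValueError, match="skull"):
            active_union(status, ["skull"])


class TestSampleCorrelation:
    def test_self_and_affine(self, toy_fpkm):
        frame = toy_fpkm.values.copy()
        frame["s4"] = 2.0 * frame["s1"]
        corr, _ = sample_correlation(frame)
        assert corr.loc["s1", "s1"] == pytest.approx(1.0)
        assert corr.loc["s1", "s4"] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 1.0, 4.0, 3.0])
        frame = pd.DataFrame({"a": a, "b": b}, index=list("wxyz"))
        corr, _ = sample_correlation(frame)
        expected = np.cov(a, b, ddof=1)[0, 1] / (a.std(ddof=1) * b.std(ddof=1))
        assert corr.loc["a", "b"] == pytest.approx(expected)
        assert expected == pytest.approx(0.6)

    def test_zero_variance_sample_is_nan_not_error(self):
        frame = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]}, index=list("xyz")
        )
        corr, _ = sample_correlation(frame)
        assert np.isnan(corr.loc["a", "b"])

    def test_group_means(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(
            rng.lognormal(2, 1, size=(50, 4)),
            index=[f"g{i}" for i in range(50)],
            columns=["t1", "t2", "f1", "f2"],
        )
        corr, means = sample_correlation(
            frame, groups={"tibia": ["t1", "t2"], "femur": ["f1", "f2"]}
        )
        assert means.loc["tibia", "tibia"] == pytest.approx(corr.loc["t1", "t2"])
        expected = corr.loc[["t1", "t2"], ["f1", "f2"]].to_numpy().mean()
        assert means.loc["tibia", "femur"] == pytest.approx(expected)

    def test_small_gene_subset_rejected(self, toy_fpkm):
        with pytest.raises(ValueError, match=">=3"):
            sample_correlation(toy_fpkm, gene_subset=["gA", "gB"])
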