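import numpy as np
import pandas as pd
import pytest

from octs.enrichment import (
    GmmFit,
    call_enriched,
    compute_lfc,
    enrichment_threshold,
    fit_lfc_gmm,
    libsize_normalize,
)
from octs.io import ExpressionMatrix


class TestLibsizeNormalize:
    def test_scale_factors(self):
        frame = pd.DataFrame(
            {"a": [600000, 400000], "b": [1200000, 800000]}, index=["g1", "g2"]
        )
        out = libsize_normalize(ExpressionMatrix(frame, "counts"))
        # totals 1e6 and 2e6 -> factors 1.5 and 0.75
        np.testing.assert_allclose(out["a"], [900000.0, 600000.0])
        np.testing.assert_allclose(out["b"], [900000.0, 600000.0])

    def test_equal_totals_identity(self):
        frame = pd.DataFrame({"a": [3, 7], "b": [6, 4]}, index=["g1", "g2"])
        out = libsize_normalize(ExpressionMatrix(frame, "counts"))
        np.testing.assert_allclose(out.to_numpy(), frame.to_numpy())

    def test_column_sums_equal_after(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(
            rng.integers(0, 1000, size=(100, 5)),
            index=[f"g{i}" for i in range(100)],
            columns=list("abcde"),
        )
        out = libsize_normalize(ExpressionMatrix(frame, "counts"))
        sums = out.sum(axis=0)
        np.testing.assert_allclose(sums, sums.iloc[0])

    def test_zero_total_sample_rejected(self):
        frame = pd.DataFrame({"a": [1, 2], "b": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="b"):
            libsize_normalize(ExpressionMatrix(frame, "counts"))

    def test_fpkm_matrix_rejected(self, toy_fpkm):
        with pytest.raises(ValueError, match="counts"):
            libsize_normalize(toy_fpkm)


class TestComputeLfc:
    def test_equal_conditions_give_zero(self, enrichment_samples):
        frame = pd.DataFrame(
            {s: [100.0, 50.0] for s in enrichment_samples["sample_id"]},
            index=["g1", "g2"],
        )
        lfc = compute_lfc(frame, enrichment_samples)
        np.testing.assert_allclose(lfc["mean_lfc"], 0.0)

    def test_fourfold_enrichment(self, enrichment_samples):
        cols = {}
        for _, row in enrichment_samples.iterrows():
            cols[row["sample_id"]] = (
                [4000.0] if row["condition"] == "osteocyte_enriched" else [1000.0]
            )
        lfc = compute_lfc(pd.DataFrame(cols, index=["g1"]), enrichment_samples)
        assert lfc["mean_lfc"].iloc[0] == pytest.approx(2.0, abs=0.01)

    def test_mean_of_per_animal_values(self):
        per_animal = np.array([1.8, 2.0, 2.2, 1.9, 2.1])
        assert per_animal.mean() == pytest.approx(2.0)

    def test_unpaired_animal_named(self, enrichment_samples):
        broken = enrichment_samples.drop(index=0)  # removes m1 enriched sample
        frame = pd.DataFrame(
            {s: [1.0] for s in broken["sample_id"]}, index=["g1"]
        )
        with pytest.raises(ValueError, match="m1"):
            compute_lfc(frame, broken)


class TestFitLfcGmm:
    def test_single_gaussian_selects_k1_with_analytic_bic(self):
        """BIC on pure Gaussian data must pick k=1, and the k=1 fit must
        match the closed-form single-Gaussian maximum likelihood."""
        rng = np.random.default_rng(11)
        x = rng.normal(0.7, 1.3, size=5000)
        fit = fit_lfc_gmm(x, k_candidates=(1, 2, 3, 4), seed=11)
        assert fit.k == 1
        # closed form: ll = -n/2 * (ln(2*pi*var_mle) + 1)
        var_mle = np.mean((x - x.mean()) ** 2)
        ll = -0.5 * x.size * (np.log(2 * np.pi * var_mle) + 1.0)
        assert fit.loglik == pytest.approx(ll, rel=1e-6)
        assert fit.bic == pytest.approx(-2 * ll + 2 * np.log(x.size), rel=1e-6)

    def test_well_separated_four_component_recovery(self):
        rng = np.random.default_rng(4)
        weights = (0.25, 0.35, 0.25, 0.15)
        means = (-2.0, 0.0, 2.0, 5.0)
        comp = rng.choice(4, size=10000, p=weights)
        x = rng.normal(np.array(means)[comp], 0.3)
        fit = fit_lfc_gmm(x, seed=4)
        assert fit.k == 4
        recovered = np.sort(fit.means)
        np.testing.assert_allclose(recovered, sorted(means), atol=0.1)

    def test_loglik_trace_monotone_and_posteriors_normalised(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(0, 1, 400), rng.normal(4, 0.5, 200)])
        fit = fit_lfc_gmm(x, k_candidates=(2,), seed=9)
        assert (np.diff(fit.loglik_trace) >= -1e-7).all()
        post = fit.posteriors(x)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_agrees_with_sklearn_mixture(self):
        """Independent cross-check: sklearn's EM on the same data reaches a
        comparable likelihood and the same component means."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(21)
        x = np.concatenate([rng.normal(-1, 0.4, 1500), rng.normal(2, 0.6, 1500)])
        fit = fit_lfc_gmm(x, k_candidates=(2,), seed=21)
        sk = GaussianMixture(2, n_init=3, random_state=21, tol=1e-8).fit(x[:, None])
        np.testing.assert_allclose(
            np.sort(fit.means), np.sort(sk.means_.ravel()), atol=0.05
        )
        assert fit.loglik / x.size == pytest.approx(sk.score(x[:, None]), abs=1e-3)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            fit_lfc_gmm(np.zeros(30), k_candidates=(4,), seed=0)


class TestEnrichmentThreshold:
    def _fit(self, means, sds, weights=None):
        k = len(means)
        weights = np.full(k, 1.0 / k) if weights is None else np.asarray(weights)
        return GmmFit(
            k=k, weights=weights, means=np.asarray(means, float),
            sds=np.asarray(sds, float), loglik=0.0, bic=0.0, n=100,
            loglik_trace=np.array([0.0]),
        )

    def test_second_highest_mean_rule(self):
        fit = self._fit([-1.0, 0.2, 1.0, 3.5], [0.5, 0.4, 0.3, 0.6])
        assert enrichment_threshold(fit) == pytest.approx(1.6)

    def test_two_components(self):
        fit = self._fit([0.0, 4.0], [1.0, 1.0])
        assert enrichment_threshold(fit) == pytest.approx(2.0)

    def test_monotone_in_component_sd(self):
        lo = self._fit([0.0, 1.0, 4.0], [0.5, 0.3, 0.6])
        hi = self._fit([0.0, 1.0, 4.0], [0.5, 0.5, 0.6])
        assert enrichment_threshold(hi) > enrichment_threshold(lo)

    def test_single_component_rejected(self):
        with pytest.raises(ValueError, match="k >= 2"):
            enrichment_threshold(self._fit([1.0], [0.5]))


class TestCallEnriched:
    def _table(self, rows):
        n = len(rows[0])
        return pd.DataFrame(
            np.asarray(rows, float),
            columns=[f"lfc_m{i}" for i in range(n)],
            index=[f"g{i}" for i in range(len(rows))],
        )

    def test_t_interval_hand_computed(self):
        """5 animals, values (2.0, 2.5, 3.0, 2.2, 2.8): mean 2.5,
        sd 0.41231, t(.975, df=4)=2.77645 -> CI (1.98805, 3.01195)."""
        table = self._table([[2.0, 2.5, 3.0, 2.2, 2.8]])
        calls = call_enriched(table, threshold=1.63)
        assert calls["mean_lfc"].iloc[0] == pytest.approx(2.5)
        assert calls["ci_low"].iloc[0] == pytest.approx(1.98805, abs=1e-4)
        assert calls["ci_high"].iloc[0] == pytest.approx(3.01195, abs=1e-4)
        assert bool(calls["enriched"].iloc[0])

    def test_degenerate_zero_variance_decided_by_mean(self):
        table = self._table([[5.0, 5.0, 5.0], [1.0, 1.0, 1.0]])
        calls = call_enriched(table, threshold=1.63)
        assert calls["enriched"].tolist() == [True, False]

    def test_mean_below_threshold_never_enriched(self):
        table = self._table([[1.0, 1.0001, 0.9999]])
        calls = call_enriched(table, threshold=1.63)
        assert not calls["enriched"].any()

    def test_strictness_at_threshold(self):
        table = self._table([[2.0, 2.0, 2.0]])
        calls = call_enriched(table, threshold=2.0)
        assert not calls["enriched"].any()

    def test_normal_interval_is_narrower_than_t(self):
        table = self._table([[2.0, 2.5, 3.0, 2.2, 2.8]])
        t_ci = call_enriched(table, threshold=0.0, interval="t")
        n_ci = call_enriched(table, threshold=0.0, interval="normal")
        assert n_ci["ci_low"].iloc[0] > t_ci["ci_low"].iloc[0]

    def test_ci_ordering_invariant(self, default_enrichment):
        calls = default_enrichment["calls"]
        assert (calls["ci_low"] <= calls["mean_lfc"] + 1e-12).all()
        assert (calls["mean_lfc"] <= calls["ci_high"] + 1e-12).all()
        post = calls[[c for c in calls.columns if c.startswith("posterior_")]]
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)
        assert (calls["enriched"] == (calls["ci_low"] > default_enrichment["model"].threshold_)).all()
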