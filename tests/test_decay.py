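"""The gene-order decay model: fitting, bootstrap, stability indices."""

import numpy as np
import pandas as pd
import pytest

from synterate import GeneOrderDecay, predict_goc
from synterate.decay import _profile_fit_batch, fit_categories, fit_goc_model

from .conftest import points_from_clade


def make_points(x, y, category="NN"):
    n = len(x)
    return pd.DataFrame({
        "species_a": [f"a{i}" for i in range(n)],
        "species_b": [f"b{i}" for i in range(n)],
        "x": x, "goc": y,
        "category": category if isinstance(category, str) else list(category),
    })


class TestPredict:
    def test_unit_at_zero_divergence(self):
        for fi, p in [(0.0, 0.5), (0.3, 0.001), (0.9, 1.0)]:
            assert predict_goc(fi, p, 0.0) == pytest.approx(1.0)

    def test_p_one_is_flat(self):
        xs = np.linspace(0, 2, 7)
        np.testing.assert_allclose(predict_goc(0.4, 1.0, xs), 1.0)

    def test_worked_value(self):
        assert predict_goc(0.2, 0.001, 0.5) == pytest.approx(0.22530, abs=1e-5)

    def test_decays_to_floor(self):
        assert predict_goc(0.15, 0.01, 50.0) == pytest.approx(0.15, abs=1e-8)


class TestFit:
    def test_noiseless_recovery(self):
        x = np.linspace(0.005, 0.4, 20)
        y = predict_goc(0.1, 0.001, x)
        res = GeneOrderDecay(make_points(x, y)).fit()
        assert res.f_i == pytest.approx(0.1, abs=1e-3)
        assert res.p == pytest.approx(0.001, abs=1e-3)
        assert res.sse < 1e-10

    def test_all_goc_one_hits_p_boundary(self):
        x = np.linspace(0.01, 0.3, 10)
        res = GeneOrderDecay(make_points(x, np.ones(10))).fit()
        assert res.p > 0.99
        assert res.sse < 1e-6

    def test_fixed_fi_refit_recovers_p(self):
        x = np.linspace(0.01, 0.4, 15)
        y = predict_goc(0.2, 0.005, x)
        res = GeneOrderDecay(make_points(x, y)).fit(fixed_f_i=0.2)
        assert res.p == pytest.approx(0.005, abs=1e-4)
        assert res.params.fit_mode == "fixed_f_i"

    def test_profile_refitter_matches_nelder_mead(self):
        """The vectorized bootstrap refitter minimizes the same SSE as
        the headline optimizer."""
        rng = np.random.default_rng(0)
        x = rng.uniform(0.02, 0.3, 40)
        y = np.clip(predict_goc(0.15, 0.002, x) + rng.normal(0, 0.03, 40), 0, 1)
        res = GeneOrderDecay(make_points(x, y)).fit()
        fi, p = _profile_fit_batch(x[None, :], y[None, :])
        assert fi[0] == pytest.approx(res.f_i, abs=2e-4)
        assert p[0] == pytest.approx(res.p, rel=0.02)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            GeneOrderDecay(make_points([0.1], [0.5])).fit()
        with pytest.raises(ValueError):
            GeneOrderDecay(make_points([0.1, 0.1], [0.5, 0.6])).fit()
        with pytest.raises(ValueError):
            GeneOrderDecay(pd.DataFrame())

    def test_functional_wrapper(self):
        x = np.linspace(0.01, 0.3, 12)
        params = fit_goc_model(make_points(x, predict_goc(0.05, 0.01, x)))
        assert params.f_i == pytest.approx(0.05, abs=1e-3)


class TestCategories:
    def test_single_category_reduces_to_plain_fit(self):
        x = np.linspace(0.01, 0.3, 12)
        pts = make_points(x, predict_goc(0.1, 0.01, x))
        cats = fit_categories(pts, mode="independent")
        assert set(cats) == {"NN"}
        assert cats["NN"].p == pytest.approx(0.01, abs=1e-3)

    def test_fixed_fi_pins_pooled_saturation(self):
        x = np.tile(np.linspace(0.01, 0.3, 10), 3)
        cat = ["RR"] * 10 + ["RN"] * 10 + ["NN"] * 10
        y = np.concatenate([
            predict_goc(0.1, 0.0005, x[:10]),
            predict_goc(0.1, 0.002, x[10:20]),
            predict_goc(0.1, 0.01, x[20:]),
        ])
        cats = fit_categories(make_points(x, y, cat), mode="fixed_f_i")
        fis = {c: p.f_i for c, p in cats.items()}
        assert len(set(fis.values())) == 1  # pinned
        assert cats["RR"].p < cats["RN"].p < cats["NN"].p

    def test_rate_contrast_orders_categories(self, small_clade):
        """On a simulated clade where resistant tips rearrange 3x
        faster, the fitted decay is steepest for R-R pairs."""
        pts = points_from_clade(small_clade)
        cats = fit_categories(pts, mode="fixed_f_i")
        assert cats["RR"].p < cats["NN"].p


class TestBootstrap:
    def test_zero_noise_degenerate_interval(self):
        x = np.linspace(0.01, 0.3, 20)
        res = GeneOrderDecay(make_points(x, predict_goc(0.1, 0.01, x))).fit()
        res = res.bootstrap_ci(n_boot=200, rng=0)
        lo, hi = res.params.ci_p
        assert hi - lo < 1e-4
        assert lo <= res.p <= hi

    def test_interval_contains_estimate_and_brackets_truth(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.02, 0.3, 60)
        y = np.clip(predict_goc(0.1, 0.001, x) + rng.normal(0, 0.03, 60), 0, 1)
        res = GeneOrderDecay(make_points(x, y)).fit().bootstrap_ci(
            n_boot=500, rng=2)
        assert res.params.ci_p[0] <= res.p <= res.params.ci_p[1]
        assert res.params.ci_f_i[0] <= res.f_i <= res.params.ci_f_i[1]

    def test_summary_mentions_intervals(self):
        x = np.linspace(0.01, 0.3, 12)
        res = GeneOrderDecay(make_points(x, predict_goc(0.1, 0.01, x))).fit()
        res = res.bootstrap_ci(n_boot=150, rng=0)
        text = res.summary()
        assert "f_i" in text and "95% CI" in text


class TestStability:
    def test_points_on_model_give_zero_indices(self):
        x = np.linspace(0.01, 0.3, 15)
        res = GeneOrderDecay(make_points(x, predict_goc(0.1, 0.01, x))).fit()
        idx = res.stability_indices()
        np.testing.assert_allclose(idx["value"], 0.0, atol=1e-4)

    def test_constant_residual_species(self):
        x = np.linspace(0.01, 0.3, 15)
        y = predict_goc(0.1, 0.01, x)
        pts = make_points(x, y)
        # species "odd" participates in every pair, each observed 0.05 low
        pts["species_a"] = "odd"
        pts["goc"] = y - 0.05
        model = GeneOrderDecay(pts)
        from synterate.decay import GeneOrderDecayResults, RateModelParams
        frozen = RateModelParams(f_i=0.1, p=0.01, sse=0.0)
        res = GeneOrderDecayResults(model, frozen)
        idx = res.stability_indices().set_index("species")
        assert idx.loc["odd", "value"] == pytest.approx(-0.05, abs=1e-9)
        assert idx.loc["odd", "n_pairs"] == 15

    def test_indices_sum_near_zero_against_own_fit(self):
        """Against the data set's own best fit, per-species mean
        residuals center on zero for a complete (all-pairs) design."""
        rng = np.random.default_rng(12)
        n_sp = 14
        pairs = [(a, b) for a in range(n_sp) for b in range(a + 1, n_sp)]
        x = rng.uniform(0.02, 0.3, len(pairs))
        y = np.clip(predict_goc(0.1, 0.002, x) + rng.normal(0, 0.03, len(pairs)),
                    0, 1)
        pts = pd.DataFrame({
            "species_a": [f"s{a}" for a, _ in pairs],
            "species_b": [f"s{b}" for _, b in pairs],
            "x": x, "goc": y, "category": "NN"})
        res = GeneOrderDecay(pts).fit()
        idx = res.stability_indices()
        assert abs(idx["value"].mean()) < 0.01
        # every species participates in n_species - 1 pairs
        assert (idx["n_pairs"] == n_sp - 1).all()

    def test_clade_indices_balance_roughly(self, small_clade):
        pts = points_from_clade(small_clade)
        idx = GeneOrderDecay(pts).fit().stability_indices()
        assert abs(idx["value"].mean()) < 0.05
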