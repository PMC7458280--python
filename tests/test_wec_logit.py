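import math

import numpy as np
import pytest

from epistasiskit.genotype_io import DataError
from epistasiskit.wec_logit import (
    build_design, build_wec_interaction, build_wec_main, compare_models,
    fit_logistic, lr_test, null_log_likelihood, predict_pair_proba,
    reconstruct_interaction_surface, reconstruct_main_effects,
)


def pair_data(seed=0, n=400, beta=None):
    """Genotype pair + outcome from a known 3x3 cell log-odds surface."""
    rng = np.random.default_rng(seed)
    va = rng.choice(3, size=n, p=[0.35, 0.45, 0.2])
    vb = rng.choice(3, size=n, p=[0.3, 0.5, 0.2])
    eta = beta if beta is not None else np.array(
        [[-1.5, -0.2, 0.4], [0.1, -1.2, 0.3], [0.6, 0.2, -1.0]]
    )
    y = (rng.random(n) < 1 / (1 + np.exp(-eta[va, vb]))).astype(int)
    return va, vb, y


class TestWecMain:
    def test_two_category_column_definition(self):
        vals = np.array([0] * 60 + [1] * 40)  # categories A:60, B:40, ref=B
        X, names, cm = build_wec_main(vals, reference=1, name="f")
        assert names == ["f[0]"]
        assert set(np.unique(X[:, 0])) == {1.0, -1.5}
        assert X[vals == 0, 0].tolist() == [1.0] * 60
        assert X[vals == 1, 0].tolist() == [-1.5] * 40

    def test_balanced_counts_reduce_to_effect_coding(self):
        vals = np.tile([0, 1, 2], 30)
        Xw, _, _ = build_wec_main(vals, reference=2)
        d = build_design({"f": vals}, scheme="effect", references={"f": 2})
        np.testing.assert_allclose(Xw, d.X[:, 1:], atol=1e-12)

    def test_empty_category_raises(self):
        with pytest.raises(DataError):
            build_wec_main(np.array([0, 0, 1]), reference=2)

    def test_weighted_zero_sum_after_fit(self):
        va, vb, y = pair_data(seed=1)
        d = build_design({"a": va}, scheme="wec", references={"a": 2})
        fit = fit_logistic(d, y)
        effects = reconstruct_main_effects(fit, "a")
        counts = {g: int((va == g).sum()) for g in (0, 1, 2)}
        weighted = sum(counts[g] * effects[g] for g in effects)
        assert weighted == pytest.approx(0.0, abs=1e-8)

    def test_reference_switch_recovers_same_effects(self):
        """Refit oracle: the zero-sum-reconstructed reference effect equals a
        direct refit with the reference switched."""
        va, vb, y = pair_data(seed=2)
        fits = {
            ref: fit_logistic(
                build_design({"a": va}, scheme="wec", references={"a": ref}), y
            )
            for ref in (0, 2)
        }
        e0 = reconstruct_main_effects(fits[0], "a")
        e2 = reconstruct_main_effects(fits[2], "a")
        for g in (0, 1, 2):
            assert e0[g] == pytest.approx(e2[g], abs=1e-8)
        assert fits[0].log_likelihood == pytest.approx(fits[2].log_likelihood, abs=1e-8)


class TestWecInteraction:
    def test_2x2_balanced_reduces_to_pm_one_product(self):
        vals_a = np.tile([0, 0, 1, 1], 25)
        vals_b = np.tile([0, 1, 0, 1], 25)
        d = build_wec_interaction(vals_a, vals_b, 0, 0, interaction_only=True)
        col = d.X[:, 1]
        prod = (2 * vals_a - 1) * (2 * vals_b - 1)  # classical effect product
        ratio = col / prod
        assert np.allclose(ratio, ratio[0])

    def test_3x3_has_four_named_interaction_columns(self):
        va, vb, y = pair_data(seed=3)
        d = build_wec_interaction(va, vb, 2, 2, names=("ACTN3", "SNAP25"))
        int_cols = [c for c in d.columns if "x" in c]
        assert len(int_cols) == 4
        assert "ACTN3[0]xSNAP25[0]" in int_cols and "ACTN3[1]xSNAP25[1]" in int_cols
        # full model: intercept + 2 + 2 main + 4 interaction = 9 columns
        assert d.n_params == 9

    def test_empty_cell_error_lists_cells(self):
        # every marginal category present but the (2, 2) joint cell is empty
        va = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2] * 10)
        vb = np.array([0, 1, 2, 0, 1, 2, 0, 1, 1] * 10)
        with pytest.raises(DataError, match=r"\(2, 2\)"):
            build_wec_interaction(va, vb, 0, 0)

    def test_double_zero_sum_constraints_on_fit(self):
        va, vb, y = pair_data(seed=4)
        fit = fit_logistic(build_wec_interaction(va, vb, 2, 2), y)
        surface = reconstruct_interaction_surface(fit).to_numpy()
        counts = np.zeros((3, 3))
        for a, b in zip(va, vb):
            counts[a, b] += 1
        np.testing.assert_allclose((counts * surface).sum(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose((counts * surface).sum(axis=1), 0.0, atol=1e-8)

    def test_reference_invariance_of_ll_and_surface(self):
        """Switching the reference cell leaves the log-likelihood, the fitted
        probabilities and the full interaction surface unchanged."""
        va, vb, y = pair_data(seed=5)
        fits = {
            refs: fit_logistic(
                build_wec_interaction(va, vb, refs[0], refs[1],
                                      interaction_only=True), y
            )
            for refs in ((2, 2), (1, 1), (0, 0))
        }
        lls = [f.log_likelihood for f in fits.values()]
        assert max(lls) - min(lls) < 1e-8
        surfaces = [reconstruct_interaction_surface(f).to_numpy() for f in fits.values()]
        np.testing.assert_allclose(surfaces[0], surfaces[1], atol=1e-8)
        np.testing.assert_allclose(surfaces[0], surfaces[2], atol=1e-8)
        probs = [predict_pair_proba(f, va, vb) for f in fits.values()]
        np.testing.assert_allclose(probs[0], probs[1], atol=1e-8)


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        # 64 cases / 218 controls: b0 = ln(64/218), LL from the closed form
        y = np.array([1] * 64 + [0] * 218)
        from epistasiskit.wec_logit import CodedDesign
        d = CodedDesign(X=np.ones((282, 1)), columns=["intercept"], scheme="dummy")
        fit = fit_logistic(d, y)
        assert fit.coefficients["intercept"] == pytest.approx(math.log(64 / 218), abs=1e-8)
        assert fit.log_likelihood == pytest.approx(null_log_likelihood(y), abs=1e-8)
        assert fit.log_likelihood == pytest.approx(-151.03, abs=5e-3)

    def test_score_equation_sum_of_probs(self):
        va, vb, y = pair_data(seed=6)
        fit = fit_logistic(build_wec_interaction(va, vb, 2, 2), y)
        probs = predict_pair_proba(fit, va, vb)
        assert probs.sum() == pytest.approx(y.sum(), abs=1e-6)

    def test_reparameterization_invariance_of_saturated_ll(self):
        va, vb, y = pair_data(seed=7)
        lls = []
        for scheme in ("dummy", "effect", "wec"):
            d = build_design({"a": va, "b": vb}, scheme=scheme,
                             references={"a": 2, "b": 2})
            lls.append(fit_logistic(d, y).log_likelihood)
        assert max(lls) - min(lls) < 1e-8

    def test_rank_deficiency_names_columns(self):
        from epistasiskit.wec_logit import CodedDesign
        X = np.ones((50, 3))
        X[:, 1] = np.arange(50)
        X[:, 2] = 2 * np.arange(50)  # collinear with column 1
        d = CodedDesign(X=X, columns=["intercept", "x", "x2"], scheme="dummy")
        with pytest.raises(DataError, match="rank"):
            fit_logistic(d, np.array([0, 1] * 25))

    def test_perfect_separation_flagged(self):
        from epistasiskit.wec_logit import CodedDesign
        x = np.concatenate([-np.ones(20), np.ones(20)])
        y = (x > 0).astype(int)
        d = CodedDesign(X=np.column_stack([np.ones(40), x]),
                        columns=["intercept", "x"], scheme="dummy")
        fit = fit_logistic(d, y)
        assert fit.separation or not fit.converged

    def test_brute_force_grid_agreement_on_toy(self):
        """Fit agrees with coarse-grid likelihood maximization (2 params)."""
        rng = np.random.default_rng(8)
        x = rng.normal(size=150)
        y = (rng.random(150) < 1 / (1 + np.exp(-(0.5 + 0.8 * x)))).astype(int)
        from epistasiskit.wec_logit import CodedDesign
        d = CodedDesign(X=np.column_stack([np.ones(150), x]),
                        columns=["intercept", "x"], scheme="dummy")
        fit = fit_logistic(d, y)
        b0s = np.linspace(-2, 2, 161)
        b1s = np.linspace(-2, 2, 161)
        def ll(b0, b1):
            eta = b0 + b1 * x
            return float(y @ eta - np.logaddexp(0, eta).sum())
        grid = [(ll(b0, b1), b0, b1) for b0 in b0s for b1 in b1s]
        _, g0, g1 = max(grid)
        assert fit.coefficients["intercept"] == pytest.approx(g0, abs=2.6e-2)
        assert fit.coefficients["x"] == pytest.approx(g1, abs=2.6e-2)

    def test_wald_ci_halfwidth_is_196_se(self):
        va, vb, y = pair_data(seed=9)
        fit = fit_logistic(build_wec_interaction(va, vb, 2, 2), y)
        tab = fit.wald_table()
        np.testing.assert_allclose(tab["ci_95_halfwidth"], 1.96 * tab["se"], atol=1e-12)


class TestCompareModels:
    def test_identical_models_zero_chi2(self):
        va, vb, y = pair_data(seed=10)
        d = build_design({"a": va}, scheme="dummy")
        f1, f2 = fit_logistic(d, y), fit_logistic(d, y)
        chi2, df, _ = lr_test(f1, f2)
        assert chi2 == pytest.approx(0.0, abs=1e-8)
        assert df == 0

    def test_nested_interaction_vs_full(self):
        va, vb, y = pair_data(seed=11)
        full = fit_logistic(build_wec_interaction(va, vb, 2, 2), y)
        inter = fit_logistic(
            build_wec_interaction(va, vb, 2, 2, interaction_only=True), y)
        chi2, df, p = lr_test(inter, full)
        assert df == 4
        assert chi2 >= -1e-10
        assert 0 <= p <= 1

    def test_non_nested_raises_with_aic(self):
        va, vb, y = pair_data(seed=12)
        f_a = fit_logistic(build_design({"a": va}, scheme="dummy"), y)
        f_b = fit_logistic(build_design({"b": vb}, scheme="dummy"), y)
        with pytest.raises(DataError, match="AIC"):
            lr_test(f_a, f_b)

    def test_comparison_table_mcfadden_bounds(self):
        va, vb, y = pair_data(seed=13)
        fits = {
            "full": fit_logistic(build_wec_interaction(va, vb, 2, 2), y),
            "additive": fit_logistic(
                build_design({"a": va, "b": vb}, scheme="additive_numeric"), y),
        }
        table = compare_models(fits)
        assert ((table["mcfadden_r2"] >= 0) & (table["mcfadden_r2"] < 1)).all()
        # the saturated WEC pair model contains the additive score model
        assert not table.attrs["pairwise"].empty
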