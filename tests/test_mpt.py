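"""Unit and property tests for the MPT engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crosswise.mpt import (
    Branch,
    CountTable,
    Factor,
    MPTModel,
    Parameter,
    TreeModel,
    compare_models,
    cwm_tree,
    dq_tree,
)
from crosswise.study import four_condition_model

from _oracles import (
    grid_maximize_1d,
    grid_maximize_coordinate,
    independent_binomial_lr,
    tree_loglik_fn,
)


def single_cwm_model(p=0.158, pi="pi"):
    return TreeModel(
        cwm_tree("cwm", pi, "p"), [Parameter(pi), Parameter("p", "constant", p)]
    )


def single_dq_model(pi="pi"):
    return TreeModel(dq_tree("dq", pi), [Parameter(pi)])


class TestCategoryProbabilities:
    def test_cwm_hand_expanded(self):
        # 0.4553*0.158 + 0.5447*0.842 = 0.5306 (hand expansion of the tree)
        probs = single_cwm_model().category_probabilities({"pi": 0.4553})
        assert probs["cwm"]["both_none"] == pytest.approx(0.5305748, abs=1e-8)
        assert probs["cwm"]["exactly_one"] == pytest.approx(1 - 0.5305748, abs=1e-8)

    def test_dq_boundary(self):
        probs = single_dq_model().category_probabilities({"pi": 0.0})
        assert probs["dq"]["true"] == 0.0
        assert probs["dq"]["false"] == 1.0

    @pytest.mark.parametrize("pi", [0.0, 0.2, 0.5, 0.9, 1.0])
    def test_cwm_uninformative_at_half(self, pi):
        probs = single_cwm_model(p=0.5).category_probabilities({"pi": pi})
        assert probs["cwm"]["both_none"] == pytest.approx(0.5, abs=1e-12)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            single_dq_model().category_probabilities({"pi": 0.2, "bogus": 0.1})

    def test_out_of_range_value_rejected(self):
        with pytest.raises(ValueError):
            single_dq_model().category_probabilities({"pi": 1.3})

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_normalization_random_vectors(self, seed):
        """Category probabilities sum to one per tree, also after the
        shrinkage rewrite (within 1e-12)."""
        rng = np.random.default_rng(seed)
        base = four_condition_model(p=rng.uniform(0.01, 0.99))
        shrunk = base.reparameterize_shrinkage(
            "pi_dq_honest", "pi_dq_fake", "alpha_dq"
        ).reparameterize_shrinkage("pi_cwm_honest", "pi_cwm_fake", "alpha_cwm")
        for model in (base, shrunk):
            values = {n: rng.uniform(0, 1) for n in model.free_names}
            probs = model.category_probabilities(values)
            for tree in model.trees:
                assert sum(probs[tree].values()) == pytest.approx(1.0, abs=1e-12)


class TestCountTable:
    def test_csv_round_trip(self, canonical_counts, tmp_path):
        path = tmp_path / "counts.csv"
        canonical_counts.to_csv(path)
        back = CountTable.from_csv(path)
        assert back.counts == canonical_counts.counts
        assert back.n("cwm_honest") == 637

    def test_declared_n_mismatch_rejected(self):
        df = pd.DataFrame(
            {
                "condition": ["a", "a"],
                "category": ["true", "false"],
                "count": [3, 4],
                "n": [10, 10],
            }
        )
        with pytest.raises(ValueError, match="declared n"):
            CountTable.from_dataframe(df)

    def test_negative_and_empty_rejected(self):
        with pytest.raises(ValueError):
            CountTable({"a": {"x": -1}})
        with pytest.raises(ValueError):
            CountTable({"a": {"x": 0, "y": 0}})


class TestFitEM:
    def test_cwm_matches_closed_form_inversion(self):
        """EM on the just-identified CWM tree equals the closed-form
        estimator (lambda + p - 1)/(2p - 1)."""
        data = CountTable({"cwm": {"both_none": 338, "exactly_one": 299}})
        res = MPTModel(single_cwm_model(), data).fit()
        closed = (338 / 637 + 0.158 - 1) / (2 * 0.158 - 1)
        assert res.converged
        assert res.params["pi"] == pytest.approx(closed, abs=1e-6)
        assert res.g_squared == pytest.approx(0.0, abs=1e-8)

    def test_dq_published_estimate(self):
        data = CountTable({"dq": {"true": 117, "false": 217}})
        res = MPTModel(single_dq_model(), data).fit()
        assert res.params["pi"] == pytest.approx(0.3503, abs=5e-5)

    def test_saturated_single_tree(self):
        data = CountTable({"t": {"a": 50, "b": 50}})
        model = TreeModel(
            [Branch("t", "a", (Factor("lam"),)), Branch("t", "b", (Factor("lam", True),))],
            [Parameter("lam")],
        )
        res = MPTModel(model, data).fit()
        assert res.params["lam"] == pytest.approx(0.5, abs=1e-8)
        assert res.g_squared == pytest.approx(0.0, abs=1e-10)
        assert res.df_resid == 0

    def test_loglik_nondecreasing_along_em_path(self):
        data = CountTable({"cwm": {"both_none": 360, "exactly_one": 289}})
        model = MPTModel(single_cwm_model(), data)
        comp = model._compiled
        theta = np.array([0.5])
        ll = comp.loglik(theta)
        for _ in range(200):
            theta = comp.em_step(theta)
            ll_new = comp.loglik(theta)
            assert ll_new >= ll - 1e-10
            ll = ll_new

    def test_non_identified_model_rejected(self):
        model = TreeModel(
            [
                Branch("t", "a", (Factor("x"), Factor("y"))),
                Branch("t", "b", (Factor("x", True),)),
                Branch("t", "b", (Factor("x"), Factor("y", True))),
            ],
            [Parameter("x"), Parameter("y")],
        )
        with pytest.raises(ValueError, match="not identified"):
            MPTModel(model, CountTable({"t": {"a": 5, "b": 5}}))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            MPTModel(single_dq_model(), CountTable({"dq": {"true": 3, "maybe": 4}}))
        with pytest.raises(ValueError):
            MPTModel(single_dq_model(), CountTable({"other": {"true": 3, "false": 4}}))

    def test_em_matches_grid_oracle_two_trees(self):
        """EM estimates agree with a brute-force coordinate grid maximizer
        of the multinomial log-likelihood (independent oracle)."""
        branches = dq_tree("dq", "pi_dq") + cwm_tree("cwm", "pi_cwm", "p")
        model = TreeModel(
            branches,
            [Parameter("pi_dq"), Parameter("pi_cwm"), Parameter("p", "constant", 0.158)],
        )
        data = CountTable(
            {"dq": {"true": 23, "false": 52}, "cwm": {"both_none": 61, "exactly_one": 48}}
        )
        res = MPTModel(model, data).fit()
        theta, _ = grid_maximize_coordinate(tree_loglik_fn(model, data), k=2, step=1e-4)
        free = list(model.free_names)
        for j, name in enumerate(free):
            assert res.params[name] == pytest.approx(theta[j], abs=1e-3)


class TestStandardErrors:
    def test_cwm_delta_method_closed_form(self):
        data = CountTable({"cwm": {"both_none": 338, "exactly_one": 299}})
        res = MPTModel(single_cwm_model(), data).fit()
        lam = 338 / 637
        closed_se = np.sqrt(lam * (1 - lam) / 637) / abs(2 * 0.158 - 1)
        assert res.bse["pi"] == pytest.approx(closed_se, rel=1e-4)
        assert res.bse["pi"] == pytest.approx(0.0289, abs=5e-5)

    def test_dq_binomial_se(self):
        data = CountTable({"dq": {"true": 117, "false": 217}})
        res = MPTModel(single_dq_model(), data).fit()
        assert res.bse["pi"] == pytest.approx(np.sqrt(0.3503 * 0.6497 / 334), abs=5e-5)

    def test_se_halves_when_n_quadruples(self):
        res1 = MPTModel(
            single_dq_model(), CountTable({"dq": {"true": 30, "false": 70}})
        ).fit()
        res4 = MPTModel(
            single_dq_model(), CountTable({"dq": {"true": 120, "false": 280}})
        ).fit()
        assert res4.bse["pi"] == pytest.approx(res1.bse["pi"] / 2, rel=1e-3)

    def test_boundary_estimate_flagged_se_undefined(self):
        res = MPTModel(
            single_dq_model(), CountTable({"dq": {"true": 0, "false": 100}})
        ).fit()
        assert res.at_boundary["pi"]
        assert np.isnan(res.bse["pi"])
        assert "pi" in res.se_flags


class TestComparisons:
    def test_dq_instruction_comparison_vs_binomial_lr(self):
        """The equality restriction on two DQ trees reproduces the classic
        two-binomial G² (independent oracle) and the published 33.40."""
        branches = dq_tree("h", "pi_h") + dq_tree("f", "pi_f")
        model = TreeModel(branches, [Parameter("pi_h"), Parameter("pi_f")])
        data = CountTable(
            {"h": {"true": 117, "false": 217}, "f": {"true": 51, "false": 275}}
        )
        comp = MPTModel(model, data).lr_test(
            model.with_equal(["pi_h", "pi_f"]), "pi_h = pi_f"
        )
        oracle = independent_binomial_lr(117, 334, 51, 326)
        assert comp.delta_g_squared == pytest.approx(oracle, abs=1e-6)
        assert comp.delta_g_squared == pytest.approx(33.40, abs=0.05)
        assert comp.df == 1
        assert comp.p_value < 0.001

    def test_restriction_already_satisfied_gives_zero(self):
        branches = dq_tree("a", "p1") + dq_tree("b", "p2")
        model = TreeModel(branches, [Parameter("p1"), Parameter("p2")])
        data = CountTable(
            {"a": {"true": 30, "false": 70}, "b": {"true": 60, "false": 140}}
        )
        comp = MPTModel(model, data).lr_test(model.with_equal(["p1", "p2"]), "eq")
        assert comp.delta_g_squared == pytest.approx(0.0, abs=1e-8)

    def test_restricted_delta_matches_profile_grid(self):
        """ΔG² equals brute-force grid maximization of the restricted
        likelihood on a 1e-5 grid (within 1e-3)."""
        branches = dq_tree("h", "pi_h") + cwm_tree("c", "pi_c", "p")
        model = TreeModel(
            branches,
            [Parameter("pi_h"), Parameter("pi_c"), Parameter("p", "constant", 0.158)],
        )
        data = CountTable(
            {"h": {"true": 117, "false": 217}, "c": {"both_none": 338, "exactly_one": 299}}
        )
        restricted = model.with_equal(["pi_h", "pi_c"])
        base_fit = MPTModel(model, data).fit()
        comp = MPTModel(model, data).lr_test(restricted, "eq")
        _, ll_r = grid_maximize_1d(tree_loglik_fn(restricted, data), step=1e-5)
        oracle_delta = 2 * (base_fit.llf - ll_r)
        assert comp.delta_g_squared == pytest.approx(oracle_delta, abs=1e-3)

    def test_unconverged_fit_refused(self):
        data = CountTable({"dq": {"true": 30, "false": 70}})
        res = MPTModel(single_dq_model(), data).fit()
        bad = MPTModel(single_dq_model(), data).fit(max_iter=1, n_restarts=0)
        if not bad.converged:
            with pytest.raises(ValueError, match="converge"):
                compare_models(res, bad)

    def test_non_nested_refused(self):
        branches = dq_tree("a", "p1") + dq_tree("b", "p2")
        model = TreeModel(branches, [Parameter("p1"), Parameter("p2")])
        data = CountTable(
            {"a": {"true": 30, "false": 70}, "b": {"true": 65, "false": 135}}
        )
        full = MPTModel(model, data).fit()
        also_full = MPTModel(model, data).fit()
        with pytest.raises(ValueError, match="fewer free parameters"):
            compare_models(full, also_full)


class TestShrinkageReparameterization:
    def test_rewrite_preserves_probabilities(self):
        """alpha*pi_h substituted for pi_f gives identical category
        probabilities when alpha = pi_f / pi_h."""
        model = four_condition_model()
        shrunk = model.reparameterize_shrinkage("pi_dq_honest", "pi_dq_fake", "a")
        vals = {
            "pi_dq_honest": 0.4,
            "pi_dq_fake": 0.3,
            "pi_cwm_honest": 0.45,
            "pi_cwm_fake": 0.42,
        }
        svals = {k: v for k, v in vals.items() if k != "pi_dq_fake"}
        svals["a"] = 0.3 / 0.4
        p1 = model.category_probabilities(vals)
        p2 = shrunk.category_probabilities(svals)
        for tree in model.trees:
            for cat in model.categories(tree):
                assert p2[tree][cat] == pytest.approx(p1[tree][cat], abs=1e-12)

    def test_missing_parameter_pair_rejected(self):
        with pytest.raises(KeyError):
            four_condition_model().reparameterize_shrinkage("pi_dq_honest", "nope", "a")

    def test_alpha_estimates_recover_ratio(self, canonical_counts):
        """Fitted shrinkage model reproduces the published ratios and the
        identity pi_fake = alpha * pi_honest."""
        model = four_condition_model()
        shrunk = model.reparameterize_shrinkage(
            "pi_dq_honest", "pi_dq_fake", "alpha_dq"
        ).reparameterize_shrinkage("pi_cwm_honest", "pi_cwm_fake", "alpha_cwm")
        res = MPTModel(shrunk, canonical_counts).fit(
            init={
                "pi_dq_honest": 0.35,
                "alpha_dq": 0.5,
                "pi_cwm_honest": 0.45,
                "alpha_cwm": 0.9,
            }
        )
        assert res.params["alpha_dq"] == pytest.approx(0.4466, abs=2e-4)
        assert res.params["alpha_cwm"] == pytest.approx(0.9226, abs=2e-4)
        base = MPTModel(model, canonical_counts).fit()
        assert res.params["alpha_dq"] * res.params["pi_dq_honest"] == pytest.approx(
            base.params["pi_dq_fake"], abs=1e-5
        )

    def test_alpha_consistent_under_equal_prevalences(self):
        """With pi_fake = pi_honest in the generating process, alpha-hat is
        within 3 Monte-Carlo SEs of 1 at n = 1e5 per group."""
        rng = np.random.default_rng(20260929)
        n = 100_000
        pi, p = 0.4, 0.158
        lam = pi * p + (1 - pi) * (1 - p)
        kh = int(rng.binomial(n, lam))
        kf = int(rng.binomial(n, lam))
        model = TreeModel(
            cwm_tree("h", "pi_h", "p") + cwm_tree("f", "pi_f", "p"),
            [Parameter("pi_h"), Parameter("pi_f"), Parameter("p", "constant", p)],
        )
        shrunk = model.reparameterize_shrinkage("pi_h", "pi_f", "alpha")
        data = CountTable(
            {"h": {"both_none": kh, "exactly_one": n - kh},
             "f": {"both_none": kf, "exactly_one": n - kf}}
        )
        res = MPTModel(shrunk, data).fit(init={"pi_h": 0.4, "alpha": 0.9})
        # MC SE of the ratio via the closed-form delta method (the model SE
        # is undefined when the order-constrained MLE sits at alpha = 1)
        from crosswise.design import CwmDesign, estimate_cwm

        eh = estimate_cwm(kh / n, n, CwmDesign(p))
        ef = estimate_cwm(kf / n, n, CwmDesign(p))
        ratio = ef.pi_hat / eh.pi_hat
        mc_se = abs(ratio) * np.sqrt(
            (ef.se / ef.pi_hat) ** 2 + (eh.se / eh.pi_hat) ** 2
        )
        assert abs(res.params["alpha"] - 1.0) <= 3 * mc_se + 1e-6


def test_tree_model_json_round_trip(tmp_path, canonical_counts):
    model = four_condition_model()
    path = tmp_path / "model.json"
    import json

    path.write_text(json.dumps(model.to_dict()))
    back = TreeModel.from_json(path)
    vals = {n: 0.3 for n in model.free_names}
    assert back.category_probabilities(vals) == model.category_probabilities(vals)
    # and the loaded model is fit-ready
    assert MPTModel(back, canonical_counts).fit().converged
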