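"""Pruning likelihoods, fitting, and marginal estimates against independent
oracles (closed forms and joint-assignment enumeration)."""

import math

import numpy as np
import pytest

import asekit as ak
from asekit.likelihood import LikelihoodError
from asekit.models import build_q, feather_hierarchy

from oracles import enum_loglik, enum_marginals
from conftest import dated_tree


def small_templates():
    """One template per family, sized so enumeration stays cheap."""
    h2 = feather_hierarchy(2)
    out = {
        "ER": ak.mk_template(3, "ER"),
        "SYM": ak.mk_template(3, "SYM"),
        "ARD": ak.mk_template(3, "ARD"),
        "ED-QL": ak.amalgamate_ed(h2, "ARD", "QL")[1],
        "ED-BD": ak.amalgamate_ed(h2, "ARD", "BD")[1],
        "SMM": ak.amalgamate_smm(h2, "ARD", "switch")[1],
        "HRM-2": ak.expand_hrm(ak.mk_template(3, "ARD"), 2)[1],
    }
    return out.items()


def rates_for(template, seed=3):
    rng = np.random.default_rng(seed)
    return rng.uniform(0.05, 0.6, size=template.n_params)


CODES_5 = {"A": "0", "B": "1", "C": "2", "D": "0&1", "E": "?"}


class TestEncodeTips:
    def test_examples(self):
        space = ak.mk_template(6, "ER").space
        tips = ak.encode_tips({"a": "0", "b": "0&1", "c": "?"}, space)
        assert tips.row("a").tolist() == [1, 0, 0, 0, 0, 0]
        assert tips.row("b").tolist() == [1, 1, 0, 0, 0, 0]
        assert tips.row("c").tolist() == [1] * 6

    def test_hidden_state_expansion(self):
        space, _ = ak.amalgamate_smm(feather_hierarchy(2), "ER", "ind")
        tips = ak.encode_tips({"a": "scales"}, space)
        assert tips.model_vectors()["a"].tolist() == [1, 1, 0, 0]

    def test_unknown_code_rejected(self):
        space = ak.mk_template(3, "ER").space
        with pytest.raises(LikelihoodError, match="unknown state"):
            ak.encode_tips({"a": "9"}, space)

    def test_taxon_mismatch_rejected(self):
        space = ak.mk_template(3, "ER").space
        with pytest.raises(LikelihoodError):
            ak.encode_tips({"a": "0"}, space, tree_taxa=["a", "b"])


class TestPruningOracle:
    @pytest.mark.parametrize("name,template", small_templates())
    def test_loglik_matches_enumeration(self, name, template, four_tip_tree):
        codes = {"A": "0", "B": "1", "C": "0", "D": "?"}
        tips = ak.encode_tips(codes, template.space)
        q = build_q(template, rates_for(template))
        got = ak.prune_loglik(four_tip_tree, q, tips)
        want = enum_loglik(four_tip_tree, q, tips)
        assert got == pytest.approx(want, rel=1e-8)

    def test_five_tip_three_state_enumeration(self, five_tip_tree):
        template = ak.mk_template(3, "ARD")
        tips = ak.encode_tips(CODES_5, template.space)
        q = build_q(template, rates_for(template))
        got = ak.prune_loglik(five_tip_tree, q, tips)
        assert got == pytest.approx(enum_loglik(five_tip_tree, q, tips), rel=1e-8)

    def test_cherry_closed_form_grid(self):
        template = ak.mk_template(2, "ER")
        for t in (0.3, 1.0, 4.0):
            tt = dated_tree("(A,B);", {"A": 0.0, "B": 0.0}, root_extra=t)
            tips = ak.encode_tips({"A": "0", "B": "0"}, template.space)
            for q in (0.05, 0.2, 0.7, 2.0):
                p_same = 0.5 + 0.5 * math.exp(-2 * q * t)
                closed = (p_same**2 + (1 - p_same) ** 2) / 2
                got = ak.prune_loglik(tt, build_q(template, [q]), tips)
                assert got == pytest.approx(math.log(closed), rel=1e-10)

    def test_tip_order_permutation_invariance(self, five_tip_tree):
        template = ak.mk_template(3, "SYM")
        q = build_q(template, rates_for(template))
        tips = ak.encode_tips(CODES_5, template.space)
        shuffled = ak.encode_tips(
            {k: CODES_5[k] for k in ["E", "C", "A", "D", "B"]}, template.space
        )
        assert ak.prune_loglik(five_tip_tree, q, tips) == pytest.approx(
            ak.prune_loglik(five_tip_tree, q, shuffled)
        )

    def test_all_unknown_tip_changes_nothing(self, five_tip_tree):
        template = ak.mk_template(3, "ER")
        q = build_q(template, [0.2])
        with_e = ak.encode_tips(CODES_5, template.space)
        lnl = ak.prune_loglik(five_tip_tree, q, with_e)
        # E is coded '?'; compare against the tree with E pruned
        pruned = ak.drop_tip(five_tip_tree, "E")
        lnl_wo = ak.prune_loglik(pruned, q, with_e.without("E"))
        assert lnl == pytest.approx(lnl_wo, rel=1e-10)

    def test_stationary_and_fitzjohn_priors_run(self, four_tip_tree):
        template = ak.mk_template(3, "ER")
        tips = ak.encode_tips({"A": "0", "B": "1", "C": "2", "D": "0"}, template.space)
        q = build_q(template, [0.2])
        flat = ak.prune_loglik(four_tip_tree, q, tips, "flat")
        stat = ak.prune_loglik(four_tip_tree, q, tips, "stationary")
        fj = ak.prune_loglik(four_tip_tree, q, tips, "fitzjohn")
        # ER is symmetric: stationary prior is flat
        assert stat == pytest.approx(flat)
        assert np.isfinite(fj)


class TestMarginals:
    @pytest.mark.parametrize("name,template", small_templates())
    def test_marginals_match_enumeration(self, name, template, four_tip_tree):
        codes = {"A": "0", "B": "1", "C": "0", "D": "?"}
        tips = ak.encode_tips(codes, template.space)
        q = build_q(template, rates_for(template, seed=9))
        table = ak.marginal_ancestral(
            four_tip_tree, q, tips, include_tips=True, clamp_known_tips=True
        )
        want = enum_marginals(four_tip_tree, q, tips)
        for node_id, expected in want.items():
            np.testing.assert_allclose(
                table.row(node_id), expected, rtol=1e-8, atol=1e-10
            )

    def test_low_rate_cherry_roots_at_shared_state(self):
        template = ak.mk_template(2, "ER")
        tt = dated_tree("(A,B);", {"A": 0.0, "B": 0.0}, root_extra=1.0)
        tips = ak.encode_tips({"A": "0", "B": "0"}, template.space)
        table = ak.marginal_ancestral(tt, build_q(template, [1e-8]), tips)
        np.testing.assert_allclose(table.row("N0"), [1.0, 0.0], atol=1e-6)

    def test_symmetric_cherry_split_root(self):
        template = ak.mk_template(2, "ER")
        tt = dated_tree("(A,B);", {"A": 0.0, "B": 0.0}, root_extra=1.0)
        tips = ak.encode_tips({"A": "0", "B": "1"}, template.space)
        table = ak.marginal_ancestral(tt, build_q(template, [0.4]), tips)
        np.testing.assert_allclose(table.row("N0"), [0.5, 0.5], atol=1e-12)

    def test_root_marginal_equals_normalized_partials(self, five_tip_tree):
        # cross-check of the two code paths under a flat prior
        from asekit.likelihood import _postorder_partials

        template = ak.mk_template(3, "ARD")
        tips = ak.encode_tips(CODES_5, template.space)
        q = build_q(template, rates_for(template))
        partials = _postorder_partials(five_tip_tree, q, tips)[1]
        root = partials[-1]
        table = ak.marginal_ancestral(five_tip_tree, q, tips)
        np.testing.assert_allclose(table.row("N0"), root / root.sum(), rtol=1e-9)

    def test_hidden_state_collapse_conserves_probability(self, four_tip_tree):
        space, template = ak.amalgamate_smm(feather_hierarchy(2), "ER", "ind")
        tips = ak.encode_tips({"A": "0", "B": "1", "C": "2", "D": "0"}, space)
        q = build_q(template, [0.2, 0.35])
        table = ak.marginal_ancestral(four_tip_tree, q, tips, include_tips=True)
        np.testing.assert_allclose(table.probs.sum(axis=1), 1.0, atol=1e-9)
        assert table.probs.shape[1] == 3  # observed, not model, states

    def test_clamped_tips_keep_their_codes(self, four_tip_tree):
        template = ak.mk_template(3, "ER")
        tips = ak.encode_tips({"A": "0", "B": "1", "C": "2", "D": "0"}, template.space)
        table = ak.marginal_ancestral(
            four_tip_tree, build_q(template, [0.3]), tips, include_tips=True
        )
        np.testing.assert_allclose(table.row("A"), [1, 0, 0], atol=1e-12)


class TestAggregate:
    def test_sum_to_groups(self):
        table = ak.MarginalTable(
            ("n1",),
            np.array([[0.4, 0.1, 0.1, 0.1, 0.2, 0.1]]),
            ("s0", "s1", "s2", "s3", "s4", "s5"),
            (False,),
        )
        grouping = {"s0": "scales", **{f"s{i}": "feathers" for i in range(1, 6)}}
        out = ak.aggregate_states(table, grouping)
        np.testing.assert_allclose(out.probs, [[0.4, 0.6]])
        assert out.states == ("scales", "feathers")

    def test_identity_grouping_unchanged(self):
        table = ak.MarginalTable(
            ("n1",), np.array([[0.25, 0.75]]), ("a", "b"), (False,)
        )
        out = ak.aggregate_states(table, {"a": "a", "b": "b"})
        np.testing.assert_allclose(out.probs, table.probs)

    def test_partial_grouping_rejected(self):
        table = ak.MarginalTable(("n1",), np.array([[0.5, 0.5]]), ("a", "b"), (False,))
        with pytest.raises(LikelihoodError):
            ak.aggregate_states(table, {"a": "x"})


class TestFitting:
    def test_monomorphic_rate_hits_lower_bound(self, five_tip_tree):
        template = ak.mk_template(2, "ER")
        tips = ak.encode_tips(dict.fromkeys("ABCDE", "0"), template.space)
        fit = ak.fit_model(
            five_tip_tree, template, tips, ak.FitOptions(n_starts=3, seed=0)
        )
        assert fit.rates[0] < 1e-3  # pushed to the no-change regime
        assert fit.loglik == pytest.approx(math.log(0.5), abs=1e-3)

    def test_scheme_nesting_on_likelihood(self, five_tip_tree):
        tips_codes = {"A": "0", "B": "2", "C": "1", "D": "0", "E": "2"}
        lnls = {}
        for scheme in ("ER", "SYM", "ARD"):
            template = ak.mk_template(3, scheme)
            tips = ak.encode_tips(tips_codes, template.space)
            lnls[scheme] = ak.fit_model(
                five_tip_tree, template, tips, ak.FitOptions(n_starts=4, seed=2)
            ).loglik
        assert lnls["ARD"] >= lnls["SYM"] - 1e-6
        assert lnls["SYM"] >= lnls["ER"] - 1e-6

    def test_deterministic_given_seed(self, fixture_tree, fixture_data):
        template = ak.mk_template(6, "ER")
        tips = ak.encode_tips(fixture_data["codes"], template.space)
        fits = [
            ak.fit_model(fixture_tree, template, tips, ak.FitOptions(n_starts=3, seed=5))
            for _ in range(2)
        ]
        assert fits[0].rates.tolist() == fits[1].rates.tolist()
        assert fits[0].loglik == fits[1].loglik

    def test_aic_bookkeeping(self, fixture_tree, fixture_data):
        template = ak.mk_template(6, "ER")
        tips = ak.encode_tips(fixture_data["codes"], template.space)
        fit = ak.fit_model(fixture_tree, template, tips, ak.FitOptions(n_starts=2, seed=1))
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)
        n, k = fit.n_tips, fit.n_params
        assert fit.aicc == pytest.approx(fit.aic + 2 * k * (k + 1) / (n - k - 1))

    def test_aicc_undefined_when_overparameterized(self, fixture_tree, fixture_data):
        # 15 SYM parameters on 12 tips: n - k - 1 <= 0
        template = ak.mk_template(6, "SYM")
        tips = ak.encode_tips(fixture_data["codes"], template.space)
        fit = ak.fit_model(fixture_tree, template, tips, ak.FitOptions(n_starts=1, seed=1))
        assert fit.aicc is None
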