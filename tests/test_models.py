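"""Rate-matrix templates: parameter counts, state spaces, forbidden
transitions, and generator properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from asekit.models import (
    ARCHITECTURES,
    SCHEMES,
    DependencyHierarchy,
    ModelError,
    amalgamate_ed,
    amalgamate_smm,
    build_q,
    expand_hrm,
    feather_hierarchy,
    mk_template,
    model_grid,
)


class TestMkTemplate:
    @pytest.mark.parametrize(
        "n,scheme,ordered,expected",
        [
            (2, "ER", False, 1),
            (6, "ER", False, 1),
            (6, "SYM", False, 15),
            (6, "ARD", False, 30),
            (6, "ARD", True, 10),
            (6, "SYM", True, 5),
            (6, "ER", True, 1),
        ],
    )
    def test_parameter_counts(self, n, scheme, ordered, expected):
        assert mk_template(n, scheme, ordered).n_params == expected

    def test_binary_er_shares_both_directions(self):
        t = mk_template(2, "ER")
        assert t.index[0, 1] == t.index[1, 0] == 1

    def test_ordered_support_is_a_chain(self):
        t = mk_template(5, "ARD", ordered=True)
        for i in range(5):
            for j in range(5):
                if i != j:
                    assert (t.index[i, j] > 0) == (abs(i - j) == 1)

    def test_too_few_states_rejected(self):
        with pytest.raises(ModelError):
            mk_template(1, "ER")


class TestEmbeddedDependency:
    def test_coding2_ql_state_space_and_jumps(self):
        space, t = amalgamate_ed(feather_hierarchy(2), "ER", "QL")
        assert space.model_states == ("scales", "filamentous", "pennaceous")
        assert t.index[0, 2] > 0  # scales -> pennaceous allowed under QL

    def test_coding2_bd_forbids_double_birth(self):
        space, t = amalgamate_ed(feather_hierarchy(2), "ER", "BD")
        assert space.model_states == ("scales", "filamentous", "pennaceous")
        assert t.index[0, 2] == 0  # two simultaneous births forbidden
        assert t.index[2, 0] > 0  # loss of the controlling trait is one death

    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_single_binary_character_degenerates_to_mk(self, scheme):
        h = DependencyHierarchy.chain(("trait",))
        _, t = amalgamate_ed(h, scheme, "QL")
        assert np.array_equal(t.index, mk_template(2, scheme).index)

    def test_cycle_rejected(self):
        with pytest.raises(ModelError):
            DependencyHierarchy(("a", "b"), (1, 0))


class TestStructuredMarkov:
    def test_coding2_state_space(self):
        space, _ = amalgamate_smm(feather_hierarchy(2), "ER", "ind")
        assert space.model_states == ("00", "01", "10", "11")
        # the two feather-absence states map to the same observed state
        assert space.observation_map[0] == space.observation_map[1]
        assert space.preimages(0) == [0, 1]

    def test_coding2_ind_er_hand_built_template(self):
        _, t = amalgamate_smm(feather_hierarchy(2), "ER", "ind")
        # independent characters, one rate each; no simultaneous changes
        expected = np.array(
            [[0, 2, 1, 0],
             [2, 0, 0, 1],
             [1, 0, 0, 2],
             [0, 1, 2, 0]]
        )
        # parameter identity up to relabelling: same partition of entries
        assert t.n_params == 2
        assert (t.index == 0).sum() == (expected == 0).sum()
        groups = {}
        for a in range(4):
            for b in range(4):
                if t.index[a, b]:
                    groups.setdefault(t.index[a, b], set()).add((a, b))
        exp_groups = {}
        for a in range(4):
            for b in range(4):
                if expected[a, b]:
                    exp_groups.setdefault(expected[a, b], set()).add((a, b))
        assert sorted(map(frozenset, groups.values())) == sorted(
            map(frozenset, exp_groups.values())
        )

    def test_double_transitions_forbidden(self):
        _, t = amalgamate_smm(feather_hierarchy(2), "ARD", "switch")
        assert t.index[0, 3] == 0 and t.index[3, 0] == 0  # 00 <-> 11

    def test_coding3_dimensions(self):
        space, _ = amalgamate_smm(feather_hierarchy(3), "ER", "ind")
        assert space.n_model == 32
        assert space.n_observed == 6

    def test_switch_has_more_parameters_than_ind(self):
        _, ind = amalgamate_smm(feather_hierarchy(2), "ARD", "ind")
        _, sw = amalgamate_smm(feather_hierarchy(2), "ARD", "switch")
        assert sw.n_params > ind.n_params


class TestHiddenRates:
    @pytest.mark.parametrize("ncat,expected_states", [(2, 12), (3, 18)])
    def test_model_state_counts(self, ncat, expected_states):
        space, _ = expand_hrm(mk_template(6, "ER"), ncat)
        assert space.n_model == expected_states

    def test_observation_roundtrip(self):
        base = mk_template(6, "SYM")
        space, _ = expand_hrm(base, 2)
        assert space.observed_states == base.space.observed_states
        collapsed = space.collapse(np.eye(space.n_model))
        assert collapsed.sum() == space.n_model

    def test_overparameterized_ard_three_categories(self):
        # 3 x 30 within-category rates + 4 chain switch rates
        _, t = expand_hrm(mk_template(6, "ARD"), 3)
        assert t.n_params == 94

    def test_switches_conserve_observed_state(self):
        space, t = expand_hrm(mk_template(3, "ER"), 2)
        for a in range(space.n_model):
            for b in range(space.n_model):
                if a != b and t.index[a, b]:
                    same_obs = space.observation_map[a] == space.observation_map[b]
                    same_cat = (a // 3) == (b // 3)
                    assert same_obs or same_cat

    def test_bad_category_count_rejected(self):
        with pytest.raises(ModelError):
            expand_hrm(mk_template(3, "ER"), 4)


class TestBuildQ:
    def test_er_binary_matrix(self):
        q = build_q(mk_template(2, "ER"), [0.3])
        assert np.allclose(q, [[-0.3, 0.3], [0.3, -0.3]])

    def test_wrong_rate_count_rejected(self):
        with pytest.raises(ModelError):
            build_q(mk_template(6, "SYM"), [1.0])
        with pytest.raises(ModelError):
            build_q(mk_template(2, "ER"), [-1.0])

    def test_forbidden_entries_stay_zero(self):
        _, t = amalgamate_ed(feather_hierarchy(2), "ARD", "BD")
        q = build_q(t, np.linspace(0.1, 1.0, t.n_params))
        assert q[0, 2] == 0.0

    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_exponential_is_stochastic(self, arch):
        t = model_grid(architectures=(arch,), schemes=("ARD",))[f"{arch} ARD"]
        q = build_q(t, np.full(t.n_params, 0.37))
        for time in (0.1, 5.0, 80.0):
            p = expm(q * time)
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)
            assert (p >= -1e-12).all() and (p <= 1 + 1e-12).all()

    @given(st.floats(0.001, 50.0), st.floats(0.01, 20.0))
    @settings(max_examples=25, deadline=None)
    def test_rows_sum_to_zero(self, rate, time):
        q = build_q(mk_template(4, "ER"), [rate])
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-9)


class TestSchemeNesting:
    """ER - SYM - ARD as parameter-sharing refinements on shared support."""

    @pytest.mark.parametrize("arch", ["unordered", "ordered"])
    def test_same_support_finer_partition(self, arch):
        er = mk_template(6, "ER", ordered=arch == "ordered")
        sym = mk_template(6, "SYM", ordered=arch == "ordered")
        ard = mk_template(6, "ARD", ordered=arch == "ordered")
        assert np.array_equal(er.index > 0, sym.index > 0)
        assert np.array_equal(sym.index > 0, ard.index > 0)
        # any SYM instantiation is an ARD instantiation: each SYM parameter
        # group is a union of ARD groups (and likewise ER within SYM)
        for coarse, fine in ((er, sym), (sym, ard)):
            mapping = {}
            for i in range(6):
                for j in range(6):
                    if i != j and fine.index[i, j]:
                        key = fine.index[i, j]
                        mapping.setdefault(key, set()).add(coarse.index[i, j])
            assert all(len(v) == 1 for v in mapping.values())


class TestGrid:
    def test_full_grid_is_21_models(self):
        grid = model_grid()
        assert len(grid) == 21
        assert {m.rsplit(" ", 1)[0] for m in grid} == set(ARCHITECTURES)
        assert {m.rsplit(" ", 1)[1] for m in grid} == set(SCHEMES)

    def test_templates_serialize(self, tmp_path):
        t = model_grid(architectures=("SMM-ind",), schemes=("ER",))["SMM-ind ER"]
        path = tmp_path / "t.json"
        t.save(path)
        import json

        payload = json.loads(path.read_text())
        assert payload["n_params"] == t.n_params
        assert len(payload["space"]["model_states"]) == 32
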