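"""Configuration statistics: worked examples, oracle agreement, change
statistics, and structural invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mergm.configs import (
    CATALOGUE,
    CATALOGUE_23,
    ConfigurationSpec,
    brute_force_count,
    change_statistics,
    default_specs,
    evaluate_statistics,
    z_bipartite_X,
    z_interaction,
    z_within_A,
)
from mergm.netdata import MultilevelNetwork

from conftest import make_random_mnet, net_from_edges

ALL_SPECS = default_specs(CATALOGUE_23) + [ConfigurationSpec("ACA_variable")]


def spec(name, lam=2.0):
    attr = {"Edu_Match": "education", "Org_Match": "organisation"}
    return ConfigurationSpec(name, lam=lam, attribute=attr.get(name))


class TestWorkedExamples:
    def test_density_reciprocity_in2star_direct_counts(self):
        net = net_from_edges(3, 1, a_edges=[(0, 1), (1, 0), (1, 2)])
        assert z_within_A(net, spec("Density")) == 3
        assert z_within_A(net, spec("Reciprocity")) == 1
        assert z_within_A(net, spec("In2Star")) == 0

    def test_alternating_in_star_single_hub_degree_3(self):
        # hub with in-degree 3 at lambda=2: alternating sum 3 - 1/2 = 2.5
        net = net_from_edges(4, 1, a_edges=[(1, 0), (2, 0), (3, 0)])
        assert z_within_A(net, spec("AinS")) == pytest.approx(2.5)

    def test_alternating_transitive_triangle_single_closure(self):
        # one transitive triad: the i->j tie sits on one two-path, 2*(1-0.5)=1
        net = net_from_edges(3, 1, a_edges=[(0, 2), (2, 1), (0, 1)])
        assert z_within_A(net, spec("ATT")) == pytest.approx(1.0)
        assert z_within_A(net, spec("ACT")) == pytest.approx(0.0)

    def test_cyclic_triangle_counted_by_act(self):
        net = net_from_edges(3, 1, a_edges=[(0, 1), (1, 2), (2, 0)])
        # each of the 3 arcs lies on exactly one cycle: 3 * 2*(1-0.5)
        assert z_within_A(net, spec("ACT")) == pytest.approx(3.0)
        assert z_within_A(net, spec("ATT")) == pytest.approx(0.0)

    def test_actor_star_asa_two_actions(self):
        net = net_from_edges(2, 3, x_edges=[(0, 0), (0, 1)])
        assert z_bipartite_X(net, spec("ASA")) == pytest.approx(1.0)

    def test_shared_choice_aca_two_common_variables(self):
        net = net_from_edges(2, 2, x_edges=[(0, 0), (0, 1), (1, 0), (1, 1)])
        assert z_bipartite_X(net, spec("ACA")) == pytest.approx(1.5)

    def test_empty_x_layer_all_x_statistics_zero(self):
        net = net_from_edges(3, 3)
        for name in ("DensityX", "ASA", "ASB", "ACA"):
            assert z_bipartite_X(net, spec(name)) == 0.0

    def test_cross_level_triangle_minimal_instance(self):
        net = net_from_edges(2, 2, x_edges=[(0, 0), (0, 1)], b_edges=[(0, 1)])
        assert z_interaction(net, spec("TXBX")) == 1.0

    def test_txbx_reciprocated_cld_dyad_counts_twice(self):
        net = net_from_edges(2, 2, x_edges=[(0, 0), (0, 1)],
                             b_edges=[(0, 1), (1, 0)])
        assert z_interaction(net, spec("TXBX")) == 2.0

    def test_l3axbin_minimal_instance(self):
        # popular member (in-degree 1) acting on a central variable (in-degree 1)
        net = net_from_edges(2, 2, a_edges=[(1, 0)], x_edges=[(0, 1)],
                             b_edges=[(0, 1)])
        assert z_interaction(net, spec("L3AXBin")) == 1.0

    def test_entrainment_exchange_orientation(self):
        # collaboration i->j, actions i->u and j->v, CLD arc u->v
        net = net_from_edges(2, 2, a_edges=[(0, 1)],
                             x_edges=[(0, 0), (1, 1)], b_edges=[(0, 1)])
        assert z_interaction(net, spec("C4AXBentrainment")) == 1.0
        assert z_interaction(net, spec("C4AXBexchange")) == 0.0
        # reversing the CLD arc swaps the two counts
        net2 = net_from_edges(2, 2, a_edges=[(0, 1)],
                              x_edges=[(0, 0), (1, 1)], b_edges=[(1, 0)])
        assert z_interaction(net2, spec("C4AXBentrainment")) == 0.0
        assert z_interaction(net2, spec("C4AXBexchange")) == 1.0

    def test_all_statistics_zero_on_empty_free_layers(self, rng):
        net = make_random_mnet(rng, p=0.0)
        for s in ALL_SPECS:
            assert evaluate_statistics(net, [s]).values[0] == 0.0

    def test_missing_attribute_values_never_match(self):
        import pandas as pd
        y = pd.DataFrame({"id": ["m0", "m1"], "education": ["", ""]})
        net = net_from_edges(2, 1, a_edges=[(0, 1), (1, 0)], Y=y)
        assert z_within_A(net, spec("Edu_Match")) == 0.0


class TestOracleAgreement:
    @pytest.mark.parametrize("name", [s.name for s in ALL_SPECS])
    def test_closed_form_equals_brute_force(self, rng, name):
        s = spec(name)
        for _ in range(25):
            net = make_random_mnet(rng, n_a=int(rng.integers(3, 7)),
                                   n_b=int(rng.integers(2, 7)),
                                   p=float(rng.uniform(0.1, 0.6)))
            assert evaluate_statistics(net, [s]).values[0] == pytest.approx(
                brute_force_count(net, s), abs=1e-9)

    @pytest.mark.parametrize("lam", [2.0, 3.0])
    @pytest.mark.parametrize("degree", range(8))
    def test_alternating_star_series_identity(self, lam, degree):
        # closed form lam^2[(1-1/lam)^d - 1 + d/lam] equals the alternating
        # k-star sum for a single hub of the given in-degree
        n = degree + 1 if degree else 2
        net = net_from_edges(max(n, 2), 1,
                             a_edges=[(i, 0) for i in range(1, degree + 1)])
        s = ConfigurationSpec("AinS", lam=lam)
        closed = z_within_A(net, s)
        import math
        series = sum(
            (-1) ** k * math.comb(degree, k) * lam ** (2 - k)
            for k in range(2, degree + 1)
        ) if degree >= 2 else 0.0
        assert closed == pytest.approx(series, abs=1e-9)

    def test_brute_force_refuses_large_networks(self, rng):
        net = make_random_mnet(rng, n_a=9, n_b=3)
        with pytest.raises(ValueError, match="8"):
            brute_force_count(net, spec("Density"))


class TestChangeStatistics:
    def test_density_delta_is_one_reciprocity_conditional(self):
        net = net_from_edges(3, 1, a_edges=[(1, 0)])
        d = change_statistics(net, ("A", 0, 1), default_specs(["Density", "Reciprocity"]))
        assert d[0] == 1.0 and d[1] == 1.0  # A[1,0] present -> reciprocal
        d2 = change_statistics(net, ("A", 0, 2), default_specs(["Density", "Reciprocity"]))
        assert d2[1] == 0.0

    def test_delta_equals_full_evaluation_difference(self, rng):
        for _ in range(12):
            net = make_random_mnet(rng, n_a=5, n_b=5, p=float(rng.uniform(0.2, 0.5)))
            for layer, jmax in (("A", 5), ("X", 5)):
                for i in range(5):
                    for j in range(jmax):
                        if layer == "A" and i == j:
                            continue
                        d = change_statistics(net, (layer, i, j), ALL_SPECS)
                        hi_A, hi_X = net.A.copy(), net.X.copy()
                        lo_A, lo_X = net.A.copy(), net.X.copy()
                        (hi_A if layer == "A" else hi_X)[i, j] = 1
                        (lo_A if layer == "A" else lo_X)[i, j] = 0
                        z_hi = evaluate_statistics(net.with_layers(A=hi_A, X=hi_X), ALL_SPECS).values
                        z_lo = evaluate_statistics(net.with_layers(A=lo_A, X=lo_X), ALL_SPECS).values
                        np.testing.assert_allclose(d, z_hi - z_lo, atol=1e-9)

    def test_exogenous_cld_layer_cannot_be_toggled(self, rng):
        net = make_random_mnet(rng)
        with pytest.raises(ValueError, match="exogenous"):
            change_statistics(net, ("B", 0, 1), ALL_SPECS)

    def test_monotone_count_statistics_never_decrease(self, rng):
        monotone = default_specs(
            ["Density", "DensityX", "In2StarBX", "Out2StarBX", "TXBX", "L3AXBin"])
        for _ in range(20):
            net = make_random_mnet(rng, p=0.4)
            for layer, j in (("A", int(rng.integers(1, 5))), ("X", int(rng.integers(5)))):
                d = change_statistics(net, (layer, 0, j), monotone)
                assert (d >= -1e-12).all()


class TestEvaluation:
    def test_vector_equals_individual_dispatch(self, rng):
        net = make_random_mnet(rng)
        vec = evaluate_statistics(net, ALL_SPECS)
        for s, v in zip(ALL_SPECS, vec.values):
            if s.level == "A":
                assert v == z_within_A(net, s)
            elif s.level == "X":
                assert v == z_bipartite_X(net, s)
            else:
                assert v == z_interaction(net, s)

    def test_community_1_model_has_17_effects(self, rng):
        from mergm.pipeline import COMMUNITY_1_EFFECTS
        specs = default_specs(COMMUNITY_1_EFFECTS)
        net = make_random_mnet(rng)
        assert len(evaluate_statistics(net, specs).values) == 17

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        net = make_random_mnet(rng, n_a=5, n_b=4)
        pa, pv = rng.permutation(5), rng.permutation(4)
        relabeled = MultilevelNetwork(
            tuple(net.actors[i] for i in pa),
            tuple(net.variables[v] for v in pv),
            net.A[np.ix_(pa, pa)],
            net.B[np.ix_(pv, pv)],
            net.X[np.ix_(pa, pv)],
            net.Y.iloc[list(pa)].reset_index(),
        )
        np.testing.assert_allclose(
            evaluate_statistics(net, ALL_SPECS).values,
            evaluate_statistics(relabeled, ALL_SPECS).values,
            atol=1e-9,
        )


class TestSpecValidation:
    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            ConfigurationSpec("NotAThing")

    def test_lambda_must_exceed_one_for_alternating(self):
        with pytest.raises(ValueError, match="lambda"):
            ConfigurationSpec("AinS", lam=1.0)
        ConfigurationSpec("Density", lam=1.0)  # non-alternating: lam unused

    def test_match_effect_requires_attribute(self):
        with pytest.raises(ValueError, match="attribute"):
            ConfigurationSpec("Edu_Match")

    def test_wrong_level_dispatch_rejected(self, rng):
        net = make_random_mnet(rng)
        with pytest.raises(ValueError, match="level"):
            z_within_A(net, spec("DensityX"))

    def test_catalogue_has_23_effects(self):
        assert len(CATALOGUE_23) == 23
        assert set(s.level for n, s in CATALOGUE.items()) == {"A", "X", "AX", "BX", "AXB"}
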