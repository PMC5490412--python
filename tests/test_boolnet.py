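"""KGML parsing, Boolean updates, continuous dynamics, treatment simulation."""

import logging

import numpy as np
import pytest

from woundnet import (
    BooleanNetwork,
    ContinuousModel,
    FormatError,
    SignedRegulation,
    UsageError,
    assemble,
    boolean_step,
    continuous_rate,
    integrate,
    make_toy_kgml,
    parse_kgml,
    simulate_treatment,
)

from _oracles import all_boolean_states, boolean_trajectory_oracle


def network_of(activators, inhibitors):
    nodes = tuple(sorted(set(activators) | set(inhibitors)
                         | set().union(*activators.values(), *inhibitors.values())))
    return BooleanNetwork(
        nodes=nodes,
        activators={n: frozenset(activators.get(n, ())) for n in nodes},
        inhibitors={n: frozenset(inhibitors.get(n, ())) for n in nodes},
    )


class TestParseKgml:
    def test_activation_relation(self):
        xml = make_toy_kgml([("A", "B", +1)])
        assert parse_kgml(xml) == [SignedRegulation("A", "B", +1)]

    def test_inhibition_relation(self):
        xml = make_toy_kgml([("A", "B", -1)])
        assert parse_kgml(xml) == [SignedRegulation("A", "B", -1)]

    def test_group_expands_to_one_regulation_per_component(self):
        xml = make_toy_kgml([("CPLX", "X", +1)], groups={"CPLX": ["A", "B"]})
        regs = set(parse_kgml(xml))
        assert regs == {SignedRegulation("A", "X", +1), SignedRegulation("B", "X", +1)}

    def test_unsigned_subtype_skipped_with_warning(self, caplog):
        xml = make_toy_kgml([("A", "B", +1)]).replace(
            'name="activation"', 'name="binding/association"'
        )
        with caplog.at_level(logging.WARNING, logger="woundnet.boolnet"):
            assert parse_kgml(xml) == []
        assert any("skipping relation" in r.message for r in caplog.records)

    def test_malformed_xml_rejected(self):
        with pytest.raises(FormatError, match="malformed"):
            parse_kgml("<pathway><entry id='1'></pathway>")

    def test_unknown_entry_reference_rejected(self):
        xml = make_toy_kgml([("A", "B", +1)]).replace('entry1="1"', 'entry1="99"')
        with pytest.raises(FormatError, match="unknown entry"):
            parse_kgml(xml)


class TestAssemble:
    def test_single_activator_rule(self):
        net = assemble([SignedRegulation("A", "B", +1)])
        assert net.activators["B"] == {"A"}
        assert net.inhibitors["B"] == frozenset()
        assert net.is_input("A")

    def test_activator_and_inhibitor(self):
        net = assemble([SignedRegulation("A", "B", +1), SignedRegulation("C", "B", -1)])
        assert net.activators["B"] == {"A"}
        assert net.inhibitors["B"] == {"C"}

    def test_contradictory_regulation_kept_both_sides(self, caplog):
        with caplog.at_level(logging.WARNING, logger="woundnet.boolnet"):
            net = assemble([SignedRegulation("A", "B", +1), SignedRegulation("A", "B", -1)])
        assert net.activators["B"] == {"A"} and net.inhibitors["B"] == {"A"}
        assert any("contradictory" in r.message for r in caplog.records)
        # inhibitor dominates through the AND NOT
        state = np.array([1, 0])  # nodes sorted: A, B
        assert boolean_step(net, state)[net.nodes.index("B")] == 0


class TestBooleanStep:
    def test_signal_propagates_along_chain(self):
        net = assemble([SignedRegulation("A", "B", +1), SignedRegulation("B", "C", +1)])
        state = np.array([1, 0, 0])
        state = boolean_step(net, state)
        state = boolean_step(net, state)
        assert state[net.nodes.index("C")] == 1

    def test_fixed_point_stays_fixed(self):
        net = assemble([SignedRegulation("A", "B", +1), SignedRegulation("B", "C", +1)])
        fixed = np.array([1, 1, 1])
        assert (boolean_step(net, fixed) == fixed).all()

    def test_repressilator_limit_cycle_matches_enumeration(self):
        net = assemble([
            SignedRegulation("A", "B", -1),
            SignedRegulation("B", "C", -1),
            SignedRegulation("C", "A", -1),
        ])

        def update(state):
            return tuple(boolean_step(net, np.array(state)))

        transient, cycle = boolean_trajectory_oracle(update, 3, (1, 0, 0))
        assert len(cycle) > 1  # oscillates rather than settling
        # every state on the cycle maps to the next one
        for i, state in enumerate(cycle):
            assert update(state) == cycle[(i + 1) % len(cycle)]

    def test_wrong_length_rejected(self):
        net = assemble([SignedRegulation("A", "B", +1)])
        with pytest.raises(ValueError):
            boolean_step(net, np.array([1, 0, 1]))


class TestContinuousRate:
    def test_and_like_rule_is_multilinear_product(self):
        # B has activator A and inhibitor C: interpolation x_A * (1 - x_C)
        net = network_of({"B": ["A"]}, {"B": ["C"]})
        model = ContinuousModel(network=net, method="boolecube")
        x = np.array([0.5, 0.4, 0.5])  # order A, B, C
        rate = continuous_rate(model, x)
        assert rate[net.nodes.index("B")] == pytest.approx((0.5 * 0.5 - 0.4) / 1.0)

    def test_or_rule_is_inclusion_exclusion(self):
        net = network_of({"C": ["A", "B"]}, {})
        model = ContinuousModel(network=net, method="boolecube")
        x = np.array([0.5, 0.5, 0.2])
        expected = 1 - (1 - 0.5) * (1 - 0.5)  # 0.75
        assert continuous_rate(model, x)[net.nodes.index("C")] == pytest.approx(
            expected - 0.2)

    @pytest.mark.parametrize("exponent", [1.0, 2.0, 3.0, 7.5])
    def test_hill_half_activation_at_threshold(self, exponent):
        from woundnet.boolnet import _hill

        assert _hill(np.array(0.5), exponent, 0.5) == pytest.approx(0.5)

    def test_out_of_hypercube_rejected(self):
        net = network_of({"B": ["A"]}, {})
        model = ContinuousModel(network=net)
        with pytest.raises(ValueError):
            continuous_rate(model, np.array([1.5, 0.0]))

    @pytest.mark.parametrize("method", ["boolecube", "normalized_hillcube"])
    def test_corner_agreement_for_all_small_rules(self, method):
        """The interpolated rule equals the Boolean rule at every hypercube
        corner, for every activator/inhibitor split of up to 3 regulators."""
        for n_act in range(4):
            for n_inh in range(4 - n_act):
                if n_act == n_inh == 0:
                    continue
                acts = [f"A{i}" for i in range(n_act)]
                inhs = [f"I{i}" for i in range(n_inh)]
                net = network_of({"T": acts}, {"T": inhs})
                model = ContinuousModel(network=net, method=method)
                index = net.index()
                for corner in all_boolean_states(len(net.nodes)):
                    x = np.array(corner, dtype=float)
                    boolean = boolean_step(net, np.array(corner))[index["T"]]
                    rate = continuous_rate(model, x)[index["T"]]
                    interpolated = rate + x[index["T"]]
                    assert interpolated == pytest.approx(float(boolean), abs=1e-12)


class TestIntegrate:
    def test_input_node_stays_constant(self):
        net = assemble([SignedRegulation("A", "B", +1)])
        model = ContinuousModel(network=net, method="boolecube")
        _, states = integrate(model, [0.7, 0.3], horizon=5.0,
                              t_eval=np.linspace(0, 5, 6))
        assert states[:, net.nodes.index("A")] == pytest.approx(0.7, abs=1e-7)

    def test_single_activator_closed_form(self):
        # dB/dt = x_A - B with A clamped at 1: B(t) = 1 - (1 - B0) e^-t
        net = assemble([SignedRegulation("A", "B", +1)])
        model = ContinuousModel(network=net, method="boolecube")
        times, states = integrate(model, [1.0, 0.2], horizon=4.0, clamp=["A"],
                                  t_eval=np.linspace(0, 4, 9))
        expected = 1 - 0.8 * np.exp(-times)
        assert states[:, net.nodes.index("B")] == pytest.approx(expected, abs=1e-5)

    def test_boolean_fixed_point_is_stationary(self):
        net = assemble([
            SignedRegulation("A", "B", +1),
            SignedRegulation("B", "C", +1),
            SignedRegulation("D", "C", -1),
        ])
        model = ContinuousModel(network=net, method="normalized_hillcube")
        fixed = np.array([1, 1, 1, 0], dtype=float)  # A,B,C,D sorted
        assert (boolean_step(net, fixed.astype(int)) == fixed).all()
        assert np.linalg.norm(continuous_rate(model, fixed)) < 1e-9
        _, states = integrate(model, fixed, horizon=5.0, t_eval=[0.0, 5.0])
        assert states[-1] == pytest.approx(fixed, abs=1e-6)

    def test_trajectories_stay_in_unit_hypercube(self):
        from woundnet.synthetic import make_random_pathway

        net = assemble([SignedRegulation(s, t, sign)
                        for s, t, sign in make_random_pathway(12, 16, seed=4)])
        model = ContinuousModel(network=net)
        rng = np.random.default_rng(4)
        x0 = rng.integers(0, 2, size=len(net.nodes)).astype(float)
        _, states = integrate(model, x0, horizon=10.0)
        assert states.min() >= -1e-6
        assert states.max() <= 1 + 1e-6

    def test_unknown_clamp_node_rejected(self):
        net = assemble([SignedRegulation("A", "B", +1)])
        model = ContinuousModel(network=net)
        with pytest.raises(UsageError):
            integrate(model, [1.0, 0.0], clamp=["Z"])


class TestSimulateTreatment:
    def test_isolated_input_node_never_switches(self):
        net = assemble([SignedRegulation("A", "B", +1), SignedRegulation("C", "C2", +1)])
        ranking = simulate_treatment(net, {"A": 1}, n_sims=100, seed=2)
        assert ranking.switch_counts["C"] == 0

    def test_same_seed_reproduces_ranking(self):
        net = assemble([SignedRegulation("A", "B", +1), SignedRegulation("B", "C", -1)])
        first = simulate_treatment(net, {"A": 1}, n_sims=200, seed=9)
        second = simulate_treatment(net, {"A": 1}, n_sims=200, seed=9)
        assert first.nodes == second.nodes
        assert first.switch_counts == second.switch_counts

    def test_downstream_switch_frequency_near_half(self):
        # B follows its only activator A (treatment=1), so B switches exactly
        # when initialized at 0: Binomial(n, 0.5) within 3 standard errors
        net = assemble([SignedRegulation("A", "B", +1)])
        n_sims = 400
        ranking = simulate_treatment(net, {"A": 1}, n_sims=n_sims, seed=5)
        se = (0.25 / n_sims) ** 0.5
        assert abs(ranking.frequency("B") - 0.5) <= 3 * se

    def test_treatment_nodes_excluded_from_ranking(self):
        net = assemble([SignedRegulation("A", "B", +1)])
        ranking = simulate_treatment(net, {"A": 1}, n_sims=50, seed=1)
        assert "A" not in ranking.nodes

    def test_unknown_treatment_node_rejected(self):
        net = assemble([SignedRegulation("A", "B", +1)])
        with pytest.raises(UsageError):
            simulate_treatment(net, {"Z": 1}, n_sims=10, seed=0)
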