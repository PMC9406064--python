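"""Network/rule construction: parsing, rule generation, synthetic topologies."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pleionet import (
    EdgeListError,
    NCFRule,
    SignedDiGraph,
    brute_force_attractors,
    generate_ba_network,
    generate_ncf_rules,
    parse_signed_edge_list,
    write_signed_edge_list,
)
from pleionet.structure import degrees


class TestEdgeListIO:
    def test_basic_parse(self):
        g = parse_signed_edge_list("v1 + v2\nv1 - v3")
        assert g.nodes == ("v1", "v2", "v3")
        assert g.links == (("v1", "v2", 1), ("v1", "v3", -1))

    def test_empty_input_gives_empty_graph(self):
        g = parse_signed_edge_list("")
        assert g.n_nodes == 0 and g.n_links == 0

    def test_comments_and_blank_lines_ignored(self):
        g = parse_signed_edge_list("# header\n\na + b\n")
        assert g.n_links == 1

    @pytest.mark.parametrize(
        "token,sign",
        [("+", 1), ("-", -1), ("1", 1), ("-1", -1),
         ("activates", 1), ("inhibits", -1)],
    )
    def test_sign_token_dialects(self, token, sign):
        g = parse_signed_edge_list(f"a {token} b")
        assert g.links[0][2] == sign

    def test_duplicate_link_is_an_error(self):
        with pytest.raises(EdgeListError, match=r"\(a, b\)"):
            parse_signed_edge_list("a + b\na + b")

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(EdgeListError, match="line 2"):
            parse_signed_edge_list("a + b\na +")

    def test_unknown_sign_token(self):
        with pytest.raises(EdgeListError, match="sign token"):
            parse_signed_edge_list("a ? b")

    def test_write_canonical_tokens(self):
        g = SignedDiGraph(nodes=("v1", "v2"), links=(("v1", "v2", 1),))
        assert write_signed_edge_list(g) == "v1\t+\tv2"
        assert write_signed_edge_list(
            SignedDiGraph(nodes=(), links=())
        ) == ""

    @settings(max_examples=50, derandomize=True)
    @given(st.data())
    def test_write_parse_round_trip(self, data):
        n = data.draw(st.integers(2, 8))
        names = [f"n{i}" for i in range(n)]
        pairs = data.draw(
            st.sets(
                st.tuples(st.integers(0, n - 1), st.integers(0, n - 1)),
                min_size=1,
                max_size=n * 2,
            )
        )
        links = tuple(
            (names[a], names[b], data.draw(st.sampled_from([1, -1])))
            for a, b in sorted(pairs)
        )
        used = []
        for s, t, _ in links:
            for x in (s, t):
                if x not in used:
                    used.append(x)
        g = SignedDiGraph(nodes=tuple(used), links=links)
        assert parse_signed_edge_list(write_signed_edge_list(g)) == g


class TestSignedDiGraphInvariants:
    def test_undeclared_endpoint_rejected(self):
        with pytest.raises(EdgeListError):
            SignedDiGraph(nodes=("a",), links=(("a", "b", 1),))

    def test_self_loop_permitted(self):
        g = SignedDiGraph(nodes=("a",), links=(("a", "a", 1),))
        assert g.n_links == 1

    def test_duplicate_pair_rejected_even_with_other_sign(self):
        with pytest.raises(EdgeListError):
            SignedDiGraph(
                nodes=("a", "b"), links=(("a", "b", 1), ("a", "b", -1))
            )


def _truth_table(rule: NCFRule):
    table = {}
    for bits in product((0, 1), repeat=len(rule.inputs)):
        table[bits] = rule.evaluate(dict(zip(rule.inputs, bits)))
    return table


class TestRuleGeneration:
    def test_deterministic_given_seed(self):
        g = generate_ba_network(20, 2, seed=5)
        a = generate_ncf_rules(g, seed=9)
        b = generate_ncf_rules(g, seed=9)
        assert a.rules == b.rules
        c = generate_ncf_rules(g, seed=10)
        assert a.rules != c.rules

    def test_no_rule_for_input_free_node(self):
        g = parse_signed_edge_list("a + b")
        net = generate_ncf_rules(g, seed=0)
        assert "a" not in net.rules and "b" in net.rules

    def test_single_activating_input_is_identity(self):
        # both random draws (I=1,O=1,Odef=0) and (I=0,O=0,Odef=1) have an
        # identity truth table; check over many seeds that both occur
        g = parse_signed_edge_list("a + b")
        seen = set()
        for seed in range(20):
            rule = generate_ncf_rules(g, seed=seed).rules["b"]
            seen.add(rule.canalyzing_values[0])
            assert _truth_table(rule) == {(0,): 0, (1,): 1}
        assert seen == {0, 1}

    def test_single_inhibiting_input_is_negation(self):
        g = parse_signed_edge_list("a - b")
        for seed in range(10):
            rule = generate_ncf_rules(g, seed=seed).rules["b"]
            assert _truth_table(rule) == {(0,): 1, (1,): 0}

    def test_default_output_convention(self):
        g = generate_ba_network(30, 2, seed=3)
        for mode in ("sign_consistent", "fully_random"):
            net = generate_ncf_rules(g, seed=11, sign_mode=mode)
            for rule in net.rules.values():
                assert rule.default_output == 1 - rule.canalyzed_values[-1]

    def test_sign_consistent_canalyzation(self):
        # flipping input m to its canalyzing value, with all earlier inputs
        # non-canalyzing, must force output O_m; and O_m must follow the
        # link sign (activator pushes on, inhibitor pushes off)
        g = generate_ba_network(25, 3, seed=17, inhibition_prob=0.4)
        net = generate_ncf_rules(g, seed=23, sign_mode="sign_consistent")
        signs = {(s, t): sign for s, t, sign in g.links}
        for node, rule in net.rules.items():
            if len(rule.inputs) > 4:
                continue
            for m in range(len(rule.inputs)):
                values = {
                    name: 1 - i_m
                    for name, i_m in zip(rule.inputs, rule.canalyzing_values)
                }
                values[rule.inputs[m]] = rule.canalyzing_values[m]
                assert rule.evaluate(values) == rule.canalyzed_values[m]
                expected = (
                    rule.canalyzing_values[m]
                    if signs[(rule.inputs[m], node)] == 1
                    else 1 - rule.canalyzing_values[m]
                )
                assert rule.canalyzed_values[m] == expected

    def test_invalid_mode_rejected(self):
        g = parse_signed_edge_list("a + b")
        with pytest.raises(ValueError):
            generate_ncf_rules(g, seed=0, sign_mode="nope")


class TestBANetwork:
    def test_link_count_is_m_times_n_minus_m(self):
        g = generate_ba_network(50, 2, seed=7, inhibition_prob=0.3)
        assert g.n_nodes == 50
        assert g.n_links == 2 * (50 - 2) == 96

    def test_deterministic_given_seed(self):
        a = generate_ba_network(40, 3, seed=11, inhibition_prob=0.5)
        b = generate_ba_network(40, 3, seed=11, inhibition_prob=0.5)
        assert a == b

    @pytest.mark.parametrize("n,m", [(2, 2), (1, 1), (5, 0)])
    def test_invalid_sizes_rejected(self, n, m):
        with pytest.raises(ValueError):
            generate_ba_network(n, m, seed=0)

    def test_inhibition_probability_extremes(self):
        all_pos = generate_ba_network(30, 2, seed=1, inhibition_prob=0.0)
        assert all(sign == 1 for _, _, sign in all_pos.links)
        all_neg = generate_ba_network(30, 2, seed=1, inhibition_prob=1.0)
        assert all(sign == -1 for _, _, sign in all_neg.links)

    def test_preferential_attachment_heavy_tail(self):
        # hubs emerge: max total degree >= 3x median in >= 18/20 graphs
        hits = 0
        for seed in range(20):
            g = generate_ba_network(200, 2, seed=seed, inhibition_prob=0.3)
            deg = np.array([degrees(g)[v][0] for v in g.nodes])
            if deg.max() >= 3 * np.median(deg):
                hits += 1
        assert hits >= 18


class TestFixtures:
    def test_neg_loop_is_a_single_period_4_cycle(self, neg_loop):
        attractors, basin = brute_force_attractors(neg_loop)
        assert len(attractors) == 1
        assert attractors[0].period == 4
        assert len(basin) == 4

    def test_const_chain_rules_are_identity(self, const_chain):
        for rule in const_chain.rules.values():
            assert _truth_table(rule) == {(0,): 0, (1,): 1}

    def test_fig1_star_topology(self, fig1_star):
        deg = degrees(fig1_star.graph)
        assert deg["v1"] == (3, 0, 3)

    def test_fixtures_have_explicit_rules(self, fixtures):
        for net in fixtures.values():
            for node in net.graph.nodes:
                regulated = bool(net.graph.in_links(node))
                assert (node in net.rules) == regulated
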