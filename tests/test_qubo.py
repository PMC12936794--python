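"""QUBO construction, energy evaluation, and walk encoding/decoding."""

import numpy as np
import pytest

from tangleasm import (Walk, WalkPair, build_qubo, decode_assignment,
                       decoded_cost, encode_walk, energy, enumerate_optimum,
                       make_instance, make_line_graph, walk_cost)
from tangleasm.qubo import read_qubo, write_qubo
from tangleasm.tangle import _all_walks


class TestBuild:
    def test_horizon_and_variable_counts(self, line15011):
        inst = build_qubo(line15011, "plain")  # sum w = 4, T = ceil(4.8) = 5
        assert inst.T == 5 and inst.n_vars == (5 + 1) * 5
        assert build_qubo(line15011, "oriented").n_vars == (2 * 5 + 1) * 5
        assert build_qubo(line15011, "diploid").n_vars == 2 * (2 * 5 + 1) * 5

    def test_variable_count_formulas_across_random_sizes(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(1, 7))
            T = int(rng.integers(1, 6))
            g = make_line_graph([1] * n, node_length=10, seed=int(rng.integers(1e6)))
            assert build_qubo(g, "plain", T_override=T).n_vars == (n + 1) * T
            assert build_qubo(g, "oriented", T_override=T).n_vars == (2 * n + 1) * T
            assert build_qubo(g, "diploid", T_override=T).n_vars == 2 * (2 * n + 1) * T

    def test_matrix_symmetric(self, line15011):
        M = build_qubo(line15011, "oriented").matrix
        assert np.array_equal(M, M.T)

    def test_zero_weight_graph_needs_override(self):
        g = make_line_graph([0, 0])
        with pytest.raises(ValueError, match="zero"):
            build_qubo(g, "plain")
        assert build_qubo(g, "plain", T_override=2).T == 2

    def test_alpha_must_exceed_one(self, line15011):
        with pytest.raises(ValueError, match="alpha"):
            build_qubo(line15011, "plain", alpha=1.0)


class TestEnergy:
    def test_all_zero_assignment_closed_form(self, line15011):
        # C1 = L1*T (every per-time constraint violated), C3 = sum w^2
        inst = build_qubo(line15011, "plain")
        expected = inst.lambda1 * inst.T + sum(
            n.weight ** 2 for n in line15011.nodes.values())
        assert energy(inst, np.zeros(inst.n_vars)) == expected

    def test_single_bit_flip_matches_finite_difference(self, line15011):
        inst = build_qubo(line15011, "oriented", T_override=3)
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, inst.n_vars).astype(np.int8)
        e0 = energy(inst, x)
        for i in rng.integers(0, inst.n_vars, size=10):
            y = x.copy()
            y[i] ^= 1
            xf = x.astype(float)
            local = inst.matrix[i, i] + 2 * (inst.matrix[i] @ xf
                                             - inst.matrix[i, i] * xf[i])
            de = (1 - 2 * x[i]) * local
            assert energy(inst, y) == pytest.approx(e0 + de, abs=1e-9)

    def test_length_mismatch_rejected(self, line15011):
        inst = build_qubo(line15011, "plain")
        with pytest.raises(ValueError, match="length"):
            energy(inst, np.zeros(inst.n_vars - 1))


class TestEncodingExactness:
    def test_encoded_walk_energy_equals_walk_cost_exhaustively(self):
        """Penalty terms vanish on valid encodings: energy == tangle cost
        for every valid walk of length <= 4 on a family of small graphs."""
        for seed in range(12):
            variant = "plain" if seed % 2 else "oriented"
            inst_g = make_instance(shape=["line", "cycle", "tangle", "random"][seed % 4],
                                   n_nodes=2 + seed % 3, node_length=15,
                                   walk_length=3, orientation=variant, seed=seed)
            g = inst_g.graph
            q = build_qubo(g, variant, T_override=4)
            sites = ([(v, "+") for v in sorted(g.nodes)] if variant == "plain"
                     else [(v, o) for v in sorted(g.nodes) for o in "+-"])
            n_checked = 0
            for steps in _all_walks(g, sites, 4):
                w = Walk(list(steps))
                assert energy(q, encode_walk(q, w)) == walk_cost(g, w, variant)
                n_checked += 1
            assert n_checked > 1

    def test_encode_places_end_after_walk(self, line15011):
        inst = build_qubo(line15011, "plain", T_override=4)
        x = encode_walk(inst, Walk([("A", "+"), ("B", "+")]))
        from tangleasm.qubo import END
        on = {inst.var_site(i) for i in np.flatnonzero(x.bits)}
        assert on == {(0, 1, ("A", "+")), (0, 2, ("B", "+")),
                      (0, 3, END), (0, 4, END)}

    def test_empty_walk_is_all_end(self, line15011):
        inst = build_qubo(line15011, "plain", T_override=3)
        x = encode_walk(inst, Walk([]))
        from tangleasm.qubo import END
        assert all(inst.var_site(i)[2] == END for i in np.flatnonzero(x.bits))
        assert x.bits.sum() == 3

    def test_walk_longer_than_horizon_rejected(self, line15011):
        inst = build_qubo(line15011, "plain", T_override=2)
        with pytest.raises(ValueError, match="horizon"):
            encode_walk(inst, Walk([(n, "+") for n in "ABC"]))


class TestDecode:
    def test_round_trip(self, line15011):
        inst = build_qubo(line15011, "plain")
        w = Walk([(n, "+") for n in "ABCDE"])
        dec = decode_assignment(inst, encode_walk(inst, w), line15011)
        assert dec.diagnostics == []
        assert [wk.steps for wk in dec.all_walks()] == [w.steps]

    def test_round_trip_random_walks(self):
        for seed in range(20):
            variant = ["plain", "oriented"][seed % 2]
            inst_g = make_instance(shape="tangle", n_nodes=4, node_length=15,
                                   walk_length=4, orientation=variant, seed=seed)
            q = build_qubo(inst_g.graph, variant, T_override=5)
            w = inst_g.truth_walk
            dec = decode_assignment(q, encode_walk(q, w), inst_g.graph)
            assert [wk.steps for wk in dec.all_walks()] == \
                ([w.steps] if len(w) else [])

    def test_non_edge_transition_splits_and_reports(self, line15011):
        inst = build_qubo(line15011, "plain", T_override=4)
        x = np.zeros(inst.n_vars, dtype=np.int8)
        for t, site in enumerate([("A", "+"), ("B", "+"), ("D", "+"), ("E", "+")], 1):
            x[inst.var_index(0, t, site)] = 1
        dec = decode_assignment(inst, x, line15011)
        assert [w.steps for w in dec.all_walks()] == \
            [[("A", "+"), ("B", "+")], [("D", "+"), ("E", "+")]]
        assert len(dec.diagnostics) == 1

    def test_all_zero_assignment_decodes_empty_with_diagnostics(self, line15011):
        inst = build_qubo(line15011, "plain", T_override=3)
        dec = decode_assignment(inst, np.zeros(inst.n_vars, dtype=np.int8),
                                line15011)
        assert dec.all_walks() == []
        assert len(dec.diagnostics) == 3  # one "no active site" per time

    def test_decode_without_graph_uses_penalty_structure(self, line15011):
        inst = build_qubo(line15011, "plain", T_override=4)
        w = Walk([(n, "+") for n in "ABCD"])
        dec = decode_assignment(inst, encode_walk(inst, w))
        assert [wk.steps for wk in dec.all_walks()] == [w.steps]


class TestPenaltySoundness:
    def test_brute_force_minimum_decodes_to_oracle_optimum(self):
        """At the default penalties the QUBO global minimum is a valid walk
        achieving the enumeration oracle's cost (small-instance family)."""
        from tangleasm import solve_exhaustive
        for seed in range(10):
            variant = "plain" if seed % 2 == 0 else "oriented"
            n_nodes = 3 if variant == "plain" else 2
            T = 4 if variant == "plain" else 3
            inst_g = make_instance(shape=["line", "tangle", "random"][seed % 3],
                                   n_nodes=n_nodes, node_length=15,
                                   walk_length=3, orientation=variant, seed=seed)
            q = build_qubo(inst_g.graph, variant, T_override=T)
            res = solve_exhaustive(q)
            dec = decode_assignment(q, res.best_assignment, inst_g.graph)
            opt, _ = enumerate_optimum(inst_g.graph, variant, max_length=T)
            assert decoded_cost(inst_g.graph, dec) == opt


def test_qubo_file_round_trip(tmp_path, line15011):
    inst = build_qubo(line15011, "oriented", T_override=3)
    p = tmp_path / "prob.qubo"
    write_qubo(inst, p)
    back = read_qubo(p)
    assert back.n_vars == inst.n_vars
    assert np.allclose(back.matrix, inst.matrix)
    assert back.sites == inst.sites
    rng = np.random.default_rng(1)
    x = rng.integers(0, 2, inst.n_vars)
    assert energy(back, x) == pytest.approx(energy(inst, x))
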