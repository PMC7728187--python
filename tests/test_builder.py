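"""Node placement, probabilistic wiring rules, and build determinism."""

import numpy as np
import pytest

from circuitkit.builder import (
    ConnectionRule,
    EdgePropertySpec,
    NetworkBuilder,
    positions_cylinder,
)


class TestAddNodes:
    def test_single_node_with_attribute(self):
        b = NetworkBuilder(seed=0)
        b.add_nodes(1, "p", per_node={"x": np.array([0.0])}, model_type="virtual")
        pop = b.model.node_populations["p"]
        assert pop.n_nodes == 1
        assert pop.attributes["x"][0] == 0.0

    def test_two_calls_distinct_types_contiguous_ids(self):
        b = NetworkBuilder(seed=0)
        ids1 = b.add_nodes(3, "p", model_type="virtual")
        ids2 = b.add_nodes(2, "p", model_type="virtual")
        assert list(ids1) == [0, 1, 2] and list(ids2) == [3, 4]
        pop = b.model.node_populations["p"]
        assert len(set(pop.node_type_ids)) == 2

    def test_ei_counts(self):
        b = NetworkBuilder(seed=0)
        b.add_nodes(10_000, "internal", model_type="point_process", ei="e")
        b.add_nodes(2_500, "internal", model_type="point_process", ei="i")
        assert b.model.node_populations["internal"].n_nodes == 12_500

    def test_bad_generator_length_rejected(self):
        b = NetworkBuilder(seed=0)
        with pytest.raises(ValueError, match="generator"):
            b.add_nodes(3, "p", per_node={"x": np.array([1.0])},
                        model_type="virtual")


class TestPositionsCylinder:
    def test_inside_cylinder(self):
        pts = positions_cylinder(5000, radius=100.0, height=400.0, seed=1)
        r2 = pts[:, 0] ** 2 + pts[:, 1] ** 2
        assert np.all(r2 <= 100.0 ** 2 + 1e-9)
        assert np.all((pts[:, 2] >= 0) & (pts[:, 2] <= 400.0))

    def test_uniform_depth_and_radial_mass(self):
        n = 100_000
        pts = positions_cylinder(n, radius=100.0, height=400.0, seed=2)
        # mean depth -> height/2 within 3 standard errors (CLT)
        se = 400.0 / np.sqrt(12 * n)
        assert abs(pts[:, 2].mean() - 200.0) < 3 * se
        # inner half-radius disc holds 1/4 of the area hence of the points
        frac = np.mean(pts[:, 0] ** 2 + pts[:, 1] ** 2 <= 50.0 ** 2)
        se_frac = np.sqrt(0.25 * 0.75 / n)
        assert abs(frac - 0.25) < 3 * se_frac

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            positions_cylinder(0, 1.0, 1.0)
        with pytest.raises(ValueError):
            positions_cylinder(5, -1.0, 1.0)


def _two_pop_builder(n_a=3, n_b=4, seed=0):
    b = NetworkBuilder(seed=seed)
    b.add_nodes(n_a, "a", model_type="virtual")
    b.add_nodes(n_b, "b", model_type="virtual")
    return b


class TestAddEdges:
    def test_probability_zero_gives_no_edges(self):
        b = _two_pop_builder()
        n = b.add_edges("a", "b", ConnectionRule("fixed_probability", p=0.0))
        assert n == 0

    def test_probability_one_complete_bipartite(self):
        b = _two_pop_builder()
        n = b.add_edges("a", "b", ConnectionRule("fixed_probability", p=1.0))
        assert n == 12

    def test_autapses_excluded_by_default(self):
        b = NetworkBuilder(seed=0)
        b.add_nodes(5, "p", model_type="virtual")
        n = b.add_edges("p", "p", ConnectionRule("all_to_all"))
        assert n == 20  # 5*5 - 5 self-pairs
        ep = b.model.edge_populations["p_to_p"]
        assert not np.any(ep.source_node_ids == ep.target_node_ids)

    def test_edge_count_concentration(self):
        """Bernoulli(p) over N_s x N_t pairs concentrates at the binomial mean."""
        b = _two_pop_builder(n_a=400, n_b=500, seed=3)
        p = 0.2
        n = b.add_edges("a", "b", ConnectionRule("fixed_probability", p=p))
        mean = 400 * 500 * p
        bound = 4 * np.sqrt(400 * 500 * p * (1 - p))
        assert abs(n - mean) < bound

    def test_gaussian_distance_rule(self):
        """Empirical P(connect | d) matches A*exp(-d^2/(2 sigma^2))."""
        n = 400
        b = NetworkBuilder(seed=4)
        b.add_nodes(n, "p", per_node={
            "x": lambda r, k: 200.0 * r.random(k),
            "y": lambda r, k: np.zeros(k), "z": lambda r, k: np.zeros(k)},
            model_type="virtual")
        A, sig = 0.5, 50.0
        b.add_edges("p", "p", ConnectionRule("gaussian_distance",
                                             amplitude=A, sigma_d=sig))
        pop = b.model.node_populations["p"]
        x = pop.attributes["x"]
        ep = b.model.edge_populations["p_to_p"]
        connected = set(zip(ep.source_node_ids.tolist(), ep.target_node_ids.tolist()))
        d = np.abs(x[:, None] - x[None, :])
        for d_lo, d_hi in ((0.0, 10.0), (40.0, 60.0), (120.0, 160.0)):
            mask = (d >= d_lo) & (d < d_hi) & ~np.eye(n, dtype=bool)
            pairs = np.argwhere(mask)
            got = np.mean([(i, j) in connected for i, j in pairs])
            expect = np.mean(A * np.exp(-d[mask] ** 2 / (2 * sig ** 2)))
            se = np.sqrt(max(expect * (1 - expect), 1e-6) / len(pairs))
            assert abs(got - expect) < 4 * se, (d_lo, d_hi)

    def test_gaussian_amplitude_at_zero_distance(self):
        """Coincident nodes connect at the rule's amplitude."""
        b = NetworkBuilder(seed=5)
        b.add_nodes(300, "a", per_node={"x": lambda r, k: np.zeros(k)},
                    model_type="virtual")
        b.add_nodes(300, "b", per_node={"x": lambda r, k: np.zeros(k)},
                    model_type="virtual")
        n = b.add_edges("a", "b", ConnectionRule("gaussian_distance",
                                                 amplitude=0.5, sigma_d=10.0))
        frac = n / (300 * 300)
        se = np.sqrt(0.25 / (300 * 300))
        assert abs(frac - 0.5) < 4 * se

    def test_fixed_indegree(self):
        b = _two_pop_builder(n_a=50, n_b=30, seed=6)
        b.add_edges("a", "b", ConnectionRule("fixed_indegree", indegree=7))
        ep = b.model.edge_populations["a_to_b"]
        counts = np.bincount(ep.target_node_ids, minlength=30)
        assert np.all(counts == 7)
        # no duplicated (source, target) pairs
        pairs = set(zip(ep.source_node_ids.tolist(), ep.target_node_ids.tolist()))
        assert len(pairs) == ep.n_edges

    def test_custom_rule_bad_probability_names_pair(self):
        b = _two_pop_builder()
        with pytest.raises(ValueError, match="source"):
            b.add_edges("a", "b", ConnectionRule("custom",
                                                 func=lambda s, t, d: d * 0 + 1.5))

    def test_one_to_one(self):
        b = _two_pop_builder(n_a=4, n_b=4)
        n = b.add_edges("a", "b", ConnectionRule("one_to_one"))
        ep = b.model.edge_populations["a_to_b"]
        assert n == 4
        assert np.array_equal(ep.source_node_ids, ep.target_node_ids)

    def test_edge_properties_on_type_and_per_edge(self):
        b = _two_pop_builder()
        b.add_edges("a", "b", ConnectionRule("all_to_all"),
                    EdgePropertySpec(syn_weight=2.5, delay=1.5, nsyns=3))
        ep = b.model.edge_populations["a_to_b"]
        row = b.model.edge_types.row(int(ep.edge_type_ids[0]))
        assert row["syn_weight"] == 2.5 and row["delay"] == 1.5 and row["nsyns"] == 3
        b2 = _two_pop_builder()
        b2.add_edges("a", "b", ConnectionRule("all_to_all"),
                     EdgePropertySpec(syn_weight=lambda rng, n: rng.random(n)))
        ep2 = b2.model.edge_populations["a_to_b"]
        assert "syn_weight" in ep2.attributes
        assert len(np.unique(ep2.attributes["syn_weight"])) > 1


class TestDeterminism:
    def test_same_seed_identical_files(self, tmp_path):
        def build(seed, out):
            b = _two_pop_builder(n_a=40, n_b=40, seed=seed)
            b.add_edges("a", "b", ConnectionRule("fixed_probability", p=0.3),
                        EdgePropertySpec(syn_weight=1.0, delay=1.0))
            return b.instantiate_and_save(out)

        build(9, tmp_path / "r1")
        build(9, tmp_path / "r2")
        for name in ("nodes.h5", "edges.h5", "node_types.csv", "edge_types.csv"):
            assert (tmp_path / "r1" / name).read_bytes() == \
                   (tmp_path / "r2" / name).read_bytes(), name

    def test_different_seeds_same_expectation_different_edges(self):
        def edges(seed):
            b = _two_pop_builder(n_a=100, n_b=100, seed=seed)
            b.add_edges("a", "b", ConnectionRule("fixed_probability", p=0.2))
            ep = b.model.edge_populations["a_to_b"]
            return set(zip(ep.source_node_ids.tolist(), ep.target_node_ids.tolist()))

        e1, e2 = edges(1), edges(2)
        mean, sd = 100 * 100 * 0.2, np.sqrt(100 * 100 * 0.2 * 0.8)
        assert abs(len(e1) - mean) < 4 * sd and abs(len(e2) - mean) < 4 * sd
        assert e1 != e2

    def test_earlier_call_unaffected_by_later_rules(self):
        """Per-call RNG sub-streams: adding a rule never changes earlier draws."""
        def first_edges(extra_rule):
            b = _two_pop_builder(n_a=30, n_b=30, seed=11)
            b.add_edges("a", "b", ConnectionRule("fixed_probability", p=0.3))
            ep = b.model.edge_populations["a_to_b"]
            pairs = list(zip(ep.source_node_ids.tolist(), ep.target_node_ids.tolist()))
            if extra_rule:
                b.add_edges("b", "a", ConnectionRule("fixed_probability", p=0.5))
            return pairs

        assert first_edges(False) == first_edges(True)

    def test_edges_emitted_in_lexicographic_order(self):
        b = _two_pop_builder(n_a=20, n_b=20, seed=12)
        b.add_edges("a", "b", ConnectionRule("fixed_probability", p=0.4))
        ep = b.model.edge_populations["a_to_b"]
        pairs = list(zip(ep.source_node_ids.tolist(), ep.target_node_ids.tolist()))
        assert pairs == sorted(pairs)

    def test_manifest_lists_all_files(self, tmp_path):
        b = _two_pop_builder()
        b.add_edges("a", "b", ConnectionRule("all_to_all"))
        files = b.instantiate_and_save(tmp_path)
        names = {f.rsplit("/", 1)[-1] for f in files}
        assert names == {"nodes.h5", "edges.h5", "node_types.csv", "edge_types.csv"}
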