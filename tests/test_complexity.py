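"""Deviating-path discovery, complexity accumulation and hotspot calling."""

import random

import numpy as np
import pytest

from conftest import make_genome_set, pipeline
from pancomplex.complexity import (
    ComplexityParams,
    ComplexityProfile,
    compute_complexity,
    detect_hotspots,
    enumerate_paths_exhaustive,
    find_paths,
)
from pancomplex.graph import ReferenceChain, build_graph


class TestFindPaths:
    def test_bypass_path_is_discovered(self, single_bypass):
        _, graph, chain = single_bypass
        rng = random.Random(0)
        paths = find_paths(graph, "A", chain, iterations=500, rng=rng)
        assert ("A", "B1", "C") in paths
        assert ("A", "X") in paths  # direct chain step, kept by the length>1 rule
        assert all(len(p) >= 2 for p in paths)

    def test_node_without_out_edges_yields_nothing(self, single_bypass):
        _, graph, chain = single_bypass
        assert find_paths(graph, "C", chain, iterations=100) == set()

    def test_unknown_start_rejected(self, single_bypass):
        _, graph, chain = single_bypass
        with pytest.raises(KeyError):
            find_paths(graph, "missing", chain, iterations=10)


class TestExhaustiveOracle:
    def test_single_bypass_exactly_two_paths(self, single_bypass):
        _, graph, chain = single_bypass
        paths = enumerate_paths_exhaustive(graph, "A", chain, max_interior=5)
        assert paths == {("A", "X"), ("A", "B1", "C")}

    def test_pure_chain_has_only_direct_steps(self):
        _, graph, chain = pipeline({"a": list("ABCDE"), "b": list("ABCDE")}, "a")
        for i, node in enumerate(chain.nodes[:-1]):
            paths = enumerate_paths_exhaustive(graph, node, chain)
            assert paths == {(node, chain.nodes[i + 1])}

    def test_sampled_paths_are_subset_of_exhaustive(self):
        """On small random graphs the walker never invents a path the
        enumeration does not contain."""
        for seed in range(10):
            graph, chain = _random_graph(seed)
            rng = random.Random(seed)
            for start in chain.nodes:
                sampled = find_paths(graph, start, chain, iterations=300, rng=rng)
                exhaustive = enumerate_paths_exhaustive(
                    graph, start, chain, max_interior=10
                )
                assert sampled <= exhaustive


def _random_graph(seed, n_ref=8, n_off=5):
    """Sparse random graph: a reference chain plus a few off-chain nodes."""
    rng = random.Random(seed)
    ref = [f"R{i}" for i in range(n_ref)]
    off = [f"O{i}" for i in range(n_off)]
    gs_spec = {"ref": ref, "alt": ref}  # base chain support
    gs = make_genome_set(gs_spec)
    graph = build_graph(gs)
    for node in off:
        graph.add_node(node)
    # each off-chain node: one in-edge and one or two out-edges
    for node in off:
        graph.add_adjacency(rng.choice(ref + off), node, "alt")
        for _ in range(rng.randrange(1, 3)):
            target = rng.choice([t for t in ref + off if t != node])
            graph.add_adjacency(node, target, "alt")
    chain = ReferenceChain(
        genome_id="ref",
        contig_id="c1",
        nodes=ref,
        coords=np.arange(1, n_ref * 1000, 1000),
        ends=np.arange(900, n_ref * 1000 + 900, 1000),
    )
    return graph, chain


class TestComputeComplexity:
    def test_identical_genomes_give_zero_profile(self):
        _, graph, chain = pipeline(
            {g: [f"N{i}" for i in range(30)] for g in ("a", "b", "c")}, "a"
        )
        profile = compute_complexity(graph, chain, ComplexityParams(window=10))
        assert np.all(profile.values == 0)

    def test_single_replacement_scores_exactly_one_over_window(self):
        ref = [f"N{i}" for i in range(50)]
        alt = ref[:]
        alt[25] = "Y"
        _, graph, chain = pipeline({"ref": ref, "alt": alt}, "ref")
        for method in ("sampled", "exhaustive"):
            profile = compute_complexity(
                graph, chain, ComplexityParams(window=20, iterations=500, rng_seed=1),
                method=method,
            )
            expected = np.zeros(50)
            expected[25] = 1 / 20
            np.testing.assert_allclose(profile.values, expected)

    def test_path_beyond_window_contributes_nothing(self):
        # a bypass connecting anchors 30 positions apart, window 20
        ref = [f"N{i}" for i in range(40)]
        alt = [ref[0], "Z", ref[30]] + ref[31:]
        _, graph, chain = pipeline({"ref": ref, "alt": alt}, "ref")
        profile = compute_complexity(
            graph, chain, ComplexityParams(window=20, iterations=500, rng_seed=0)
        )
        assert np.all(profile.values == 0)

    def test_distant_replacements_are_additive(self):
        """Independent replacements ≥ 2·window apart each score exactly
        1/window at their own position."""
        ref = [f"N{i}" for i in range(100)]
        alt = ref[:]
        alt[20], alt[60] = "Y1", "Y2"
        _, graph, chain = pipeline({"ref": ref, "alt": alt}, "ref")
        profile = compute_complexity(
            graph, chain, ComplexityParams(window=20, iterations=500, rng_seed=3)
        )
        expected = np.zeros(100)
        expected[20] = expected[60] = 1 / 20
        np.testing.assert_allclose(profile.values, expected)

    def test_fixed_seed_is_bit_reproducible(self):
        graph, chain = _random_graph(3)
        params = ComplexityParams(window=4, iterations=200, rng_seed=77)
        p1 = compute_complexity(graph, chain, params)
        p2 = compute_complexity(graph, chain, params)
        assert np.array_equal(p1.values, p2.values)

    def test_values_are_multiples_of_one_over_window(self):
        graph, chain = _random_graph(5)
        profile = compute_complexity(
            graph, chain, ComplexityParams(window=4, iterations=500, rng_seed=5)
        )
        scaled = profile.values * 4
        np.testing.assert_allclose(scaled, np.round(scaled), atol=1e-9)
        assert np.all(profile.values >= 0)

    def test_window_must_be_smaller_than_chain(self):
        _, graph, chain = pipeline({"a": list("ABC"), "b": list("ABC")}, "a")
        with pytest.raises(ValueError, match="window"):
            compute_complexity(graph, chain, ComplexityParams(window=3))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ComplexityParams(window=0)
        with pytest.raises(ValueError):
            ComplexityParams(iterations=0)


def _profile_from_values(values):
    n = len(values)
    chain = ReferenceChain(
        genome_id="ref",
        contig_id="c1",
        nodes=[f"N{i}" for i in range(n)],
        coords=np.arange(1, n * 1000, 1000),
        ends=np.arange(900, n * 1000 + 900, 1000),
    )
    return ComplexityProfile(
        chain=chain, values=np.asarray(values, dtype=float),
        params=ComplexityParams(),
    )


class TestHotspots:
    def test_constant_profile_has_no_hotspots(self):
        result = detect_hotspots(_profile_from_values([0.3] * 50))
        assert result.threshold == pytest.approx(0.3)
        assert len(result) == 0

    def test_outlier_block_forms_single_region(self):
        values = [0.0] * 96 + [5.0] * 4
        result = detect_hotspots(_profile_from_values(values))
        assert result.threshold == pytest.approx(0.0)
        assert len(result) == 1
        region = result.regions[0]
        assert region.n_genes == 4
        assert region.start_bp == 96 * 1000 + 1
        assert region.end_bp == 99 * 1000 + 900
        assert region.max_complexity == pytest.approx(5.0)

    def test_zero_iqr_makes_k_irrelevant(self):
        values = [0.0] * 96 + [5.0] * 4
        r1 = detect_hotspots(_profile_from_values(values), k=1.5)
        r10 = detect_hotspots(_profile_from_values(values), k=10)
        assert [r.start_bp for r in r1] == [r.start_bp for r in r10]

    def test_threshold_matches_direct_quartile_computation(self):
        rng = np.random.default_rng(9)
        values = rng.gamma(0.5, 1.0, size=200)
        result = detect_hotspots(_profile_from_values(values), k=1.5)
        q1, q3 = np.percentile(values, [25, 75])
        assert result.threshold == pytest.approx(q3 + 1.5 * (q3 - q1))

    def test_hotspot_gene_count_monotone_in_k(self):
        """A larger k raises the threshold, so the hotspot gene set shrinks."""
        rng = np.random.default_rng(2)
        values = rng.gamma(0.5, 1.0, size=300)
        profile = _profile_from_values(values)
        gene_counts = [
            sum(r.n_genes for r in detect_hotspots(profile, k=k))
            for k in (0.0, 0.5, 1.5, 3.0, 10.0)
        ]
        assert gene_counts == sorted(gene_counts, reverse=True)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            detect_hotspots(_profile_from_values([1.0, 2.0]), k=-1)
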