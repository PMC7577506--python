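"""Coalignment, paralog policies and graph construction."""

import io as stringio
import random

import pytest

from conftest import make_genome_set
from pancomplex.graph import (
    ParalogPolicy,
    apply_paralog_policy,
    build_graph,
    coalign_genomes,
    export_graph_sif,
    extract_reference_chain,
)


def chain_ogs(gs, genome, contig="c1"):
    return [og for og, _ in gs.chain(genome, contig)]


class TestCoalign:
    def test_exact_reverse_is_flipped(self):
        gs = make_genome_set({"ref": list("ABCDE"), "other": list("EDCBA")})
        out = coalign_genomes(gs, "ref")
        assert chain_ogs(out, "other") == list("ABCDE")
        assert out.flipped[("other", "c1")]
        strands = {rec.strand for _, rec in out.chain("other", "c1")}
        assert strands == {"-"}  # strands toggled by the flip

    def test_identical_contig_unchanged(self):
        gs = make_genome_set({"ref": list("ABCDE"), "other": list("ABCDE")})
        out = coalign_genomes(gs, "ref")
        assert chain_ogs(out, "other") == list("ABCDE")
        assert not out.flipped[("other", "c1")]

    def test_reference_is_never_flipped(self):
        gs = make_genome_set({"ref": list("ABCDE"), "o1": list("EDCBA"),
                              "o2": list("EDCBA")})
        out = coalign_genomes(gs, "ref")
        assert chain_ogs(out, "ref") == list("ABCDE")

    def test_disabled_returns_input_unchanged(self):
        gs = make_genome_set({"ref": list("ABCDE"), "other": list("EDCBA")})
        assert coalign_genomes(gs, "ref", enabled=False) is gs

    def test_missing_reference_rejected(self):
        gs = make_genome_set({"a": list("AB"), "b": list("AB")})
        with pytest.raises(KeyError):
            coalign_genomes(gs, "nope")

    def test_majority_orientation_decides(self):
        # 6 forward-shared vs 2 reverse-shared adjacencies -> unchanged
        ref = list("ABCDEFGHIJ")
        other = list("ABCDEFG") + list("JIH")  # AB..FG forward, JI/IH reversed
        gs = make_genome_set({"ref": ref, "other": other})
        out = coalign_genomes(gs, "ref")
        assert chain_ogs(out, "other") == other
        # the mirrored contig has 6 reverse-shared vs 2 forward-shared -> flipped
        gs2 = make_genome_set({"ref": ref, "other": other[::-1]})
        out2 = coalign_genomes(gs2, "ref")
        assert chain_ogs(out2, "other") == other

    def test_decision_matches_brute_force(self):
        """The flip decision equals brute-force adjacency counting for
        random shuffled/reversed contigs."""
        rng = random.Random(4)
        ref = [f"N{i}" for i in range(12)]
        for _ in range(25):
            other = ref[:]
            rng.shuffle(other)
            if rng.random() < 0.5:
                other = other[::-1]
            gs = make_genome_set({"ref": ref, "other": other})
            out = coalign_genomes(gs, "ref")
            ref_adj = set(zip(ref, ref[1:]))
            fwd = sum(p in ref_adj for p in zip(other, other[1:]))
            rev_chain = other[::-1]
            bwd = sum(p in ref_adj for p in zip(rev_chain, rev_chain[1:]))
            expected = rev_chain if bwd > fwd else other
            assert chain_ogs(out, "other") == expected


class TestParalogPolicies:
    def test_skip_drops_only_in_paralogous_genome(self):
        gs = make_genome_set({
            "A": ["OG1", "X", "OG1", "Y"],  # OG1 duplicated here
            "B": ["OG1", "X", "Y"],
        })
        out = apply_paralog_policy(gs, "skip")
        assert chain_ogs(out, "A") == ["X", "Y"]
        assert chain_ogs(out, "B") == ["OG1", "X", "Y"]

    def test_no_paralogs_identity_under_both_modes(self):
        spec = {"A": list("ABC"), "B": list("ACB")}
        for mode in ("skip", "orthologize"):
            out = apply_paralog_policy(make_genome_set(spec), mode)
            assert chain_ogs(out, "A") == list("ABC")
            assert chain_ogs(out, "B") == list("ACB")

    def test_orthologize_splits_by_context(self):
        gs = make_genome_set({
            "A": ["OG2", "OG1", "OG3", "OG7", "OG1", "OG8"],
            "B": ["OG2", "OG1", "OG3"],
        })
        out = apply_paralog_policy(gs, "orthologize")
        assert chain_ogs(out, "A") == ["OG2", "OG1_p1", "OG3", "OG7", "OG1_p2", "OG8"]
        # B's single copy shares the (OG2, OG3) context, hence the suffix
        assert chain_ogs(out, "B") == ["OG2", "OG1_p1", "OG3"]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            ParalogPolicy("drop")


class TestBuildGraph:
    def test_identical_chains_form_path_graph(self):
        gs = make_genome_set({g: list("ABCD") for g in ("g1", "g2", "g3")})
        graph = build_graph(gs)
        assert graph.n_nodes == 4
        assert sorted(graph.edges()) == [
            ("A", "B", 3), ("B", "C", 3), ("C", "D", 3)
        ]

    def test_deletion_adds_bypass_edge(self):
        gs = make_genome_set({"g1": list("ABCD"), "g2": list("ABD")})
        graph = build_graph(gs)
        weights = {(u, v): w for u, v, w in graph.edges()}
        assert weights == {("A", "B"): 2, ("B", "C"): 1, ("C", "D"): 1, ("B", "D"): 1}

    def test_self_loop_permitted(self):
        gs = make_genome_set({"g1": ["X", "A", "A", "Y"], "g2": ["X", "Y"]})
        graph = build_graph(gs)
        assert graph.weight("A", "A") == 1

    def test_same_adjacency_on_two_contigs_counts_once(self):
        gs = make_genome_set({
            "g1": {"c1": ["A", "B"], "c2": ["A2", "B2"]},
            "g2": {"c1": ["A", "B", "A2", "B2"]},
        })
        # clone the A->B adjacency onto both contigs of g1
        gs.chains[("g1", "c2")] = gs.chains[("g1", "c1")]
        graph = build_graph(gs)
        assert graph.weight("A", "B") == 2  # g1 counted once, g2 once

    def test_total_weight_equals_total_adjacencies(self):
        rng = random.Random(11)
        spec = {
            f"g{k}": [f"N{rng.randrange(30)}" for _ in range(rng.randrange(5, 40))]
            for k in range(6)
        }
        gs = apply_paralog_policy(make_genome_set(spec), "skip")
        graph = build_graph(gs)
        assert graph.total_weight() == sum(
            len(c) - 1 for c in gs.chains.values() if c
        )

    def test_permutation_invariance_over_genome_order(self):
        spec = {"g1": list("ABCD"), "g2": list("ABD"), "g3": list("DCBA")}
        g_fwd = build_graph(make_genome_set(spec))
        g_rev = build_graph(make_genome_set(dict(reversed(list(spec.items())))))
        assert sorted(g_fwd.edges()) == sorted(g_rev.edges())

    def test_empty_set_rejected(self):
        from pancomplex.genomes import GenomeSet
        with pytest.raises(ValueError):
            build_graph(GenomeSet({}))


class TestReferenceChain:
    def test_chain_carries_coordinates(self):
        gs = make_genome_set({"ref": list("ABCDE"), "o": list("ABCDE")})
        graph = build_graph(gs)
        chain = extract_reference_chain(graph, gs, "ref", "c1")
        assert chain.nodes == list("ABCDE")
        assert list(chain.coords) == [1, 1001, 2001, 3001, 4001]
        assert chain.position["C"] == 2

    def test_policy_shortened_chain(self):
        gs = make_genome_set({"ref": ["A", "P", "B", "P", "C"], "o": list("ABC")})
        gs = apply_paralog_policy(gs, "skip")
        graph = build_graph(gs)
        chain = extract_reference_chain(graph, gs, "ref", "c1")
        assert chain.nodes == list("ABC")

    def test_flipped_contig_chain_is_reversed(self):
        gs = make_genome_set({"ref": list("ABCDE"), "o": list("EDCBA")})
        gs = coalign_genomes(gs, "ref")
        graph = build_graph(gs)
        chain = extract_reference_chain(graph, gs, "o", "c1")
        assert chain.nodes == list("ABCDE")
        assert list(chain.coords) == [4001, 3001, 2001, 1001, 1]

    def test_unknown_genome_or_contig_rejected(self):
        gs = make_genome_set({"a": list("AB"), "b": list("AB")})
        graph = build_graph(gs)
        with pytest.raises(KeyError):
            extract_reference_chain(graph, gs, "zz")
        with pytest.raises(KeyError):
            extract_reference_chain(graph, gs, "a", "c9")

    def test_genome_chain_walks_existing_edges(self):
        spec = {"g1": list("ABCD"), "g2": list("ABD"), "g3": list("ACD")}
        gs = make_genome_set(spec)
        graph = build_graph(gs)
        for genome, ogs in spec.items():
            for u, v in zip(ogs, ogs[1:]):
                assert graph.weight(u, v) >= 1


def test_sif_export_lists_every_edge():
    gs = make_genome_set({"g1": list("ABC"), "g2": list("ABC")})
    graph = build_graph(gs)
    sif, wts = stringio.StringIO(), stringio.StringIO()
    export_graph_sif(graph, sif, wts)
    assert sif.getvalue() == "A\tadj\tB\nB\tadj\tC\n"
    assert "A\tB\t2" in wts.getvalue()
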