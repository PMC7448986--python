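"""Tree-stage tests: filters, MSA, JTT distances, NJ, bootstraps, pairs."""

import dendropy
import numpy as np
import pytest

from chemoscan.phylo import (
    JttModel,
    Msa,
    build_msa,
    build_tree,
    decode_aa,
    empirical_freqs,
    evolve_jtt,
    filter_for_tree,
    find_ortholog_pairs,
    jtt_distance,
    nj_tree,
    simulate_jtt_sequence,
    simulate_ortholog_family,
)

from conftest import random_protein


class TestFilterForTree:
    def test_or_length_cutoff(self):
        prots = {"a": "A" * 229, "b": "A" * 230}
        assert set(filter_for_tree(prots, "OR")) == {"b"}

    def test_gr_length_cutoff_inclusive_at_250(self):
        prots = {"a": "A" * 249, "b": "A" * 250}
        assert set(filter_for_tree(prots, "GR")) == {"b"}

    def test_ir_has_no_filter(self):
        prots = {"a": "A" * 200}
        assert set(filter_for_tree(prots, "IR")) == {"a"}


class TestBuildMsa:
    def test_identical_pair_aligns_without_gaps(self):
        msa = build_msa({"x": "MKVLLAGHE", "y": "MKVLLAGHE"})
        assert msa.rows[0] == msa.rows[1] == "MKVLLAGHE"

    def test_single_gap_placed_opposite_missing_residue(self):
        msa = build_msa({"a": "ACDEFG", "b": "ACEFG"})
        assert msa.row("a") == "ACDEFG"
        assert msa.row("b") == "AC-EFG"

    def test_degap_roundtrip_random_inputs(self):
        rng = np.random.default_rng(0)
        prots = {f"s{i}": random_protein(rng, int(rng.integers(80, 120))) for i in range(6)}
        msa = build_msa(prots)
        for sid, seq in prots.items():
            assert msa.degapped(sid) == seq

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            build_msa({"only": "MKVLLA"})


class TestJttDistance:
    def test_identical_rows_zero(self):
        assert jtt_distance("ACDEFGHIKLMNPQRSTVWYACDEFGHIKL", "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL") == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        anc = simulate_jtt_sequence(300, rng)
        der = evolve_jtt(anc, 0.4, rng)
        a, b = decode_aa(anc), decode_aa(der)
        assert jtt_distance(a, b) == pytest.approx(jtt_distance(b, a))

    @pytest.mark.parametrize("t_true", [0.2, 0.5, 1.0])
    def test_simulation_recovery(self, t_true):
        rng = np.random.default_rng(42)
        anc = simulate_jtt_sequence(10_000, rng)
        der = evolve_jtt(anc, t_true, rng)
        d = jtt_distance(decode_aa(anc), decode_aa(der))
        assert abs(d - t_true) <= 0.1 * t_true

    def test_gamma_distance_exceeds_plain_on_divergent_pair(self):
        rng = np.random.default_rng(7)
        anc = simulate_jtt_sequence(5000, rng)
        der = evolve_jtt(anc, 1.0, rng)
        plain = jtt_distance(decode_aa(anc), decode_aa(der))
        gamma = jtt_distance(decode_aa(anc), decode_aa(der), alpha=0.5)
        assert gamma > plain  # rate heterogeneity implies more hidden change

    def test_pairwise_deletion_of_gap_columns(self):
        a = "ACDEFGHIKL" * 10
        b = "-" * 5 + a[5:]
        assert jtt_distance(a, b) == 0.0


class TestTreesAndPairs:
    def test_nj_recovers_four_taxon_additive_topology(self):
        labels = ["a", "b", "c", "d"]
        # ((a,b),(c,d)) with internal branch 2
        D = np.array(
            [[0, 3, 7, 9], [3, 0, 8, 10], [7, 8, 0, 6], [9, 10, 6, 0]], dtype=float
        )
        t = nj_tree(D, labels)
        tns = t.taxon_namespace
        t.encode_bipartitions()
        splits = {frozenset(l.taxon.label for l in e.head_node.leaf_iter())
                  for e in t.preorder_edge_iter() if e.head_node.parent_node}
        assert frozenset({"a", "b"}) in splits or frozenset({"c", "d"}) in splits

    def test_bootstrap_support_determinism(self):
        prots, smap, pairs, og = simulate_ortholog_family(n_ancestors=4, seed=11)
        msa = build_msa(prots)
        t1 = build_tree(msa, "IR", n_bootstrap=30, seed=5, outgroup=[og])
        t2 = build_tree(msa, "IR", n_bootstrap=30, seed=5, outgroup=[og])
        assert t1.supports == t2.supports

    def test_true_bipartitions_recovered_with_high_support(self):
        """Sequences simulated on a known topology with long internal
        branches: every true species cherry comes back supported."""
        prots, smap, pairs, og = simulate_ortholog_family(n_ancestors=8, seed=2)
        msa = build_msa(prots)
        pt = build_tree(msa, "IR", n_bootstrap=40, seed=3, outgroup=[og])
        for a, b in pairs:
            key = frozenset({a, b})
            assert key in pt.supports
            assert pt.supports[key] >= 75

    def test_sister_pair_rule(self):
        nwk = "((A1:1,B1:1):1,((A2:1,B2:1):1,(A3:1,A4:1):1):1);"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        from chemoscan.phylo import PhyloTree

        pt = PhyloTree(tree=tree, rooted=True)
        smap = {"A1": "A", "A2": "A", "A3": "A", "A4": "A", "B1": "B", "B2": "B"}
        got = {(p.gene_a, p.gene_b) for p in find_ortholog_pairs(pt, smap, focal=("A", "B"))}
        assert got == {("A1", "B1"), ("A2", "B2")}  # (A3,A4) is same-species

    def test_unrooted_tree_rejected_for_pairing(self):
        from chemoscan.phylo import PhyloTree

        tree = dendropy.Tree.get(data="((A1:1,B1:1):1,A2:1,B2:1);", schema="newick")
        pt = PhyloTree(tree=tree, rooted=False)
        with pytest.raises(ValueError, match="rooted"):
            find_ortholog_pairs(pt, {"A1": "A", "B1": "B", "A2": "A", "B2": "B"})

    def test_each_gene_in_at_most_one_pair(self):
        prots, smap, pairs, og = simulate_ortholog_family(seed=9)
        msa = build_msa(prots)
        pt = build_tree(msa, "IR", n_bootstrap=20, seed=1, outgroup=[og])
        got = find_ortholog_pairs(pt, smap, focal=("spA", "spB"))
        genes = [g for p in got for g in (p.gene_a, p.gene_b)]
        assert len(genes) == len(set(genes))
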