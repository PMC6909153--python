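"""Alignment, p-distance, Fitch parsimony and tree search.

The Fitch implementation is checked against a brute-force oracle that
enumerates every internal-state assignment; the hill-climbing search is
checked against exhaustive topology enumeration; neighbor joining is
checked on exactly additive distance matrices.
"""
import itertools

import numpy as np
import pytest

from cnidopep import phylo
from cnidopep.phylo import (Alignment, PhyloError, PhyloTree, best_tree,
                            make_tree, nj_from_matrix, p_distance,
                            parse_newick, parsimony_score, progressive_align)


# ---------------------------------------------------------------- oracles

def _edges(tree: PhyloTree):
    """Edge list of the unrooted tree; internal nodes numbered."""
    edges = []
    counter = itertools.count()

    def walk(node):
        if isinstance(node, str):
            return node
        nid = f"#{next(counter)}"
        for child in node:
            edges.append((nid, walk(child)))
        return nid

    root = walk(tree.subtree)
    edges.append((root, tree.anchor))
    return edges


def fitch_oracle(tree: PhyloTree, alignment: Alignment) -> int:
    """Minimum changes by enumerating all internal-node state assignments."""
    edges = _edges(tree)
    internal = sorted({n for e in edges for n in e if n.startswith("#")})
    leaf_seq = dict(alignment.rows)
    total = 0
    for col in range(alignment.length):
        states = sorted({seq[col] for seq in leaf_seq.values()})
        best = None
        for assign in itertools.product(states, repeat=len(internal)):
            lookup = dict(zip(internal, assign))
            cost = 0
            for a, b in edges:
                sa = lookup[a] if a in lookup else leaf_seq[a][col]
                sb = lookup[b] if b in lookup else leaf_seq[b][col]
                cost += sa != sb
            best = cost if best is None else min(best, cost)
        total += best
    return total


# ------------------------------------------------------------- alignment

class TestProgressiveAlign:
    def test_identical_sequences_gap_free(self):
        aln = progressive_align([("a", "MKTAYIAK"), ("b", "MKTAYIAK")])
        assert aln.rows == (("a", "MKTAYIAK"), ("b", "MKTAYIAK"))

    def test_single_gap_leftmost_placement(self):
        aln = progressive_align([("a", "ACDE"), ("b", "ACE")])
        assert dict(aln.rows) == {"a": "ACDE", "b": "AC-E"}

    def test_ungapping_returns_inputs(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = [(f"s{i}", "".join(rng.choice(aas, size=int(rng.integers(20, 40)))))
                for i in range(5)]
        aln = progressive_align(seqs)
        for name, gapped in aln.rows:
            assert gapped.replace("-", "") == dict(seqs)[name]

    def test_input_order_does_not_change_taxa(self):
        seqs = [("a", "MKTAYIAK"), ("b", "MKTAYIV"), ("c", "MKTWYIAK")]
        a1 = progressive_align(seqs)
        a2 = progressive_align(seqs[::-1])
        assert sorted(a1.taxa) == sorted(a2.taxa)

    def test_single_sequence_errors(self):
        with pytest.raises(PhyloError):
            progressive_align([("a", "MKT")])


class TestPDistance:
    def test_identical_rows_zero(self):
        aln = Alignment(rows=(("a", "MKTA"), ("b", "MKTA")))
        _, m = p_distance(aln)
        assert m[0][1] == 0.0

    def test_hand_counts(self):
        aln = Alignment(rows=(("a", "AAAA"), ("b", "AATT")))
        _, m = p_distance(aln)
        assert m[0][1] == 0.5

    def test_pairwise_deletion_skips_gap_columns(self):
        aln = Alignment(rows=(("a", "AA--"), ("b", "AATT")))
        _, m = p_distance(aln)
        assert m[0][1] == 0.0

    def test_complete_deletion(self):
        aln = Alignment(rows=(("a", "AA-A"), ("b", "ATTA"), ("c", "ATAA")))
        _, m = p_distance(aln, deletion_mode="complete")
        assert m[0][1] == pytest.approx(1 / 3)

    def test_no_comparable_sites_errors(self):
        aln = Alignment(rows=(("a", "AA--"), ("b", "--TT")))
        with pytest.raises(PhyloError, match="a.*b|b.*a"):
            p_distance(aln)

    def test_bounds(self, rng):
        rows = tuple((f"t{i}", "".join(rng.choice(list("ACDE-"), size=30)))
                     for i in range(4))
        try:
            _, m = p_distance(Alignment(rows=rows))
        except PhyloError:
            return
        assert (m >= 0).all() and (m <= 1).all()


class TestFitch:
    def test_all_identical_columns_zero(self):
        aln = Alignment(rows=tuple((f"t{i}", "AAA") for i in range(4)))
        tree = make_tree((("t0", "t1"), ("t2", "t3")))
        assert parsimony_score(tree, aln) == 0

    def test_hand_example_two_topologies(self):
        aln = Alignment(rows=(("t1", "A"), ("t2", "A"), ("t3", "C"), ("t4", "C")))
        assert parsimony_score(make_tree((("t1", "t2"), ("t3", "t4"))), aln) == 1
        assert parsimony_score(make_tree((("t1", "t3"), ("t2", "t4"))), aln) == 2

    def test_score_invariant_under_rerooting(self):
        aln = Alignment(rows=(("t1", "ACD"), ("t2", "ACE"), ("t3", "QCD"),
                              ("t4", "QWE"), ("t5", "AWD")))
        base = make_tree((("t1", "t2"), (("t3", "t4"), "t5")))
        s0 = parsimony_score(base, aln)
        for og in aln.taxa:
            rerooted = parse_newick(phylo.reroot_newick(base, og))
            assert parsimony_score(rerooted, aln) == s0

    def test_matches_state_enumeration_oracle(self, rng):
        # random 6-leaf trees, <= 4 states
        taxa = [f"t{i}" for i in range(6)]
        for rep in range(10):
            rows = tuple((t, "".join(rng.choice(list("ACGT"), size=8)))
                         for t in taxa)
            aln = Alignment(rows=rows)
            subs = list(phylo.enumerate_subtrees(taxa[1:]))
            sub = subs[int(rng.integers(len(subs)))]
            tree = PhyloTree(anchor=taxa[0], subtree=sub)
            assert parsimony_score(tree, aln) == fitch_oracle(tree, aln)

    def test_gap_state_vs_missing_mode(self):
        aln = Alignment(rows=(("t1", "A-"), ("t2", "A-"), ("t3", "AC"),
                              ("t4", "AC")))
        tree = make_tree((("t1", "t2"), ("t3", "t4")))
        assert parsimony_score(tree, aln, gap_mode="state") == 1
        assert parsimony_score(tree, aln, gap_mode="missing") == 0

    def test_mismatched_taxa_error(self):
        aln = Alignment(rows=(("a", "A"), ("b", "A")))
        with pytest.raises(PhyloError):
            parsimony_score(make_tree((("a", "b"), ("c", "d"))), aln)


class TestNewick:
    def test_roundtrip_byte_stable(self):
        tree = make_tree((("beta", "alpha"), (("delta", "epsilon"), "gamma")))
        nwk = tree.newick()
        assert parse_newick(nwk).newick() == nwk

    def test_children_sorted_by_smallest_descendant(self):
        t1 = make_tree((("b", "a"), ("d", "c")))
        t2 = make_tree((("c", "d"), ("a", "b")))
        assert t1.newick() == t2.newick()

    def test_branch_lengths_and_quotes_ignored(self):
        t = parse_newick("(('a b':0.1,c:0.2):0.05,(d:0.3,e:0.1):0.2,f:0.4);")
        assert sorted(t.taxa) == ["a b", "c", "d", "e", "f"]


class TestTreeSearch:
    def test_topology_counts(self):
        for n, expect in [(5, 15), (6, 105), (7, 945)]:
            taxa = [f"t{i}" for i in range(n - 1)]
            assert sum(1 for _ in phylo.enumerate_subtrees(taxa)) == expect

    def test_hill_climb_equals_exhaustive(self, rng):
        for rep in range(10):
            rows = tuple((f"t{i}", "".join(rng.choice(list("ACDEF"), size=30)))
                         for i in range(7))
            aln = Alignment(rows=rows)
            ex = best_tree(aln, method="parsimony", max_exhaustive=8)
            hc = best_tree(aln, method="parsimony", max_exhaustive=4, seed=1)
            assert hc.parsimony_score == ex.parsimony_score

    def test_nj_recovers_additive_topology(self, rng):
        # random binary tree with random positive branch lengths -> additive
        taxa = [f"t{i}" for i in range(6)]
        subs = list(phylo.enumerate_subtrees(taxa[1:]))
        sub = subs[int(rng.integers(len(subs)))]
        truth = PhyloTree(anchor=taxa[0], subtree=sub)
        dist = _additive_matrix(truth, rng)
        got = nj_from_matrix(taxa, dist)
        assert got.splits() == truth.splits()

    def test_too_few_taxa_errors(self):
        aln = Alignment(rows=(("a", "ACD"), ("b", "ACE")))
        with pytest.raises(PhyloError):
            best_tree(aln)


def _additive_matrix(tree: PhyloTree, rng) -> np.ndarray:
    edges = _edges(tree)
    lengths = {tuple(sorted(e)): float(rng.uniform(0.5, 2.0)) for e in edges}
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    taxa = sorted(tree.taxa)
    n = len(taxa)
    mat = np.zeros((n, n))

    def path_len(src, dst):
        stack = [(src, None, 0.0)]
        while stack:
            node, parent, acc = stack.pop()
            if node == dst:
                return acc
            for nb in adj[node]:
                if nb != parent:
                    stack.append((nb, node, acc + lengths[tuple(sorted((node, nb)))]))
        raise AssertionError("disconnected tree")

    for i in range(n):
        for j in range(i + 1, n):
            mat[i][j] = mat[j][i] = path_len(taxa[i], taxa[j])
    return mat
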