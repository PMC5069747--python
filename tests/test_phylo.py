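"""Alignment, distance models, neighbor-joining and bootstrap contracts."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from puctools import phylo
from puctools.io import SeqRecord, write_newick
from puctools.phylo import (
    DistanceMatrix,
    MultipleAlignment,
    align_codons,
    bootstrap,
    neighbor_joining,
    pairwise_distance,
)


def _dm(ids, matrix):
    m = np.asarray(matrix, float)
    return DistanceMatrix(list(ids), m, np.full_like(m, 100, dtype=np.int64),
                          np.zeros_like(m, dtype=bool))


def _mutate(seq, k, rng):
    s = list(seq)
    for pos in rng.choice(len(s), size=k, replace=False):
        s[pos] = rng.choice([b for b in "ACGT" if b != s[pos]])
    return "".join(s)


class TestAlignCodons:
    def test_identical_pair_is_gapless(self):
        rec = SeqRecord("a", "", "ATGAAACCCGGGTAA")
        msa = align_codons([rec, SeqRecord("b", "", rec.sequence)])
        assert msa.rows[0] == msa.rows[1] == rec.sequence

    def test_single_codon_deletion_gives_one_codon_gap(self):
        a = "ATGAAACCCGGGTTTTAA"
        b = "ATGAAAGGGTTTTAA"  # CCC codon deleted
        msa = align_codons([SeqRecord("a", "", a), SeqRecord("b", "", b)])
        # oracle: exhaustive codon-unit alignment of this pair has a unique
        # optimum with one gap opposite the CCC codon
        assert msa.rows[0] == a
        assert msa.rows[1] == "ATGAAA---GGGTTTTAA"
        assert msa.rows[1].replace("-", "") == b  # ungapping recovers input

    def test_gaps_only_in_whole_codon_units(self):
        rng = np.random.default_rng(3)
        base = "".join(rng.choice(list("ACGT"), 60))
        variants = [base, base[:21] + base[24:], _mutate(base, 5, rng)]
        msa = align_codons([SeqRecord(f"s{i}", "", s) for i, s in enumerate(variants)])
        for row in msa.rows:
            for i in range(0, msa.ncol, 3):
                codon = row[i:i + 3]
                assert codon == "---" or "-" not in codon

    def test_realignment_of_ungapped_rows_is_idempotent(self):
        rng = np.random.default_rng(4)
        base = "".join(rng.choice(list("ACGT"), 90))
        recs = [SeqRecord("a", "", base), SeqRecord("b", "", _mutate(base, 6, rng)),
                SeqRecord("c", "", base[:30] + base[33:])]
        msa1 = align_codons(recs)
        msa2 = align_codons([SeqRecord(i, "", msa1.ungapped(k))
                             for k, i in enumerate(msa1.ids)])
        assert msa1.ncol == msa2.ncol

    def test_fewer_than_two_sequences_is_an_error(self):
        with pytest.raises(ValueError):
            align_codons([SeqRecord("a", "", "ATGTAA")])


class TestDistances:
    def test_identical_pair_is_zero_under_every_model(self):
        msa = MultipleAlignment(["a", "b"], ["ACGTACGTACGT", "ACGTACGTACGT"])
        for model in ("JC69", "TN93", "MCL"):
            dm = pairwise_distance(msa, model)
            assert dm.matrix[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_jc69_matches_closed_form(self):
        # 2 differences over 20 sites -> p = 0.1
        a = "ACGTACGTACGTACGTACGT"
        b = "ACGTACGTACGTACGTACAA"
        dm = pairwise_distance(MultipleAlignment(["a", "b"], [a, b]), "JC69")
        expected = -0.75 * math.log(1 - 4 * 0.1 / 3)
        assert dm.matrix[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_pairwise_deletion_drops_ambiguous_columns(self):
        a = "ACGTNCGTAC"
        b = "AC-TGCGTAA"
        # columns 2 (gap in b) and 4 (N in a) are deleted for this pair
        dm = pairwise_distance(MultipleAlignment(["a", "b"], [a, b]), "JC69")
        assert dm.usable_sites[0, 1] == 8
        p = 1 / 8
        assert dm.matrix[0, 1] == pytest.approx(-0.75 * math.log(1 - 4 * p / 3))

    def test_saturation_is_flagged_not_raised(self):
        a = "A" * 40
        b = "C" * 40
        dm = pairwise_distance(MultipleAlignment(["a", "b"], [a, b]), "JC69")
        assert dm.saturated[0, 1]
        assert dm.saturated_pairs() == [("a", "b")]

    def test_tn93_expected_proportions_match_matrix_exponential(self):
        g = np.array([0.3, 0.2, 0.25, 0.25])
        k1, k2 = 3.0, 1.5
        Q = np.zeros((4, 4))
        for i, j in itertools.permutations(range(4), 2):
            rate = k1 if {i, j} == {0, 2} else (k2 if {i, j} == {1, 3} else 1.0)
            Q[i, j] = rate * g[j]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.sum(g * np.diag(Q))
        for d in (0.05, 0.3, 1.0):
            P = expm(Q * d / mu)
            joint = g[:, None] * P
            oracle = (joint[0, 2] + joint[2, 0], joint[1, 3] + joint[3, 1],
                      1 - joint.trace() - joint[0, 2] - joint[2, 0]
                      - joint[1, 3] - joint[3, 1])
            mine = phylo.tn93_expected_proportions(d, k1, k2, g)
            assert np.allclose(mine, oracle, atol=1e-12)

    def test_tn93_closed_form_inverts_the_model(self):
        g = np.array([0.3, 0.2, 0.25, 0.25])
        for d in (0.05, 0.4, 1.2):
            P1, P2, Q = phylo.tn93_expected_proportions(d, 2.5, 1.3, g)
            assert phylo._tn93_closed_form(P1, P2, Q, g) == pytest.approx(d, abs=1e-9)

    def test_mcl_agrees_with_jc69_on_equal_rate_data(self):
        rng = np.random.default_rng(1)
        base = "".join(rng.choice(list("ACGT"), 600))
        seqs = [base, _mutate(base, 25, rng), _mutate(base, 40, rng),
                _mutate(base, 55, rng)]
        msa = MultipleAlignment(list("abcd"), seqs)
        d_jc = pairwise_distance(msa, "JC69").matrix
        d_mcl = pairwise_distance(msa, "MCL").matrix
        assert np.allclose(d_jc, d_mcl, atol=0.01)

    def test_monotone_in_observed_divergence(self):
        base = "ACGT" * 50
        rng = np.random.default_rng(7)
        prev = {m: 0.0 for m in ("JC69", "TN93", "MCL")}
        for k in (5, 15, 30):
            msa = MultipleAlignment(["a", "b"], [base, _mutate(base, k, rng)])
            for model in prev:
                d = pairwise_distance(msa, model).matrix[0, 1]
                assert d > prev[model]
                prev[model] = d


def least_squares_fit_4taxa(D, split):
    """Least-squares branch lengths for a 4-taxon topology; returns SSE.

    split = ((i, j), (k, l)): cherries on either side of the internal edge.
    Branch vector: [b_i, b_j, b_k, b_l, b_mid].
    """
    (i, j), (k, l) = split
    pairs = list(itertools.combinations(range(4), 2))
    A = np.zeros((6, 5))
    y = np.zeros(6)
    pos = {i: 0, j: 1, k: 2, l: 3}
    for row, (p, q) in enumerate(pairs):
        A[row, pos[p]] = 1
        A[row, pos[q]] = 1
        same_side = {p, q} in ({i, j}, {k, l})
        if not same_side:
            A[row, 4] = 1
        y[row] = D[p, q]
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef, float(np.sum((A @ coef - y) ** 2))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = [[0, 3, 4], [3, 0, 5], [4, 5, 0]]
        tree = neighbor_joining(_dm("ABC", D))
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # tree ((A:2,B:3):1,(C:4,D:5)); oracle: enumerate all 3 topologies
        # with least squares and confirm the same winner and branch lengths
        D = np.array([[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]],
                     float)
        splits = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
        fits = [least_squares_fit_4taxa(D, s) for s in splits]
        best = min(range(3), key=lambda i: fits[i][1])
        assert best == 0 and fits[0][1] == pytest.approx(0.0, abs=1e-18)
        tree = neighbor_joining(_dm("ABCD", D))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        coef = fits[0][0]
        leaf_len = {}

        def collect(node):
            for child in node.children:
                if child.is_leaf:
                    leaf_len[child.name] = child.length
                collect(child)

        collect(tree.root)
        assert leaf_len == pytest.approx(
            {"A": coef[0], "B": coef[1], "C": coef[2], "D": coef[3]})

    def test_random_additive_matrices_recover_topology_up_to_8_taxa(self):
        rng = np.random.default_rng(12)
        for n in (5, 6, 8):
            tree_true, D = _random_additive(n, rng)
            tree = neighbor_joining(_dm([f"t{i}" for i in range(n)], D))
            assert tree.bipartitions() == tree_true

    def test_matches_scikit_bio_on_random_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        true_parts, D = _random_additive(6, rng)
        ids = [f"t{i}" for i in range(6)]
        mine = neighbor_joining(_dm(ids, D))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D, ids))
        their_parts = set()
        for node in theirs.non_tips(include_self=False):
            tips = frozenset(t.name for t in node.tips())
            if 1 < len(tips) < 5:
                anchor = min(ids)
                side = tips if anchor not in tips else frozenset(ids) - tips
                their_parts.add(frozenset(side))
        assert mine.bipartitions() == their_parts

    def test_taxon_order_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(3)
        _, D = _random_additive(6, rng)
        ids = [f"t{i}" for i in range(6)]
        tree1 = neighbor_joining(_dm(ids, D))
        perm = rng.permutation(6)
        D2 = D[np.ix_(perm, perm)]
        tree2 = neighbor_joining(_dm([ids[i] for i in perm], D2))
        assert tree1.bipartitions() == tree2.bipartitions()
        assert tree1.total_branch_length() == pytest.approx(
            tree2.total_branch_length())

    def test_negative_branches_clamped_without_losing_path_length(self):
        # slightly non-additive matrix that forces a negative NJ estimate
        D = np.array([[0, 0.1, 1, 1], [0.1, 0, 1, 1],
                      [1, 1, 0, 0.01], [1, 1, 0.01, 0]], float)
        tree = neighbor_joining(_dm("ABCD", D))
        lengths = []

        def walk(node):
            for child in node.children:
                lengths.append(child.length)
                walk(child)

        walk(tree.root)
        assert all(l >= 0 for l in lengths)

    def test_small_or_saturated_inputs_error(self):
        with pytest.raises(ValueError):
            neighbor_joining(_dm("AB", [[0, 1], [1, 0]]))
        dm = _dm("ABC", [[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        dm.saturated[0, 1] = dm.saturated[1, 0] = True
        with pytest.raises(phylo.SaturationError, match="A-B"):
            neighbor_joining(dm)


def _random_additive(n, rng):
    """Random binary tree on n taxa -> (bipartition set, additive matrix)."""
    nodes = [phylo.Node(name=f"t{i}", length=float(rng.uniform(0.05, 0.5)))
             for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        merged = phylo.Node(children=[nodes[i], nodes[j]],
                            length=float(rng.uniform(0.05, 0.5)))
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [merged]
    tree = phylo.Tree(phylo.Node(children=nodes))
    ids = sorted(tree.leaf_names(), key=lambda s: int(s[1:]))
    # path-length matrix by brute force over leaf-to-root edge lists
    edges = {}

    def collect(node, acc):
        if node.is_leaf:
            edges[node.name] = acc
        for child in node.children:
            collect(child, acc + [(id(child), child.length)])

    collect(tree.root, [])
    D = np.zeros((n, n))
    for a, b in itertools.combinations(range(n), 2):
        ea, eb = edges[ids[a]], edges[ids[b]]
        sa = {e[0]: e[1] for e in ea}
        sb = {e[0]: e[1] for e in eb}
        shared = set(sa) & set(sb)
        d = sum(v for k, v in sa.items() if k not in shared) + \
            sum(v for k, v in sb.items() if k not in shared)
        D[a, b] = D[b, a] = d
    return tree.bipartitions(), D


class TestBootstrap:
    def _signal_msa(self):
        # every column is either constant or carries the same (a,b)|(c,d)
        # split signal, so each replicate supports that split
        rng = np.random.default_rng(6)
        base = "".join(rng.choice(list("ACGT"), 60))
        other = _mutate(base, 18, rng)
        return MultipleAlignment(list("abcd"), [base, base, other, other])

    def test_clean_split_gets_full_support(self):
        msa = self._signal_msa()
        supports = bootstrap(msa, replicates=50, seed=1, model="JC69")
        assert supports[frozenset({"c", "d"})] == 100.0

    def test_fixed_seed_is_bit_reproducible(self):
        msa = self._signal_msa()
        s1 = bootstrap(msa, replicates=40, seed=9, model="JC69")
        s2 = bootstrap(msa, replicates=40, seed=9, model="JC69")
        assert s1 == s2

    def test_supports_stable_across_replicate_counts(self):
        rng = np.random.default_rng(0)
        base = "".join(rng.choice(list("ACGT"), 120))
        rows = [base, _mutate(base, 4, rng), _mutate(base, 14, rng),
                _mutate(base, 16, rng)]
        msa = MultipleAlignment(list("abcd"), rows)
        s_small = bootstrap(msa, 100, seed=2, model="JC69")
        s_big = bootstrap(msa, 400, seed=3, model="JC69")
        for part, val in s_big.items():
            # binomial sampling error at n=100: ~3 sigma
            p = val / 100
            sigma = 100 * math.sqrt(max(p * (1 - p), 1e-4) / 100)
            assert abs(s_small[part] - val) <= 3.5 * sigma + 1.0

    def test_newick_round_trip_through_scikit_bio(self, tmp_path):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(8)
        _, D = _random_additive(5, rng)
        ids = [f"t{i}" for i in range(5)]
        tree = neighbor_joining(_dm(ids, D))
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        parsed = skbio.TreeNode.read(str(path))
        total = sum(n.length or 0 for n in parsed.traverse())
        assert total == pytest.approx(tree.total_branch_length(), abs=1e-9)
        assert sorted(t.name for t in parsed.tips()) == ids
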