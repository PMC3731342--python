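import warnings

import dendropy
import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from caprachron import phylo
from caprachron.alignio import NucAlignment
from caprachron.errors import UsageError
from caprachron.phylo import (
    DistanceMatrix,
    HaplogroupAssignment,
    assign_haplogroups,
    bootstrap_support,
    categorize_branches,
    k80_gamma_distance,
    nj_tree,
)
from caprachron.tree import PhyloTree


# --------------------------------------------------------------------------
# K80 + gamma distances
# --------------------------------------------------------------------------
class TestK80GammaDistance:
    def test_identical_sequences_zero(self):
        aln = NucAlignment(["a", "b"], ["ACGTACGT", "ACGTACGT"])
        assert k80_gamma_distance(aln, 0.22).values[0, 1] == 0.0

    @pytest.mark.parametrize("d_true,kappa,shape", [(0.1, 4.0, 0.22), (0.4, 8.0, 0.5)])
    def test_inverts_expected_difference_curves(self, d_true, kappa, shape):
        """Independent oracle: compute E[P], E[Q] under gamma-mixed K80 by
        numerical integration, then check the distance formula recovers d."""
        # K80 with transition rate a, transversion rate b (total rate a+2b=1)
        b = 1.0 / (kappa + 2.0)
        a = kappa * b

        def p_trans(t):
            return 0.25 + 0.25 * np.exp(-4 * b * t) - 0.5 * np.exp(-2 * (a + b) * t)

        def q_tranv(t):
            return 0.5 - 0.5 * np.exp(-4 * b * t)

        pdf = gamma_dist(shape, scale=1.0 / shape).pdf
        P = quad(lambda r: p_trans(d_true * r) * pdf(r), 0, np.inf, limit=200)[0]
        Q = quad(lambda r: q_tranv(d_true * r) * pdf(r), 0, np.inf, limit=200)[0]
        w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
        d = (shape / 2) * (w1 ** (-1 / shape) - 1) + (shape / 4) * (
            w2 ** (-1 / shape) - 1
        )
        assert d == pytest.approx(d_true, rel=1e-6)
        # and the implementation agrees with the closed form on count data
        n = 400000
        ts_count = round(P * n)
        tv_count = round(Q * n)
        seq_a = "A" * n
        seq_b = "G" * ts_count + "C" * tv_count + "A" * (n - ts_count - tv_count)
        aln = NucAlignment(["a", "b"], [seq_a, seq_b])
        got = k80_gamma_distance(aln, shape).values[0, 1]
        assert got == pytest.approx(d_true, rel=1e-3)

    def test_transition_class_relabel_invariance(self):
        aln1 = NucAlignment(["a", "b"], ["AAACCCGG", "AGACTCGG"])
        swapped = str.maketrans("AGCT", "GATC")
        aln2 = NucAlignment(["a", "b"], [s.translate(swapped) for s in aln1.seqs])
        d1 = k80_gamma_distance(aln1, 0.22).values[0, 1]
        d2 = k80_gamma_distance(aln2, 0.22).values[0, 1]
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_saturation_flagged(self):
        aln = NucAlignment(["a", "b"], ["AAAAAAAA", "GGGGGGGG"])
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            dm = k80_gamma_distance(aln, 0.22)
        assert np.isnan(dm.values[0, 1]) and ("a", "b") in dm.undefined
        assert any("saturated" in str(w.message) for w in rec)


# --------------------------------------------------------------------------
# neighbor joining
# --------------------------------------------------------------------------
def tree_distances(tree: PhyloTree):
    """Leaf-to-leaf path lengths."""
    names = tree.leaf_names()
    dist = {}
    for leaf in tree.leaves():
        depth = {}
        node, acc = leaf, 0.0
        while node is not None:
            depth[id(node)] = acc
            acc += node.length or 0.0
            node = node.parent
        dist[leaf.name] = depth
    out = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i >= j:
                continue
            mrca = tree.mrca([a, b])
            da = dist[a][id(mrca)] if id(mrca) in dist[a] else None
            db = dist[b][id(mrca)]
            out[i, j] = out[j, i] = da + db
    return names, out


class TestNeighborJoining:
    def test_three_taxa_three_point_solution(self):
        dm = DistanceMatrix(["a", "b", "c"], np.array(
            [[0, 0.3, 0.5], [0.3, 0, 0.4], [0.5, 0.4, 0]]))
        tree = nj_tree(dm)
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths["a"] == pytest.approx(0.2)
        assert lengths["b"] == pytest.approx(0.1)
        assert lengths["c"] == pytest.approx(0.3)

    def test_additive_four_taxon_roundtrip(self):
        # ((a:0.1,b:0.2):0.05,c:0.3,d:0.4) additive matrix
        t = PhyloTree.from_newick("((a:0.1,b:0.2):0.05,c:0.3,d:0.4);")
        names, mat = tree_distances(t)
        rebuilt = nj_tree(DistanceMatrix(names, mat))
        names2, mat2 = tree_distances(rebuilt)
        order = [names2.index(n) for n in names]
        assert np.allclose(mat2[np.ix_(order, order)], mat, atol=1e-12)

    def test_deterministic_under_ties(self):
        d = np.array(
            [[0, 2, 4, 4, 4],
             [2, 0, 4, 4, 4],
             [4, 4, 0, 2, 4],
             [4, 4, 2, 0, 4],
             [4, 4, 4, 4, 0]], dtype=float)
        dm = DistanceMatrix(list("abcde"), d)
        assert nj_tree(dm).to_newick() == nj_tree(dm).to_newick()

    def test_matches_dendropy_topology_on_additive_matrix(self):
        rng = np.random.default_rng(5)
        t = PhyloTree.from_newick(
            "(((a:0.11,b:0.23):0.07,(c:0.31,d:0.05):0.09):0.13,(e:0.2,f:0.1):0.04,g:0.4);"
        )
        names, mat = tree_distances(t)
        ours = nj_tree(DistanceMatrix(names, mat))
        # independent implementation: dendropy's NJ on the same matrix
        csv = "," + ",".join(names) + "\n"
        for i, nm in enumerate(names):
            csv += nm + "," + ",".join(f"{x:.10f}" for x in mat[i]) + "\n"
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), delimiter=",")
        theirs = PhyloTree._from_dendropy(pdm.nj_tree())
        assert ours.bipartitions() == theirs.bipartitions()

    def test_too_few_sequences(self):
        with pytest.raises(UsageError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------
def _mutate(seq, positions, rng):
    arr = np.array(list(seq))
    for p in positions:
        arr[p] = rng.choice([c for c in "ACGT" if c != arr[p]])
    return "".join(arr)


def two_clade_alignment():
    """Two well-separated 3-leaf clades over a shared random background."""
    rng = np.random.default_rng(42)
    L = 200
    base = "".join(rng.choice(list("ACGT"), size=L))
    clade1 = _mutate(base, range(0, 20), rng)
    clade2 = _mutate(base, range(20, 40), rng)
    seqs = [
        _mutate(clade1, [50 + i], rng) for i in range(3)
    ] + [
        _mutate(clade2, [60 + i], rng) for i in range(3)
    ]
    return NucAlignment(list("abcdef"), seqs)


class TestBootstrap:
    def test_strong_signal_high_support(self):
        tree = bootstrap_support(two_clade_alignment(), reps=100, seed=1, shape=1.0)
        clade_support = {
            frozenset(tree.clade_leafset(n)): n.support
            for n in tree.branches() if n.support is not None
        }
        target = [s for c, s in clade_support.items()
                  if c in (frozenset("abc"), frozenset("def"))]
        assert target and min(target) >= 95.0

    def test_single_rep_supports_are_binary(self):
        tree = bootstrap_support(two_clade_alignment(), reps=1, seed=3, shape=1.0)
        for n in tree.branches():
            if n.support is not None:
                assert n.support in (0.0, 100.0)

    def test_same_seed_reproducible_and_leaf_order_invariant(self):
        aln = two_clade_alignment()
        t1 = bootstrap_support(aln, reps=50, seed=7, shape=1.0)
        t2 = bootstrap_support(aln, reps=50, seed=7, shape=1.0)
        collect = lambda t: sorted(
            (tuple(sorted(t.clade_leafset(n))), n.support)
            for n in t.branches() if n.support is not None
        )
        assert collect(t1) == collect(t2)
        perm = NucAlignment(aln.ids[::-1], aln.seqs[::-1])
        t3 = bootstrap_support(perm, reps=50, seed=7, shape=1.0)
        assert collect(t1) == collect(t3)


# --------------------------------------------------------------------------
# haplogroup assignment
# --------------------------------------------------------------------------
def reference_panel():
    """Four haplogroup clusters (12 diagnostic sites each) plus an outgroup,
    with inter-cluster distance far exceeding intra-cluster distance."""
    rng = np.random.default_rng(7)
    L = 240
    ancestral = "".join(rng.choice(list("ACGT"), size=L))
    base = {
        g: _mutate(ancestral, range(12 * k, 12 * (k + 1)), rng)
        for k, g in enumerate("ABCD")
    }
    ids, seqs, meta = [], [], {}
    for g, s in base.items():
        for k in range(2):
            rid = f"ref{g}{k}"
            ids.append(rid)
            seqs.append(_mutate(s, [100 + 10 * k], rng))
            meta[rid] = g
    ids.append("out")
    seqs.append(_mutate(ancestral, range(48, 90), rng))
    meta["out"] = "outgroup"
    return NucAlignment(ids, seqs, meta), base


class TestAssignHaplogroups:
    def test_identical_to_reference(self):
        refs, base = reference_panel()
        query = NucAlignment(["q1"], [base["A"]])
        assert assign_haplogroups(query, refs).labels["q1"] == "A"

    def test_simulated_queries_assigned_correctly(self):
        refs, base = reference_panel()
        rng = np.random.default_rng(2)
        qids, qseqs, truth = [], [], {}
        for g, s in base.items():
            for k in range(5):
                arr = np.array(list(s))
                pos = rng.choice(len(arr), size=2, replace=False)
                arr[pos] = [rng.choice(list("ACGT")) for _ in pos]
                qid = f"q{g}{k}"
                qids.append(qid)
                qseqs.append("".join(arr))
                truth[qid] = g
        got = assign_haplogroups(NucAlignment(qids, qseqs), refs).labels
        correct = sum(got[q] == truth[q] for q in qids)
        assert correct / len(qids) >= 0.95

    def test_empty_query(self):
        refs, _ = reference_panel()
        assert assign_haplogroups(NucAlignment([], []), refs).labels == {}


# --------------------------------------------------------------------------
# branch categorization
# --------------------------------------------------------------------------
def study_topology(n_per_group=(2, 2, 2, 2)):
    nA, nB, nC, nD = n_per_group
    sub = lambda g, n: "(" + ",".join(f"{g}_{i}:0.01" for i in range(n)) + "):0.05" \
        if n > 1 else f"{g}_0:0.06"
    nwk = (f"(({sub('C', nC)},({sub('B', nB)},({sub('D', nD)},"
           f"{sub('A', nA)}):0.04):0.04):0.3,markhor:0.5);")
    labels = {}
    for g, n in zip("ABCD", n_per_group):
        for i in range(n):
            labels[f"{g}_{i}"] = g
    labels["markhor"] = "outgroup"
    return PhyloTree.from_newick(nwk), HaplogroupAssignment(labels)


class TestCategorizeBranches:
    def test_study_topology_six_deep_branches(self):
        tree, hg = study_topology()
        cat = categorize_branches(tree, hg)
        assert cat.counts()["deep"] == 6
        assert cat.deep_tags() == ["a", "b", "c", "d", "x", "y"]

    def test_partition_covers_every_branch(self):
        tree, hg = study_topology((3, 2, 2, 2))
        cat = categorize_branches(tree, hg)
        counts = cat.counts()
        assert sum(counts.values()) == len(cat.tree.branches())

    def test_single_haplogroup_tree(self):
        tree = PhyloTree.from_newick(
            "(((A_0:0.01,A_1:0.01):0.01,A_2:0.02):0.3,markhor:0.5);")
        hg = HaplogroupAssignment(
            {"A_0": "A", "A_1": "A", "A_2": "A", "markhor": "outgroup"})
        cat = categorize_branches(tree, hg)
        counts = cat.counts()
        assert counts["shallow"] == 4 and counts.get("deep", 0) == 0

    def test_singleton_haplogroup_pendant_is_shallow(self):
        tree, hg = study_topology((2, 2, 1, 2))
        cat = categorize_branches(tree, hg)
        key = frozenset(["C_0"])
        assert cat.category[key] == "shallow" and cat.tag[key] == "C"

    def test_non_monophyletic_haplogroup_lists_intruders(self):
        tree = PhyloTree.from_newick(
            "(((A_0:0.01,B_0:0.01):0.01,A_1:0.02):0.3,markhor:0.5);")
        hg = HaplogroupAssignment(
            {"A_0": "A", "A_1": "A", "B_0": "B", "markhor": "outgroup"})
        with pytest.raises(UsageError, match="B_0"):
            categorize_branches(tree, hg)

    def test_simulated_fixture_is_consistent(self, small_fixture):
        counts = small_fixture.categories.counts()
        assert counts["deep"] == 6
        assert counts["interspecies"] == 2
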