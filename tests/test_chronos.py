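import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from caprachron import chronos
from caprachron.alignio import NucAlignment
from caprachron.chronos import (
    StrictClockModel,
    clock_test,
    date_tree,
    discrete_gamma_rates,
    fit_gtr_gamma,
    gtr_rate_matrix,
    rate_from_calibrated_node,
)
from caprachron.errors import UsageError
from caprachron.simgen import (
    EvolveConfig,
    evolve_sequences,
    simulate_genealogy,
    study_demography,
)
from caprachron.tree import PhyloTree


class TestDiscreteGamma:
    def test_category_means_average_to_one(self):
        for shape in (0.1, 0.5, 1.0, 5.0):
            rates = discrete_gamma_rates(shape, 4)
            assert rates.mean() == pytest.approx(1.0, abs=1e-10)
            assert np.all(np.diff(rates) > 0)

    def test_large_shape_recovers_homogeneity(self):
        rates = discrete_gamma_rates(150.0, 4)
        assert np.allclose(rates, 1.0, atol=0.12)


class TestGTRMatrix:
    def test_detailed_balance_and_scaling(self):
        rng = np.random.default_rng(4)
        pi = rng.dirichlet(np.ones(4))
        exch = rng.uniform(0.5, 5.0, 5)
        q = gtr_rate_matrix(exch, pi)
        flux = pi[:, None] * q
        assert np.allclose(flux, flux.T, atol=1e-14)
        assert -float(pi @ np.diag(q)) == pytest.approx(1.0)


def brute_force_gtr_gamma(aln, tree, exch, shape, t, pi, n_cat=4):
    """Exhaustive enumeration over internal states and gamma categories."""
    q = gtr_rate_matrix(exch, pi)
    rates = discrete_gamma_rates(shape, n_cat)
    post = tree.postorder()
    internal = [n for n in post if not n.is_leaf]
    code = {c: i for i, c in enumerate("ACGT")}
    branch_index = {}
    bi = 0
    for n in post:
        if n.parent is not None:
            branch_index[id(n)] = bi
            bi += 1
    lnl = 0.0
    for col in range(aln.length):
        total = 0.0
        for r in rates:
            P = {id(n): expm(q * t[branch_index[id(n)]] * r)
                 for n in post if n.parent is not None}
            for assign in itertools.product(range(4), repeat=len(internal)):
                st = {id(n): s for n, s in zip(internal, assign)}
                term = pi[st[id(tree.root)]]
                for n in post:
                    if n.parent is None:
                        continue
                    sp = st[id(n.parent)]
                    if n.is_leaf:
                        ch = aln.seqs[aln.ids.index(n.name)][col]
                        if ch not in code:
                            term *= 1.0
                            continue
                        sc = code[ch]
                    else:
                        sc = st[id(n)]
                    term *= P[id(n)][sp, sc]
                total += term / len(rates)
        lnl += np.log(total)
    return lnl


class TestNucLikelihood:
    def test_pruning_equals_enumeration_three_taxa(self):
        tree = PhyloTree.from_newick("((a:0.1,b:0.3):0.2,c:0.4);")
        aln = NucAlignment(["a", "b", "c"], ["ACGTTAGA", "ACCTTAGG", "GCGTTANA"])
        model = StrictClockModel(aln, tree)
        eng = model.engine
        exch = np.array([1.5, 4.0, 0.7, 1.2, 6.0])
        t = eng.t0
        got = eng.loglik(exch, 0.5, t)
        want = brute_force_gtr_gamma(aln, eng.tree, exch, 0.5, t, eng.pi)
        assert got == pytest.approx(want, abs=1e-8)

    def test_degenerate_alignment_rejected(self):
        tree = PhyloTree.from_newick("((a:0.1,b:0.3):0.2,c:0.4);")
        aln = NucAlignment(["a", "b", "c"], ["ACGT", "ACGT", "ACGT"])
        with pytest.raises(UsageError, match="no variation"):
            StrictClockModel(aln, tree)


@pytest.fixture(scope="module")
def clock_data():
    demo = study_demography({"A": 5, "B": 4, "C": 2, "D": 2})
    tree, _ = simulate_genealogy(demo, seed=8)
    aln = evolve_sequences(
        tree, EvolveConfig(model="gtr-gamma", length=900, rate=1.4e-8, shape=0.4),
        seed=9)
    return tree, aln


class TestClockAndDating:
    def test_jc_simulation_recovers_near_equal_exchangeabilities(self):
        tree = PhyloTree.from_newick(
            "(((a:0.05,b:0.05):0.05,(c:0.05,d:0.05):0.05):0.05,e:0.1);")
        cfg = EvolveConfig(model="gtr-gamma", length=4000, rate=1.0,
                           shape=100.0, pi_nuc=np.full(4, 0.25),
                           exch=np.ones(5))
        aln = evolve_sequences(tree, cfg, seed=13)
        fit = fit_gtr_gamma(aln, tree)
        assert np.all(fit.exch > 0.55) and np.all(fit.exch < 1.8)

    def test_clock_not_rejected_on_clock_data(self, clock_data):
        tree, aln = clock_data
        ct = clock_test(aln, tree, maxiter=300)
        assert ct.lnL_free >= ct.lnL_clock - 1e-6
        assert ct.df == len(aln.ids) - 2
        assert ct.p > 0.05

    def test_rate_accelerated_lineage_rejected(self):
        demo = study_demography({"A": 4, "B": 3, "C": 2, "D": 2})
        rejected = 0
        for seed in range(3):
            tree, _ = simulate_genealogy(demo, seed=50 + seed)
            # 5x acceleration of the haplogroup-C stem lineage (an internal
            # branch; a root-adjacent pendant would be absorbed by the clock)
            c_leaves = {n.name for n in tree.leaves() if n.name.startswith("C_")}
            stem = tree.mrca(c_leaves)
            stem.length *= 5.0
            aln = evolve_sequences(
                tree, EvolveConfig(model="gtr-gamma", length=900,
                                   rate=1.4e-8, shape=0.4), seed=60 + seed)
            ct = clock_test(aln, tree, maxiter=300)
            rejected += ct.p < 0.05
        assert rejected >= 2

    def test_chronogram_ultrametric_and_calibration_exact(self, clock_data):
        tree, aln = clock_data
        chron = date_tree(aln, tree, (aln.ids, 3.4e6), maxiter=300)
        post = chron.tree.postorder()
        root = post[-1]
        assert root.age == pytest.approx(3.4e6)
        depths = []
        for leaf in chron.tree.leaves():
            d, node = 0.0, leaf
            while node.parent is not None:
                d += node.length
                node = node.parent
            depths.append(d)
        assert max(depths) - min(depths) < 1e-6 * max(depths)
        assert chron.ses[len(post) - 1] == 0.0  # calibrated node

    def test_calibration_equivariance_exact(self, clock_data):
        tree, aln = clock_data
        c1 = date_tree(aln, tree, (aln.ids, 3.4e6), maxiter=300)
        c2 = date_tree(aln, tree, (aln.ids, 2 * 3.4e6), maxiter=300)
        for k in c1.ages:
            assert c2.ages[k] == pytest.approx(2 * c1.ages[k], rel=1e-12)
            assert c2.ses[k] == pytest.approx(2 * c1.ses[k], rel=1e-9)
        assert c2.rate == pytest.approx(c1.rate / 2, rel=1e-12)

    def test_calibration_on_leaf_rejected(self, clock_data):
        tree, aln = clock_data
        with pytest.raises(UsageError, match="leaf"):
            date_tree(aln, tree, (["markhor"], 3.4e6))

    def test_nonpositive_age_rejected(self, clock_data):
        tree, aln = clock_data
        with pytest.raises(UsageError):
            date_tree(aln, tree, (aln.ids, -5.0))


class TestRateFromCalibratedNode:
    def make_tree(self, h=0.091):
        tree = PhyloTree.from_newick("((a:1,b:1):1,c:2);")
        node = tree.mrca(["a", "b"])
        node.age = h
        tree.root.age = 2 * h
        for leaf in tree.leaves():
            leaf.age = 0.0
        return tree

    def test_definitional_rate(self):
        tree = self.make_tree(0.091)
        assert rate_from_calibrated_node(tree, ["a", "b"], 91_000) == pytest.approx(1.0e-6)

    def test_dloop_style_rate(self):
        tree = self.make_tree(0.024843)
        got = rate_from_calibrated_node(tree, ["a", "b"], 91_000)
        assert got == pytest.approx(2.73e-7, rel=1e-3)

    def test_rate_inverse_in_age(self):
        tree = self.make_tree(0.05)
        r1 = rate_from_calibrated_node(tree, ["a", "b"], 50_000)
        r2 = rate_from_calibrated_node(tree, ["a", "b"], 25_000)
        assert r2 == pytest.approx(2 * r1)

    def test_zero_age_rejected(self):
        tree = self.make_tree()
        with pytest.raises(UsageError):
            rate_from_calibrated_node(tree, ["a", "b"], 0.0)
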