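"""Phylogenetics: pruning likelihood vs enumeration, NJ, NNI, BIC, bootstrap.

The likelihood oracle below is fully independent of the production code
path: transition matrices come from scipy.linalg.expm and the site
likelihood is an explicit sum over all internal-state assignments.
"""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from conftest import random_unrooted_tree, tree_path_distances
from nitriscan.phylo import (Msa, SubstitutionModel, bic_select,
                             bootstrap_support, distance_matrix,
                             log_likelihood, ml_distance, nj_tree, nni_search,
                             read_newick)
from nitriscan.phylo.distances import ml_distance_from_counts, pair_count_matrix
from nitriscan.phylo.models import discrete_gamma_rates
from nitriscan.simulate import evolve_alignment


def brute_force_log_likelihood(msa, tree, model):
    """Exhaustive sum over internal-node state assignments, P(t) via expm."""
    pi = model.frequencies
    q = model.rate_matrix()
    rates, weights = model.rate_classes()
    enc = msa.encoded()
    row = {l: i for i, l in enumerate(msa.labels)}
    internals = [n for n in tree.postorder() if not n.is_leaf]
    total = 0.0
    for s in range(msa.n_sites):
        lik = 0.0
        for rate, w in zip(rates, weights):
            p_of = {id(n): expm(q * n.length * rate) for n in tree.postorder()
                    if n is not tree.root}
            sub = 0.0
            for states in itertools.product(range(20), repeat=len(internals)):
                st = {id(n): states[k] for k, n in enumerate(internals)}
                term = pi[st[id(tree.root)]]
                for node in tree.postorder():
                    if node is tree.root:
                        continue
                    parent_state = st[id(node.parent)]
                    if node.is_leaf:
                        obs = enc[row[node.name], s]
                        if obs >= 0:
                            term *= p_of[id(node)][parent_state, obs]
                    else:
                        term *= p_of[id(node)][parent_state, st[id(node)]]
                sub += term
            lik += w * sub
        if model.p_inv > 0:
            col = enc[:, s]
            obs = col[col >= 0]
            inv = 1.0 if obs.size == 0 else (
                pi[obs[0]] if np.all(obs == obs[0]) else 0.0)
            lik += model.p_inv * inv
        total += math.log(lik)
    return total


FOUR_TAXON_FIXTURES = [
    ("((A:0.1,B:0.2):0.15,(C:0.3,D:0.05):0.1);",
     ["MKL-V", "MRLAV", "MKIAV", "MK-AV"]),
    ("((A:0.02,C:0.4):0.02,(B:0.25,D:0.1):0.3);",
     ["AAA", "ARN", "A-N", "WYV"]),
    ("((A:0.5,B:0.5):0.5,(C:0.5,D:0.5):0.5);",
     ["MM", "MM", "MM", "MM"]),
]

MODELS = [
    SubstitutionModel(matrix="Poisson"),
    SubstitutionModel(matrix="LG"),
    SubstitutionModel(matrix="LG", alpha=0.7, gamma_categories=5),
    SubstitutionModel(matrix="LG", alpha=1.2, gamma_categories=5, p_inv=0.2),
]


class TestLikelihood:
    def test_zero_branch_identical_pair_gives_log_pi(self):
        model = SubstitutionModel(matrix="LG")
        tree = read_newick("(A:0.0,B:0.0);")
        msa = Msa(["A", "B"], ["M", "M"])
        i = "ARNDCQEGHILKMFPSTWYV".index("M")
        assert log_likelihood(msa, tree, model) == pytest.approx(
            math.log(model.frequencies[i]), abs=1e-12)

    @pytest.mark.parametrize("model", MODELS, ids=lambda m: m.describe())
    @pytest.mark.parametrize("newick,rows", FOUR_TAXON_FIXTURES)
    def test_matches_enumeration_oracle(self, newick, rows, model):
        tree = read_newick(newick)
        msa = Msa(["A", "B", "C", "D"], rows)
        got = log_likelihood(msa, tree, model)
        expect = brute_force_log_likelihood(msa, tree, model)
        assert got == pytest.approx(expect, abs=1e-10)

    @pytest.mark.parametrize("model", MODELS[1:3], ids=lambda m: m.describe())
    def test_rerooting_invariance(self, model):
        tree = read_newick(FOUR_TAXON_FIXTURES[0][0])
        msa = Msa(["A", "B", "C", "D"], FOUR_TAXON_FIXTURES[0][1])
        base = log_likelihood(msa, tree, model)
        for leaf in "ABCD":
            assert log_likelihood(msa, tree.rerooted_at(leaf), model) == \
                pytest.approx(base, abs=1e-9)

    def test_label_mismatch_rejected(self):
        tree = read_newick("(A:0.1,B:0.1);")
        with pytest.raises(ValueError):
            log_likelihood(Msa(["A", "X"], ["M", "M"]), tree,
                           SubstitutionModel())


class TestGammaRates:
    @pytest.mark.parametrize("alpha", [0.2, 0.7, 1.0, 5.0])
    def test_mean_one(self, alpha):
        rates = discrete_gamma_rates(alpha, 5)
        assert rates.mean() == pytest.approx(1.0, abs=1e-10)
        assert (np.diff(rates) > 0).all()

    def test_mixture_mean_one_with_invariant_class(self):
        model = SubstitutionModel(matrix="LG", alpha=0.5, p_inv=0.3)
        rates, weights = model.rate_classes()
        total = float(np.dot(rates, weights))  # invariant class adds 0
        assert total == pytest.approx(1.0, abs=1e-10)


class TestMlDistance:
    def test_identical_sequences_zero(self):
        m = SubstitutionModel(matrix="LG")
        assert ml_distance("MKLV" * 10, "MKLV" * 10, m) == 0.0

    def test_poisson_closed_form_vs_optimizer(self, rng):
        """The numeric optimizer agrees with the closed form to 1e-8.

        Setting explicit uniform frequencies forces the generic optimizer
        route, which is then compared against the analytic solution.
        """
        aas = list("ARNDCQEGHILKMFPSTWYV")
        forced = SubstitutionModel(matrix="Poisson", freqs=np.full(20, 0.05))
        for _ in range(10):
            a = "".join(rng.choice(aas, size=200))
            b = list(a)
            for pos in rng.choice(200, size=rng.integers(5, 60), replace=False):
                b[pos] = str(rng.choice(aas))
            b = "".join(b)
            p = sum(x != y for x, y in zip(a, b)) / 200
            closed = -19 / 20 * math.log(1 - 20 * p / 19)
            assert ml_distance(a, b, forced) == pytest.approx(closed, abs=1e-8)

    def test_symmetry(self, rng):
        aas = list("ARNDCQEGHILKMFPSTWYV")
        m = SubstitutionModel(matrix="LG", alpha=1.0)
        a = "".join(rng.choice(aas, size=80))
        b = list(a)
        for pos in rng.choice(80, size=25, replace=False):
            b[pos] = str(rng.choice(aas))
        b = "".join(b)
        assert ml_distance(a, b, m) == pytest.approx(ml_distance(b, a, m), abs=1e-9)

    def test_no_overlap_undefined(self):
        m = SubstitutionModel(matrix="LG")
        assert ml_distance("MK--", "--LV", m) is None


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(d, ["A", "B", "C"])
        lengths = {l.name: l.length for l in tree.leaves()}
        assert lengths["A"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["B"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["C"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_additive_matrix_topology_recovery(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 11))
            gen = random_unrooted_tree(n, rng)
            d, labels = tree_path_distances(gen)
            rec = nj_tree(d, labels)
            assert rec.bipartitions() == gen.bipartitions()

    def test_additive_branch_lengths_recovered(self, rng):
        gen = random_unrooted_tree(6, rng)
        d, labels = tree_path_distances(gen)
        rec = nj_tree(d, labels)
        d2, labels2 = tree_path_distances(rec)
        assert labels == labels2
        assert np.abs(d - d2).max() < 1e-9

    def test_label_permutation_equivariance(self, rng):
        gen = random_unrooted_tree(7, rng)
        d, labels = tree_path_distances(gen)
        perm = rng.permutation(len(labels))
        d_p = d[np.ix_(perm, perm)]
        labels_p = [labels[i] for i in perm]
        assert nj_tree(d_p, labels_p).bipartitions() == \
               nj_tree(d, labels).bipartitions()

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0, 1.0], [2.0, 0]]), ["A", "B"])


@pytest.fixture(scope="module")
def clean_case():
    rng = np.random.default_rng(77)
    gen = random_unrooted_tree(6, rng, blen_lo=0.1, blen_hi=0.4)
    model = SubstitutionModel(matrix="LG", alpha=1.0)
    msa = evolve_alignment(gen, model, 400, seed=9)
    return gen, model, msa


class TestNniSearch:
    def test_fixed_point_on_clean_data(self, clean_case):
        gen, model, msa = clean_case
        start = nj_tree(distance_matrix(msa, model), msa.labels)
        assert start.bipartitions() == gen.bipartitions()  # NJ already right
        refined = nni_search(msa, start, model)
        assert refined.bipartitions() == gen.bipartitions()

    def test_likelihood_never_decreases(self, clean_case):
        gen, model, msa = clean_case
        # start from a deliberately wrong topology
        rng = np.random.default_rng(5)
        wrong = random_unrooted_tree(6, rng)
        for leaf, name in zip(wrong.leaves(), sorted(msa.labels)):
            leaf.name = name
        before = log_likelihood(msa, wrong, model)
        refined = nni_search(msa, wrong, model)
        after = log_likelihood(msa, refined, model)
        assert after >= before - 1e-9


class TestBicSelect:
    def test_single_candidate_returned(self):
        rng = np.random.default_rng(3)
        gen = random_unrooted_tree(4, rng)
        model = SubstitutionModel(matrix="Poisson")
        msa = evolve_alignment(gen, model, 100, seed=2)
        tree = nj_tree(distance_matrix(msa, model), msa.labels)
        best, table = bic_select(msa, tree, [model])
        assert best.matrix == "Poisson" and len(table) == 1

    def test_lg_data_prefers_lg(self):
        rng = np.random.default_rng(8)
        gen = random_unrooted_tree(6, rng, blen_lo=0.1, blen_hi=0.5)
        true_model = SubstitutionModel(matrix="LG", alpha=1.0)
        msa = evolve_alignment(gen, true_model, 300, seed=4)
        tree = nj_tree(distance_matrix(msa, true_model), msa.labels)
        best, table = bic_select(msa, tree, [
            SubstitutionModel(matrix="Poisson"),
            SubstitutionModel(matrix="LG", alpha=1.0)])
        assert best.matrix == "LG"

    def test_nested_models_lnl_and_bic(self):
        """Adding +G never lowers the fitted lnL; BIC pays for the parameter."""
        rng = np.random.default_rng(13)
        gen = random_unrooted_tree(5, rng)
        plain = SubstitutionModel(matrix="Poisson")
        msa = evolve_alignment(gen, plain, 200, seed=6)
        tree = nj_tree(distance_matrix(msa, plain), msa.labels)
        _, table = bic_select(msa, tree, [
            plain, SubstitutionModel(matrix="Poisson", alpha=1.0)])
        t = table.set_index("model")
        lnl_plain = t.loc["Poisson", "lnL"]
        row_g = t[t.index.str.startswith("Poisson+G")].iloc[0]
        assert row_g["lnL"] >= lnl_plain - 1e-6
        assert row_g["k"] == t.loc["Poisson", "k"] + 1


class TestBootstrap:
    def test_identical_columns_full_support(self):
        rng = np.random.default_rng(21)
        gen = random_unrooted_tree(6, rng, blen_lo=0.1, blen_hi=0.3)
        msa0 = evolve_alignment(gen, SubstitutionModel(matrix="Poisson"), 1, seed=3)
        # repeat the single column: resampling cannot change anything
        msa = Msa(msa0.labels, [r * 100 for r in msa0.rows])
        tree = bootstrap_support(msa, SubstitutionModel(matrix="Poisson"),
                                 n_reps=50, seed=1)
        sups = [n.support for n in tree.internal_nodes() if n.support is not None]
        assert sups and all(s == 100.0 for s in sups)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(22)
        gen = random_unrooted_tree(7, rng)
        msa = evolve_alignment(gen, SubstitutionModel(matrix="Poisson"), 200, seed=5)
        t1 = bootstrap_support(msa, SubstitutionModel(matrix="Poisson"),
                               n_reps=60, seed=9)
        t2 = bootstrap_support(msa, SubstitutionModel(matrix="Poisson"),
                               n_reps=60, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_invalid_reps_rejected(self):
        msa = Msa(["A", "B"], ["MK", "MK"])
        with pytest.raises(ValueError):
            bootstrap_support(msa, SubstitutionModel(), n_reps=0)


class TestNewickRoundTrip:
    def test_topology_lengths_supports_preserved(self, rng):
        gen = random_unrooted_tree(8, rng)
        for i, node in enumerate(gen.internal_nodes()):
            if node is not gen.root:
                node.support = float(10 * i % 101)
        back = read_newick(gen.to_newick())
        assert back.bipartitions() == gen.bipartitions()
        d1, l1 = tree_path_distances(gen)
        d2, l2 = tree_path_distances(back)
        assert l1 == l2 and np.abs(d1 - d2).max() < 1e-9
        sup1 = sorted(n.support for n in gen.internal_nodes()
                      if n.support is not None)
        sup2 = sorted(n.support for n in back.internal_nodes()
                      if n.support is not None)
        assert sup1 == sup2
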