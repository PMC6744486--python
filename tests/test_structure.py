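"""PCA, neighbor joining and ancestry-model tests."""

import itertools

import numpy as np
import pytest

from ginkgopop.stats import DistanceMatrix, ibs_distance_matrix
from ginkgopop.structure import admixture_cv, admixture_fit, nj_tree, pca
from tests.conftest import make_matrix


def dist(values, labels):
    v = np.asarray(values, dtype=float)
    return DistanceMatrix(list(labels), v, np.ones_like(v, dtype=np.int64))


class TestPca:
    def test_two_fixed_groups_separate_on_pc1(self):
        g = np.vstack([np.zeros((4, 30)), np.full((4, 30), 2)]).astype(np.int8)
        res = pca(make_matrix(g), n_components=3)
        pc1 = res.eigenvectors[:, 0]
        assert np.all(np.sign(pc1[:4]) != np.sign(pc1[4:]))
        assert res.percent_variance[0] > 95.0

    def test_duplicated_sample_gets_identical_coordinates(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        g[5] = g[0]
        res = pca(make_matrix(g), n_components=4)
        assert np.allclose(res.eigenvectors[0], res.eigenvectors[5])

    def test_percent_variance_is_eigenvalue_over_trace(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, size=(3, 25)).astype(np.int8)
        G = make_matrix(g)
        res = pca(G, n_components=3)
        # recompute the 3x3 relationship matrix by hand
        x = g.astype(float)
        present = x >= 0
        alt = x.sum(axis=0)
        p = alt / (2 * 3)
        poly = (p > 0) & (p < 1)
        xs = (x[:, poly] - 2 * p[poly]) / np.sqrt(2 * p[poly] * (1 - p[poly]))
        grm = xs @ xs.T / poly.sum()
        vals = np.sort(np.linalg.eigvalsh(grm))[::-1]
        assert np.allclose(res.eigenvalues, vals[:3], atol=1e-9)
        assert np.allclose(
            res.percent_variance, 100 * vals[:3] / np.trace(grm), atol=1e-9
        )

    def test_eigenvalues_non_increasing_and_variance_bounded(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, size=(8, 60)).astype(np.int8)
        res = pca(make_matrix(g), n_components=5)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert res.percent_variance.sum() <= 100.0 + 1e-9

    def test_all_monomorphic_rejected(self):
        g = np.ones((4, 10), dtype=np.int8) * 2
        with pytest.raises(ValueError):
            pca(make_matrix(g))

    def test_lineage_clusters_with_admixed_between(self):
        """Three deep lineages form three clusters; admixed samples fall
        between their sources in PC space."""
        from ginkgopop.coalescent import simulate_genotypes
        from ginkgopop.models import SampleConfig, build_ginkgo_model

        model = build_ginkgo_model()
        G = simulate_genotypes(
            model,
            SampleConfig({"EAST": 6, "SOUTH": 6, "NORTH": 6, "SWEST": 6}),
            60,
            20_000,
            seed=11,
        )
        res = pca(G, n_components=2)
        coords = res.eigenvectors
        cent = {
            pop: coords[[i for i, s in enumerate(G.samples) if s.startswith(pop)]].mean(axis=0)
            for pop in ("EAST", "SOUTH", "NORTH", "SWEST")
        }
        # ancient lineages mutually well separated ...
        ancient = ["EAST", "SOUTH", "SWEST"]
        sep = min(
            np.linalg.norm(cent[a] - cent[b])
            for a, b in itertools.combinations(ancient, 2)
        )
        # ... while NORTH (admixed SOUTH+SWEST) sits between its sources
        d_north_to_sources = max(
            np.linalg.norm(cent["NORTH"] - cent["SOUTH"]),
            np.linalg.norm(cent["NORTH"] - cent["SWEST"]),
        )
        assert d_north_to_sources < np.linalg.norm(cent["SOUTH"] - cent["SWEST"])
        assert sep > 0


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        """Distances (2, 4, 6), scaled into the IBS range by 1/10, resolve
        to branches (A:0, B:2, C:4)/10 via the three-point formulas."""
        D = dist(np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0]]) / 10, "ABC")
        tree = nj_tree(D)
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == pytest.approx({"A": 0.0, "B": 0.2, "C": 0.4})

    def test_recovers_additive_four_taxon_tree(self):
        """Tree ((A:1,B:2):1,(C:3,D:4)) is recovered exactly from its
        additive distance matrix."""
        d = {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
        }
        labels = "ABCD"
        m = np.zeros((4, 4))
        for (a, b), v in d.items():
            i, j = labels.index(a), labels.index(b)
            m[i, j] = m[j, i] = v
        tree = nj_tree(dist(m / 10, labels))  # scale into [0,1] (IBS range)
        # verify additivity: tip-to-tip path lengths reproduce the matrix
        paths = _tip_distances(tree)
        for (a, b), v in d.items():
            assert paths[frozenset((a, b))] == pytest.approx(v / 10)

    @pytest.mark.parametrize("seed", range(10))
    def test_inverts_random_additive_matrices(self, seed):
        """NJ exactly inverts distances generated from random binary trees
        (additivity oracle, up to 12 taxa)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        labels = [f"t{i:02d}" for i in range(n)]
        # random binary tree: successively attach leaves to random edges
        dmat = _random_additive_distances(rng, labels)
        tree = nj_tree(dist(dmat, labels))
        paths = _tip_distances(tree)
        for i, j in itertools.combinations(range(n), 2):
            assert paths[frozenset((labels[i], labels[j]))] == pytest.approx(
                dmat[i, j], abs=1e-9
            )

    def test_equidistant_matrix_resolves_deterministically(self):
        m = np.full((4, 4), 0.5)
        np.fill_diagonal(m, 0.0)
        t1 = nj_tree(dist(m, "ABCD")).newick
        t2 = nj_tree(dist(m, "ABCD")).newick
        assert t1 == t2  # tie-break rule pins the output

    def test_matches_skbio_on_simulated_ibs(self):
        skbio = pytest.importorskip("skbio")

        from ginkgopop.coalescent import simulate_genotypes
        from ginkgopop.models import DemographicModel, SampleConfig, Split

        model = DemographicModel(
            demes=("P1", "P2"),
            sizes={"P1": 3e4, "P2": 3e4},
            splits=[Split(1e6, "P2", "P1")],
        )
        G = simulate_genotypes(model, SampleConfig({"P1": 4, "P2": 4}), 20, 20_000, seed=3)
        D = ibs_distance_matrix(G)
        mine = nj_tree(D)
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        theirs = skbio_nj(SkbioDM(D.values, ids=D.samples))
        mine_tree = skbio.TreeNode.read([mine.newick])
        # same topology: Robinson-Foulds distance of zero
        assert mine_tree.compare_rfd(theirs) == 0.0

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(dist([[0, 0.1], [0.1, 0]], "AB"))  # too few taxa
        bad = np.array([[0, 0.5, 0.2], [0.5, 0, np.nan], [0.2, np.nan, 0]])
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b", "c"], bad, np.ones((3, 3), dtype=np.int64)))


def _tip_distances(tree):
    """Path lengths between all leaf pairs of a PhyloTree."""
    out = {}

    def walk(node):
        if not node.children:
            return {node.name: node.length}
        acc = {}
        groups = []
        for c in node.children:
            sub = walk(c)
            groups.append(sub)
            acc.update(sub)
        for g1, g2 in itertools.combinations(groups, 2):
            for a, da in g1.items():
                for b, db in g2.items():
                    out[frozenset((a, b))] = da + db
        return {k: v + node.length for k, v in acc.items()}

    walk(tree.root)
    return out


def _random_additive_distances(rng, labels):
    """Distances from a random binary tree with positive branch lengths."""
    n = len(labels)
    # grow a tree as a set of edges over node ids; 0..n-1 are leaves
    # start with a 3-star around internal node n
    next_id = n + 1
    edges = {}
    for leaf in range(3):
        edges[(leaf, n)] = rng.uniform(0.01, 0.2)
    for leaf in range(3, n):
        # split a random existing edge with a new internal node
        (a, b), w = list(edges.items())[int(rng.integers(len(edges)))]
        del edges[(a, b)]
        mid = next_id
        next_id += 1
        cut = rng.uniform(0.25, 0.75) * w
        edges[(a, mid)] = cut
        edges[(mid, b)] = w - cut
        edges[(leaf, mid)] = rng.uniform(0.01, 0.2)
    # all-pairs shortest paths over the tree
    import networkx as nx

    g = nx.Graph()
    for (a, b), w in edges.items():
        g.add_edge(a, b, weight=w)
    dmat = np.zeros((n, n))
    sp = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    for i, j in itertools.combinations(range(n), 2):
        dmat[i, j] = dmat[j, i] = sp[i][j]
    return dmat


class TestAncestryModel:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(5, 40)).astype(np.int8)
        G = make_matrix(g)
        fit = admixture_fit(G, K=1)
        assert np.allclose(fit.Q, 1.0)
        p = g.sum(axis=0) / 10
        pc = np.clip(p, 1e-6, 1 - 1e-6)
        ll = np.sum(g * np.log(pc) + (2 - g) * np.log(1 - pc))
        assert fit.loglik == pytest.approx(ll)

    def test_loglik_monotone_along_trace(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, size=(12, 80)).astype(np.int8)
        fit = admixture_fit(make_matrix(g), K=3, seed=5, max_iter=60)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-6)

    def test_two_deep_demes_assigned_cleanly(self, two_deme_split_model):
        """K=2 on deeply split demes: mean max-ancestry >= 0.95."""
        from ginkgopop.coalescent import simulate_genotypes
        from ginkgopop.models import SampleConfig

        G = simulate_genotypes(
            two_deme_split_model, SampleConfig({"P1": 8, "P2": 8}), 30, 20_000, seed=2
        )
        fit = admixture_fit(G, K=2, seed=3, n_replicates=2)
        assert fit.Q.max(axis=1).mean() >= 0.95

    def test_constructed_hybrids_near_half_ancestry(self):
        """50/50 hybrids of two reference panels get Q within 0.1 of 0.5."""
        rng = np.random.default_rng(9)
        m = 400
        pa = rng.uniform(0.05, 0.95, m)
        pb = rng.uniform(0.05, 0.95, m)
        # make the panels informative: push frequencies apart
        pa = np.where(pa > pb, np.minimum(pa + 0.3, 0.98), np.maximum(pa - 0.3, 0.02))
        panel_a = rng.binomial(2, pa, size=(15, m)).astype(np.int8)
        panel_b = rng.binomial(2, pb, size=(15, m)).astype(np.int8)
        hyb = (rng.binomial(1, pa, size=(6, m)) + rng.binomial(1, pb, size=(6, m))).astype(np.int8)
        G = make_matrix(np.vstack([panel_a, panel_b, hyb]))
        fit = admixture_fit(G, K=2, seed=7, n_replicates=2)
        hyb_q = fit.Q[30:]
        assert np.all(np.abs(hyb_q - 0.5) < 0.1)

    def test_label_permutation_leaves_loglik_unchanged(self):
        from ginkgopop.structure import _admixture_loglik

        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, size=(8, 50)).astype(np.int8)
        G = make_matrix(g)
        fit = admixture_fit(G, K=3, seed=1, max_iter=40)
        perm = [2, 0, 1]
        ll = _admixture_loglik(
            g.astype(float), g != -1, fit.Q[:, perm], fit.P[perm]
        )
        assert ll == pytest.approx(fit.loglik)

    def test_k_exceeding_samples_rejected(self):
        g = np.zeros((3, 10), dtype=np.int8)
        with pytest.raises(ValueError):
            admixture_fit(make_matrix(g), K=4)


class TestCrossValidation:
    def test_cv_minimized_at_true_k(self):
        """CV error over K in 1..4 bottoms out at the simulated K=3 in a
        majority of seeded runs."""
        from ginkgopop.coalescent import simulate_genotypes
        from ginkgopop.models import DemographicModel, SampleConfig, Split

        model = DemographicModel(
            demes=("P1", "P2", "P3"),
            sizes={"P1": 3e4, "P2": 3e4, "P3": 3e4},
            splits=[Split(2e6, "P3", "P1"), Split(1e6, "P2", "P1")],
        )
        G = simulate_genotypes(
            model, SampleConfig({"P1": 6, "P2": 6, "P3": 6}), 25, 10_000, seed=8
        )
        wins = 0
        for seed in (1, 2, 3):
            errs = admixture_cv(G, [1, 2, 3, 4], n_folds=4, seed=seed, max_iter=80)
            if min(errs, key=errs.get) == 3:
                wins += 1
        assert wins >= 2

    def test_single_k_returns_single_value(self):
        rng = np.random.default_rng(4)
        g = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        errs = admixture_cv(make_matrix(g), [2], n_folds=3, seed=0, max_iter=30)
        assert list(errs) == [2]

    def test_duplicating_all_samples_keeps_argmin(self):
        rng = np.random.default_rng(5)
        base = np.vstack(
            [rng.binomial(2, 0.1, size=(5, 120)), rng.binomial(2, 0.9, size=(5, 120))]
        ).astype(np.int8)
        doubled = np.vstack([base, base])
        e1 = admixture_cv(make_matrix(base), [1, 2, 3], n_folds=3, seed=2, max_iter=60)
        e2 = admixture_cv(make_matrix(doubled), [1, 2, 3], n_folds=3, seed=2, max_iter=60)
        assert min(e1, key=e1.get) == min(e2, key=e2.get)
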