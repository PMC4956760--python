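"""k-means, PCA, correlations and cluster statistics on elemental maps."""

import itertools

import numpy as np
import pytest

from nanoxrf import (FeatureMatrix, Geometry, Label, TissueProfile,
                     assign_concentrations, build_feature_matrix,
                     cluster_statistics, correlation_matrix, generate_label_map,
                     kmeans_cluster, match_clusters, pca)
from nanoxrf.phantom import CELL_LABELS
from nanoxrf.pipeline import build_phantom


def phantom_features(seed, elements=("P", "S", "Zn", "Pt")):
    truth = build_phantom("normothermic", (128, 128), seed=seed)
    feats = build_feature_matrix({el: truth.conc[el] for el in elements})
    return truth, feats


class TestFeatureMatrix:
    def test_zscore_columns_standardized(self):
        rng = np.random.default_rng(0)
        maps = {"A": rng.normal(5, 2, (9, 9)), "B": rng.normal(0, 1, (9, 9))}
        fm = build_feature_matrix(maps, scaling="zscore")
        assert np.allclose(fm.X.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(fm.X.std(axis=0), 1, atol=1e-9)

    def test_no_scaling_preserves_values_and_order(self):
        maps = {"A": np.arange(9.0).reshape(3, 3), "B": np.ones((3, 3))}
        fm = build_feature_matrix(maps, scaling="none")
        assert fm.X.shape == (9, 2)
        assert np.array_equal(fm.X[:, 0], np.arange(9.0))  # row-major order

    def test_constant_column_flagged_not_scaled(self):
        maps = {"A": np.random.default_rng(1).normal(size=(4, 4)),
                "B": np.full((4, 4), 3.0)}
        fm = build_feature_matrix(maps, scaling="zscore")
        assert fm.constant_columns == ("B",)
        assert np.allclose(fm.X[:, 1], 3.0)


class TestKMeans:
    def test_two_well_separated_groups(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        fm = FeatureMatrix(X, ("x",), (4, 1), "none")
        cm = kmeans_cluster(fm, k=2, seed=0)
        labels = cm.labels.ravel()
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]
        assert sorted(np.round(cm.centroids.ravel(), 6)) == [0.05, 10.05]

    def test_k1_centroid_is_mean(self):
        X = np.random.default_rng(3).normal(size=(20, 2))
        fm = FeatureMatrix(X, ("a", "b"), (4, 5), "none")
        cm = kmeans_cluster(fm, k=1, seed=0)
        assert np.allclose(cm.centroids[0], X.mean(axis=0))

    def test_matches_exhaustive_partition_oracle(self):
        """Global optimum by enumeration of all k^n assignments, n<=10."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 2))
        fm = FeatureMatrix(X, ("a", "b"), (8, 1), "none")
        for k in (2, 3):
            best = np.inf
            for assign in itertools.product(range(k), repeat=len(X)):
                assign = np.array(assign)
                if len(set(assign)) < k:
                    continue
                inertia = sum(((X[assign == j] - X[assign == j].mean(axis=0)) ** 2).sum()
                              for j in range(k))
                best = min(best, inertia)
            cm = kmeans_cluster(fm, k=k, seed=0, n_init=20)
            assert cm.inertia == pytest.approx(best, rel=1e-9)

    def test_inertia_trace_monotone_and_consistent(self):
        _, feats = phantom_features(0)
        cm = kmeans_cluster(feats, k=3, seed=1, n_init=3)
        trace = np.array(cm.inertia_trace)
        assert (np.diff(trace) <= 1e-6 * trace[:-1]).all()
        # recompute inertia from assignments and centroids
        d2 = ((feats.X[:, None, :] - cm.centroids[None]) ** 2).sum(-1)
        recomputed = d2[np.arange(len(feats.X)), cm.labels.ravel()].sum()
        assert cm.inertia == pytest.approx(recomputed, rel=1e-6)

    def test_agrees_with_sklearn(self):
        from sklearn.cluster import KMeans
        rng = np.random.default_rng(12)
        X = np.vstack([rng.normal(0, 0.4, (40, 3)), rng.normal(3, 0.4, (40, 3)),
                       rng.normal((0, 5, 1), 0.4, (40, 3))])
        fm = FeatureMatrix(X, ("a", "b", "c"), (120, 1), "none")
        ours = kmeans_cluster(fm, k=3, seed=0, n_init=10)
        sk = KMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
        assert ours.inertia == pytest.approx(sk.inertia_, rel=1e-6)

    def test_k_larger_than_distinct_points_rejected(self):
        X = np.array([[1.0], [1.0], [2.0]])
        fm = FeatureMatrix(X, ("x",), (3, 1), "none")
        with pytest.raises(ValueError):
            kmeans_cluster(fm, k=3, seed=0)

    def test_seeded_determinism(self):
        _, feats = phantom_features(2)
        a = kmeans_cluster(feats, k=3, seed=9, n_init=3)
        b = kmeans_cluster(feats, k=3, seed=9, n_init=3)
        assert np.array_equal(a.labels, b.labels)

    def test_nucleus_detail_three_clusters_recover_compartments(self):
        """k=3 on (P,S,Zn) of the 20-nm nucleus zoom separates cytoplasm,
        nucleus matrix and nucleoli by majority ground-truth label."""
        lm = generate_label_map((96, 96), 20.0, Geometry(mode="nucleus_detail"),
                                seed=6)
        truth = assign_concentrations(lm, TissueProfile.preset("normothermic"),
                                      seed=7)
        feats = build_feature_matrix({el: truth.conc[el] for el in ("P", "S", "Zn")})
        cm = kmeans_cluster(feats, k=3, seed=1, n_init=10)
        majorities = set()
        for c in range(3):
            vals, counts = np.unique(lm.labels.ravel()[cm.labels.ravel() == c],
                                     return_counts=True)
            majorities.add(int(vals[counts.argmax()]))
        assert majorities == {int(Label.CYTOPLASM), int(Label.NUCLEUS_MATRIX),
                              int(Label.NUCLEOLUS)}


class TestSegmentationRecovery:
    def test_pt_cluster_is_extracellular_and_structure_recovered(self):
        """Over 10 phantom seeds: at k=3 the Pt-rich cluster is almost
        entirely extracellular (the drug stays outside the cells); at k=4
        (nucleus/cytoplasm split absorbed) majority-label mapping recovers
        {cell, stroma, string} with median agreement >= 0.80."""
        purities, agreements = [], []
        for seed in range(10):
            truth, feats = phantom_features(seed)
            labels = truth.label_map.labels
            cell = np.isin(labels, [int(l) for l in CELL_LABELS]).ravel()
            groups = np.select([cell.reshape(labels.shape),
                                labels == int(Label.PT_STRING)], [1, 2],
                               default=0).ravel()
            cm3 = kmeans_cluster(feats, k=3, seed=200 + seed, n_init=5)
            pt_cl = cm3.centroids[:, list(feats.elements).index("Pt")].argmax()
            purities.append((~cell[cm3.labels.ravel() == pt_cl]).mean())
            cm4 = kmeans_cluster(feats, k=4, seed=300 + seed, n_init=5)
            agree = 0
            for c in range(4):
                member = groups[cm4.labels.ravel() == c]
                if len(member):
                    agree += np.bincount(member).max()
            agreements.append(agree / len(groups))
        assert np.median(purities) > 0.9
        assert np.median(agreements) >= 0.80


class TestPCA:
    def test_duplicate_columns_one_component(self):
        base = np.random.default_rng(5).normal(size=(50, 1))
        fm = FeatureMatrix(np.hstack([base, base]), ("a", "b"), (50, 1), "none")
        res = pca(fm)
        assert res.explained[0] == pytest.approx(1.0)

    def test_hand_computed_eigenstructure(self):
        X = np.array([[1, 0], [-1, 0], [0, 0.5], [0, -0.5]], dtype=float)
        fm = FeatureMatrix(X, ("a", "b"), (4, 1), "none")
        res = pca(fm)
        assert abs(res.loadings[0, 0]) == pytest.approx(1.0, abs=1e-9)
        assert res.explained[0] == pytest.approx(0.8, abs=1e-9)

    def test_loadings_orthonormal_and_explained_sorted(self):
        _, feats = phantom_features(1)
        res = pca(feats)
        assert np.allclose(res.loadings.T @ res.loadings,
                           np.eye(res.loadings.shape[1]), atol=1e-8)
        assert (np.diff(res.explained) <= 1e-12).all()
        assert res.explained.sum() <= 1 + 1e-9

    def test_full_rank_reconstruction(self):
        _, feats = phantom_features(1)
        res = pca(feats)
        X = feats.X
        recon = res.scores @ res.loadings.T + X.mean(axis=0)
        err = np.linalg.norm(recon - X) / np.linalg.norm(X)
        assert err < 1e-8

    def test_pt_br_load_together_apart_from_p_zn(self):
        """Pt and Br co-load on the Pt-dominant component; P and Zn pair on
        a different one — the halide follows the drug, not the cells."""
        truth = build_phantom("normothermic", (128, 128), seed=3)
        feats = build_feature_matrix(
            {el: truth.conc[el] for el in ("P", "S", "Ca", "Mn", "Fe", "Zn",
                                           "Br", "Pt")})
        res = pca(feats)
        els = list(res.elements)
        pt, br, p, zn = (els.index(e) for e in ("Pt", "Br", "P", "Zn"))
        # restrict to structure components (>= 5% variance each); trailing
        # components are single-element noise contrasts
        lead = np.flatnonzero(res.explained >= 0.05)
        pt_comp = lead[np.abs(res.loadings[pt, lead]).argmax()]
        assert np.sign(res.loadings[pt, pt_comp]) == np.sign(res.loadings[br, pt_comp])
        ratio = abs(res.loadings[pt, pt_comp]) / abs(res.loadings[br, pt_comp])
        assert 0.5 <= ratio <= 2.0
        # P and Zn load together (same sign, both substantial) on a
        # different component: the cellular axis
        joint = res.loadings[p, lead] * res.loadings[zn, lead]
        p_zn_comp = lead[joint.argmax()]
        assert p_zn_comp != pt_comp
        assert joint.max() > 0
        assert min(abs(res.loadings[p, p_zn_comp]),
                   abs(res.loadings[zn, p_zn_comp])) > 0.2

    def test_too_few_pixels_rejected(self):
        fm = FeatureMatrix(np.ones((1, 3)), ("a", "b", "c"), (1, 1), "none")
        with pytest.raises(ValueError):
            pca(fm)


class TestCorrelations:
    def test_identical_maps_r_one(self):
        m = np.random.default_rng(2).normal(size=(8, 8))
        R, flagged = correlation_matrix({"A": m, "B": m.copy()})
        assert R.loc["A", "B"] == pytest.approx(1.0)
        assert not flagged

    def test_constant_map_flagged_zero(self):
        m = np.random.default_rng(2).normal(size=(8, 8))
        R, flagged = correlation_matrix({"A": m, "B": np.full((8, 8), 2.0)})
        assert flagged == ["B"]
        assert R.loc["A", "B"] == 0.0
        assert R.loc["B", "B"] == 1.0

    def test_pt_correlates_with_br_above_p_and_zn(self):
        truth = build_phantom("normothermic", (128, 128), seed=3)
        R, _ = correlation_matrix(truth.conc)
        assert R.loc["Pt", "Br"] > R.loc["Pt", "P"]
        assert R.loc["Pt", "Br"] > R.loc["Pt", "Zn"]

    def test_symmetry_unit_diagonal(self):
        truth = build_phantom("normothermic", (64, 64), seed=5)
        R, _ = correlation_matrix(truth.conc)
        assert np.allclose(R.values, R.values.T)
        assert np.allclose(np.diag(R.values), 1.0)


class TestClusterStats:
    def test_single_cluster_means_equal_map_means(self):
        maps = {"A": np.arange(16.0).reshape(4, 4)}
        stats = cluster_statistics(np.zeros((4, 4), dtype=int), maps)
        assert stats.table.loc[(0, "A"), "mean"] == pytest.approx(7.5)

    def test_two_cluster_known_constants(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[2:] = 1
        maps = {"A": np.where(labels == 0, 3.0, 5.0)}
        stats = cluster_statistics(labels, maps)
        assert stats.table.loc[(0, "A"), "mean"] == 3.0
        assert stats.table.loc[(1, "A"), "mean"] == 5.0
        assert stats.table.loc[(1, "A"), "count"] == 8

    def test_merged_mean_is_count_weighted(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 3, (10, 10))
        maps = {"A": rng.normal(size=(10, 10))}
        stats = cluster_statistics(labels, maps)
        t = stats.table
        merged = (t.loc[(0, "A"), "mean"] * t.loc[(0, "A"), "count"]
                  + t.loc[(1, "A"), "mean"] * t.loc[(1, "A"), "count"])
        direct = maps["A"][labels <= 1].sum()
        assert merged == pytest.approx(direct)
        assert t["count"].groupby("element").sum()["A"] == 100

    def test_ratio_helper_and_empty_set_error(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[2:] = 1
        maps = {"Pt": np.where(labels == 0, 1.0, 2.0)}
        stats = cluster_statistics(labels, maps)
        assert stats.ratio([1], [0], "Pt") == pytest.approx(2.0)
        with pytest.raises(ValueError):
            stats.ratio([5], [0], "Pt")

    def test_match_clusters_recovers_permutation(self):
        truth = np.repeat([0, 1, 2], 20)
        clusters = np.choose(truth, [2, 0, 1])
        mapping, agreement = match_clusters(clusters, truth)
        assert agreement == 1.0
        assert mapping == {2: 0, 0: 1, 1: 2}
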