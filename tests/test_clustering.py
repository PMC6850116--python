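"""Tissue clustering: sqrt-Euclidean distances, UPGMA, Newick export."""
import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform

from ddmosaic import (
    build_maf_matrix,
    dendrogram_to_newick,
    hierarchical_cluster,
    load_fixture,
    sqrt_euclidean_distances,
)
from ddmosaic.errors import ClusteringError, ParameterError

from _oracles import pairwise_sqrt_euclidean


def tidy(rows):
    return pd.DataFrame(rows, columns=["row_id", "feature", "value"])


@pytest.fixture
def tissue_matrix():
    """Family x tissue MAF matrix (fractions) from the published tissue table."""
    df = load_fixture("tissue_maf")
    rows = [
        {"row_id": r.family_id, "feature": r.tissue,
         "value": r.maf / 100.0 if np.isfinite(r.maf) else np.nan}
        for r in df.itertuples()
    ]
    return build_maf_matrix(rows, na_policy="drop_feature")


class TestBuildMatrix:
    def test_complete_input_unchanged(self):
        m = build_maf_matrix(tidy([("a", "maf", 0.1), ("b", "maf", 0.2)]))
        assert m.values.shape == (2, 1)
        assert m.values.loc["a", "maf"] == 0.1

    def test_drop_feature_removes_any_na_column(self, tissue_matrix):
        # only blood is measured in every multi-tissue family; all other
        # tissue columns carry at least one NA and are dropped
        assert list(tissue_matrix.values.columns) == ["blood"]
        blood = tissue_matrix.values["blood"]
        assert blood.loc["A052"] == pytest.approx(0.1882)
        assert blood.loc["A015"] == pytest.approx(0.0001)

    def test_drop_sample_removes_incomplete_rows(self):
        m = build_maf_matrix(
            tidy([("a", "f1", 0.1), ("a", "f2", 0.2),
                  ("b", "f1", 0.3), ("b", "f2", np.nan),
                  ("c", "f1", 0.4), ("c", "f2", 0.5)]),
            na_policy="drop_sample",
        )
        assert sorted(m.values.index) == ["a", "c"]

    def test_too_few_rows_after_policy_rejected(self):
        with pytest.raises(ClusteringError):
            build_maf_matrix(
                tidy([("a", "f1", np.nan), ("b", "f1", 0.1)]),
                na_policy="drop_sample",
            )

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ParameterError):
            build_maf_matrix(tidy([("a", "maf", 1.5), ("b", "maf", 0.2)]))


class TestDistances:
    def test_identical_rows_distance_zero(self):
        m = build_maf_matrix(tidy([("a", "maf", 0.25), ("b", "maf", 0.25)]))
        d = sqrt_euclidean_distances(m)
        assert d.loc["a", "b"] == 0.0

    def test_single_feature_hand_arithmetic(self):
        m = build_maf_matrix(tidy([("a", "maf", 0.25), ("b", "maf", 0.04)]))
        d = sqrt_euclidean_distances(m)
        assert d.loc["a", "b"] == pytest.approx(0.3)  # |0.5 - 0.2|

    def test_fixture_distances_match_per_pair_oracle(self, tissue_matrix):
        d = sqrt_euclidean_distances(tissue_matrix).to_numpy()
        oracle = pairwise_sqrt_euclidean(tissue_matrix.values.to_numpy())
        assert np.max(np.abs(d - oracle)) < 1e-12

    def test_distance_axioms_on_fixture(self, tissue_matrix):
        d = sqrt_euclidean_distances(tissue_matrix).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_pairwise_policy_uses_shared_features(self):
        m = build_maf_matrix(
            tidy([("a", "f1", 0.25), ("a", "f2", 0.09),
                  ("b", "f1", 0.04), ("b", "f2", np.nan)]),
            na_policy="pairwise",
        )
        d = sqrt_euclidean_distances(m)
        assert d.loc["a", "b"] == pytest.approx(0.3)


class TestHierarchicalCluster:
    def test_two_leaves_merge_at_their_distance(self):
        d = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=["A", "B"], columns=["A", "B"])
        t = hierarchical_cluster(d)
        assert t.heights[0] == pytest.approx(0.4)

    def test_closest_pair_merges_first(self):
        labels = ["A", "B", "C"]
        d = pd.DataFrame(
            [[0, 1, 10], [1, 0, 10], [10, 10, 0]], dtype=float,
            index=labels, columns=labels,
        )
        t = hierarchical_cluster(d)
        first = set(t.linkage[0, :2].astype(int))
        assert {t.labels[i] for i in first} == {"A", "B"}

    def test_heights_monotone_under_average_and_complete(self, rng):
        x = rng.uniform(0, 1, size=(12, 3))
        from scipy.spatial.distance import pdist

        d = pd.DataFrame(squareform(pdist(x)))
        for linkage in ("average", "complete"):
            t = hierarchical_cluster(d, linkage=linkage)
            assert np.all(np.diff(t.heights) >= -1e-12)

    def test_row_permutation_gives_identical_tree(self, tissue_matrix):
        d = sqrt_euclidean_distances(tissue_matrix)
        perm = d.sample(frac=1.0, random_state=1)
        perm = perm[perm.index]
        a = hierarchical_cluster(d)
        b = hierarchical_cluster(perm)
        assert a.labels == b.labels
        assert np.allclose(a.linkage, b.linkage)

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ParameterError, match="symmetric"):
            hierarchical_cluster(d)

    def test_separated_groups_form_pure_subtrees(self):
        # mosaic-parent samples near a common MAF vs controls near zero
        rng = np.random.default_rng(3)
        rows = []
        for i in range(5):
            rows.append((f"mosaic{i}", "maf", 0.05 * (1 + 0.1 * rng.normal())))
        for i in range(5):
            rows.append((f"ctrl{i}", "maf", abs(rng.normal(0, 1e-4))))
        m = build_maf_matrix(tidy(rows))
        t = hierarchical_cluster(sqrt_euclidean_distances(m))
        from ddmosaic.clustering import cut_clusters

        groups = cut_clusters(t, 2)
        mosaic_ids = {groups[l] for l in groups if l.startswith("mosaic")}
        ctrl_ids = {groups[l] for l in groups if l.startswith("ctrl")}
        assert len(mosaic_ids) == 1 and len(ctrl_ids) == 1
        assert mosaic_ids != ctrl_ids


class TestNewick:
    def test_two_leaf_ultrametric_split(self):
        d = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=["A", "B"], columns=["A", "B"])
        t = hierarchical_cluster(d)
        assert dendrogram_to_newick(t) == "(A:0.2,B:0.2);"

    def test_single_leaf_rejected(self):
        from ddmosaic.clustering import Dendrogram

        with pytest.raises(ParameterError):
            dendrogram_to_newick(Dendrogram(linkage=np.empty((0, 4)), labels=("A",)))

    def test_round_trip_preserves_topology_and_heights(self, rng):
        # patristic leaf-leaf distances in the exported tree equal the
        # cophenetic merge heights of the dendrogram
        x = rng.uniform(0, 1, size=(8, 4))
        from scipy.spatial.distance import pdist

        d = pd.DataFrame(squareform(pdist(x)),
                         index=[f"L{i}" for i in range(8)],
                         columns=[f"L{i}" for i in range(8)])
        t = hierarchical_cluster(d)
        tree = dendropy.Tree.get(data=dendrogram_to_newick(t), schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        coph = squareform(cophenet(t.linkage))
        taxa = {x.label: x for x in tree.taxon_namespace}
        for i, a in enumerate(t.labels):
            for j, b in enumerate(t.labels):
                if i < j:
                    got = pdm.patristic_distance(taxa[a], taxa[b])
                    assert got == pytest.approx(coph[i, j], abs=1e-9)
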