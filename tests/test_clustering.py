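"""Angular clustering, principal-tree refinement, layering and validation."""

import numpy as np
import pytest

from ltrtrace.clustering import (
    ClusterAssignment,
    agglomerative_cluster,
    iterate_layers,
    principal_tree_refine,
    validate_clusters,
    pairwise_identity,
)
from ltrtrace.config import RunConfig
from ltrtrace.embedding import EmbedParams, Embedding, angular_matrix
from ltrtrace.io_formats import ElementRecord


def _angles_from_coords(coords):
    emb = Embedding(coords=np.asarray(coords, float), params=EmbedParams())
    ang, valid = angular_matrix(emb)
    assert valid.all()
    return ang


class TestAgglomerativeCluster:
    def test_antipodal_bundles_perfect_split(self):
        rng = np.random.default_rng(0)
        a = np.array([5.0, 0, 0]) + rng.normal(scale=0.1, size=(20, 3))
        b = np.array([-5.0, 0, 0]) + rng.normal(scale=0.1, size=(20, 3))
        ang = _angles_from_coords(np.vstack([a, b]))
        labels = agglomerative_cluster(ang, k_range=range(2, 7))
        assert len(set(labels)) == 2
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[20]

    def test_degenerate_codirectional_single_cluster(self):
        ang = np.zeros((10, 10))
        with pytest.warns(UserWarning, match="degenerate"):
            labels = agglomerative_cluster(ang)
        assert set(labels) == {0}

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        pts = np.vstack(
            [
                np.array([4.0, 0, 0]) + rng.normal(scale=0.2, size=(15, 3)),
                np.array([0, 4.0, 0]) + rng.normal(scale=0.2, size=(15, 3)),
                np.array([0, 0, 4.0]) + rng.normal(scale=0.2, size=(15, 3)),
            ]
        )
        ang = _angles_from_coords(pts)
        labels = agglomerative_cluster(ang)
        perm = rng.permutation(len(pts))
        labels_p = agglomerative_cluster(ang[np.ix_(perm, perm)])
        # same partition up to relabeling
        for i in range(len(pts)):
            for j in range(len(pts)):
                assert (labels[perm[i]] == labels[perm[j]]) == (labels_p[i] == labels_p[j])

    def test_infeasible_k_range_rejected(self):
        ang = np.zeros((3, 3))
        with pytest.raises(ValueError, match="feasible"):
            agglomerative_cluster(ang, k_range=[5, 6])


class TestPrincipalTree:
    def test_points_at_centroids_unchanged(self):
        pts = np.repeat(np.array([[0.0, 0, 0], [10.0, 0, 0], [0, 10.0, 0]]), 10, axis=0)
        labels = np.repeat([0, 1, 2], 10)
        refined, tree = principal_tree_refine(pts, labels)
        assert np.array_equal(refined, labels)
        assert tree.nodes.shape == (3, 3)
        assert len(tree.edges) == 2  # spanning tree on 3 nodes

    def test_point_near_other_branch_reassigned(self):
        # clusters at (0,0,0), (10,0,0), (0,10,0); a stray point close to the
        # branch toward (0,10,0) must adopt that branch's cluster
        pts = [[0.0, 0, 0]] * 10 + [[10.0, 0, 0]] * 10 + [[0, 10.0, 0]] * 10
        pts.append([0.4, 7.0, 0.0])  # near segment (0,0,0)-(0,10,0), upper half
        pts = np.array(pts)
        labels = np.array([0] * 10 + [1] * 10 + [2] * 10 + [1])
        refined, _ = principal_tree_refine(pts, labels)
        assert refined[-1] == 2

    def test_single_cluster_identity(self):
        pts = np.random.default_rng(0).normal(size=(12, 3))
        labels = np.zeros(12, dtype=int)
        refined, tree = principal_tree_refine(pts, labels)
        assert np.array_equal(refined, labels)
        assert tree.edges == []


def _elements_two_families(n_per=8, length=600, divergence=0.3, seed=0):
    rng = np.random.default_rng(seed)

    def rand(n):
        return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

    def mutate(s, d):
        s = list(s)
        for i in rng.choice(len(s), int(d * len(s)), replace=False):
            s[i] = "ACGT"[rng.integers(0, 4)]
        return "".join(s)

    fam_a, fam_b = rand(length), rand(length)
    elements, assignments = [], []
    for fam, base in (("A", fam_a), ("B", fam_b)):
        for i in range(n_per):
            eid = f"{fam.lower()}{i}"
            elements.append(ElementRecord(eid, mutate(base, 0.02)))
            assignments.append(ClusterAssignment(eid, fam))
    return elements, assignments


class TestValidateClusters:
    def test_distinct_families_validate(self):
        elements, assignments = _elements_two_families()
        report = validate_clusters(assignments, elements, n_sample=8, seed=1)
        (pair,) = report.pairs
        assert pair.fold_change > 1.5
        assert pair.p_value < 0.05

    def test_split_single_family_fails_validation(self):
        elements, assignments = _elements_two_families()
        # relabel family A's members arbitrarily into two fake clusters
        fake = []
        for i, a in enumerate(assignments):
            if a.label == "A":
                fake.append(ClusterAssignment(a.element_id, "A1" if i % 2 else "A2"))
        report = validate_clusters(fake, [e for e in elements if e.element_id.startswith("a")],
                                   n_sample=8, seed=1)
        (pair,) = report.pairs
        assert pair.fold_change == pytest.approx(1.0, abs=0.25)
        assert pair.p_value > 0.05

    def test_report_covers_all_cluster_pairs(self):
        elements, assignments = _elements_two_families()
        third = [ClusterAssignment(a.element_id, "C") for a in assignments[:4]]
        merged = assignments[4:] + third
        report = validate_clusters(merged, elements, n_sample=5, seed=0)
        assert len(report.pairs) == 3  # C(3,2)

    def test_singleton_cluster_excluded_with_note(self):
        elements, assignments = _elements_two_families(n_per=3)
        assignments[0] = ClusterAssignment(assignments[0].element_id, "solo")
        report = validate_clusters(assignments, elements, n_sample=5, seed=0)
        assert any("solo" in note for note in report.excluded)

    def test_n_sample_floor(self):
        with pytest.raises(ValueError):
            validate_clusters([], [], n_sample=1)


def test_pairwise_identity_known_values():
    assert pairwise_identity("ACGTACGT", "ACGTACGT") == 1.0
    assert pairwise_identity("AAAA", "AAAT") == pytest.approx(0.75)
    # one insertion: 4 matching columns of 5
    assert pairwise_identity("ACGT", "ACGGT") == pytest.approx(4 / 5)


class TestIterateLayers:
    def _small_dataset(self):
        from ltrtrace.align import self_align
        from ltrtrace.simulator import SimConfig, simulate

        cfg = SimConfig(seed=5, n_paths=2, n_generations=2, ancestor_len=3000,
                        founder_svs=6)
        elements, truth = simulate(cfg)
        hits = self_align(elements, seed=5)
        return elements, truth, hits

    def test_max_depth_zero_single_layer(self):
        elements, _, hits = self._small_dataset()
        res = iterate_layers(elements, hits, RunConfig(seed=2, max_depth=0))
        assert all(a.layer == 0 for a in res.assignments)
        assert {a.element_id for a in res.assignments} == {e.element_id for e in elements}

    def test_partition_and_reproducibility(self):
        elements, _, hits = self._small_dataset()
        cfg = RunConfig(seed=2)
        r1 = iterate_layers(elements, hits, cfg)
        r2 = iterate_layers(elements, hits, cfg)
        assert r1.labels_dict() == r2.labels_dict()
        labels = r1.labels_dict()
        assert set(labels) == {e.element_id for e in elements}

    def test_low_confidence_fraction_near_origin(self):
        elements, _, hits = self._small_dataset()
        res = iterate_layers(elements, hits, RunConfig(seed=2, max_depth=0))
        n_low = sum(1 for a in res.assignments if a.confidence == "low")
        # about half the points sit below the origin-proximity quantile
        assert 0.2 <= n_low / len(res.assignments) <= 0.8
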