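"""Candidate cell centre estimation cascade."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from txseg.candidates import (
    cluster_marker_categories,
    cluster_molecules_to_candidates,
    estimate_candidates,
    grid_node_features,
    merge_candidates,
    score_markers,
    select_valid_nodes,
)
from txseg.preprocess import ReferencePanel, TranscriptTable, quantile


def _panel(counts, genes, types):
    counts = np.asarray(counts, dtype=float)
    return ReferencePanel(S=counts, U=counts, cell_type=np.array(types, dtype=object),
                          gene_ids=list(genes), all_genes=list(genes))


class TestScoreMarkers:
    def test_score_formula_and_exclusive_gene(self):
        # gene g0 expressed only in type A -> P = 1 for that type
        counts = [[8, 2], [0, 10]]  # cells x genes; cell0 type A, cell1 type B
        panel = _panel(counts, ["g0", "g1"], ["A", "B"])
        msm = score_markers(panel, p=1)
        assert np.allclose(msm.scores.values,
                           np.log(msm.A.values + 1) * msm.P.values)
        assert msm.P.loc["g0", "A"] == 1.0

    def test_unexpressed_gene_never_selected(self):
        counts = [[5, 0], [7, 0]]
        panel = _panel(counts, ["g0", "gdead"], ["A", "B"])
        msm = score_markers(panel, p=2)
        assert "gdead" not in msm.markers
        assert (msm.scores.loc["gdead"] == 0).all()

    def test_toy_matrix_matches_exhaustive_enumeration(self, rng):
        counts = rng.integers(0, 20, size=(6, 6)).astype(float)
        genes = [f"g{i}" for i in range(6)]
        types = ["A", "A", "A", "B", "B", "B"]
        panel = _panel(counts, genes, types)
        msm = score_markers(panel, p=2)
        # brute force from the returned A/P frames
        S = np.log(msm.A.values + 1) * msm.P.values
        expected = []
        for j, t in enumerate(["A", "B"]):
            order = sorted(range(6), key=lambda i: (-S[i, j], genes[i]))
            expected.extend(genes[i] for i in order[:2] if S[i, j] > 0)
        dedup = list(dict.fromkeys(expected))
        assert msm.markers == dedup


class TestGridNodeFeatures:
    def test_counts_match_all_pairs_oracle(self, rng):
        pts = rng.uniform(0, 40, size=(20, 2))
        genes = rng.choice(["m1", "m2", "other"], size=20)
        table = TranscriptTable(pts[:, 0], pts[:, 1], genes)
        r = 3.0
        F, nodes = grid_node_features(table, ["m1", "m2"], r)
        raw = np.zeros((2, len(nodes)))
        for gi, g in enumerate(["m1", "m2"]):
            sel = pts[genes == g]
            for ni, node in enumerate(nodes):
                raw[gi, ni] = (np.linalg.norm(sel - node, axis=1) < 2 * r / np.pi).sum()
        mu, sd = raw.mean(0), raw.std(0)
        expected = np.where(sd > 0, (raw - mu) / np.where(sd > 0, sd, 1), 0.0)
        assert np.allclose(F, expected)

    def test_no_marker_molecules_is_fatal(self):
        table = TranscriptTable([0.0, 1.0], [0.0, 1.0], ["x", "y"])
        with pytest.raises(ValueError, match="marker"):
            grid_node_features(table, ["absent"], 2.0)


class TestValidNodes:
    def test_stated_quantile_arithmetic(self):
        h = np.arange(1, 101)
        valid = select_valid_nodes(h, q=0.9)
        # cutoff1 = Q(h, .9) * .01 = 0.901; cutoff2 = mean(1..100) = 50.5
        assert quantile(h, 0.9) * 0.01 == pytest.approx(0.901)
        assert valid.sum() == 50
        assert valid[h > 50.5].all()

    def test_all_equal_counts_give_no_valid_nodes(self):
        assert select_valid_nodes(np.full(10, 7.0), 0.9).sum() == 0

    def test_single_node_never_valid(self):
        assert select_valid_nodes(np.array([5.0]), 0.9).sum() == 0


class TestMarkerCategories:
    def test_identical_feature_rows_share_category(self, rng):
        base = rng.normal(size=(1, 30))
        F = np.vstack([base, base, rng.normal(size=(2, 30))])
        A = pd.DataFrame(np.ones((4, 2)), index=list("abcd"), columns=["A", "B"])
        labels, t = cluster_marker_categories(F, A, list("abcd"), c=3)
        assert labels[0] == labels[1]

    def test_m_equals_c_gives_singletons(self, rng):
        F = rng.normal(size=(4, 10))
        A = pd.DataFrame(np.ones((4, 2)), index=list("abcd"), columns=["A", "B"])
        labels, _ = cluster_marker_categories(F, A, list("abcd"), c=4)
        assert len(set(labels)) == 4

    def test_thresholds_match_direct_summation(self, rng):
        F = rng.normal(size=(8, 20))
        A = pd.DataFrame(rng.uniform(0, 5, size=(8, 3)),
                         index=[f"g{i}" for i in range(8)],
                         columns=["A", "B", "C"])
        labels, t = cluster_marker_categories(F, A, list(A.index), c=3)
        for cat in range(3):
            expect = sum(A.loc[g].max() for g, l in zip(A.index, labels) if l == cat)
            assert t[cat] == pytest.approx(expect)

    def test_fewer_markers_than_categories_reduces_c(self, rng):
        F = rng.normal(size=(2, 10))
        A = pd.DataFrame(np.ones((2, 2)), index=["a", "b"], columns=["A", "B"])
        labels, t = cluster_marker_categories(F, A, ["a", "b"], c=5)
        assert len(t) == 2


class TestMoleculeClustering:
    def test_kmeans_split_count_follows_formula(self, rng):
        # one dense blob of h molecules, t_c = max_t -> k = max(1, int(.25 h ln 2))
        h = 40
        pts = rng.normal(0, 1.0, size=(h, 2))
        centers = cluster_molecules_to_candidates(pts, r=5.0, max_t=3.0, t_c=3.0,
                                                  seed=0)
        assert len(centers) == max(1, int(0.25 * h * np.log(2.0)))

    def test_small_groups_clamp_to_single_candidate(self, rng):
        pts = rng.normal(0, 0.5, size=(5, 2))
        centers = cluster_molecules_to_candidates(pts, r=5.0, max_t=3.0, t_c=3.0)
        assert len(centers) == 1
        assert np.allclose(centers[0], pts.mean(axis=0))

    def test_single_molecule_becomes_its_own_candidate(self):
        centers = cluster_molecules_to_candidates(np.array([[2.0, 3.0]]),
                                                  r=5.0, max_t=1.0, t_c=1.0)
        assert np.allclose(centers, [[2.0, 3.0]])

    def test_separated_blobs_yield_centers_near_means(self, rng):
        a = rng.normal(0, 0.5, size=(8, 2))
        b = rng.normal(0, 0.5, size=(8, 2)) + [50.0, 0.0]
        centers = cluster_molecules_to_candidates(np.vstack([a, b]), r=2.0,
                                                  max_t=1.0, t_c=1.0)
        assert len(centers) == 2
        d = cKDTree(centers).query(np.vstack([a.mean(0), b.mean(0)]))[0]
        assert (d < 1.0).all()


class TestMerge:
    def test_duplicates_collapse(self):
        out = merge_candidates(np.array([[1.0, 1.0]] * 5), r=6.5)
        assert len(out) == 1

    def test_distant_centers_survive(self):
        r = 6.5
        out = merge_candidates(np.array([[0.0, 0.0], [100 * r, 0.0]]), r=r)
        assert len(out) == 2

    def test_empty_input_is_fatal(self):
        with pytest.raises(ValueError):
            merge_candidates(np.zeros((0, 2)), r=6.5)


class TestCascade:
    def test_candidate_count_within_factor_two_of_truth(self, tiny_data, tiny_spec):
        table, panel, truth = tiny_data
        cands = estimate_candidates(table, panel, r=tiny_spec.cell_radius,
                                    c=tiny_spec.n_types, seed=0)
        assert tiny_spec.n_cells / 2 <= len(cands) <= tiny_spec.n_cells * 2

    def test_candidates_inside_bounding_box(self, tiny_data, tiny_spec):
        table, panel, _ = tiny_data
        cands = estimate_candidates(table, panel, r=tiny_spec.cell_radius,
                                    c=tiny_spec.n_types, seed=0)
        lo, hi = table.coords.min(0), table.coords.max(0)
        assert (cands.centers >= lo - 1e-9).all()
        assert (cands.centers <= hi + 1e-9).all()

    def test_translation_equivariance(self, tiny_data, tiny_spec):
        table, panel, _ = tiny_data
        shift = np.array([123.0, -45.0])
        moved = TranscriptTable(table.x + shift[0], table.y + shift[1],
                                table.raw_gene, table.gene_code, table.nds)
        c1 = estimate_candidates(table, panel, r=tiny_spec.cell_radius,
                                 c=tiny_spec.n_types, seed=0)
        c2 = estimate_candidates(moved, panel, r=tiny_spec.cell_radius,
                                 c=tiny_spec.n_types, seed=0)
        assert len(c1) == len(c2)
        a = c1.centers[np.lexsort(c1.centers.T)]
        b = c2.centers[np.lexsort(c2.centers.T)] - shift
        assert np.allclose(a, b, atol=1e-6)
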