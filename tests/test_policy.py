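"""Segmentation policy: probabilities, sampling, scores, rewards, loss."""

import numpy as np
import pytest

from txseg.autodiff import Var
from txseg.candidates import CandidateSet
from txseg.policy import (
    NOISE,
    NON_NOISE,
    PolicyParameters,
    assignment_probabilities,
    center_distance_scores,
    compute_rewards,
    nearest_candidate_cells,
    noise_probabilities,
    region_loss,
    sample_assignments,
)
from txseg.preprocess import TranscriptTable, quantile


def _table(n, rng, k=3):
    pts = rng.uniform(0, 50, size=(n, 2))
    t = TranscriptTable(pts[:, 0], pts[:, 1], ["g"] * n)
    t.gene_code = rng.integers(1, k + 1, size=n)
    t.nds = rng.uniform(0, 1, size=n)
    return t


def _policy(n_cand, k, nds, rng, **kw):
    return PolicyParameters(n_cand, k, nds, rng=rng, **kw)


class TestNearestCandidates:
    def test_single_candidate_takes_all(self, rng):
        t = _table(10, rng)
        cands = CandidateSet(np.array([[25.0, 25.0]]))
        nb = nearest_candidate_cells(t, cands, m=1)
        assert (nb == 0).all()

    def test_matches_exhaustive_distance_sort(self, rng):
        t = _table(50, rng)
        centers = rng.uniform(0, 50, size=(10, 2))
        nb = nearest_candidate_cells(t, CandidateSet(centers), m=4)
        d = np.linalg.norm(t.coords[:, None] - centers[None], axis=2)
        expect = np.argsort(d, axis=1, kind="stable")[:, :4]
        assert np.array_equal(nb, expect)

    def test_m_lowered_when_few_candidates(self, rng):
        t = _table(5, rng)
        nb = nearest_candidate_cells(t, CandidateSet(rng.uniform(0, 50, (3, 2))), m=8)
        assert nb.shape == (5, 3)


class TestAssignmentProbabilities:
    def test_single_neighbor_gets_probability_one(self, rng):
        t = _table(6, rng)
        pol = _policy(1, 3, t.nds, rng)
        nb = np.zeros((6, 1), dtype=int)
        c_prob, _ = assignment_probabilities(pol, t, nb, np.array([[25.0, 25.0]]))
        assert np.allclose(c_prob, 1.0)

    def test_zeroed_final_affine_gives_uniform_rows(self, rng):
        t = _table(7, rng)
        centers = rng.uniform(0, 50, size=(5, 2))
        pol = _policy(5, 3, t.nds, rng)
        pol.fus_W3.data[:] = 0.0
        pol.fus_b3.data[:] = 0.0
        nb = nearest_candidate_cells(t, CandidateSet(centers), m=4)
        c_prob, _ = assignment_probabilities(pol, t, nb, centers)
        assert np.allclose(c_prob, 0.25)

    def test_rows_are_simplexes(self, rng):
        t = _table(20, rng)
        centers = rng.uniform(0, 50, size=(6, 2))
        pol = _policy(6, 3, t.nds, rng)
        nb = nearest_candidate_cells(t, CandidateSet(centers), m=5)
        c_prob, _ = assignment_probabilities(pol, t, nb, centers)
        assert np.allclose(c_prob.sum(axis=1), 1.0, atol=1e-6)
        assert (c_prob >= 0).all()

    def test_translation_equivariance(self, rng):
        t = _table(15, rng)
        centers = rng.uniform(0, 50, size=(6, 2))
        pol = _policy(6, 3, t.nds, rng)
        nb = nearest_candidate_cells(t, CandidateSet(centers), m=4)
        p1, _ = assignment_probabilities(pol, t, nb, centers)
        shift = np.array([300.0, -200.0])
        moved = TranscriptTable(t.x + shift[0], t.y + shift[1], t.raw_gene,
                                t.gene_code, t.nds)
        p2, _ = assignment_probabilities(pol, moved, nb, centers + shift)
        assert np.allclose(p1, p2, atol=1e-12)


class TestNoiseHead:
    def test_half_nds_initialises_even_odds(self, rng):
        nds = np.full(4, 0.5)
        pol = _policy(3, 2, nds, rng)
        n_prob, _ = noise_probabilities(pol)
        assert np.allclose(n_prob, 0.5)

    def test_high_nds_softmax_value(self, rng):
        pol = _policy(3, 2, np.array([0.9]), rng)
        n_prob, _ = noise_probabilities(pol)
        # softmax(0.1, 0.9) = (0.31, 0.69) to 2 dp
        assert n_prob[0].round(2).tolist() == [0.31, 0.69]
        assert n_prob.sum(axis=1) == pytest.approx(1.0)


class TestSampling:
    def test_degenerate_row_is_deterministic(self, rng):
        c = np.tile([1.0, 0.0, 0.0], (20, 1))
        n = np.tile([0.0, 1.0], (20, 1))
        G, H = sample_assignments(c, n, rng)
        assert (G == 0).all() and (H == NON_NOISE).all()

    def test_fixed_seed_reproducible(self):
        c = np.tile([0.2, 0.3, 0.5], (50, 1))
        n = np.tile([0.4, 0.6], (50, 1))
        g1, h1 = sample_assignments(c, n, np.random.default_rng(7))
        g2, h2 = sample_assignments(c, n, np.random.default_rng(7))
        assert np.array_equal(g1, g2) and np.array_equal(h1, h2)

    def test_empirical_frequencies_match_binomial(self):
        n = 100_000
        c = np.tile([0.3, 0.7], (n, 1))
        G, _ = sample_assignments(c, np.tile([0.5, 0.5], (n, 1)),
                                  np.random.default_rng(0))
        p_hat = (G == 1).mean()
        sd = np.sqrt(0.3 * 0.7 / n)
        assert abs(p_hat - 0.7) < 3 * sd


class TestCenterDistanceScores:
    def test_molecule_at_center_scores_one(self, rng):
        coords = rng.uniform(0, 10, size=(30, 2))
        centers = coords.copy()
        centers[1:] += rng.uniform(1, 5, size=(29, 2))
        cds = center_distance_scores(coords, centers, q=0.9)
        assert cds[0] == 1.0

    def test_beyond_quantile_scores_zero(self):
        coords = np.zeros((10, 2))
        centers = np.column_stack([np.arange(10.0), np.zeros(10)])
        cds = center_distance_scores(coords, centers, q=0.5)
        Q = quantile(np.arange(10.0), 0.5)
        assert (cds[np.arange(10.0) >= Q] == 0).all()

    def test_stated_quantile_arithmetic(self):
        g = np.arange(1.0, 101.0)
        coords = np.zeros((100, 2))
        centers = np.column_stack([g, np.zeros(100)])
        cds = center_distance_scores(coords, centers, q=0.999)
        Q = quantile(g, 0.999)
        assert Q == pytest.approx(99.901)
        assert cds[49] == pytest.approx(1 - 50.0 / Q)

    def test_coincident_batch_scores_one(self):
        coords = np.ones((5, 2))
        cds = center_distance_scores(coords, coords, q=0.999)
        assert (cds == 1.0).all()


class TestRewards:
    def test_printed_orientation_examples(self):
        # dense molecule assigned non-noise earns nothing under the
        # printed branch order
        r = compute_rewards(np.array([1.0]), np.array([0.8]), np.array([0.9]),
                            np.array([NON_NOISE]), orientation="density")
        assert r[0] == 0.0
        r = compute_rewards(np.array([0.0]), np.array([1.0]), np.array([1.0]),
                            np.array([NON_NOISE]), orientation="density")
        assert r[0] == 1.0
        r = compute_rewards(np.array([0.4]), np.array([0.5]), np.array([0.5]),
                            np.array([NOISE]), orientation="density")
        assert r[0] == pytest.approx(0.1)

    def test_default_orientation_rewards_isolated_noise_calls(self):
        nds = np.array([0.1, 0.9])
        r_noise = compute_rewards(nds, np.ones(2), np.ones(2),
                                  np.array([NOISE, NOISE]))
        assert r_noise[0] > r_noise[1]  # isolated molecule: noise call pays
        r_cell = compute_rewards(nds, np.ones(2), np.ones(2),
                                 np.array([NON_NOISE, NON_NOISE]))
        assert r_cell[1] > r_cell[0]  # dense molecule: assignment pays

    def test_orientations_are_mirror_images(self, rng):
        nds, cds, ess = rng.uniform(0, 1, (3, 6))
        H = rng.integers(0, 2, 6)
        a = compute_rewards(nds, cds, ess, H, "isolation")
        b = compute_rewards(nds, cds, ess, 1 - H, "density")
        assert np.allclose(a, b)


class TestRegionLoss:
    def test_zero_rewards_give_zero_loss(self, rng):
        c = rng.dirichlet(np.ones(3), size=4)
        n = rng.dirichlet(np.ones(2), size=4)
        loss = region_loss(np.zeros(4), c, n, np.zeros(4, int), np.zeros(4, int))
        assert float(loss.data) == 0.0

    def test_deterministic_policy_gives_zero_loss(self):
        c = np.tile([1.0, 0.0], (3, 1))
        n = np.tile([0.0, 1.0], (3, 1))
        loss = region_loss(np.ones(3), c, n, np.zeros(3, int), np.ones(3, int))
        assert float(loss.data) == pytest.approx(0.0)

    def test_closed_form_single_molecule(self):
        loss = region_loss(np.array([1.0]), np.array([[0.5, 0.5]]),
                           np.array([[0.5, 0.5]]), np.array([0]), np.array([0]))
        assert float(loss.data) == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        """Full policy graph (n=3, m=3) against central differences."""
        t = _table(3, rng)
        centers = rng.uniform(0, 50, size=(4, 2))
        pol = _policy(4, 3, t.nds, rng)
        nb = nearest_candidate_cells(t, CandidateSet(centers), m=3)
        G = np.array([0, 2, 1])
        H = np.array([0, 1, 1])
        reward = rng.uniform(0, 1, 3)

        def build():
            _, logits = assignment_probabilities(pol, t, nb, centers)
            c_prob = logits.log_softmax(axis=-1).exp()
            n_prob = pol.noise_logits(np.arange(3)).log_softmax(axis=-1).exp()
            return region_loss(reward, c_prob, n_prob, G, H)

        loss = build()
        loss.backward()
        for p in pol.all_params:
            if p.grad is None:
                continue
            grad = p.grad.copy()
            num = np.zeros_like(p.data)
            it = np.nditer(p.data, flags=["multi_index"])
            eps = 1e-6
            while not it.finished:
                i = it.multi_index
                p.data[i] += eps
                fp = float(build().data)
                p.data[i] -= 2 * eps
                fm = float(build().data)
                p.data[i] += eps
                num[i] = (fp - fm) / (2 * eps)
                it.iternext()
            denom = max(np.abs(num).max(), 1e-8)
            assert np.abs(grad - num).max() / denom < 1e-4
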