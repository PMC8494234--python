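"""Collapsed Gibbs LDA: oracle equivalence, conservation, recovery, IO."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from conftest import collapsed_posterior_enumeration
from scitopic.lda import (
    LatentDirichletAllocationGibbs,
    LDAConfig,
    LDAModel,
    export_bow,
    fit_lda,
    import_bow,
    predict_theta,
)
from scitopic.matrix import CellsByPeaksMatrix
from scitopic.synthetic import DESK_PRESET, simulate_matrix


class TestFitBasics:
    def test_k1_theta_is_all_ones_and_phi_is_smoothed_frequencies(self, tiny_corpus):
        model = fit_lda(
            tiny_corpus,
            LDAConfig(n_topics=1, alpha=1.0, beta=1.0, iterations=50,
                      sample_stride=5, seed=0),
        )
        np.testing.assert_allclose(model.theta, np.ones((2, 1)))
        V = 4
        expected_phi = (np.ones(4) + 1.0 / V) / (4 + 1.0)
        np.testing.assert_allclose(model.phi[0], expected_phi)

    def test_doc_topic_counts_conserve_tokens(self):
        m, _ = simulate_matrix(n_cells=60, n_types=3, peaks_per_type=8,
                               shared_peaks=2, detect_rate_specific=0.6,
                               detect_rate_background=0.05, seed=1)
        model = fit_lda(m, LDAConfig(n_topics=4, beta=5.0, iterations=200,
                                     sample_stride=10, seed=2))
        np.testing.assert_array_equal(
            model.doc_topic.sum(axis=1), np.asarray(m.matrix.sum(axis=1)).ravel()
        )
        assert model.doc_topic.sum() == model.word_topic.sum() == m.matrix.nnz

    def test_theta_and_phi_rows_normalized(self):
        m, _ = simulate_matrix(n_cells=50, n_types=2, peaks_per_type=10,
                               shared_peaks=0, detect_rate_specific=0.5,
                               detect_rate_background=0.05, seed=3)
        model = fit_lda(m, LDAConfig(n_topics=3, beta=5.0, iterations=200,
                                     sample_stride=10, seed=4))
        np.testing.assert_allclose(model.theta.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(model.phi.sum(axis=1), 1.0, atol=1e-9)

    def test_single_worker_runs_are_bit_reproducible(self, tiny_corpus):
        cfg = LDAConfig(n_topics=2, iterations=100, sample_stride=10, seed=7)
        a = fit_lda(tiny_corpus, cfg)
        b = fit_lda(tiny_corpus, cfg)
        np.testing.assert_array_equal(a.assignments, b.assignments)
        np.testing.assert_allclose(a.theta, b.theta)

    def test_zero_token_cell_rejected(self):
        m = CellsByPeaksMatrix(
            sp.csr_matrix(np.array([[1, 1], [0, 0]], dtype=np.int8)),
            pd.Index(["a", "b"]), pd.Index(["p", "q"]),
        )
        with pytest.raises(ValueError, match="zero tokens"):
            fit_lda(m, LDAConfig(n_topics=2, iterations=20, sample_stride=5))

    def test_k_above_vocabulary_warns(self, tiny_corpus):
        with pytest.warns(UserWarning, match="vocabulary"):
            fit_lda(tiny_corpus, LDAConfig(n_topics=9, iterations=20, sample_stride=5))


class TestOracleEquivalence:
    def test_co_assignment_matches_enumeration(self, tiny_corpus):
        """Label-invariant posterior statistics agree with brute force.

        P(z_i == z_j) is invariant to topic relabeling, so it checks the
        sampler against the enumerated collapsed posterior much more
        sharply than per-token marginals (which are 1/K by symmetry).
        """
        alpha = beta = 1.0
        doc = np.array([0, 0, 1, 1])
        word = np.array([0, 1, 2, 3])
        _, co_exact = collapsed_posterior_enumeration(doc, word, 2, 4, 2, alpha, beta)

        from scitopic._gibbs import gibbs_train

        K = 2
        a, b_v, b_tot = alpha / K, beta / 4, beta
        rng = np.random.default_rng(0)
        z = rng.integers(0, K, 4).astype(np.int64)
        n_dk = np.zeros((2, K), dtype=np.int64)
        n_wk = np.zeros((4, K), dtype=np.int64)
        np.add.at(n_dk, (doc, z), 1)
        np.add.at(n_wk, (word, z), 1)
        n_k = n_wk.sum(axis=0)
        dummy = np.zeros((1, K), dtype=np.int64)
        co = np.zeros((4, 4))
        n_sweeps, burn = 20000, 2000
        for s in range(n_sweeps):
            gibbs_train(doc, word, z, n_dk, n_wk, n_k, a, b_v, float(b_tot),
                        1, 2, 1, s + 1, dummy, dummy, dummy, False)
            if s >= burn:
                co += z[:, None] == z[None, :]
        co /= n_sweeps - burn
        assert np.abs(co - co_exact).max() < 0.03

    def test_assignment_frequencies_match_enumeration(self, tiny_corpus):
        marg, _ = collapsed_posterior_enumeration(
            np.array([0, 0, 1, 1]), np.array([0, 1, 2, 3]), 2, 4, 2, 1.0, 1.0
        )
        est = LatentDirichletAllocationGibbs(
            n_topics=2, alpha=1.0, beta=1.0, iterations=20000, burn_in=2000,
            sample_stride=1, seed=5, track_assignments=True,
        ).fit(tiny_corpus)
        tv = 0.5 * np.abs(est.assignment_freq_ - marg).sum(axis=1)
        assert tv.max() <= 0.05


class TestParameterRecovery:
    def test_planted_five_type_recovery(self):
        m, truth = simulate_matrix(seed=42, **DESK_PRESET)
        model = fit_lda(m, LDAConfig(n_topics=8, iterations=1500,
                                     sample_stride=25, seed=0))
        ari = adjusted_rand_score(truth.cell_types, model.theta.argmax(axis=1))
        assert ari >= 0.9


@pytest.fixture(scope="module")
def trained():
    m, truth = simulate_matrix(n_cells=200, n_types=4, peaks_per_type=30,
                               shared_peaks=0, detect_rate_specific=0.5,
                               detect_rate_background=0.01, seed=3)
    model = fit_lda(m, LDAConfig(n_topics=4, beta=10.0, iterations=600,
                                 sample_stride=20, seed=1))
    return m, truth, model


class TestPredictTheta:
    def test_training_cell_concentrates_on_its_block_topic(self, trained):
        m, truth, model = trained
        new = CellsByPeaksMatrix(m.matrix[:6], pd.Index([f"n{i}" for i in range(6)]),
                                 m.peaks)
        theta = predict_theta(model, new, iterations=500, seed=9)
        assert (theta.max(axis=1) > 0.6).all()
        # the predicted dominant topic matches the training row's
        np.testing.assert_array_equal(
            theta.argmax(axis=1), model.theta[:6].argmax(axis=1)
        )

    def test_permuting_cells_permutes_theta_rows(self, trained):
        m, _, model = trained
        ids = pd.Index([f"n{i}" for i in range(8)])
        new = CellsByPeaksMatrix(m.matrix[:8], ids, m.peaks)
        perm = np.array([5, 2, 7, 0, 1, 6, 3, 4])
        permuted = CellsByPeaksMatrix(m.matrix[:8][perm], ids[perm], m.peaks)
        a = predict_theta(model, new, iterations=300, seed=4)
        b = predict_theta(model, permuted, iterations=300, seed=4)
        np.testing.assert_allclose(b, a[perm])

    def test_uniform_phi_gives_prior_mean(self, trained):
        import dataclasses

        m, _, model = trained
        flat = dataclasses.replace(
            model, phi=np.full_like(model.phi, 1.0 / model.phi.shape[1])
        )
        new = CellsByPeaksMatrix(m.matrix[:40], pd.Index([f"n{i}" for i in range(40)]),
                                 m.peaks)
        theta = predict_theta(flat, new, iterations=400, seed=2)
        np.testing.assert_allclose(theta.mean(axis=0), 0.25, atol=0.04)

    def test_empty_new_cell_set(self, trained):
        _, _, model = trained
        empty = sp.csr_matrix((0, model.phi.shape[1]))
        assert predict_theta(model, empty, iterations=50, seed=1).shape == (0, 4)

    def test_cell_without_vocabulary_tokens_gets_prior_row(self, trained):
        _, _, model = trained
        x = sp.csr_matrix((1, model.phi.shape[1]))
        with pytest.warns(UserWarning, match="no in-vocabulary"):
            theta = predict_theta(model, x, iterations=50, seed=1)
        np.testing.assert_allclose(theta[0], 0.25)


class TestParallelContract:
    def test_parallel_run_matches_serial_heldout_perplexity(self):
        from scitopic.model_selection import heldout_loglik_chib

        m, _ = simulate_matrix(n_cells=240, n_types=3, peaks_per_type=30,
                               shared_peaks=0, detect_rate_specific=0.4,
                               detect_rate_background=0.02, seed=8)
        train, test = m.matrix[:200], m.matrix[200:]
        perp = {}
        for workers in (1, 4):
            est = LatentDirichletAllocationGibbs(
                n_topics=3, beta=10.0, iterations=400, sample_stride=20,
                seed=2, n_workers=workers,
            ).fit(train)
            vals = []
            for i in range(test.shape[0]):
                toks = test.indices[test.indptr[i]: test.indptr[i + 1]]
                vals.append(
                    heldout_loglik_chib(est.phi_, toks, 3.0, iterations=600,
                                        seed=100 + i).perplexity
                )
            perp[workers] = np.mean(vals)
        assert abs(perp[1] - perp[4]) / perp[1] < 0.02


class TestBowIO:
    def test_round_trip(self, tiny_corpus, tmp_path):
        p = tmp_path / "corpus.bow"
        export_bow(tiny_corpus, p)
        back = import_bow(p)
        assert (tiny_corpus.matrix != back.matrix).nnz == 0

    def test_empty_matrix_rejected(self, tmp_path):
        empty = CellsByPeaksMatrix(
            sp.csr_matrix((2, 3), dtype=np.int8), pd.Index(["a", "b"]),
            pd.Index(["p", "q", "r"]),
        )
        with pytest.raises(ValueError):
            export_bow(empty, tmp_path / "x.bow")

    def test_duplicate_entries_collapse_with_warning(self, tmp_path):
        p = tmp_path / "dup.bow"
        p.write_text("1\n3\n3\n3 0:1 0:1 2:1\n")
        with pytest.warns(UserWarning, match="duplicate"):
            m = import_bow(p)
        assert m.matrix.toarray().tolist() == [[1, 0, 1]]

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.bow"
        p.write_text("1\n3\n2\n2 0:1 nope\n")
        with pytest.raises(ValueError, match=":4"):
            import_bow(p)


def test_model_checkpoint_round_trip(tmp_path, tiny_corpus):
    model = fit_lda(tiny_corpus, LDAConfig(n_topics=2, iterations=60,
                                           sample_stride=10, seed=1))
    model.save(tmp_path / "model")
    back = LDAModel.load(tmp_path / "model")
    np.testing.assert_allclose(back.theta, model.theta)
    np.testing.assert_allclose(back.phi, model.phi)
    assert back.config.n_topics == 2
    assert list(back.cells) == list(model.cells)
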