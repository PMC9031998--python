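"""Unit tests for the scoring pipeline stages."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from epochscore.core import (
    DegenerateSpectrumError,
    PSDSet,
    Recording,
    WelchConfig,
    aggregate_scores,
    channel_score_vector,
    rank_epochs,
    score_epochs,
    segment_recording,
    spearman_similarity,
    welch_psd,
)

from conftest import oracle_spearman


class TestRecording:
    def test_rejects_nonfinite(self):
        data = np.zeros((2, 10))
        data[1, 3] = np.nan
        with pytest.raises(ValueError, match="channel 1, sample 3"):
            Recording(data=data, fs=100.0)

    def test_rejects_bad_fs(self):
        with pytest.raises(ValueError, match="sampling rate"):
            Recording(data=np.zeros((1, 10)), fs=0.0)

    def test_rejects_duplicate_labels(self):
        with pytest.raises(ValueError, match="unique"):
            Recording(data=np.zeros((2, 10)), fs=1.0, channel_labels=("x", "x"))

    def test_synthesizes_labels(self):
        rec = Recording(data=np.zeros((2, 10)), fs=1.0)
        assert rec.channel_labels == ("ch0", "ch1")


class TestSegmentRecording:
    def test_paper_layout_twelve_epochs(self):
        # 60 s at 160 Hz with 5 s epochs -> 12 epochs of 800 samples
        rec = Recording(data=np.zeros((2, 9600)), fs=160.0)
        epochs = segment_recording(rec, 5.0)
        assert epochs.n_epochs == 12
        assert epochs.samples_per_epoch == 800

    def test_remainder_discarded(self):
        rec = Recording(data=np.zeros((1, 9600)), fs=160.0)
        epochs = segment_recording(rec, 8.0)
        assert epochs.n_epochs == 7  # floor(60 / 8); 4 s dropped

    def test_single_epoch_identity(self):
        rec = Recording(
            data=np.arange(800, dtype=float).reshape(1, 800), fs=160.0
        )
        epochs = segment_recording(rec, 5.0)
        assert epochs.n_epochs == 1
        assert epochs.source_offsets[0] == 0
        np.testing.assert_array_equal(epochs.data[0, 0], rec.data[0])

    def test_verbatim_slices(self, small_recording):
        epochs = segment_recording(small_recording, 2.0)
        for e in range(epochs.n_epochs):
            np.testing.assert_array_equal(
                epochs.data[e], small_recording.data[:, e * 200 : (e + 1) * 200]
            )

    def test_offsets_contiguous(self, small_recording):
        epochs = segment_recording(small_recording, 1.0)
        np.testing.assert_array_equal(
            epochs.source_offsets, np.arange(8) * 100
        )

    def test_too_short_error_names_sizes(self):
        rec = Recording(data=np.zeros((1, 100)), fs=100.0)
        with pytest.raises(ValueError, match="160 samples.*100"):
            segment_recording(rec, 1.6)


class TestWelchPsd:
    def test_tone_peak_at_tone_frequency(self):
        t = np.arange(1600) / 160.0
        rec = Recording(data=np.sin(2 * np.pi * 10 * t)[None, :], fs=160.0)
        psds = welch_psd(segment_recording(rec, 5.0), (1.0, 40.0))
        for e in range(psds.n_epochs):
            peak = psds.freqs[np.argmax(psds.psd[e, 0])]
            assert peak == psds.freqs[np.argmin(np.abs(psds.freqs - 10.0))]

    def test_dc_signal_near_zero_in_band(self):
        rec = Recording(data=np.full((1, 1600), 7.0), fs=160.0)
        psds = welch_psd(segment_recording(rec, 5.0), (1.0, 40.0))
        assert np.all(psds.psd < 1e-20)

    def test_white_noise_flat_level(self):
        # mean PSD of unit-variance white noise ~ sigma^2 / (fs/2) per Hz
        rng = np.random.default_rng(77)
        fs, n_epochs, spe = 200.0, 100, 400
        data = rng.standard_normal((1, n_epochs * spe))
        rec = Recording(data=data, fs=fs)
        # start at 2 Hz: the constant-detrend bites the DC-adjacent bin
        psds = welch_psd(segment_recording(rec, spe / fs), (2.0, 90.0))
        level = 1.0 / (fs / 2.0)
        mean_psd = psds.psd[:, 0, :].mean(axis=0)
        sem = psds.psd[:, 0, :].std(axis=0, ddof=1) / np.sqrt(n_epochs)
        # band average within 3 standard errors of the analytic flat level
        band_sem = sem.mean() / np.sqrt(len(sem))
        assert abs(mean_psd.mean() - level) < 3 * band_sem
        # each bin within a multiple-comparison-aware envelope
        assert np.all(np.abs(mean_psd - level) < 4.5 * sem)

    def test_grid_restricted_and_shared(self, small_recording):
        psds = welch_psd(segment_recording(small_recording, 2.0), (4.0, 30.0))
        assert psds.freqs[0] >= 4.0 and psds.freqs[-1] <= 30.0
        assert np.all(np.diff(psds.freqs) > 0)
        assert psds.psd.shape == (4, 3, len(psds.freqs))

    def test_fmax_beyond_nyquist_errors(self, small_recording):
        epochs = segment_recording(small_recording, 2.0)
        with pytest.raises(ValueError, match="Nyquist"):
            welch_psd(epochs, (1.0, 60.0))

    def test_explicit_overlong_window_errors(self, small_recording):
        epochs = segment_recording(small_recording, 1.0)
        with pytest.raises(ValueError, match="exceeds"):
            welch_psd(epochs, (1.0, 40.0), WelchConfig(window_s=3.0))

    def test_default_window_clips_to_short_epochs(self, small_recording):
        epochs = segment_recording(small_recording, 0.5)
        psds = welch_psd(epochs, (4.0, 40.0))
        assert psds.n_epochs == 16


def _psdset(psd):
    psd = np.asarray(psd, dtype=float)
    freqs = np.arange(1.0, 1.0 + psd.shape[2])
    return PSDSet(psd=psd, freqs=freqs, freq_range=(freqs[0], freqs[-1]))


class TestSpearmanSimilarity:
    def test_monotone_transform_gives_one(self):
        base = np.array([0.5, 1.0, 3.0, 2.0, 7.0])
        psd = np.stack([base, np.exp(base)])[:, None, :]
        sim = spearman_similarity(_psdset(psd), 0)
        assert sim[0, 1] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        psd = np.stack([[1.0, 2, 3, 4], [9.0, 6, 4, 1]])[:, None, :]
        sim = spearman_similarity(_psdset(psd), 0)
        assert sim[0, 1] == pytest.approx(-1.0)

    def test_midrank_ties_match_bruteforce_oracle(self):
        x = [1.0, 2.0, 2.0, 4.0]
        y = [3.0, 1.0, 1.0, 2.0]
        psd = np.stack([x, y])[:, None, :]
        sim = spearman_similarity(_psdset(psd), 0)
        assert sim[0, 1] == pytest.approx(oracle_spearman(x, y), abs=1e-12)
        # and scipy agrees
        assert sim[0, 1] == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)

    def test_symmetric_unit_diagonal(self, rng):
        psd = rng.random((6, 2, 33))
        sim = spearman_similarity(_psdset(psd), 1)
        np.testing.assert_allclose(sim, sim.T, atol=1e-14)
        np.testing.assert_array_equal(np.diag(sim), np.ones(6))
        assert np.all(sim >= -1) and np.all(sim <= 1)

    def test_constant_spectrum_raises_named_error(self, rng):
        psd = rng.random((3, 2, 8))
        psd[2, 1, :] = 0.4
        with pytest.raises(DegenerateSpectrumError, match="epoch 2.*channel 1"):
            spearman_similarity(_psdset(psd), 1)

    def test_random_pairs_match_oracle(self, rng):
        psd = rng.random((5, 1, 17))
        sim = spearman_similarity(_psdset(psd), 0)
        for i in range(5):
            for j in range(5):
                expected = 1.0 if i == j else oracle_spearman(psd[i, 0], psd[j, 0])
                assert sim[i, j] == pytest.approx(expected, abs=1e-12)


class TestChannelScoreVector:
    def test_all_ones(self):
        vec = channel_score_vector(np.ones((12, 12)))
        np.testing.assert_array_equal(vec, np.ones(12))

    def test_two_epoch_closed_form(self):
        rho = 0.42
        sim = np.array([[1.0, rho], [rho, 1.0]])
        np.testing.assert_allclose(
            channel_score_vector(sim), [(1 + rho) / 2] * 2
        )

    def test_diagonal_convention_does_not_change_order(self, rng):
        n = 6
        m = rng.uniform(-1, 1, (n, n))
        sim = (m + m.T) / 2
        np.fill_diagonal(sim, 1.0)
        with_diag = channel_score_vector(sim)
        without_diag = (sim.sum(axis=1) - 1.0) / (n - 1)
        np.testing.assert_array_equal(
            np.argsort(-with_diag, kind="stable"),
            np.argsort(-without_diag, kind="stable"),
        )
        # affine relation between the two conventions
        np.testing.assert_allclose(with_diag, ((n - 1) * without_diag + 1) / n)

    def test_non_square_errors(self):
        with pytest.raises(ValueError, match="square"):
            channel_score_vector(np.ones((3, 4)))


class TestAggregateScores:
    def test_single_channel_identity(self, rng):
        v = rng.random((1, 7))
        np.testing.assert_array_equal(aggregate_scores(v), v[0])

    def test_opposite_channels_cancel(self, rng):
        v = rng.random(7)
        out = aggregate_scores(np.stack([v, -v]))
        np.testing.assert_allclose(out, np.zeros(7), atol=1e-15)

    def test_duplicated_channel_idempotent(self, rng):
        v = rng.random(7)
        np.testing.assert_allclose(
            aggregate_scores(np.stack([v, v])), aggregate_scores(v[None, :])
        )


class TestRankEpochs:
    def test_basic_descending(self):
        np.testing.assert_array_equal(
            rank_epochs([0.2, 0.9, 0.5]), [1, 2, 0]
        )

    def test_ties_identity(self):
        np.testing.assert_array_equal(
            rank_epochs(np.full(5, 0.3)), np.arange(5)
        )

    def test_top4_matches_bruteforce(self, rng):
        scores = rng.random(12)
        ranking = rank_epochs(scores)
        best = max(
            __import__("itertools").combinations(range(12), 4),
            key=lambda combo: sum(scores[i] for i in combo),
        )
        assert set(ranking[:4]) == set(best)

    def test_nonfinite_errors(self):
        with pytest.raises(ValueError, match="non-finite score at epoch 1"):
            rank_epochs([0.1, np.nan, 0.2])


class TestScoreEpochs:
    def test_tiled_recording_scores_exactly_one(self, tiled_recording):
        result = score_epochs(tiled_recording, 5.0)
        np.testing.assert_array_equal(result.scores, np.ones(12))
        np.testing.assert_array_equal(result.ranking, np.arange(12))

    def test_per_channel_scaling_bit_identical(self, small_recording):
        base = score_epochs(small_recording, 2.0, (1.0, 40.0))
        scaled = Recording(
            data=small_recording.data * np.array([[2.0], [0.5], [13.0]]),
            fs=small_recording.fs,
            channel_labels=small_recording.channel_labels,
        )
        result = score_epochs(scaled, 2.0, (1.0, 40.0))
        np.testing.assert_array_equal(result.scores, base.scores)

    def test_intermediates_shapes(self, small_recording):
        result = score_epochs(small_recording, 2.0)
        assert result.similarity.shape == (3, 4, 4)
        assert result.score_vectors.shape == (3, 4)
        assert result.scores.shape == (4,)
        assert sorted(result.ranking) == [0, 1, 2, 3]

    def test_score_vectors_are_row_means(self, small_recording):
        result = score_epochs(small_recording, 2.0)
        np.testing.assert_allclose(
            result.score_vectors, result.similarity.mean(axis=2)
        )
        np.testing.assert_allclose(
            result.scores, result.score_vectors.mean(axis=0)
        )

    def test_error_tagged_with_stage(self):
        rec = Recording(data=np.zeros((1, 800)) + 3.0, fs=160.0)
        with pytest.raises(Exception) as exc_info:
            score_epochs(rec, 5.0)
        notes = getattr(exc_info.value, "__notes__", [])
        assert any("failing stage" in n for n in notes)

    def test_top_k_bounds(self, small_recording):
        result = score_epochs(small_recording, 2.0)
        assert len(result.top_k(2)) == 2
        with pytest.raises(ValueError):
            result.top_k(99)
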