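"""Per-epoch spectral self-similarity scoring.

The scorer segments a continuous multichannel recording into fixed-length,
non-overlapping epochs, estimates one Welch power spectrum per (epoch,
channel), correlates the spectra of every epoch pair within each channel
using Spearman's rank correlation, and averages twice (over epochs, then
over channels) to obtain a single quality score per epoch.  High scores
mark epochs whose spectral content resembles the rest of the recording;
artifact-laden epochs stand out with low scores.

No filtering, detrending, or re-referencing happens here: the scorer sees
the samples exactly as provided by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.stats import rankdata

__all__ = [
    "Recording",
    "EpochTensor",
    "PSDSet",
    "ScoreResult",
    "WelchConfig",
    "DegenerateSpectrumError",
    "segment_recording",
    "welch_psd",
    "spearman_similarity",
    "channel_score_vector",
    "aggregate_scores",
    "rank_epochs",
    "score_epochs",
]

DEFAULT_FREQ_RANGE = (1.0, 40.0)


class DegenerateSpectrumError(ValueError):
    """A constant PSD vector has zero rank variance: Spearman correlation
    against it is undefined."""

    def __init__(self, epoch: int, channel: int):
        self.epoch = epoch
        self.channel = channel
        super().__init__(
            f"constant power spectrum in epoch {epoch} (channel {channel}): "
            "Spearman similarity is undefined for a zero-variance spectrum"
        )


@dataclass(frozen=True)
class Recording:
    """Continuous multichannel signal.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` float array, amplitude in µV.
    fs
        Sampling rate in Hz, strictly positive.
    channel_labels
        Unique, non-empty label per channel.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got ndim={data.ndim}")
        if data.shape[0] < 1 or data.shape[1] < 1:
            raise ValueError(f"need at least 1 channel and 1 sample, got shape {data.shape}")
        if not np.isfinite(data).all():
            bad = np.argwhere(~np.isfinite(data))[0]
            raise ValueError(
                f"non-finite value at channel {bad[0]}, sample {bad[1]}"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be > 0, got {self.fs}")
        labels = tuple(self.channel_labels) or tuple(
            f"ch{i}" for i in range(data.shape[0])
        )
        if len(labels) != data.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for {data.shape[0]} channels"
            )
        if len(set(labels)) != len(labels) or any(not l for l in labels):
            raise ValueError("channel labels must be unique and non-empty")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_labels", labels)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class EpochTensor:
    """Non-overlapping segmentation of a :class:`Recording`.

    ``data`` has shape ``(n_epochs, n_channels, samples_per_epoch)``;
    ``source_offsets[i]`` is the start sample of epoch ``i`` in the parent
    recording (always ``i * samples_per_epoch`` here).
    """

    data: np.ndarray
    epoch_length_s: float
    fs: float
    source_offsets: np.ndarray

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def samples_per_epoch(self) -> int:
        return self.data.shape[2]


@dataclass(frozen=True)
class PSDSet:
    """Welch power spectral densities on a shared frequency grid.

    ``psd`` has shape ``(n_epochs, n_channels, n_freq_bins)`` in µV²/Hz;
    ``freqs`` is strictly increasing and restricted to ``freq_range``.
    """

    psd: np.ndarray
    freqs: np.ndarray
    freq_range: tuple[float, float]

    @property
    def n_epochs(self) -> int:
        return self.psd.shape[0]

    @property
    def n_channels(self) -> int:
        return self.psd.shape[1]

    @property
    def n_freq_bins(self) -> int:
        return self.psd.shape[2]


@dataclass(frozen=True)
class ScoreResult:
    """All intermediates of a scoring run.

    Attributes
    ----------
    similarity
        ``(n_channels, n_epochs, n_epochs)`` Spearman ρ matrices, one per
        channel; each slice is symmetric with a unit diagonal.
    score_vectors
        ``(n_channels, n_epochs)`` row means of the similarity slices
        (diagonal included).
    scores
        ``(n_epochs,)`` final per-epoch score: mean of the score vectors
        across channels.
    ranking
        Permutation of epoch indices (0-based) sorting ``scores``
        descending, ties broken by ascending epoch index.
    """

    similarity: np.ndarray
    score_vectors: np.ndarray
    scores: np.ndarray
    ranking: np.ndarray

    @property
    def n_epochs(self) -> int:
        return self.scores.shape[0]

    def top_k(self, k: int) -> np.ndarray:
        """First ``k`` epochs of the descending ranking (0-based)."""
        if not 1 <= k <= self.n_epochs:
            raise ValueError(f"k must be in [1, {self.n_epochs}], got {k}")
        return self.ranking[:k]


@dataclass(frozen=True)
class WelchConfig:
    """Welch estimator parameters.

    ``window_s`` is the segment length in seconds (clipped to the epoch
    length), ``overlap_fraction`` the fractional overlap between segments,
    ``window_shape`` any window name accepted by ``scipy.signal.get_window``.
    """

    window_s: float = 1.0
    overlap_fraction: float = 0.5
    window_shape: str = "hann"

    def __post_init__(self):
        if not self.window_s > 0:
            raise ValueError(f"window_s must be > 0, got {self.window_s}")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError(
                f"overlap_fraction must be in [0, 1), got {self.overlap_fraction}"
            )


def segment_recording(rec: Recording, epoch_length_s: float) -> EpochTensor:
    """Cut a recording into non-overlapping epochs of ``epoch_length_s``.

    Epochs are verbatim slices starting at sample 0; trailing samples that
    do not fill a whole epoch are discarded.

    Raises
    ------
    ValueError
        If the recording is shorter than one epoch.
    """
    samples_per_epoch = int(np.floor(epoch_length_s * rec.fs))
    if samples_per_epoch < 1:
        raise ValueError(
            f"epoch of {epoch_length_s} s at {rec.fs} Hz holds no sample"
        )
    if rec.n_samples < samples_per_epoch:
        raise ValueError(
            f"recording too short: one {epoch_length_s} s epoch needs "
            f"{samples_per_epoch} samples but only {rec.n_samples} are available"
        )
    n_epochs = rec.n_samples // samples_per_epoch
    used = n_epochs * samples_per_epoch
    data = rec.data[:, :used].reshape(rec.n_channels, n_epochs, samples_per_epoch)
    data = np.ascontiguousarray(np.swapaxes(data, 0, 1))
    offsets = np.arange(n_epochs) * samples_per_epoch
    return EpochTensor(
        data=data,
        epoch_length_s=float(epoch_length_s),
        fs=float(rec.fs),
        source_offsets=offsets,
    )


def welch_psd(
    epochs: EpochTensor,
    freq_range: tuple[float, float] = DEFAULT_FREQ_RANGE,
    welch_cfg: WelchConfig = WelchConfig(),
) -> PSDSet:
    """Welch PSD per (epoch, channel), restricted to ``freq_range``.

    The frequency grid is identical across epochs and channels.

    Raises
    ------
    ValueError
        If ``f_max`` exceeds Nyquist, or the requested Welch segment is
        longer than the epoch, or the range retains no frequency bin.
    """
    f_min, f_max = float(freq_range[0]), float(freq_range[1])
    if not f_min < f_max:
        raise ValueError(f"need f_min < f_max, got [{f_min}, {f_max}]")
    nyquist = epochs.fs / 2.0
    if f_max > nyquist:
        raise ValueError(
            f"f_max = {f_max} Hz exceeds Nyquist ({nyquist} Hz at fs = {epochs.fs})"
        )
    nperseg = min(int(round(welch_cfg.window_s * epochs.fs)), epochs.samples_per_epoch)
    if nperseg < 2:
        raise ValueError(f"Welch segment of {nperseg} samples is too short")
    if int(round(welch_cfg.window_s * epochs.fs)) > epochs.samples_per_epoch:
        # clip rather than fail only when the caller kept the default;
        # an explicit over-long window is a configuration error
        if welch_cfg.window_s != WelchConfig.window_s:
            raise ValueError(
                f"Welch window of {welch_cfg.window_s} s exceeds the "
                f"{epochs.epoch_length_s} s epoch"
            )
    noverlap = int(np.floor(nperseg * welch_cfg.overlap_fraction))
    freqs, psd = signal.welch(
        epochs.data,
        fs=epochs.fs,
        window=welch_cfg.window_shape,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        average="mean",
        axis=-1,
    )
    keep = (freqs >= f_min) & (freqs <= f_max)
    if not keep.any():
        raise ValueError(
            f"no frequency bin falls inside [{f_min}, {f_max}] Hz "
            f"(grid resolution {freqs[1] - freqs[0]:g} Hz)"
        )
    return PSDSet(psd=psd[..., keep], freqs=freqs[keep], freq_range=(f_min, f_max))


def _rank_spectra(psd_2d: np.ndarray, channel: int) -> np.ndarray:
    """Mid-rank transform of each epoch's PSD vector; rejects constants.

    Degeneracy is detected on the ranks (all-tied), which also catches
    spectra that are constant up to float rounding.
    """
    ranks = rankdata(psd_2d, method="average", axis=1)
    degenerate = ranks.var(axis=1) == 0
    if np.any(degenerate):
        raise DegenerateSpectrumError(
            epoch=int(np.argmax(degenerate)), channel=channel
        )
    return ranks


def spearman_similarity(psds: PSDSet, channel: int) -> np.ndarray:
    """Epoch-by-epoch Spearman correlation matrix for one channel.

    Entry ``(i, j)`` is the Spearman ρ between the PSD vectors of epochs
    ``i`` and ``j`` over frequency bins (mid-rank tie handling).  The
    result is symmetric with a unit diagonal.

    Raises
    ------
    DegenerateSpectrumError
        If any epoch has a constant PSD vector on this channel.
    """
    if psds.n_freq_bins < 2:
        raise ValueError("need at least 2 frequency bins for rank correlation")
    if not 0 <= channel < psds.n_channels:
        raise IndexError(f"channel {channel} out of range [0, {psds.n_channels})")
    ranks = _rank_spectra(psds.psd[:, channel, :], channel)
    sim = np.corrcoef(ranks)
    np.fill_diagonal(sim, 1.0)
    return np.clip(sim, -1.0, 1.0)


def channel_score_vector(similarity: np.ndarray) -> np.ndarray:
    """Row means of a symmetric unit-diagonal similarity matrix.

    The diagonal is included in the mean; this shifts every entry by the
    same affine map ``m -> ((n-1) m' + 1) / n`` and therefore never
    changes the induced epoch ranking.
    """
    similarity = np.asarray(similarity, dtype=float)
    if similarity.ndim != 2 or similarity.shape[0] != similarity.shape[1]:
        raise ValueError(f"similarity must be square, got shape {similarity.shape}")
    return similarity.mean(axis=1)


def aggregate_scores(score_vectors: np.ndarray) -> np.ndarray:
    """Unweighted mean of the per-channel score vectors."""
    score_vectors = np.asarray(score_vectors, dtype=float)
    if score_vectors.ndim != 2:
        raise ValueError(
            f"score_vectors must be (channels x epochs), got shape {score_vectors.shape}"
        )
    if score_vectors.shape[0] < 1:
        raise ValueError("need at least one channel")
    return score_vectors.mean(axis=0)


def rank_epochs(scores: np.ndarray) -> np.ndarray:
    """Stable descending argsort of the scores.

    Ties are broken by ascending epoch index, so the permutation is fully
    reproducible.  The caller takes the first ``k`` entries to select
    epochs.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        bad = int(np.argmax(~np.isfinite(scores)))
        raise ValueError(f"non-finite score at epoch {bad}")
    return np.argsort(-scores, kind="stable")


def score_epochs(
    rec: Recording,
    epoch_length_s: float,
    freq_range: tuple[float, float] = DEFAULT_FREQ_RANGE,
    welch_cfg: WelchConfig = WelchConfig(),
) -> ScoreResult:
    """Full scoring pipeline: segment → PSD → similarity → score → rank.

    All intermediates are retained in the returned :class:`ScoreResult`.
    Errors raised by a stage carry a note naming the failing stage.
    """

    def _staged(stage, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            exc.add_note(f"[epochscore] failing stage: {stage}")
            raise

    epochs = _staged("segment", segment_recording, rec, epoch_length_s)
    psds = _staged("welch_psd", welch_psd, epochs, freq_range, welch_cfg)
    similarity = np.stack(
        [
            _staged("spearman_similarity", spearman_similarity, psds, c)
            for c in range(psds.n_channels)
        ]
    )
    score_vectors = np.stack(
        [
            _staged("channel_score_vector", channel_score_vector, similarity[c])
            for c in range(psds.n_channels)
        ]
    )
    scores = _staged("aggregate_scores", aggregate_scores, score_vectors)
    ranking = _staged("rank_epochs", rank_epochs, scores)
    return ScoreResult(
        similarity=similarity,
        score_vectors=score_vectors,
        scores=scores,
        ranking=ranking,
    )
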