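"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (explicit loops, textbook
formulas) and never call into the package's vectorized code paths, so
they stay valid as cross-checks.
"""

import numpy as np
import pytest
from scipy import signal

from epochscore.core import Recording


# ---------------------------------------------------------------- oracles


def oracle_rank(values):
    """Mid-rank (average tie) assignment, brute force."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # 1-based average rank of the tie block
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def oracle_spearman(x, y):
    """Pearson correlation of mid-ranks, textbook formula."""
    rx, ry = oracle_rank(x), oracle_rank(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) ** 0.5
        * sum((b - my) ** 2 for b in ry) ** 0.5
    )
    return num / den


def oracle_score_pipeline(data, fs, epoch_length_s, f_min, f_max):
    """Loop-based re-implementation of the whole scoring pipeline.

    Shares only scipy.signal.welch (the spectral estimator itself) with
    the package; segmentation, ranking, correlation, and averaging are
    all explicit loops over textbook formulas.
    """
    n_channels, n_samples = data.shape
    spe = int(np.floor(epoch_length_s * fs))
    n_epochs = n_samples // spe
    nperseg = min(int(round(fs)), spe)
    psds = []  # [epoch][channel] -> PSD vector
    for e in range(n_epochs):
        per_channel = []
        for c in range(n_channels):
            seg = data[c, e * spe : (e + 1) * spe]
            freqs, psd = signal.welch(
                seg, fs=fs, window="hann", nperseg=nperseg,
                noverlap=nperseg // 2, scaling="density",
            )
            keep = [i for i, f in enumerate(freqs) if f_min <= f <= f_max]
            per_channel.append([psd[i] for i in keep])
        psds.append(per_channel)
    scores = []
    for e in range(n_epochs):
        total = 0.0
        for c in range(n_channels):
            row_sum = 0.0
            for e2 in range(n_epochs):
                if e2 == e:
                    row_sum += 1.0
                else:
                    row_sum += oracle_spearman(psds[e][c], psds[e2][c])
            total += row_sum / n_epochs
        scores.append(total / n_channels)
    ranking = sorted(range(n_epochs), key=lambda i: (-scores[i], i))
    return np.asarray(scores), np.asarray(ranking)


def oracle_paired_t(x, y):
    """Textbook paired t statistic."""
    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    mean = sum(d) / n
    var = sum((v - mean) ** 2 for v in d) / (n - 1)
    return mean / (var / n) ** 0.5


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_recording(rng):
    """4 epochs x 3 channels of colored noise at 100 Hz, 2 s epochs."""
    data = rng.standard_normal((3, 800))
    data = np.cumsum(data, axis=1) * 0.1 + rng.standard_normal((3, 800))
    return Recording(data=data, fs=100.0, channel_labels=("a", "b", "c"))


@pytest.fixture
def tiled_recording(rng):
    """12 identical 5-s epochs at 160 Hz (every score must be exactly 1)."""
    segment = rng.standard_normal((3, 800))
    return Recording(data=np.tile(segment, 12), fs=160.0)
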