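"""Exhaustive epoch-selection sweep and paired effect-size statistics.

Given per-subject, per-epoch feature values for two paired conditions
(eyes-open vs eyes-closed), every possible selection of ``k`` out of
``n`` epochs is applied identically to all subjects and both conditions;
each selection yields one paired Cohen's d (and t statistic) across
subjects.  The score-guided selection — each run's own top-``k`` epochs —
is then placed on that empirical distribution as a percentile.

Sign convention: d is computed on (EC − EO) differences, so the classic
eyes-closed alpha increase comes out positive.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SubjectFeatures",
    "EffectSizeSweep",
    "paired_cohens_d",
    "paired_t_test",
    "enumerate_combinations",
    "selection_sweep",
    "percentile_of",
]


@dataclass(frozen=True)
class SubjectFeatures:
    """One subject's per-epoch global feature values and epoch rankings.

    ``eo_per_epoch`` / ``ec_per_epoch`` hold the feature (global relative
    alpha power or global PLI) per epoch for the eyes-open and eyes-closed
    runs; ``eo_ranking`` / ``ec_ranking`` are the scoring permutations
    (0-based, descending) of the corresponding runs.
    """

    subject_id: str
    eo_per_epoch: np.ndarray
    ec_per_epoch: np.ndarray
    eo_ranking: np.ndarray
    ec_ranking: np.ndarray

    def __post_init__(self):
        eo = np.asarray(self.eo_per_epoch, dtype=float)
        ec = np.asarray(self.ec_per_epoch, dtype=float)
        if eo.shape != ec.shape or eo.ndim != 1:
            raise ValueError(
                f"subject {self.subject_id}: EO and EC feature vectors must be "
                f"1-D and equally long, got {eo.shape} vs {ec.shape}"
            )
        object.__setattr__(self, "eo_per_epoch", eo)
        object.__setattr__(self, "ec_per_epoch", ec)
        object.__setattr__(self, "eo_ranking", np.asarray(self.eo_ranking, dtype=int))
        object.__setattr__(self, "ec_ranking", np.asarray(self.ec_ranking, dtype=int))

    @property
    def n_epochs(self) -> int:
        return self.eo_per_epoch.shape[0]


@dataclass(frozen=True)
class EffectSizeSweep:
    """Every k-subset's paired effect size, plus the score-guided one.

    ``combos`` are 1-based epoch index tuples in lexicographic order;
    ``d_values`` / ``t_values`` align with them.  ``scorepochs_percentile``
    is ``100 × (#{d ≤ scorepochs_d}) / len(d_values)``.
    """

    combos: tuple[tuple[int, ...], ...]
    d_values: np.ndarray
    t_values: np.ndarray
    scorepochs_d: float
    scorepochs_percentile: float
    k: int
    n_epochs: int

    def to_dict(self) -> dict:
        return {
            "n_epochs": self.n_epochs,
            "k": self.k,
            "combos": [list(c) for c in self.combos],
            "d_values": [float(d) for d in self.d_values],
            "t_values": [float(t) for t in self.t_values],
            "scorepochs_d": float(self.scorepochs_d),
            "scorepochs_percentile": float(self.scorepochs_percentile),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _paired_diff(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"paired samples must be 1-D and equal length, got {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError(f"need at least 2 pairs, got {x.size}")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences: effect size undefined")
    return diff, sd


def paired_cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Paired Cohen's d: mean(x − y) / sd(x − y), sample sd (n − 1).

    Identical samples (every difference exactly zero) give d = 0; a
    nonzero mean with zero spread is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape == y.shape and x.ndim == 1 and x.size >= 2 and np.all(x == y):
        return 0.0
    diff, sd = _paired_diff(x, y)
    return float(diff.mean() / sd)


def paired_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Classical two-sided paired t test; returns (t, p).

    Satisfies ``t = d·sqrt(n)`` with :func:`paired_cohens_d` on the same
    pairs.
    """
    _paired_diff(x, y)  # shape + zero-variance gate
    res = stats.ttest_rel(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)


def enumerate_combinations(n_epochs: int, k: int) -> list[tuple[int, ...]]:
    """All k-subsets of {1, …, n_epochs} in lexicographic order.

    1-based tuples: with n=12, k=4 the first is (1, 2, 3, 4), the second
    (1, 2, 3, 5), the last (9, 10, 11, 12), 495 in total.
    """
    if not 1 <= k <= n_epochs:
        raise ValueError(f"need 1 <= k <= n_epochs, got k={k}, n_epochs={n_epochs}")
    return list(itertools.combinations(range(1, n_epochs + 1), k))


def percentile_of(value: float, distribution: np.ndarray) -> float:
    """Empirical percentile: 100 × (#{entries ≤ value}) / size."""
    distribution = np.asarray(distribution, dtype=float)
    if distribution.size == 0:
        raise ValueError("empty distribution")
    return float(100.0 * np.count_nonzero(distribution <= value) / distribution.size)


def selection_sweep(features: list[SubjectFeatures], k: int) -> EffectSizeSweep:
    """Exhaustive k-of-n selection sweep with paired statistics.

    For every combination the same epochs are selected for all subjects
    and both conditions; the per-subject feature is the unweighted mean
    over the selected epochs, and Cohen's d / t are computed on the paired
    (EC − EO) differences across subjects.  The score-guided effect size
    uses each subject's own top-``k`` epochs, chosen independently per
    condition from that run's ranking.
    """
    if not features:
        raise ValueError("need at least one subject")
    n_epochs = features[0].n_epochs
    for f in features:
        if f.n_epochs != n_epochs:
            raise ValueError(
                f"subject {f.subject_id} has {f.n_epochs} epochs, expected {n_epochs}"
            )
    combos = enumerate_combinations(n_epochs, k)
    eo = np.stack([f.eo_per_epoch for f in features])  # subjects x epochs
    ec = np.stack([f.ec_per_epoch for f in features])

    combo_idx = np.asarray(combos) - 1  # 0-based, (n_combos, k)
    eo_means = eo[:, combo_idx].mean(axis=2)  # subjects x n_combos
    ec_means = ec[:, combo_idx].mean(axis=2)
    diffs = ec_means - eo_means
    sds = diffs.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = combos[int(np.argmax(sds == 0))]
        raise ValueError(f"zero variance of paired differences for combo {bad}")
    d_values = diffs.mean(axis=0) / sds
    t_values = d_values * np.sqrt(len(features))

    eo_sel = np.stack(
        [f.eo_per_epoch[f.eo_ranking[:k]].mean() for f in features]
    )
    ec_sel = np.stack(
        [f.ec_per_epoch[f.ec_ranking[:k]].mean() for f in features]
    )
    scorepochs_d = paired_cohens_d(ec_sel, eo_sel)
    return EffectSizeSweep(
        combos=tuple(combos),
        d_values=d_values,
        t_values=t_values,
        scorepochs_d=scorepochs_d,
        scorepochs_percentile=percentile_of(scorepochs_d, d_values),
        k=k,
        n_epochs=n_epochs,
    )
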