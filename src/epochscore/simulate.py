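"""Synthetic resting-state EEG with known ground truth.

Each channel is the sum of a 1/f^β Gaussian background (built by spectral
shaping of white noise, so its expected spectrum is known analytically),
an alpha-band sinusoid whose amplitude can decay epoch by epoch (a crude
vigilance drift), and optional epoch-localized artifacts.  Everything is
reproducible from a single integer seed via ``numpy.random.default_rng``
(PCG64); cohorts derive per-subject streams from ``SeedSequence.spawn``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import Recording

__all__ = [
    "ARTIFACT_KINDS",
    "SyntheticSpec",
    "SyntheticSubject",
    "SyntheticCohort",
    "generate_recording",
    "generate_cohort",
]

ARTIFACT_KINDS = ("broadband_burst", "low_freq_drift", "line_spike")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic recording.

    ``artifact_plan`` lists ``(epoch_index, kind, amplitude)`` triples
    with kind in :data:`ARTIFACT_KINDS`; artifact amplitude is in µV.
    ``alpha_decay_per_epoch`` multiplies the alpha amplitude once per
    epoch (1.0 = stationary).
    """

    n_channels: int = 4
    fs: float = 160.0
    duration_s: float = 60.0
    epoch_length_s: float = 5.0
    background_exponent: float = 1.0
    background_amplitude: float = 10.0
    alpha_freq: float = 10.0
    alpha_amplitude: float = 10.0
    alpha_decay_per_epoch: float = 1.0
    artifact_plan: tuple[tuple[int, str, float], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 1 or self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("need n_channels >= 1, fs > 0, duration_s > 0")
        if self.alpha_amplitude < 0 or self.background_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if not 0 < self.alpha_decay_per_epoch <= 1:
            raise ValueError(
                f"alpha_decay_per_epoch must be in (0, 1], got {self.alpha_decay_per_epoch}"
            )
        n_ep = self.n_epochs
        for idx, kind, amp in self.artifact_plan:
            if kind not in ARTIFACT_KINDS:
                raise ValueError(f"unknown artifact kind '{kind}' (choose from {ARTIFACT_KINDS})")
            if not 0 <= idx < n_ep:
                raise ValueError(
                    f"artifact epoch index {idx} out of range [0, {n_ep})"
                )
            if amp < 0:
                raise ValueError("artifact amplitude must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    @property
    def samples_per_epoch(self) -> int:
        return int(np.floor(self.epoch_length_s * self.fs))

    @property
    def n_epochs(self) -> int:
        return self.n_samples // self.samples_per_epoch


@dataclass(frozen=True)
class SyntheticSubject:
    subject_id: str
    eo: Recording
    ec: Recording
    truth: dict


@dataclass(frozen=True)
class SyntheticCohort:
    subjects: tuple[SyntheticSubject, ...]


def _pink_background(rng, n_channels, n_samples, fs, exponent, rms):
    """Gaussian noise with power spectrum ∝ 1/f^exponent, unit-free RMS."""
    white = rng.standard_normal((n_channels, n_samples))
    if exponent == 0 or rms == 0:
        return white * rms
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * shaping, n=n_samples, axis=-1)
    std = shaped.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return shaped / std * rms


def _alpha_component(rng, spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch-amplitude alpha sinusoid with channel-specific phase."""
    t = np.arange(spec.n_samples) / spec.fs
    phases = rng.uniform(0, 2 * np.pi, size=spec.n_channels)
    carrier = np.sin(2 * np.pi * spec.alpha_freq * t[None, :] + phases[:, None])
    envelope = np.zeros(spec.n_samples)
    per_epoch_amp = spec.alpha_amplitude * (
        spec.alpha_decay_per_epoch ** np.arange(spec.n_epochs)
    )
    spe = spec.samples_per_epoch
    for e in range(spec.n_epochs):
        envelope[e * spe : (e + 1) * spe] = per_epoch_amp[e]
    # tail beyond the last whole epoch keeps the final amplitude
    if spec.n_epochs * spe < spec.n_samples:
        envelope[spec.n_epochs * spe :] = per_epoch_amp[-1]
    return carrier * envelope[None, :], per_epoch_amp


def _inject_artifact(rng, data, spec: SyntheticSpec, epoch, kind, amplitude):
    spe = spec.samples_per_epoch
    sl = slice(epoch * spe, (epoch + 1) * spe)
    t = np.arange(spe) / spec.fs
    if kind == "broadband_burst":
        data[:, sl] += amplitude * rng.standard_normal((spec.n_channels, spe))
    elif kind == "low_freq_drift":
        phases = rng.uniform(0, 2 * np.pi, size=spec.n_channels)
        data[:, sl] += amplitude * np.sin(
            2 * np.pi * 0.3 * t[None, :] + phases[:, None]
        )
    elif kind == "line_spike":
        line_freq = min(50.0, 0.45 * spec.fs)
        phases = rng.uniform(0, 2 * np.pi, size=spec.n_channels)
        data[:, sl] += amplitude * np.sin(
            2 * np.pi * line_freq * t[None, :] + phases[:, None]
        )


def generate_recording(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[Recording, dict]:
    """Generate one recording plus its ground truth.

    The truth dict records per-epoch alpha amplitudes and the artifact
    plan, so tests can check that scoring, band power, and the sweep
    recover what was programmed.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    data = _pink_background(
        rng, spec.n_channels, spec.n_samples, spec.fs,
        spec.background_exponent, spec.background_amplitude,
    )
    alpha, per_epoch_amp = _alpha_component(rng, spec)
    data = data + alpha
    artifact_epochs = []
    for epoch, kind, amplitude in spec.artifact_plan:
        _inject_artifact(rng, data, spec, epoch, kind, amplitude)
        artifact_epochs.append(int(epoch))
    rec = Recording(
        data=data,
        fs=spec.fs,
        channel_labels=tuple(f"SIM{i:03d}" for i in range(spec.n_channels)),
    )
    truth = {
        "alpha_amplitude_per_epoch": per_epoch_amp.tolist(),
        "artifact_epochs": sorted(set(artifact_epochs)),
        "artifact_plan": [
            [int(e), str(k), float(a)] for e, k, a in spec.artifact_plan
        ],
        "background_exponent": spec.background_exponent,
        "alpha_freq": spec.alpha_freq,
        "n_epochs": spec.n_epochs,
    }
    return rec, truth


def generate_cohort(
    n_subjects: int,
    eo_spec: SyntheticSpec,
    ec_spec: SyntheticSpec,
    between_subject_sd: float = 0.1,
    seed: int = 0,
) -> SyntheticCohort:
    """Paired eyes-open / eyes-closed cohort with per-subject alpha jitter.

    Each subject's alpha amplitude (in both conditions) is multiplied by a
    log-normal factor ``exp(N(0, between_subject_sd))``, so the programmed
    EC/EO amplitude ratio is preserved exactly within subject.

    Raises
    ------
    ValueError
        If the two specs disagree on fs, channel count, or duration.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    if (eo_spec.fs, eo_spec.n_channels, eo_spec.duration_s) != (
        ec_spec.fs, ec_spec.n_channels, ec_spec.duration_s
    ):
        raise ValueError("EO and EC specs must share fs, channels, and duration")
    if between_subject_sd < 0:
        raise ValueError("between_subject_sd must be >= 0")
    seq = np.random.SeedSequence(seed)
    subjects = []
    for i, child in enumerate(seq.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        factor = float(np.exp(rng.normal(0.0, between_subject_sd)))
        eo_i = replace(eo_spec, alpha_amplitude=eo_spec.alpha_amplitude * factor)
        ec_i = replace(ec_spec, alpha_amplitude=ec_spec.alpha_amplitude * factor)
        eo_rec, eo_truth = generate_recording(eo_i, rng=rng)
        ec_rec, ec_truth = generate_recording(ec_i, rng=rng)
        subjects.append(
            SyntheticSubject(
                subject_id=f"S{i + 1:03d}",
                eo=eo_rec,
                ec=ec_rec,
                truth={
                    "alpha_factor": factor,
                    "eo": eo_truth,
                    "ec": ec_truth,
                },
            )
        )
    return SyntheticCohort(subjects=tuple(subjects))
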