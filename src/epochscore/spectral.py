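"""Relative band power features.

Relative power of a band = sum of PSD bins whose center frequency lies in
the closed band interval, divided by the sum over every bin retained in
the :class:`~epochscore.core.PSDSet`'s frequency range.  Rectangle (plain
bin-sum) integration keeps results bit-reproducible; the denominator is
the analysis range, not the full Nyquist band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PSDSet

__all__ = ["BandDefinition", "BandPowerResult", "relative_band_power", "ALPHA_BAND"]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_low: float
    f_high: float

    def __post_init__(self):
        if not 0 <= self.f_low < self.f_high:
            raise ValueError(
                f"band '{self.name}' needs 0 <= f_low < f_high, "
                f"got [{self.f_low}, {self.f_high}]"
            )


ALPHA_BAND = BandDefinition("alpha", 8.0, 13.0)


@dataclass(frozen=True)
class BandPowerResult:
    """Relative band power, per (epoch, channel) and channel-averaged.

    ``per_epoch_per_channel`` has shape ``(n_epochs, n_channels)``;
    ``per_epoch_global`` is the unweighted channel mean per epoch.  All
    values lie in [0, 1].
    """

    band: BandDefinition
    per_epoch_per_channel: np.ndarray
    per_epoch_global: np.ndarray


def relative_band_power(psds: PSDSet, band: BandDefinition) -> BandPowerResult:
    """Fraction of retained spectral power falling inside ``band``.

    Band edges are inclusive on both sides; a bin belongs to the band if
    its center frequency does.

    Raises
    ------
    ValueError
        If the band does not overlap the PSD grid, or an epoch/channel has
        zero total power.
    """
    in_band = (psds.freqs >= band.f_low) & (psds.freqs <= band.f_high)
    if not in_band.any():
        raise ValueError(
            f"band '{band.name}' [{band.f_low}, {band.f_high}] Hz contains no "
            f"bin of the retained grid [{psds.freqs[0]:g}, {psds.freqs[-1]:g}] Hz"
        )
    total = psds.psd.sum(axis=2)
    if np.any(total <= 0):
        epoch, channel = np.argwhere(total <= 0)[0]
        raise ValueError(
            f"zero total power in epoch {epoch}, channel {channel}: "
            "relative power is undefined"
        )
    rel = psds.psd[:, :, in_band].sum(axis=2) / total
    return BandPowerResult(
        band=band,
        per_epoch_per_channel=rel,
        per_epoch_global=rel.mean(axis=1),
    )
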