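"""Minimal EDF/EDF+ codec.

Implements just enough of the European Data Format (16-bit, fixed-layout
ASCII header) to write synthetic recordings and read them — or simple
EDF(+) files such as the PhysioNet baselines — back.  Signals labelled
``EDF Annotations`` are parsed as present but carry no samples of
interest; callers typically drop them.

This is deliberately not a general EDF+ implementation: discontinuous
files, TALs, and sub-second record structure are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EdfSignal", "EdfFile", "read_edf_file", "write_edf_file"]

ANNOTATION_LABEL = "EDF Annotations"
_DIG_MIN, _DIG_MAX = -32768, 32767


@dataclass(frozen=True)
class EdfSignal:
    label: str
    samples_per_record: int
    physical_dimension: str
    data: np.ndarray  # physical units, float

    @property
    def is_annotation(self) -> bool:
        return self.label == ANNOTATION_LABEL


@dataclass(frozen=True)
class EdfFile:
    signals: tuple[EdfSignal, ...]
    record_duration_s: float
    n_records: int

    def sampling_rate(self, signal: EdfSignal) -> float:
        return signal.samples_per_record / self.record_duration_s


def _ascii(field: bytes) -> str:
    return field.decode("ascii", errors="replace").strip()


def _fit8(x: float) -> bytes:
    """Render a float into EDF's 8-character ASCII numeric field."""
    for fmt in ("%.8g", "%.6g", "%.5g", "%.4g", "%.3g", "%.2g", "%.1g"):
        s = fmt % x
        if len(s) <= 8:
            return s.ljust(8).encode("ascii")
    raise ValueError(f"cannot encode {x!r} in 8 ASCII characters")


def read_edf_file(path) -> EdfFile:
    """Parse an EDF/EDF+ file into physical-unit signals."""
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        n_records = int(_ascii(header[236:244]))
        record_duration = float(_ascii(header[244:252]))
        n_signals = int(_ascii(header[252:256]))
        if n_signals < 1:
            raise ValueError(f"{path}: EDF file declares no signals")
        sig_header = fh.read(256 * n_signals)

        def fields(offset, width):
            base = offset * n_signals
            return [
                _ascii(sig_header[base + i * width : base + (i + 1) * width])
                for i in range(n_signals)
            ]

        labels = fields(0, 16)
        phys_dims = fields(16 + 80, 8)
        phys_min = [float(v) for v in fields(16 + 80 + 8, 8)]
        phys_max = [float(v) for v in fields(16 + 80 + 16, 8)]
        dig_min = [int(float(v)) for v in fields(16 + 80 + 24, 8)]
        dig_max = [int(float(v)) for v in fields(16 + 80 + 32, 8)]
        spr = [int(v) for v in fields(16 + 80 + 40 + 80, 8)]

        record_len = sum(spr)
        raw = np.fromfile(fh, dtype="<i2")

    if n_records < 0:  # writer did not know the count; infer it
        n_records = raw.size // record_len
    raw = raw[: n_records * record_len].reshape(n_records, record_len)

    signals = []
    col = 0
    for i in range(n_signals):
        dig = raw[:, col : col + spr[i]].reshape(-1).astype(float)
        col += spr[i]
        dig_span = dig_max[i] - dig_min[i]
        if dig_span == 0:
            phys = np.full_like(dig, phys_min[i])
        else:
            gain = (phys_max[i] - phys_min[i]) / dig_span
            phys = (dig - dig_min[i]) * gain + phys_min[i]
        signals.append(
            EdfSignal(
                label=labels[i],
                samples_per_record=spr[i],
                physical_dimension=phys_dims[i],
                data=phys,
            )
        )
    return EdfFile(
        signals=tuple(signals),
        record_duration_s=record_duration,
        n_records=n_records,
    )


def write_edf_file(
    path,
    data: np.ndarray,
    fs: float,
    labels: list[str],
    physical_dimension: str = "uV",
) -> None:
    """Write a ``(channels, samples)`` array as a plain EDF file.

    Requires an integer sampling rate (one record per second); samples
    beyond a whole record are zero-padded into the final record.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be (channels, samples)")
    n_channels, n_samples = data.shape
    if len(labels) != n_channels:
        raise ValueError(f"{len(labels)} labels for {n_channels} channels")
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    spr = int(round(fs))
    n_records = int(np.ceil(n_samples / spr))
    padded = np.zeros((n_channels, n_records * spr))
    padded[:, :n_samples] = data

    # symmetric physical range per channel, snapped to an encodable value
    phys_max = np.maximum(np.abs(padded).max(axis=1), 1e-6)
    phys_max = np.array([float(_fit8(v * 1.0001).decode()) for v in phys_max])
    gains = phys_max * 2 / (_DIG_MAX - _DIG_MIN)
    dig = np.round((padded + phys_max[:, None]) / gains[:, None]) + _DIG_MIN
    dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")

    header = b""
    header += b"0".ljust(8)
    header += b"X X X X".ljust(80)  # patient
    header += b"Startdate X X X X".ljust(80)  # recording
    header += b"01.01.00"
    header += b"00.00.00"
    header += str(256 * (1 + n_channels)).ljust(8).encode("ascii")
    header += b"".ljust(44)
    header += str(n_records).ljust(8).encode("ascii")
    header += b"1".ljust(8)  # record duration: 1 s
    header += str(n_channels).ljust(4).encode("ascii")

    def col(values, width):
        out = b""
        for v in values:
            b_ = v if isinstance(v, bytes) else str(v).encode("ascii")
            if len(b_) > width:
                raise ValueError(f"field {v!r} exceeds {width} characters")
            out += b_.ljust(width)
        return out

    header += col(labels, 16)
    header += col([""] * n_channels, 80)  # transducer
    header += col([physical_dimension] * n_channels, 8)
    header += col([_fit8(-v) for v in phys_max], 8)
    header += col([_fit8(v) for v in phys_max], 8)
    header += col([_DIG_MIN] * n_channels, 8)
    header += col([_DIG_MAX] * n_channels, 8)
    header += col([""] * n_channels, 80)  # prefiltering
    header += col([spr] * n_channels, 8)
    header += col([""] * n_channels, 32)

    with open(path, "wb") as fh:
        fh.write(header)
        # records interleave channels: all of ch0's spr samples, then ch1's, ...
        records = dig.reshape(n_channels, n_records, spr).swapaxes(0, 1)
        fh.write(np.ascontiguousarray(records).tobytes())
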