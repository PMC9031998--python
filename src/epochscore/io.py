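"""Ingestion of recordings and serialization of results.

Readers produce :class:`~epochscore.core.Recording` objects from EDF/EDF+
or plain delimited numeric tables; writers emit score tables (TSV), score
reports, and sweep reports (JSON) with deterministic field order and
floats at 12 significant digits, so identical runs give byte-identical
files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .core import Recording, ScoreResult, WelchConfig
from .edf import read_edf_file, write_edf_file
from .evaluation import EffectSizeSweep

__all__ = [
    "ScoreReport",
    "read_edf",
    "write_edf",
    "read_delimited",
    "write_reports",
]


def read_edf(path, channel_selection: list[str] | None = None) -> Recording:
    """Read an EDF/EDF+ file into a Recording (amplitudes in µV).

    Annotation signals are dropped.  If the remaining signals do not share
    a single sampling rate, ``channel_selection`` must narrow them down to
    one rate; the subset is honored in the given order.

    Raises
    ------
    ValueError
        On missing channels (the error lists the available labels) or
        unresolved mixed sampling rates.
    """
    edf = read_edf_file(path)
    signals = [s for s in edf.signals if not s.is_annotation]
    if not signals:
        raise ValueError(f"{path}: no data signals (annotations only)")
    by_label = {s.label: s for s in signals}
    if channel_selection is not None:
        missing = [c for c in channel_selection if c not in by_label]
        if missing:
            raise ValueError(
                f"{path}: channel(s) {missing} not found; available: "
                f"{sorted(by_label)}"
            )
        signals = [by_label[c] for c in channel_selection]
    rates = {edf.sampling_rate(s) for s in signals}
    if len(rates) > 1:
        raise ValueError(
            f"{path}: mixed sampling rates {sorted(rates)}; select channels "
            "sharing a single rate"
        )
    fs = rates.pop()
    data = np.stack([s.data for s in signals])
    return Recording(data=data, fs=fs, channel_labels=tuple(s.label for s in signals))


def write_edf(path, rec: Recording) -> None:
    """Write a Recording as a plain EDF file (16-bit quantization)."""
    write_edf_file(path, rec.data, rec.fs, list(rec.channel_labels))


def _sniff_delimiter(first_line: str) -> str:
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    return None  # whitespace


def read_delimited(
    path,
    fs: float,
    channels_in: str = "rows",
    labels: list[str] | None = None,
) -> Recording:
    """Read a rectangular numeric table as a Recording.

    ``channels_in`` selects the orientation ("rows" or "columns"); the
    delimiter (tab/comma/whitespace) is auto-detected; labels are
    synthesized when absent.  Ragged rows and non-numeric or non-finite
    cells raise errors naming the offending row and column (1-based).
    """
    if channels_in not in ("rows", "columns"):
        raise ValueError(f"channels_in must be 'rows' or 'columns', got {channels_in!r}")
    lines = [
        ln for ln in Path(path).read_text().splitlines() if ln.strip() != ""
    ]
    if not lines:
        raise ValueError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0])
    rows = []
    width = None
    for r, line in enumerate(lines, start=1):
        cells = line.split(delim) if delim else line.split()
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise ValueError(
                f"{path}: ragged table — row {r} has {len(cells)} cells, expected {width}"
            )
        row = []
        for c, cell in enumerate(cells, start=1):
            try:
                value = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {r}, column {c}"
                ) from None
            if not np.isfinite(value):
                raise ValueError(
                    f"{path}: non-finite value {cell!r} at row {r}, column {c}"
                )
            row.append(value)
        rows.append(row)
    data = np.asarray(rows)
    if channels_in == "columns":
        data = data.T
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(data.shape[0]))
    return Recording(data=data, fs=fs, channel_labels=tuple(labels))


@dataclass(frozen=True)
class ScoreReport:
    """Serializable summary of a scoring run."""

    scores: list[float]
    ranking_0based: list[int]
    ranking_1based: list[int]
    top_k: int
    suggested_epochs_1based: list[int]
    epoch_length_s: float
    freq_range: tuple[float, float]
    welch: dict
    input_file: str
    channels: list[str]
    fs: float
    version: str = __version__

    @classmethod
    def from_result(
        cls,
        result: ScoreResult,
        *,
        epoch_length_s: float,
        freq_range,
        welch_cfg: WelchConfig,
        input_file: str,
        channels,
        fs: float,
        top_k: int = 4,
    ) -> "ScoreReport":
        top_k = min(top_k, result.n_epochs)
        ranking0 = [int(i) for i in result.ranking]
        return cls(
            scores=[float(s) for s in result.scores],
            ranking_0based=ranking0,
            ranking_1based=[i + 1 for i in ranking0],
            top_k=top_k,
            suggested_epochs_1based=[i + 1 for i in ranking0[:top_k]],
            epoch_length_s=float(epoch_length_s),
            freq_range=(float(freq_range[0]), float(freq_range[1])),
            welch={
                "window_s": welch_cfg.window_s,
                "overlap_fraction": welch_cfg.overlap_fraction,
                "window_shape": welch_cfg.window_shape,
            },
            input_file=str(input_file),
            channels=[str(c) for c in channels],
            fs=float(fs),
        )

    def to_dict(self) -> dict:
        return {
            "scores": self.scores,
            "ranking_0based": self.ranking_0based,
            "ranking_1based": self.ranking_1based,
            "top_k": self.top_k,
            "suggested_epochs_1based": self.suggested_epochs_1based,
            "config": {
                "epoch_length_s": self.epoch_length_s,
                "freq_range": list(self.freq_range),
                "welch": self.welch,
            },
            "input": {
                "file": self.input_file,
                "channels": self.channels,
                "fs": self.fs,
            },
            "version": self.version,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreReport":
        return cls(
            scores=list(d["scores"]),
            ranking_0based=list(d["ranking_0based"]),
            ranking_1based=list(d["ranking_1based"]),
            top_k=int(d["top_k"]),
            suggested_epochs_1based=list(d["suggested_epochs_1based"]),
            epoch_length_s=d["config"]["epoch_length_s"],
            freq_range=tuple(d["config"]["freq_range"]),
            welch=dict(d["config"]["welch"]),
            input_file=d["input"]["file"],
            channels=list(d["input"]["channels"]),
            fs=d["input"]["fs"],
            version=d["version"],
        )


def _round_floats(obj):
    """12-significant-digit float canonicalization for stable JSON."""
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def _dump_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(_round_floats(payload), indent=2) + "\n")


def write_reports(
    out_dir,
    score_report: ScoreReport | None = None,
    sweep: EffectSizeSweep | None = None,
    prefix: str = "",
) -> list[Path]:
    """Write score table (TSV), score report and sweep report (JSON).

    Field order is deterministic and floats are serialized at 12
    significant digits, so identical inputs produce byte-identical files.
    Returns the paths written.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValueError(f"cannot create output directory {out_dir}: {exc}") from exc
    written = []
    if score_report is not None:
        table = out_dir / f"{prefix}scores.tsv"
        lines = ["epoch_1based\tscore\trank"]
        rank_of = {e: r + 1 for r, e in enumerate(score_report.ranking_0based)}
        for e, score in enumerate(score_report.scores):
            lines.append(f"{e + 1}\t{score:.12g}\t{rank_of[e]}")
        table.write_text("\n".join(lines) + "\n")
        written.append(table)
        report = out_dir / f"{prefix}score_report.json"
        _dump_json(report, score_report.to_dict())
        written.append(report)
    if sweep is not None:
        sweep_path = out_dir / f"{prefix}sweep_report.json"
        _dump_json(sweep_path, sweep.to_dict())
        written.append(sweep_path)
    return written
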