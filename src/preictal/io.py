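"""Multichannel EEG text I/O and preprocessing.

Records are plain-text matrices with a one-line header::

    # fs=256 channels=24
    <sample row with one column per channel>
    ...

Rows are samples, columns are channels.  Preprocessing reproduces the
acquisition convention of the analysis: anti-artifact low-pass filtering at
35 Hz followed by resampling to 35 samples/s, so a 3-minute record becomes
6300 values per channel.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

__all__ = [
    "EEGRecord",
    "FormatError",
    "read_eeg_text",
    "write_eeg_text",
    "read_annotation_csv",
    "write_annotation_csv",
    "lowpass_decimate",
    "select_dominant_channel",
    "average_trials",
]


class FormatError(ValueError):
    """Raised when an EEG text file violates the expected dialect."""


@dataclass
class EEGRecord:
    """A multichannel voltage record.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    fs:
        Sampling rate in Hz.
    subject_id, trial_id:
        Free-form labels used when records are grouped into cohorts.
    """

    data: np.ndarray
    fs: float
    subject_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[1] < 2:
            raise ValueError("record needs at least 2 samples per channel")
        if not np.isfinite(self.data).all():
            raise ValueError("record contains non-finite voltages")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Total duration T in seconds (= samples / fs)."""
        return self.n_samples / self.fs


_HEADER_RE = re.compile(r"#\s*fs\s*=\s*([0-9.eE+-]+)\s+channels\s*=\s*(\d+)")


def read_eeg_text(path) -> EEGRecord:
    """Read a plain-text EEG record.

    The first line must be ``# fs=<Hz> channels=<n>``; the body is a
    whitespace- or comma-delimited numeric matrix with samples as rows.
    Malformed content raises :class:`FormatError` naming the offending line
    (1-based, counting the header).
    """
    with open(path) as fh:
        header = fh.readline()
        m = _HEADER_RE.match(header.strip())
        if m is None:
            raise FormatError(f"{path}: line 1: missing or malformed header "
                              "(expected '# fs=<Hz> channels=<n>')")
        fs, n_ch = float(m.group(1)), int(m.group(2))
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != n_ch:
                raise FormatError(
                    f"{path}: line {lineno}: expected {n_ch} columns, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric value") from exc
    if not rows:
        raise FormatError(f"{path}: no sample rows")
    return EEGRecord(data=np.asarray(rows).T, fs=fs)


def write_eeg_text(record: EEGRecord, path) -> None:
    """Write ``record`` in the dialect :func:`read_eeg_text` accepts."""
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs:g} channels={record.n_channels}\n")
        np.savetxt(fh, record.data.T, fmt="%.12g")


def write_annotation_csv(annotation, path) -> None:
    """Write event times as a one-row CSV ``t_precursor,t_onset,t_end``."""
    with open(path, "w") as fh:
        fh.write("t_precursor,t_onset,t_end\n")
        fh.write(f"{annotation.t_precursor:g},{annotation.t_onset:g},"
                 f"{annotation.t_end:g}\n")


def read_annotation_csv(path):
    """Read the 3-column event-time CSV written by
    :func:`write_annotation_csv`."""
    from .synthetic import EventAnnotation
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if header != ["t_precursor", "t_onset", "t_end"]:
            raise FormatError(f"{path}: line 1: unexpected annotation header")
        try:
            vals = [float(v) for v in fh.readline().strip().split(",")]
        except ValueError as exc:
            raise FormatError(f"{path}: line 2: non-numeric time") from exc
        if len(vals) != 3:
            raise FormatError(f"{path}: line 2: expected 3 times")
    return EventAnnotation(*vals)


def lowpass_decimate(record: EEGRecord, cutoff: float = 35.0,
                     target_fs: float = 35.0) -> EEGRecord:
    """Zero-phase low-pass filter then resample to ``target_fs``.

    A 4th-order Butterworth filter applied forward-backward (no phase delay,
    so downstream detection timestamps are unbiased) followed by linear
    interpolation onto the uniform ``target_fs`` grid.  Output length is
    ``round(T * target_fs)``; DC gain is 1.
    """
    if target_fs > record.fs:
        raise ValueError("target_fs may not exceed the record sampling rate")
    if record.fs < 2 * cutoff:
        raise ValueError("sampling rate below Nyquist for the requested cutoff")
    sos = _signal.butter(4, cutoff / (record.fs / 2), output="sos")
    filtered = _signal.sosfiltfilt(sos, record.data, axis=1)
    n_out = int(round(record.duration * target_fs))
    t_in = np.arange(record.n_samples) / record.fs
    t_out = np.arange(n_out) / target_fs
    out = np.vstack([np.interp(t_out, t_in, ch) for ch in filtered])
    return EEGRecord(data=out, fs=target_fs,
                     subject_id=record.subject_id, trial_id=record.trial_id)


def select_dominant_channel(record: EEGRecord, criterion: str = "ptp") -> int:
    """Index of the channel with the biggest fluctuations.

    ``criterion`` is ``"ptp"`` (peak-to-peak amplitude, the default) or
    ``"variance"``.  Ties break toward the lowest index.
    """
    if criterion == "ptp":
        stat = record.data.max(axis=1) - record.data.min(axis=1)
    elif criterion == "variance":
        stat = record.data.var(axis=1)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return int(np.argmax(stat))


def average_trials(records: list[EEGRecord]) -> EEGRecord:
    """Element-wise arithmetic mean across same-shape trials (grand average)."""
    if not records:
        raise ValueError("need at least one record")
    first = records[0]
    for r in records[1:]:
        if r.data.shape != first.data.shape or r.fs != first.fs:
            raise ValueError("records differ in shape or sampling rate")
    mean = np.mean([r.data for r in records], axis=0)
    return EEGRecord(data=mean, fs=first.fs, subject_id=first.subject_id,
                     trial_id="grand_average")
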