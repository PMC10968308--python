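"""Signal/annotation data model and the plain-text formats used throughout.

All amplitudes are physical millivolts, never ADC codes; the converter
resolution is carried as device metadata only.  Time is 0-based seconds from
the start of the recording and every window or sample is the half-open
interval ``[t, t + len)``.

File formats (comma-separated, optional header auto-detected by a
non-numeric first row):

* signal:      ``time_s,value_mV`` or a single ``value_mV`` column (the
               sampling rate must then be supplied by the caller);
* labels:      ``sample_index,start_s,end_s,label``;
* annotations: ``start_s,end_s,label``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

logger = logging.getLogger(__name__)

#: Quality label for a readable trace (P, QRS and T all identifiable).
ACCEPTABLE = "acceptable"
#: Quality label for a trace whose QRS complexes cannot be identified.
UNACCEPTABLE = "unacceptable"

_LABEL_ALIASES = {
    "acceptable": ACCEPTABLE,
    "a": ACCEPTABLE,
    "unacceptable": UNACCEPTABLE,
    "u": UNACCEPTABLE,
}


class SignalIOError(ValueError):
    """Malformed signal, label or annotation input."""


def _canonical_label(token: str, *, where: str = "") -> str:
    try:
        return _LABEL_ALIASES[token.strip().lower()]
    except KeyError:
        raise SignalIOError(
            f"unknown quality label {token!r}{where}; "
            f"expected 'acceptable' or 'unacceptable'"
        ) from None


@dataclass(frozen=True)
class DeviceProfile:
    """Static description of the acquisition front end.

    Defaults describe a wearable single-lead recorder with an 18-bit ADC
    spanning ±500 mV.  ``full_span_mv`` (max − min) is the quantity the
    saturation rule is anchored to.
    """

    adc_min_mv: float = -500.0
    adc_max_mv: float = 500.0
    resolution_bits: int = 18
    name: str = "wearable-18bit"

    def __post_init__(self) -> None:
        if not self.adc_max_mv > self.adc_min_mv:
            raise ValueError("adc_max_mv must exceed adc_min_mv")
        if self.resolution_bits < 8:
            raise ValueError("resolution_bits must be >= 8")

    @property
    def full_span_mv(self) -> float:
        return self.adc_max_mv - self.adc_min_mv


@dataclass(frozen=True)
class ECGSignal:
    """A uniformly sampled single-lead ECG trace in mV.

    ``values`` are clipped to the device rails on construction; ``n_clipped``
    records how many input samples hit a rail (useful as a data-quality
    warning, independent of the window classifier).
    """

    values: np.ndarray
    fs: float
    device: DeviceProfile = field(default_factory=DeviceProfile)
    start_time_s: float = 0.0
    n_clipped: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("values must be a non-empty 1-D sequence")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        clipped = np.clip(values, self.device.adc_min_mv, self.device.adc_max_mv)
        n_clip = int(np.count_nonzero(clipped != values)) + self.n_clipped
        object.__setattr__(self, "values", clipped)
        object.__setattr__(self, "n_clipped", n_clip)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fs


@dataclass(frozen=True)
class AnnotationInterval:
    """One annotated quality period ``[start_s, end_s)``."""

    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(
                f"interval end ({self.end_s}) must exceed start ({self.start_s})"
            )
        object.__setattr__(self, "label", _canonical_label(self.label))

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class LabelSeries:
    """Consecutive fixed-length quality labels from the recording start."""

    sample_len_s: float
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.sample_len_s > 0:
            raise ValueError("sample_len_s must be positive")
        object.__setattr__(
            self, "labels", tuple(_canonical_label(lbl) for lbl in self.labels)
        )

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def unacceptable_fraction(self) -> float:
        if not self.labels:
            return 0.0
        return sum(lbl == UNACCEPTABLE for lbl in self.labels) / len(self.labels)


# ---------------------------------------------------------------------------
# parsing helpers


def _numeric_rows(path: Path | str, n_cols: Iterable[int]) -> list[tuple[int, list[str]]]:
    """Split a CSV file into (line_number, fields) rows, skipping one header.

    The header is detected by a non-numeric first field on the first
    non-blank line.  Raises :class:`SignalIOError` on an empty file or a
    column-count mismatch; per-field numeric validation is left to callers
    so error messages can name both the line and the offending value.
    """
    path = Path(path)
    rows: list[tuple[int, list[str]]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            rows.append((lineno, [tok.strip() for tok in line.split(",")]))
    if not rows:
        raise SignalIOError(f"{path}: file contains no data")
    first_field = rows[0][1][0]
    try:
        float(first_field)
    except ValueError:
        rows = rows[1:]  # header row
    if not rows:
        raise SignalIOError(f"{path}: file contains a header but no data")
    allowed = set(n_cols)
    for lineno, fields in rows:
        if len(fields) not in allowed:
            raise SignalIOError(
                f"{path}: line {lineno}: expected {sorted(allowed)} columns, "
                f"got {len(fields)}"
            )
    widths = {len(fields) for _, fields in rows}
    if len(widths) != 1:
        raise SignalIOError(f"{path}: inconsistent column counts {sorted(widths)}")
    return rows


def _parse_float(token: str, path: Path | str, lineno: int, col: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise SignalIOError(
            f"{path}: line {lineno}: non-numeric {col} value {token!r}"
        ) from None


def read_signal(
    path: Path | str,
    fs: float | None = None,
    device: DeviceProfile | None = None,
) -> ECGSignal:
    """Read a signal CSV (``time_s,value_mV`` or single ``value_mV`` column).

    For the two-column form the sampling rate is inferred from the time
    column when ``fs`` is not given, and the time grid must be uniform
    (any gap larger than 1.5 sampling intervals is an error).  Values are
    clipped to the device rails; the count of clipped samples is logged and
    stored on the returned signal.
    """
    device = device or DeviceProfile()
    rows = _numeric_rows(path, (1, 2))
    two_col = len(rows[0][1]) == 2
    if not two_col and fs is None:
        raise SignalIOError(
            f"{path}: single-column signal file requires an explicit sampling rate"
        )

    values = np.empty(len(rows))
    if two_col:
        times = np.empty(len(rows))
        for i, (lineno, fields) in enumerate(rows):
            times[i] = _parse_float(fields[0], path, lineno, "time_s")
            values[i] = _parse_float(fields[1], path, lineno, "value_mV")
        if len(rows) >= 2:
            dt = np.diff(times)
            if np.any(dt <= 0):
                bad = int(np.argmax(dt <= 0))
                raise SignalIOError(
                    f"{path}: time column not strictly increasing near row {bad + 1}"
                )
            if fs is None:
                fs = 1.0 / float(np.median(dt))
            if np.any(dt > 1.5 / fs):
                bad = int(np.argmax(dt > 1.5 / fs))
                raise SignalIOError(
                    f"{path}: non-uniform time column (gap of {dt[bad]:.6g} s "
                    f"near row {bad + 1} at fs={fs:.6g} Hz)"
                )
        elif fs is None:
            raise SignalIOError(
                f"{path}: cannot infer sampling rate from a single row"
            )
        start = float(times[0])
    else:
        for i, (lineno, fields) in enumerate(rows):
            values[i] = _parse_float(fields[0], path, lineno, "value_mV")
        start = 0.0

    n_clip = int(
        np.count_nonzero((values < device.adc_min_mv) | (values > device.adc_max_mv))
    )
    if n_clip:
        logger.warning("%s: %d sample(s) clipped to the device rails", path, n_clip)
    return ECGSignal(values=values, fs=float(fs), device=device, start_time_s=start)


def write_signal(
    signal: ECGSignal, path: Path | str, include_time: bool = True
) -> None:
    """Write a signal CSV with 6-decimal amplitudes (round-trip stable)."""
    path = Path(path)
    n = len(signal)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if include_time:
            fh.write("time_s,value_mV\n")
            t0 = signal.start_time_s
            for i in range(n):
                fh.write(f"{t0 + i / signal.fs:.6f},{signal.values[i]:.6f}\n")
        else:
            fh.write("value_mV\n")
            for i in range(n):
                fh.write(f"{signal.values[i]:.6f}\n")


def write_labels(series: LabelSeries, path: Path | str) -> None:
    """Write a label series CSV ``sample_index,start_s,end_s,label``."""
    if len(series) == 0:
        raise SignalIOError("refusing to write an empty label series")
    path = Path(path)
    step = series.sample_len_s
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_index,start_s,end_s,label\n")
        for i, lbl in enumerate(series):
            fh.write(f"{i},{i * step:g},{(i + 1) * step:g},{lbl}\n")


def read_labels(path: Path | str) -> LabelSeries:
    """Read a label series CSV written by :func:`write_labels`."""
    rows = _numeric_rows(path, (4,))
    labels: list[str] = []
    sample_len: float | None = None
    for lineno, fields in rows:
        start = _parse_float(fields[1], path, lineno, "start_s")
        end = _parse_float(fields[2], path, lineno, "end_s")
        if not end > start:
            raise SignalIOError(f"{path}: line {lineno}: end_s must exceed start_s")
        if sample_len is None:
            sample_len = end - start
        labels.append(
            _canonical_label(fields[3], where=f" at {path} line {lineno}")
        )
    assert sample_len is not None
    return LabelSeries(sample_len_s=sample_len, labels=tuple(labels))


def read_annotations(path: Path | str) -> tuple[AnnotationInterval, ...]:
    """Read, sort and validate an annotation track CSV ``start_s,end_s,label``.

    Intervals must be non-overlapping once sorted by start time; a violation
    is reported naming the offending pair.
    """
    rows = _numeric_rows(path, (3,))
    intervals: list[AnnotationInterval] = []
    for lineno, fields in rows:
        start = _parse_float(fields[0], path, lineno, "start_s")
        end = _parse_float(fields[1], path, lineno, "end_s")
        label = _canonical_label(fields[2], where=f" at {path} line {lineno}")
        try:
            intervals.append(AnnotationInterval(start, end, label))
        except ValueError as exc:
            raise SignalIOError(f"{path}: line {lineno}: {exc}") from None
    intervals.sort(key=lambda iv: (iv.start_s, iv.end_s))
    for prev, cur in zip(intervals, intervals[1:]):
        if cur.start_s < prev.end_s:
            raise SignalIOError(
                f"{path}: overlapping annotation intervals "
                f"[{prev.start_s}, {prev.end_s}) and [{cur.start_s}, {cur.end_s})"
            )
    return tuple(intervals)


def with_values(signal: ECGSignal, values: np.ndarray) -> ECGSignal:
    """Return a copy of ``signal`` with new amplitude values (re-clipped)."""
    return replace(signal, values=values, n_clipped=0)
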