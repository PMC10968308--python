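"""Template-referenced window classification of ECG readability.

The classifier runs in four stages:

1. **Reference template** — scan the recording (1 s steps from t = 0) for
   the first stable 10 s span: peak-to-peak amplitude below 70 % of the ADC
   full span and an approximately constant isoelectric line.  Its max, min
   and standard deviation (``max_t``, ``min_t``, ``sd_t``) become the
   per-recording standard of a readable signal.
2. **Window statistics** — split the trace into consecutive, non-overlapping
   2 s windows and compute mean, max, min and SD for each.
3. **Absolute rules** — a window is unacceptable if it nearly spans the ADC
   range (``max_w − min_w > 0.95 × full span``: electrode loss/saturation)
   or if its range falls below 5 % of the template range (flat or missing
   ECG).
4. **Relative rule** — a window is unacceptable if ``SD_w > 2 × SD_t``
   (high-variability noise such as muscle artifact).  Because only the SD is
   compared, a drifting but otherwise clean baseline stays acceptable.

Window verdicts are aggregated into 10 s sample labels by prevalence
(the class covering at least half of the sample), which is also how interval
annotations from a human reader are rasterized for comparison.

All inequalities are strict and the rules short-circuit in the order
saturation → low_amplitude → excess_sd; the reported ``reason`` is the first
rule fired.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .signal_io import (
    ACCEPTABLE,
    UNACCEPTABLE,
    AnnotationInterval,
    DeviceProfile,
    ECGSignal,
    LabelSeries,
)

logger = logging.getLogger(__name__)

REASON_OK = "ok"
REASON_SATURATION = "saturation"
REASON_LOW_AMPLITUDE = "low_amplitude"
REASON_EXCESS_SD = "excess_sd"


class NoStableReferenceError(RuntimeError):
    """No stable reference period exists in the recording.

    Callers may fall back to a preset template derived from the device
    characteristics, or to manually chosen template bounds.
    """


@dataclass(frozen=True)
class ReferenceTemplate:
    """Reference statistics from the first stable 10 s period."""

    max_t: float
    min_t: float
    sd_t: float
    start_s: float = 0.0
    duration_s: float = 10.0

    def __post_init__(self) -> None:
        if not self.max_t > self.min_t:
            raise ValueError("template max must exceed min")
        if not self.sd_t > 0:
            raise ValueError("template SD must be positive")
        if self.duration_s < 10.0:
            raise ValueError("template period must last at least 10 s")

    @property
    def range_t(self) -> float:
        return self.max_t - self.min_t


@dataclass(frozen=True)
class WindowStats:
    """Descriptive statistics of one analysis window.

    The mean is computed and reported because it is one of the readability
    parameters (and is cheap in a streaming implementation), but no decision
    rule uses it — classification relies on max, min and SD only.
    """

    index: int
    start_s: float
    mean_w: float
    max_w: float
    min_w: float
    sd_w: float

    @property
    def range_w(self) -> float:
        return self.max_w - self.min_w


@dataclass(frozen=True)
class WindowVerdict:
    """Quality verdict for one window: label plus the first rule fired."""

    stats: WindowStats
    label: str
    reason: str

    def __post_init__(self) -> None:
        if (self.label == ACCEPTABLE) != (self.reason == REASON_OK):
            raise ValueError("label 'acceptable' must pair with reason 'ok'")


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable thresholds; the defaults are the validated configuration.

    ``saturation_factor``, ``floor_fraction`` and ``sd_multiplier`` are the
    three published rule thresholds (0.95 × ADC span, 5 % of the template
    range, 2 × SD_t).  ``template_variability_fraction`` (70 % of the ADC
    span) bounds a candidate template's peak-to-peak amplitude;
    ``baseline_drift_fraction`` operationalizes "constant isoelectric line"
    as the spread of per-1 s sub-window means relative to the candidate's
    own peak-to-peak amplitude.
    """

    window_len_s: float = 2.0
    sample_len_s: float = 10.0
    saturation_factor: float = 0.95
    floor_fraction: float = 0.05
    sd_multiplier: float = 2.0
    template_min_duration_s: float = 10.0
    template_variability_fraction: float = 0.70
    baseline_drift_fraction: float = 0.10

    def __post_init__(self) -> None:
        for name in (
            "saturation_factor",
            "floor_fraction",
            "template_variability_fraction",
            "baseline_drift_fraction",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not self.sd_multiplier > 1:
            raise ValueError("sd_multiplier must exceed 1")
        if self.window_len_s <= 0 or self.sample_len_s <= 0:
            raise ValueError("window and sample lengths must be positive")
        if self.template_min_duration_s <= 0:
            raise ValueError("template_min_duration_s must be positive")
        k = self.sample_len_s / self.window_len_s
        if abs(k - round(k)) > 1e-9 or round(k) < 1:
            raise ValueError("window_len_s must divide sample_len_s")

    @property
    def windows_per_sample(self) -> int:
        return int(round(self.sample_len_s / self.window_len_s))


def compute_window_stats(
    segment: Sequence[float] | np.ndarray, start_s: float, index: int
) -> WindowStats:
    """Mean/max/min/SD of one contiguous window.

    The SD uses the population denominator (n); at the hundreds of samples
    per window typical here the n vs n−1 difference is negligible, and
    fixing it keeps results reproducible.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.ndim != 1 or seg.size < 2:
        raise ValueError("window segment must contain at least 2 samples")
    return WindowStats(
        index=index,
        start_s=start_s,
        mean_w=float(np.mean(seg)),
        max_w=float(np.max(seg)),
        min_w=float(np.min(seg)),
        sd_w=float(np.std(seg)),
    )


def find_reference_template(
    signal: ECGSignal, cfg: ClassifierConfig | None = None
) -> ReferenceTemplate:
    """Locate the earliest stable span and return its reference statistics.

    Candidate spans of ``template_min_duration_s`` are scanned in 1 s steps
    from t = 0.  A span qualifies when (a) its peak-to-peak amplitude is
    below ``template_variability_fraction`` of the ADC full span, and (b) the
    spread of its per-1 s sub-window means is at most
    ``baseline_drift_fraction`` of its own peak-to-peak amplitude (stable
    isoelectric line).  Dead-flat spans (zero peak-to-peak) are rejected:
    they carry no amplitude reference and would make ``sd_t`` degenerate.

    Raises :class:`NoStableReferenceError` when no span qualifies.
    """
    cfg = cfg or ClassifierConfig()
    fs = signal.fs
    n_tpl = int(round(cfg.template_min_duration_s * fs))
    if len(signal) < n_tpl:
        raise NoStableReferenceError(
            f"recording shorter ({signal.duration_s:.1f} s) than the "
            f"minimum template duration ({cfg.template_min_duration_s:g} s)"
        )
    step = max(1, int(round(fs)))  # 1 s scan granularity
    n_sub = max(1, int(round(fs)))  # 1 s sub-windows for baseline stability
    span_limit = cfg.template_variability_fraction * signal.device.full_span_mv
    values = signal.values
    for i0 in range(0, len(values) - n_tpl + 1, step):
        seg = values[i0 : i0 + n_tpl]
        ptp = float(np.max(seg) - np.min(seg))
        if ptp <= 0 or ptp >= span_limit:
            continue
        n_full = (seg.size // n_sub) * n_sub
        means = seg[:n_full].reshape(-1, n_sub).mean(axis=1)
        if float(np.max(means) - np.min(means)) <= cfg.baseline_drift_fraction * ptp:
            return ReferenceTemplate(
                max_t=float(np.max(seg)),
                min_t=float(np.min(seg)),
                sd_t=float(np.std(seg)),
                start_s=signal.start_time_s + i0 / fs,
                duration_s=cfg.template_min_duration_s,
            )
    raise NoStableReferenceError(
        "no stable reference period found; supply a preset template"
    )


def classify_window(
    stats: WindowStats,
    template: ReferenceTemplate,
    device: DeviceProfile,
    cfg: ClassifierConfig | None = None,
) -> WindowVerdict:
    """Apply the three rejection rules to one window's statistics.

    Rule order (short-circuit): saturation → low_amplitude → excess_sd.
    All comparisons are strict.  The saturation rule is anchored to the ADC
    full span (max − min of the input range) and is therefore absolute; the
    amplitude floor and SD rules are relative to the template.
    """
    cfg = cfg or ClassifierConfig()
    rng_w = stats.max_w - stats.min_w
    if rng_w > cfg.saturation_factor * device.full_span_mv:
        return WindowVerdict(stats, UNACCEPTABLE, REASON_SATURATION)
    if rng_w < cfg.floor_fraction * template.range_t:
        return WindowVerdict(stats, UNACCEPTABLE, REASON_LOW_AMPLITUDE)
    if stats.sd_w > cfg.sd_multiplier * template.sd_t:
        return WindowVerdict(stats, UNACCEPTABLE, REASON_EXCESS_SD)
    return WindowVerdict(stats, ACCEPTABLE, REASON_OK)


def classify_signal(
    signal: ECGSignal,
    cfg: ClassifierConfig | None = None,
    template: ReferenceTemplate | None = None,
) -> list[WindowVerdict]:
    """Classify every consecutive window of a recording.

    If no template is supplied one is located first with
    :func:`find_reference_template` (windows inside the template span are
    still classified like any others).  A trailing partial window is
    discarded and logged.
    """
    cfg = cfg or ClassifierConfig()
    if template is None:
        template = find_reference_template(signal, cfg)
    n_win = int(round(cfg.window_len_s * signal.fs))
    if len(signal) < n_win:
        raise ValueError(
            f"recording shorter ({signal.duration_s:.1f} s) than one "
            f"window ({cfg.window_len_s:g} s)"
        )
    n_windows = len(signal) // n_win
    leftover = len(signal) - n_windows * n_win
    if leftover:
        logger.info(
            "discarding trailing partial window of %d sample(s) (%.3f s)",
            leftover,
            leftover / signal.fs,
        )
    verdicts: list[WindowVerdict] = []
    for w in range(n_windows):
        stats = compute_window_stats(
            signal.values[w * n_win : (w + 1) * n_win],
            start_s=signal.start_time_s + w * cfg.window_len_s,
            index=w,
        )
        verdicts.append(classify_window(stats, template, signal.device, cfg))
    return verdicts


def aggregate_windows_to_samples(
    verdicts: Sequence[WindowVerdict], cfg: ClassifierConfig | None = None
) -> LabelSeries:
    """Collapse consecutive window verdicts into fixed-length sample labels.

    Each group of ``sample_len_s / window_len_s`` windows yields one label by
    majority of covered duration.  With the default 2 s windows in 10 s
    samples (k = 5) no tie is possible; for even k an exact tie is labeled
    unacceptable — the conservative choice for a quality gate.  A trailing
    incomplete group is dropped with a log entry.
    """
    cfg = cfg or ClassifierConfig()
    if not verdicts:
        raise ValueError("cannot aggregate an empty verdict sequence")
    k = cfg.windows_per_sample
    n_samples = len(verdicts) // k
    if len(verdicts) % k:
        logger.info(
            "discarding %d trailing window verdict(s) not filling a sample",
            len(verdicts) % k,
        )
    labels = []
    for s in range(n_samples):
        group = verdicts[s * k : (s + 1) * k]
        n_unacc = sum(v.label == UNACCEPTABLE for v in group)
        labels.append(UNACCEPTABLE if 2 * n_unacc >= k else ACCEPTABLE)
    return LabelSeries(sample_len_s=cfg.sample_len_s, labels=tuple(labels))


def intervals_to_sample_labels(
    track: Iterable[AnnotationInterval],
    total_duration_s: float,
    sample_len_s: float = 10.0,
) -> LabelSeries:
    """Rasterize interval annotations onto fixed-length sample labels.

    Each sample takes the label of whichever class covers at least half of
    it (prevalence rule); an exact tie is unacceptable.  Time not covered by
    any interval is treated as unacceptable and logged.  A trailing
    remainder of ``total_duration_s`` shorter than one sample is dropped
    with a warning.
    """
    intervals = sorted(track, key=lambda iv: iv.start_s)
    n_samples = int(math.floor(total_duration_s / sample_len_s + 1e-9))
    if n_samples < 1:
        raise ValueError("total duration shorter than one sample")
    remainder = total_duration_s - n_samples * sample_len_s
    if remainder > 1e-9:
        logger.warning(
            "dropping trailing %.3f s not filling a %g s sample",
            remainder,
            sample_len_s,
        )
    covered = sum(
        max(0.0, min(iv.end_s, n_samples * sample_len_s) - max(iv.start_s, 0.0))
        for iv in intervals
    )
    if covered < n_samples * sample_len_s - 1e-6:
        logger.warning(
            "annotation track leaves %.3f s uncovered; uncovered time "
            "counts as unacceptable",
            n_samples * sample_len_s - covered,
        )
    labels = []
    for s in range(n_samples):
        a, b = s * sample_len_s, (s + 1) * sample_len_s
        acc = sum(
            max(0.0, min(iv.end_s, b) - max(iv.start_s, a))
            for iv in intervals
            if iv.label == ACCEPTABLE
        )
        labels.append(ACCEPTABLE if acc > sample_len_s / 2 else UNACCEPTABLE)
    return LabelSeries(sample_len_s=sample_len_s, labels=tuple(labels))


class StreamingClassifier:
    """Sample-by-sample classifier, verdict-for-verdict identical to batch.

    Samples are pushed as they are acquired; one :class:`WindowVerdict` is
    emitted every ``window_len_s × fs`` pushes — i.e. classification is
    available with the delay of one window length.  The window buffer is
    handed to the same statistics routine as the batch path, so emitted
    verdicts equal :func:`classify_signal` on the same series exactly.

    A template must be supplied up front (preset, or found earlier on a
    stable stretch of the same stream).
    """

    def __init__(
        self,
        fs: float,
        template: ReferenceTemplate,
        device: DeviceProfile | None = None,
        cfg: ClassifierConfig | None = None,
        start_time_s: float = 0.0,
    ) -> None:
        if not fs > 0:
            raise ValueError("sampling rate must be positive")
        self.fs = fs
        self.template = template
        self.device = device or DeviceProfile()
        self.cfg = cfg or ClassifierConfig()
        self.start_time_s = start_time_s
        self._n_win = int(round(self.cfg.window_len_s * fs))
        if self._n_win < 2:
            raise ValueError("window must span at least 2 samples")
        self._buf = np.empty(self._n_win)
        self._fill = 0
        self._emitted = 0
        self._closed = False

    def push(self, value: float) -> WindowVerdict | None:
        """Feed one sample; returns a verdict when a window completes."""
        if self._closed:
            raise RuntimeError("push() after close()")
        self._buf[self._fill] = np.clip(
            value, self.device.adc_min_mv, self.device.adc_max_mv
        )
        self._fill += 1
        if self._fill < self._n_win:
            return None
        stats = compute_window_stats(
            self._buf,
            start_s=self.start_time_s + self._emitted * self.cfg.window_len_s,
            index=self._emitted,
        )
        verdict = classify_window(stats, self.template, self.device, self.cfg)
        self._emitted += 1
        self._fill = 0
        return verdict

    def push_many(self, values: Iterable[float]) -> list[WindowVerdict]:
        """Convenience wrapper: push a chunk, return the verdicts emitted."""
        out = []
        for v in values:
            verdict = self.push(v)
            if verdict is not None:
                out.append(verdict)
        return out

    def close(self) -> int:
        """Stop the stream; returns the number of buffered samples dropped."""
        self._closed = True
        dropped = self._fill
        if dropped:
            logger.info("closing stream: %d buffered sample(s) dropped", dropped)
        self._fill = 0
        return dropped

    @property
    def n_emitted(self) -> int:
        return self._emitted
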