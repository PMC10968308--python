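"""Seeded synthetic single-lead ECG with scheduled artifact episodes.

The generator exists so the full validation study — template search, window
classification, prevalence aggregation, diagnostic metrics — can run without
any recorded data.  A clean trace is a train of Gaussian deflections (one
per P, Q, R, S, T wave) at jittered RR intervals; artifact episodes are then
laid on top:

``baseline_wander``
    low-frequency (≤ 0.5 Hz) sinusoid added to the trace — a readable
    artifact the classifier is meant to tolerate;
``powerline``
    50 Hz mains sinusoid added to the trace — the classifier's documented
    blind spot (small amplitude barely moves the window SD);
``muscle``
    band-limited (high-passed) zero-mean noise of a given SD — unreadable
    when the noise SD reaches the clean-signal SD;
``saturation``
    the trace is replaced by a large low-frequency oscillation clipped at
    the ADC rails, emulating electrode loss;
``flatline``
    the trace is scaled down to a small residual fraction, emulating a
    disconnected or shorted lead.

Ground-truth labels derive deterministically from the episode schedule: a
2 s window is truth-unacceptable iff at least half of it is covered by a
corrupting episode (saturation, flatline, or muscle whose SD is at least
the clean-signal SD).  Baseline wander is always truth-acceptable;
powerline is truth-acceptable by default and truth-unacceptable under the
``strict_powerline`` convention, which mirrors how a human reader scores
mains interference and lets the blind spot be measured as a sensitivity
deficit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .signal_io import (
    ACCEPTABLE,
    UNACCEPTABLE,
    DeviceProfile,
    ECGSignal,
    LabelSeries,
)

EPISODE_KINDS = ("baseline_wander", "saturation", "muscle", "flatline", "powerline")

#: Episodes that corrupt readability (used by the ground-truth rule).
CORRUPTING_KINDS = ("saturation", "flatline", "muscle")

_EPISODE_DEFAULTS: dict[str, dict[str, float]] = {
    "baseline_wander": {"amplitude_mv": 0.15, "frequency_hz": 0.25},
    "powerline": {"amplitude_mv": 0.10, "frequency_hz": 50.0},
    "muscle": {"sd_mv": 0.5, "highpass_hz": 20.0},
    "saturation": {"amplitude_mv": 600.0, "frequency_hz": 1.0},
    "flatline": {"residual_fraction": 0.02},
}


@dataclass(frozen=True)
class Wave:
    """One Gaussian deflection: amplitude (mV), center (fraction of the
    RR interval relative to the R peak) and width (s)."""

    amplitude_mv: float
    center_frac: float
    width_s: float

    def __post_init__(self) -> None:
        if not self.width_s > 0:
            raise ValueError("wave width must be positive")


@dataclass(frozen=True)
class BeatModel:
    """Sum-of-Gaussians beat morphology with typical single-lead amplitudes.

    Defaults: R = 1.0 mV, P = 0.15 mV, T = 0.3 mV, Q = S = −0.1 mV, with
    wave centers placed as fractions of the RR interval around the R peak.
    """

    p: Wave = Wave(0.15, -0.18, 0.025)
    q: Wave = Wave(-0.10, -0.035, 0.010)
    r: Wave = Wave(1.00, 0.0, 0.012)
    s: Wave = Wave(-0.10, 0.035, 0.010)
    t: Wave = Wave(0.30, 0.28, 0.050)
    heart_rate_bpm: float = 70.0
    hr_jitter_fraction: float = 0.03

    def __post_init__(self) -> None:
        if not 30 <= self.heart_rate_bpm <= 220:
            raise ValueError("heart rate must lie in [30, 220] bpm")
        if self.hr_jitter_fraction < 0:
            raise ValueError("hr_jitter_fraction must be non-negative")
        r_amp = abs(self.r.amplitude_mv)
        for w in (self.p, self.q, self.s, self.t):
            if abs(w.amplitude_mv) >= r_amp:
                raise ValueError("R wave must dominate all other amplitudes")

    @property
    def waves(self) -> tuple[Wave, ...]:
        return (self.p, self.q, self.r, self.s, self.t)

    @property
    def rr_s(self) -> float:
        return 60.0 / self.heart_rate_bpm


@dataclass(frozen=True)
class NoiseEpisode:
    """One scheduled artifact episode ``[start_s, start_s + duration_s)``."""

    kind: str
    start_s: float
    duration_s: float
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EPISODE_KINDS:
            raise ValueError(f"unknown episode kind {self.kind!r}")
        if not self.duration_s > 0:
            raise ValueError("episode duration must be positive")
        if self.start_s < 0:
            raise ValueError("episode start must be non-negative")
        merged = dict(_EPISODE_DEFAULTS[self.kind])
        unknown = set(self.params) - set(merged)
        if unknown:
            raise ValueError(f"unknown {self.kind} parameter(s): {sorted(unknown)}")
        merged.update(self.params)
        object.__setattr__(self, "params", merged)

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class SynthRecipe:
    """Full, seeded description of one synthetic recording."""

    duration_s: float
    fs: float = 250.0
    device: DeviceProfile = field(default_factory=DeviceProfile)
    beat: BeatModel = field(default_factory=BeatModel)
    episodes: tuple[NoiseEpisode, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s < 20:
            raise ValueError(
                "recording must last at least 20 s (room for a stable template)"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "episodes", tuple(self.episodes))
        for ep in self.episodes:
            if ep.end_s > self.duration_s + 1e-9:
                raise ValueError(
                    f"{ep.kind} episode [{ep.start_s}, {ep.end_s}) extends "
                    f"past the {self.duration_s} s recording"
                )


@dataclass(frozen=True)
class SynthResult:
    """A generated recording with its deterministic ground truth."""

    signal: ECGSignal
    truth_windows: LabelSeries
    truth_samples: LabelSeries
    recipe: SynthRecipe


def _beat_times(recipe: SynthRecipe, rng: np.random.Generator) -> np.ndarray:
    """R-peak times: first peak at 0.4·RR, then jittered RR increments."""
    rr = recipe.beat.rr_s
    jitter = recipe.beat.hr_jitter_fraction
    times = []
    t = 0.4 * rr
    while t < recipe.duration_s + rr:
        times.append(t)
        step = rr * (1.0 + jitter * rng.standard_normal()) if jitter else rr
        t += max(0.3 * rr, step)
    return np.asarray(times)


def generate_clean_ecg(recipe: SynthRecipe) -> ECGSignal:
    """Render the artifact-free beat train for a recipe (episodes ignored).

    Deterministic given the recipe seed; amplitudes are checked to stay well
    inside the ADC rails.
    """
    rng = np.random.default_rng([recipe.seed, 0])
    n = int(round(recipe.duration_s * recipe.fs))
    t = np.arange(n) / recipe.fs
    values = np.zeros(n)
    rr = recipe.beat.rr_s
    for tk in _beat_times(recipe, rng):
        for wave in recipe.beat.waves:
            c = tk + wave.center_frac * rr
            lo = max(0, int((c - 4 * wave.width_s) * recipe.fs))
            hi = min(n, int((c + 4 * wave.width_s) * recipe.fs) + 1)
            if lo >= hi:
                continue
            values[lo:hi] += wave.amplitude_mv * np.exp(
                -0.5 * ((t[lo:hi] - c) / wave.width_s) ** 2
            )
    rail = min(abs(recipe.device.adc_min_mv), abs(recipe.device.adc_max_mv))
    if np.max(np.abs(values)) > 0.9 * rail:
        raise ValueError("beat model drives amplitudes into the ADC rails")
    return ECGSignal(values=values, fs=recipe.fs, device=recipe.device)


def apply_episodes(clean: ECGSignal, recipe: SynthRecipe) -> ECGSignal:
    """Overlay the recipe's artifact episodes on a clean trace.

    Additive kinds (wander, powerline, muscle) sum onto the signal;
    replacement kinds (saturation, flatline) overwrite it.  The result is
    clipped to the ADC rails.  Muscle noise is seeded from the recipe seed
    and the episode index, so identical recipes yield identical traces.
    """
    n = len(clean)
    fs = clean.fs
    values = clean.values.copy()
    for idx, ep in enumerate(recipe.episodes):
        i0 = int(round(ep.start_s * fs))
        i1 = min(n, int(round(ep.end_s * fs)))
        if i0 >= n or i0 >= i1:
            raise ValueError(f"episode {idx} ({ep.kind}) lies outside the record")
        tt = np.arange(i1 - i0) / fs
        p = ep.params
        if ep.kind == "baseline_wander":
            if p["frequency_hz"] > 0.5:
                raise ValueError("baseline wander must stay at or below 0.5 Hz")
            values[i0:i1] += p["amplitude_mv"] * np.sin(
                2 * np.pi * p["frequency_hz"] * tt
            )
        elif ep.kind == "powerline":
            values[i0:i1] += p["amplitude_mv"] * np.sin(
                2 * np.pi * p["frequency_hz"] * tt
            )
        elif ep.kind == "muscle":
            rng = np.random.default_rng([recipe.seed, 1, idx])
            noise = rng.standard_normal(i1 - i0)
            nyq = fs / 2.0
            if 0 < p["highpass_hz"] < nyq:
                b, a = sps.butter(4, p["highpass_hz"] / nyq, btype="highpass")
                noise = sps.filtfilt(b, a, noise)
            sd = float(np.std(noise))
            if sd > 0:
                noise *= p["sd_mv"] / sd
            values[i0:i1] += noise
        elif ep.kind == "saturation":
            values[i0:i1] = p["amplitude_mv"] * np.sin(
                2 * np.pi * p["frequency_hz"] * tt
            )
        elif ep.kind == "flatline":
            values[i0:i1] = clean.values[i0:i1] * p["residual_fraction"]
    np.clip(values, clean.device.adc_min_mv, clean.device.adc_max_mv, out=values)
    return ECGSignal(values=values, fs=fs, device=clean.device)


def _union_length(intervals: Sequence[tuple[float, float]]) -> float:
    merged_end = -math.inf
    total = 0.0
    for a, b in sorted(intervals):
        if b <= merged_end:
            continue
        total += b - max(a, merged_end)
        merged_end = b
    return total


def ground_truth_labels(
    recipe: SynthRecipe,
    window_len_s: float = 2.0,
    sample_len_s: float = 10.0,
    strict_powerline: bool = False,
) -> tuple[LabelSeries, LabelSeries]:
    """Derive window- and sample-level ground truth from the schedule.

    A window is truth-unacceptable iff corrupting episodes cover at least
    half of it.  Corrupting kinds are saturation, flatline, muscle with
    ``sd_mv`` at least the clean-signal SD, and — only under
    ``strict_powerline`` — powerline.  Sample labels follow the same
    prevalence rule the classifier uses (ties → unacceptable).
    """
    clean_sd = float(np.std(generate_clean_ecg(recipe).values))
    corrupting = []
    for ep in recipe.episodes:
        if ep.kind in ("saturation", "flatline"):
            corrupting.append((ep.start_s, ep.end_s))
        elif ep.kind == "muscle" and ep.params["sd_mv"] >= clean_sd:
            corrupting.append((ep.start_s, ep.end_s))
        elif ep.kind == "powerline" and strict_powerline:
            corrupting.append((ep.start_s, ep.end_s))
    n_windows = int(math.floor(recipe.duration_s / window_len_s + 1e-9))
    window_labels = []
    for w in range(n_windows):
        a, b = w * window_len_s, (w + 1) * window_len_s
        overlap = [
            (max(a, s), min(b, e)) for s, e in corrupting if min(b, e) > max(a, s)
        ]
        cov = _union_length(overlap)
        window_labels.append(
            UNACCEPTABLE if cov >= window_len_s / 2 else ACCEPTABLE
        )
    truth_windows = LabelSeries(window_len_s, tuple(window_labels))
    k = int(round(sample_len_s / window_len_s))
    n_samples = n_windows // k
    sample_labels = []
    for s in range(n_samples):
        group = window_labels[s * k : (s + 1) * k]
        n_unacc = sum(lbl == UNACCEPTABLE for lbl in group)
        sample_labels.append(UNACCEPTABLE if 2 * n_unacc >= k else ACCEPTABLE)
    truth_samples = LabelSeries(sample_len_s, tuple(sample_labels))
    return truth_windows, truth_samples


def simulate(
    recipe: SynthRecipe, strict_powerline: bool = False
) -> SynthResult:
    """Generate clean trace, overlay episodes, and attach ground truth."""
    clean = generate_clean_ecg(recipe)
    noisy = apply_episodes(clean, recipe)
    truth_w, truth_s = ground_truth_labels(recipe, strict_powerline=strict_powerline)
    return SynthResult(
        signal=noisy, truth_windows=truth_w, truth_samples=truth_s, recipe=recipe
    )


def generate_cohort(
    n_recordings: int,
    duration_s: float = 3600.0,
    target_unacceptable_fraction: float = 0.46,
    seed: int = 0,
    fs: float = 250.0,
    muscle_sd_mv: float = 0.5,
    strict_powerline: bool = False,
) -> list[SynthResult]:
    """Generate a cohort of recordings with a target corruption prevalence.

    Each recording opens with a 20 s clean lead-in (two whole 10 s samples)
    so the reference-template search always succeeds; every later 10 s
    sample is independently corrupted — by a saturation, flatline or muscle
    episode covering it entirely — with a probability rescaled so the
    expected pooled truth-unacceptable fraction equals the target.  Clean
    samples occasionally carry benign baseline-wander or low-amplitude
    powerline episodes.  Heart rate varies across recordings (55–85 bpm).
    """
    if not 0 <= target_unacceptable_fraction < 1:
        raise ValueError("target fraction must lie in [0, 1)")
    if n_recordings < 1:
        raise ValueError("need at least one recording")
    sample_len = 10.0
    n_samples = int(math.floor(duration_s / sample_len + 1e-9))
    lead_in_samples = 2
    n_eligible = n_samples - lead_in_samples
    if n_eligible < 1:
        raise ValueError("recording too short for a clean lead-in plus episodes")
    p_corrupt = target_unacceptable_fraction * n_samples / n_eligible
    if p_corrupt >= 1:
        raise ValueError(
            "target fraction infeasible with the mandatory clean lead-in"
        )
    rng = np.random.default_rng([seed, 2])
    results = []
    for _ in range(n_recordings):
        rec_seed = int(rng.integers(2**31))
        beat = BeatModel(
            heart_rate_bpm=float(rng.uniform(55, 85)), hr_jitter_fraction=0.03
        )
        episodes = []
        for k in range(lead_in_samples, n_samples):
            start = k * sample_len
            u = rng.random()
            if u < p_corrupt:
                kind = CORRUPTING_KINDS[int(rng.integers(len(CORRUPTING_KINDS)))]
                params = {"sd_mv": muscle_sd_mv} if kind == "muscle" else {}
                episodes.append(NoiseEpisode(kind, start, sample_len, params))
            elif u < p_corrupt + 0.10:
                episodes.append(NoiseEpisode("baseline_wander", start, sample_len))
            elif u < p_corrupt + 0.15:
                episodes.append(
                    NoiseEpisode("powerline", start, sample_len, {"amplitude_mv": 0.05})
                )
        recipe = SynthRecipe(
            duration_s=duration_s,
            fs=fs,
            beat=beat,
            episodes=tuple(episodes),
            seed=rec_seed,
        )
        results.append(simulate(recipe, strict_powerline=strict_powerline))
    return results


def recipe_from_dict(spec: Mapping, seed: int | None = None) -> SynthRecipe:
    """Build a recipe from a plain mapping (the JSON recipe file contract)."""
    beat_kwargs = dict(spec.get("beat", {}))
    episodes = tuple(
        NoiseEpisode(
            kind=ep["kind"],
            start_s=float(ep["start_s"]),
            duration_s=float(ep["duration_s"]),
            params={k: float(v) for k, v in ep.get("params", {}).items()},
        )
        for ep in spec.get("episodes", ())
    )
    return SynthRecipe(
        duration_s=float(spec["duration_s"]),
        fs=float(spec.get("fs", 250.0)),
        beat=BeatModel(**beat_kwargs) if beat_kwargs else BeatModel(),
        episodes=episodes,
        seed=int(spec["seed"] if seed is None else seed),
    )
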