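"""Agreement tables and diagnostic statistics for 10 s sample labels.

The positive class is *unacceptable* throughout: sensitivity is the
fraction of truly unreadable samples the algorithm flags, specificity the
fraction of readable samples it passes.  Confidence intervals use the
normal (Wald) approximation ``z · sqrt(p(1−p)/n)`` on the respective
denominators.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats as spstats

from .signal_io import UNACCEPTABLE, LabelSeries


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 agreement counts with positive class = unacceptable.

    ``tp``: both say unacceptable; ``fp``: reference acceptable but flagged;
    ``fn``: reference unacceptable but passed; ``tn``: both acceptable.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )

    def efficiency(self) -> float:
        """Fraction of correct classifications (overall agreement)."""
        if self.total == 0:
            raise ValueError("empty confusion matrix")
        return (self.tp + self.tn) / self.total


@dataclass(frozen=True)
class MetricsReport:
    """Diagnostic statistics derived from one confusion matrix.

    Ratios with a zero denominator are NaN and listed in ``undefined``
    rather than reported as infinities.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float
    efficiency: float
    prevalence: float
    ci_sensitivity_halfwidth: float
    ci_specificity_halfwidth: float
    ci_level: float
    n_total: int
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "lr_pos": self.lr_pos,
            "lr_neg": self.lr_neg,
            "efficiency": self.efficiency,
            "prevalence": self.prevalence,
            "ci_sensitivity_halfwidth": self.ci_sensitivity_halfwidth,
            "ci_specificity_halfwidth": self.ci_specificity_halfwidth,
            "ci_level": self.ci_level,
            "n_total": self.n_total,
            "undefined": list(self.undefined),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.as_dict(), indent=indent)

    def printed(self) -> dict:
        """Values at reporting precision: percentages to one decimal,
        LR+ to three significant figures, LR− to two."""
        out = {
            "sensitivity_pct": round(100 * self.sensitivity, 1),
            "specificity_pct": round(100 * self.specificity, 1),
            "ppv_pct": round(100 * self.ppv, 1),
            "npv_pct": round(100 * self.npv, 1),
            "efficiency_pct": round(100 * self.efficiency, 1),
            "prevalence_pct": round(100 * self.prevalence, 1),
            "ci_sensitivity_halfwidth_pct": round(
                100 * self.ci_sensitivity_halfwidth, 1
            ),
            "ci_specificity_halfwidth_pct": round(
                100 * self.ci_specificity_halfwidth, 1
            ),
            "lr_pos": _round_sig(self.lr_pos, 3),
            "lr_neg": _round_sig(self.lr_neg, 2),
        }
        return out

    def format_text(self) -> str:
        p = self.printed()
        lines = [
            f"n samples            {self.n_total}",
            f"prevalence           {p['prevalence_pct']:.1f}%",
            f"efficiency           {p['efficiency_pct']:.1f}%",
            f"sensitivity          {p['sensitivity_pct']:.1f}%  "
            f"(±{p['ci_sensitivity_halfwidth_pct']:.1f}% at "
            f"{self.ci_level:.0%} CI)",
            f"specificity          {p['specificity_pct']:.1f}%  "
            f"(±{p['ci_specificity_halfwidth_pct']:.1f}% at "
            f"{self.ci_level:.0%} CI)",
            f"PPV                  {p['ppv_pct']:.1f}%",
            f"NPV                  {p['npv_pct']:.1f}%",
            f"LR+                  {p['lr_pos']:g}",
            f"LR-                  {p['lr_neg']:g}",
        ]
        if self.undefined:
            lines.append(f"undefined            {', '.join(self.undefined)}")
        return "\n".join(lines)


def _round_sig(x: float, sig: int) -> float:
    if not math.isfinite(x) or x == 0:
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def confusion_from_labels(
    predicted: LabelSeries, reference: LabelSeries
) -> ConfusionMatrix:
    """Count 2×2 agreement between aligned predicted and reference labels."""
    if len(predicted) != len(reference):
        raise ValueError(
            f"label series lengths differ: {len(predicted)} vs {len(reference)}"
        )
    if abs(predicted.sample_len_s - reference.sample_len_s) > 1e-9:
        raise ValueError("label series use different sample lengths")
    tp = fp = fn = tn = 0
    for pred, ref in zip(predicted, reference):
        if ref == UNACCEPTABLE:
            if pred == UNACCEPTABLE:
                tp += 1
            else:
                fn += 1
        else:
            if pred == UNACCEPTABLE:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def compute_metrics(cm: ConfusionMatrix, ci_level: float = 0.95) -> MetricsReport:
    """Derive the full diagnostic report from a confusion matrix.

    sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), ppv = tp/(tp+fp),
    npv = tn/(tn+fn), efficiency = (tp+tn)/total, prevalence =
    (tp+fn)/total, LR+ = sens/(1−spec), LR− = (1−sens)/spec; Wald CI
    half-widths on sensitivity and specificity.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must lie in (0, 1)")
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    sens = ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    spec = ratio(cm.tn, cm.tn + cm.fp, "specificity")
    ppv = ratio(cm.tp, cm.tp + cm.fp, "ppv")
    npv = ratio(cm.tn, cm.tn + cm.fn, "npv")

    if math.isnan(sens) or math.isnan(spec) or spec == 1.0:
        undefined.append("lr_pos")
        lr_pos = float("nan")
    else:
        lr_pos = sens / (1.0 - spec)
    if math.isnan(sens) or math.isnan(spec) or spec == 0.0:
        undefined.append("lr_neg")
        lr_neg = float("nan")
    else:
        lr_neg = (1.0 - sens) / spec

    z = float(spstats.norm.ppf(0.5 + ci_level / 2.0))

    def wald(p: float, n: int) -> float:
        if math.isnan(p) or n == 0:
            return float("nan")
        return z * math.sqrt(p * (1.0 - p) / n)

    return MetricsReport(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        efficiency=cm.efficiency(),
        prevalence=(cm.tp + cm.fn) / cm.total,
        ci_sensitivity_halfwidth=wald(sens, cm.tp + cm.fn),
        ci_specificity_halfwidth=wald(spec, cm.tn + cm.fp),
        ci_level=ci_level,
        n_total=cm.total,
        undefined=tuple(undefined),
    )


@dataclass(frozen=True)
class RecordingSummary:
    """Per-recording efficiencies with their order statistics."""

    ids: tuple[str, ...]
    efficiencies: tuple[float, ...]
    mean: float
    median: float
    min: float
    max: float


def summarize_by_recording(
    per_recording: Sequence[tuple[str, ConfusionMatrix]]
) -> RecordingSummary:
    """Per-recording efficiency list plus mean/median/min/max."""
    if not per_recording:
        raise ValueError("no recordings to summarize")
    ids = tuple(str(rid) for rid, _ in per_recording)
    effs = tuple(cm.efficiency() for _, cm in per_recording)
    ordered = sorted(effs)
    n = len(ordered)
    median = (
        ordered[n // 2]
        if n % 2
        else 0.5 * (ordered[n // 2 - 1] + ordered[n // 2])
    )
    return RecordingSummary(
        ids=ids,
        efficiencies=effs,
        mean=sum(effs) / n,
        median=median,
        min=ordered[0],
        max=ordered[-1],
    )


def confusion_to_csv(cm: ConfusionMatrix) -> str:
    """Agreement table as CSV: algorithm rows × reference columns."""
    return (
        "algorithm\\reference,unacceptable,acceptable,total\n"
        f"unacceptable,{cm.tp},{cm.fp},{cm.tp + cm.fp}\n"
        f"acceptable,{cm.fn},{cm.tn},{cm.fn + cm.tn}\n"
        f"total,{cm.tp + cm.fn},{cm.fp + cm.tn},{cm.total}\n"
    )
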