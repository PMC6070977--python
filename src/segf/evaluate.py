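"""Confusion-matrix statistics and dilution arithmetic for caller benchmarking.

Sensitivity, specificity and positive-detection (TP) rate are computed with
exact rational arithmetic and only rounded (half-up, two decimals) for
display; an undefined statistic (e.g. specificity on an all-positive cohort)
is reported as absent and rendered "-".
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Mapping

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ConfusionStats:
    """Percentages as exact Fractions; None where the denominator is zero."""

    sensitivity: Fraction | None
    specificity: Fraction | None
    tp_rate: Fraction | None

    def display(self) -> dict[str, str]:
        return {
            "sensitivity": format_percent(self.sensitivity),
            "specificity": format_percent(self.specificity),
            "tp_rate": format_percent(self.tp_rate),
        }


def round2(value: float | Fraction) -> float:
    """Round half-up to two decimals (display convention)."""
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(str(value))
    return float(dec.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def format_percent(value: float | Fraction | None) -> str:
    if value is None:
        return "-"
    return f"{round2(value):.2f}%"


def confusion_stats(c: ConfusionCounts) -> ConfusionStats:
    """sensitivity = 100*tp/(tp+fn); specificity = 100*tn/(tn+fp);
    tp_rate = 100*tp/total. Each is None when its denominator is zero."""
    sensitivity = Fraction(100 * c.tp, c.tp + c.fn) if c.tp + c.fn > 0 else None
    specificity = Fraction(100 * c.tn, c.tn + c.fp) if c.tn + c.fp > 0 else None
    tp_rate = Fraction(100 * c.tp, c.total) if c.total > 0 else None
    return ConfusionStats(sensitivity=sensitivity, specificity=specificity, tp_rate=tp_rate)


def diluted_frequency(base_freq: float, dilution_factor: float) -> float:
    """Fusion frequency (in percent) after diluting by ``dilution_factor``."""
    if base_freq < 0:
        raise ValueError(f"base frequency must be >= 0, got {base_freq}")
    if dilution_factor < 1:
        raise ValueError(f"dilution factor must be >= 1, got {dilution_factor}")
    return base_freq / dilution_factor


def calls_contain_pair(calls: Iterable, pair: tuple[str, str]) -> bool:
    """True when any call matches the (order-insensitive) gene pair."""
    want = tuple(sorted(pair))
    return any(tuple(sorted((c.gene_a, c.gene_b))) == want for c in calls)


def compare_to_truth(
    calls_by_sample: Mapping[str, Iterable],
    labels: Mapping[str, str],
    pair: tuple[str, str],
) -> ConfusionCounts:
    """Tally per-sample binary classification for one gene pair.

    A sample is classified positive when its call set contains the pair of
    interest; calls for other gene pairs do not make a negative sample
    false-positive (the tally is pair-scoped). Samples present in
    ``calls_by_sample`` but missing from ``labels`` are an error; labelled
    samples with no calls entry count as uncalled.
    """
    unlabelled = set(calls_by_sample) - set(labels)
    if unlabelled:
        raise ValueError(f"unlabelled sample(s): {sorted(unlabelled)}")
    tp = tn = fp = fn = 0
    for sample, label in labels.items():
        if label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"sample {sample!r}: label must be positive/negative, got {label!r}")
        called = calls_contain_pair(calls_by_sample.get(sample, ()), pair)
        if label == POSITIVE:
            tp, fn = (tp + 1, fn) if called else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if called else (fp, tn + 1)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
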