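"""Classifier validation metrics and affinity/energy conversion.

Balanced accuracy, precision, TPR, FPR, TPR/FPR ratio on a 2x2 confusion
table; the two-sided Fisher exact test under the probability-mass
extremeness criterion; and the conversion dG = R T ln(Kd) used to turn
dissociation constants into binding free energies for ground-truth
strength labels (strong iff dG < -12 kcal/mol, weak iff dG > -8,
intermediate excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import hypergeom

#: Gas constant in kcal / (mol K).
R_KCAL = 1.987e-3

#: Ground-truth strength thresholds (kcal/mol) for affinity benchmarks.
STRONG_DG_MAX = -12.0
WEAK_DG_MIN = -8.0


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("confusion table must be non-empty")


@dataclass(frozen=True)
class ConfusionMetrics:
    balanced_accuracy: float | None
    precision: float | None
    tpr: float | None
    fpr: float | None
    tpr_fpr_ratio: float | None
    ratio_infinite: bool = False


def confusion_metrics(table: ConfusionTable) -> ConfusionMetrics:
    """Standard rates from a confusion table.

    Undefined quantities (empty margins, zero FPR for the ratio) are
    returned as None, with ``ratio_infinite`` flagging a positive TPR
    over a zero FPR.
    """
    pos = table.tp + table.fn
    neg = table.fp + table.tn
    tpr = table.tp / pos if pos > 0 else None
    fpr = table.fp / neg if neg > 0 else None
    precision = (
        table.tp / (table.tp + table.fp) if (table.tp + table.fp) > 0 else None
    )
    ba = (tpr + (1 - fpr)) / 2 if tpr is not None and fpr is not None else None
    ratio = None
    ratio_infinite = False
    if tpr is not None and fpr is not None:
        if fpr > 0:
            ratio = tpr / fpr
        elif tpr > 0:
            ratio_infinite = True
    return ConfusionMetrics(
        balanced_accuracy=ba,
        precision=precision,
        tpr=tpr,
        fpr=fpr,
        tpr_fpr_ratio=ratio,
        ratio_infinite=ratio_infinite,
    )


def fisher_exact_two_sided(table: ConfusionTable) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Sums hypergeometric probabilities of all tables with the same
    margins whose probability does not exceed that of the observed table
    (probability-mass criterion), within a small relative tolerance to
    absorb floating-point ties.
    """
    a, b = table.tp, table.fp
    c, d = table.fn, table.tn
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    dist = hypergeom(n, col1, row1)
    p_obs = dist.pmf(a)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    total = 0.0
    for k in range(lo, hi + 1):
        p_k = dist.pmf(k)
        if p_k <= p_obs * (1 + 1e-7):
            total += p_k
    return min(total, 1.0)


def kd_to_delta_g(kd: float, temperature: float = 298.0) -> float:
    """Binding free energy dG = R T ln(Kd), kcal/mol.

    Monotone increasing in Kd; Kd = 1 M gives 0.
    """
    if kd <= 0:
        raise ValueError("kd must be positive (molar)")
    if temperature <= 0:
        raise ValueError("temperature must be positive (Kelvin)")
    return R_KCAL * temperature * math.log(kd)


def delta_g_to_kd(delta_g: float, temperature: float = 298.0) -> float:
    """Inverse of :func:`kd_to_delta_g`."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (Kelvin)")
    return math.exp(delta_g / (R_KCAL * temperature))


def affinity_strength_label(delta_g: float) -> str | None:
    """Ground-truth strength from experimental dG.

    'strong' iff dG < -12 kcal/mol, 'weak' iff dG > -8; the intermediate
    band is excluded (None).
    """
    if delta_g < STRONG_DG_MAX:
        return "strong"
    if delta_g > WEAK_DG_MIN:
        return "weak"
    return None


def confusion_from_labels(
    predicted: list[str], truth: list[str], positive: str = "weak"
) -> ConfusionTable:
    """Build a confusion table from parallel label lists."""
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    tp = fp = tn = fn = 0
    for p, t in zip(predicted, truth):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn)
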