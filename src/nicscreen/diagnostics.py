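"""Diagnostic concordance of ploidy calls against a gold-standard reference.

The positive class throughout is "aneuploid/mosaic": sensitivity
TP/(TP+FN), specificity TN/(TN+FP), NPV TN/(TN+FN), PPV TP/(TP+FP), and
two-category concordance (TP+TN)/n. Samples without a result (technical
failure, indeterminate sex in sex mode) are excluded from denominators and
their count logged. Subgroup matrices (e.g. scored against inner-cell-mass
vs whole-blastocyst references) pool cellwise into the total matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .call import POSITIVE_CLASS, PloidyCall

__all__ = [
    "Rate",
    "ConfusionMatrix",
    "DiagnosticSummary",
    "confusion_matrix",
    "diagnostic_metrics",
    "pool_matrices",
    "concordance",
    "chi_square_2x2",
]

logger = logging.getLogger(__name__)

_POSITIVE_ALIASES = {POSITIVE_CLASS, "aneuploid", "mosaic", "positive"}
_NEGATIVE_ALIASES = {"euploid", "negative"}
_EXCLUDED = {"no_result", "indeterminate", "", "na", "nan", None}


@dataclass(frozen=True)
class Rate:
    """An exact fraction with its display convention (percent, 1 decimal)."""

    numerator: int
    denominator: int

    @property
    def value(self) -> float:
        return self.numerator / self.denominator

    @property
    def percent(self) -> float:
        """Percent rounded half-up to one decimal, the usual display
        convention (so 51.25% prints as 51.3)."""
        return float(np.floor(1000.0 * self.value + 0.5) / 10.0)

    def __str__(self) -> str:
        return f"{self.percent}% ({self.numerator}/{self.denominator})"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class DiagnosticSummary:
    """The four screening metrics plus two-category concordance; a metric
    whose denominator is zero is None (undefined), never 0."""

    sensitivity: Rate | None
    specificity: Rate | None
    npv: Rate | None
    ppv: Rate | None
    concordance: Rate | None


def _is_positive(label) -> bool:
    lab = str(label).strip().lower()
    if lab in {a.lower() for a in _POSITIVE_ALIASES}:
        return True
    if lab in {str(a).lower() for a in _NEGATIVE_ALIASES}:
        return False
    raise ValueError(f"unrecognized ploidy label {label!r}")


def _as_mapping(calls, attr: str = "classification") -> dict:
    if isinstance(calls, Mapping):
        return dict(calls)
    out = {}
    for item in calls:
        if isinstance(item, PloidyCall):
            out[item.sample_id] = getattr(item, attr)
        else:
            sid, label = item
            out[sid] = label
    return out


def _excluded(label) -> bool:
    return label is None or str(label).strip().lower() in {str(e).lower() for e in _EXCLUDED if e is not None} | {""}


def confusion_matrix(calls, truths) -> ConfusionMatrix:
    """Cross-tabulate calls against reference classifications by sample id.

    ``calls``/``truths`` are mappings id -> label, iterables of (id, label),
    or lists of PloidyCall (calls only). no_result calls are dropped (count
    logged); a call id missing from the truths raises.
    """
    call_map = _as_mapping(calls)
    truth_map = _as_mapping(truths)
    missing = sorted(set(call_map) - set(truth_map))
    if missing:
        raise ValueError(f"call ids without matching truth: {missing[:5]}")
    tp = fp = tn = fn = dropped = 0
    for sid, label in call_map.items():
        if _excluded(label):
            dropped += 1
            continue
        called = _is_positive(label)
        true = _is_positive(truth_map[sid])
        if called and true:
            tp += 1
        elif called and not true:
            fp += 1
        elif not called and true:
            fn += 1
        else:
            tn += 1
    if dropped:
        logger.info("confusion_matrix: %d no-result samples excluded", dropped)
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def diagnostic_metrics(cm: ConfusionMatrix) -> DiagnosticSummary:
    def rate(num: int, den: int) -> Rate | None:
        return Rate(num, den) if den > 0 else None

    return DiagnosticSummary(
        sensitivity=rate(cm.tp, cm.tp + cm.fn),
        specificity=rate(cm.tn, cm.tn + cm.fp),
        npv=rate(cm.tn, cm.tn + cm.fn),
        ppv=rate(cm.tp, cm.tp + cm.fp),
        concordance=rate(cm.tp + cm.tn, cm.n),
    )


def pool_matrices(*matrices: ConfusionMatrix) -> ConfusionMatrix:
    """Cellwise sum of confusion matrices (subgroup -> total pooling)."""
    return ConfusionMatrix(
        tp=sum(m.tp for m in matrices),
        fp=sum(m.fp for m in matrices),
        tn=sum(m.tn for m in matrices),
        fn=sum(m.fn for m in matrices),
    )


def concordance(calls, truths, mode: str = "ploidy") -> Rate:
    """Fraction of evaluable samples whose call matches the reference.

    mode='ploidy' compares the two-category classification; mode='sex'
    compares sex calls. no_result / indeterminate samples are excluded and
    logged; an empty evaluable set raises.
    """
    if mode not in ("ploidy", "sex"):
        raise ValueError("mode must be 'ploidy' or 'sex'")
    attr = "classification" if mode == "ploidy" else "sex"
    call_map = _as_mapping(calls, attr=attr)
    truth_map = _as_mapping(truths, attr=attr)
    missing = sorted(set(call_map) - set(truth_map))
    if missing:
        raise ValueError(f"call ids without matching truth: {missing[:5]}")
    matches = evaluable = dropped = 0
    for sid, label in call_map.items():
        truth = truth_map[sid]
        if _excluded(label) or _excluded(truth):
            dropped += 1
            continue
        evaluable += 1
        if mode == "ploidy":
            same = _is_positive(label) == _is_positive(truth)
        else:
            same = str(label).strip().upper() == str(truth).strip().upper()
        matches += int(same)
    if dropped:
        logger.info("concordance[%s]: %d samples excluded", mode, dropped)
    if evaluable == 0:
        raise ValueError("no evaluable samples for concordance")
    return Rate(matches, evaluable)


def chi_square_2x2(
    a: int, b: int, c: int, d: int, continuity_correction: bool = True
) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]] with 1 df,
    optionally Yates-corrected. Requires positive row and column margins."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("cells must be non-negative")
    if np.any(table.sum(axis=0) <= 0) or np.any(table.sum(axis=1) <= 0):
        raise ValueError("both margins must be positive")
    stat, p, _, _ = stats.chi2_contingency(table, correction=continuity_correction)
    return float(stat), float(p)
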