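"""Screening evaluation metrics.

Sensitivity, specificity, accuracy, their unweighted mean (MAcc, the
PhysioNet challenge score with both coefficients at 0.5), and an
F-measure combining Sp and Se:

    F_beta = (1 + beta^2) * Sp * Se / (beta^2 * Sp + Se)

Note this F-measure pairs specificity with sensitivity where the
textbook F-score would use precision; it is kept in that form
deliberately (for beta = 1 it is the harmonic mean of Se and Sp).
All metrics are percentages, computed at full precision and rounded
half-up to 2 decimals only for display.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals (table formatting convention)."""
    if x is None:
        return None
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def confusion(labels, predictions, threshold: float = 0.5) -> tuple[int, int, int, int]:
    """(TP, FN, TN, FP) counts; prediction >= threshold is called positive (CHD)."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions, dtype=float)
    if labels.shape != predictions.shape:
        raise ValueError(f"length mismatch: {labels.shape} labels vs "
                         f"{predictions.shape} predictions")
    pos = predictions >= threshold
    y = labels.astype(bool)
    tp = int(np.sum(pos & y))
    fn = int(np.sum(~pos & y))
    tn = int(np.sum(~pos & ~y))
    fp = int(np.sum(pos & ~y))
    return tp, fn, tn, fp


def macc(se: float, sp: float) -> float:
    """Mean of sensitivity and specificity (percent), unweighted (0.5/0.5)."""
    return (se + sp) / 2.0


def f_beta(se: float, sp: float, beta: float = 1.0) -> float:
    """(1 + b^2) * Sp * Se / (b^2 * Sp + Se), in percent."""
    denom = beta ** 2 * sp + se
    if denom == 0:
        return 0.0
    return (1 + beta ** 2) * sp * se / denom


@dataclass
class EvalReport:
    """Confusion counts and derived screening metrics (percent)."""

    TP: int
    FN: int
    TN: int
    FP: int
    Se: float | None
    Sp: float | None
    Acc: float | None
    MAcc: float | None
    F_beta: float | None
    beta: float = 1.0

    @property
    def n(self) -> int:
        return self.TP + self.FN + self.TN + self.FP

    def rounded(self) -> dict:
        return {
            "TP": self.TP, "FN": self.FN, "TN": self.TN, "FP": self.FP,
            "Se": round2(self.Se), "Sp": round2(self.Sp), "Acc": round2(self.Acc),
            "MAcc": round2(self.MAcc), "F_beta": round2(self.F_beta),
            "beta": self.beta,
        }

    def to_json(self) -> str:
        return json.dumps(self.rounded(), indent=2)

    def to_csv_row(self) -> str:
        """One-row CSV in table column order: Acc, Se, Sp, MAcc, F-score."""
        r = self.rounded()
        vals = [r["Acc"], r["Se"], r["Sp"], r["MAcc"], r["F_beta"]]
        head = "Acc,Se,Sp,MAcc,F_score"
        return head + "\n" + ",".join("" if v is None else f"{v:.2f}" for v in vals)


def report(tp: int, fn: int, tn: int, fp: int, beta: float = 1.0) -> EvalReport:
    """Build an :class:`EvalReport` from confusion counts.

    A metric whose denominator class is empty is reported as None
    (missing) rather than 0, and MAcc/F follow suit.
    """
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("confusion counts must be non-negative")
    se = 100.0 * tp / (tp + fn) if tp + fn > 0 else None
    sp = 100.0 * tn / (tn + fp) if tn + fp > 0 else None
    total = tp + fn + tn + fp
    acc = 100.0 * (tp + tn) / total if total > 0 else None
    if se is not None and sp is not None:
        ma = macc(se, sp)
        fb = f_beta(se, sp, beta)
    else:
        ma = fb = None
    return EvalReport(TP=tp, FN=fn, TN=tn, FP=fp, Se=se, Sp=sp, Acc=acc,
                      MAcc=ma, F_beta=fb, beta=beta)


def evaluate(labels, predictions, threshold: float = 0.5, beta: float = 1.0) -> EvalReport:
    """Confusion + report in one call."""
    return report(*confusion(labels, predictions, threshold), beta=beta)
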