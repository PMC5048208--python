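"""Dichotomization and diagnostic test performance.

Turns raw predictor values into binary calls at a threshold and
summarizes calls against the outcome as a confusion matrix with the
derived quantities the odds-ratio chain consumes:

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    LR+ = sensitivity / (1 − specificity)
    LR− = (1 − sensitivity) / specificity
    Youden J = sensitivity + specificity − 1

Likelihood ratios are carried at full precision; rounding to the
conventional two decimals happens only at reporting time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import GROUPS

__all__ = ["PredictorSpec", "DiagnosticPerformance", "dichotomize", "performance"]

_KINDS = ("binary", "continuous")
_DIRECTIONS = ("high_is_risk", "low_is_risk")


@dataclass(frozen=True)
class PredictorSpec:
    """A predictor's assessment group, type, risk direction and cut.

    ``threshold`` may be None for a continuous predictor whose cut is to
    be learned (Youden-optimal) during model fitting; binary predictors
    have it fixed at 1 ("value == 1 is a positive call").
    """

    name: str
    group: str
    kind: str
    direction: str
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}")
        if self.kind == "binary":
            if self.threshold is None:
                object.__setattr__(self, "threshold", 1.0)
            elif self.threshold != 1:
                raise ValueError("binary predictors use threshold 1")


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Confusion counts and derived diagnostic quantities at one cut."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    lr_pos: float
    lr_neg: float
    youden_j: float
    lr_pos_infinite: bool = False
    lr_neg_zero: bool = False

    @classmethod
    def from_counts(
        cls, tp: int, fp: int, tn: int, fn: int, zero_cell_policy: str = "infinite"
    ) -> "DiagnosticPerformance":
        if min(tp, fp, tn, fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if tp + fn == 0 or tn + fp == 0:
            raise ValueError("both outcome classes must be present")
        if zero_cell_policy not in ("infinite", "haldane"):
            raise ValueError("zero_cell_policy must be 'infinite' or 'haldane'")
        if zero_cell_policy == "haldane" and 0 in (tp, fp, tn, fn):
            # Haldane–Anscombe: +0.5 to every cell before forming rates
            sens = (tp + 0.5) / (tp + fn + 1.0)
            spec = (tn + 0.5) / (tn + fp + 1.0)
        else:
            sens = tp / (tp + fn)
            spec = tn / (tn + fp)
        derived = cls.from_rates(sens, spec)
        return cls(
            tp=tp, fp=fp, tn=tn, fn=fn,
            sensitivity=sens, specificity=spec,
            lr_pos=derived.lr_pos, lr_neg=derived.lr_neg,
            youden_j=derived.youden_j,
            lr_pos_infinite=derived.lr_pos_infinite,
            lr_neg_zero=derived.lr_neg_zero,
        )

    @classmethod
    def from_rates(cls, sensitivity: float, specificity: float) -> "DiagnosticPerformance":
        """Derived quantities from a published (sens, spec) pair; counts unset."""
        if not 0.0 <= sensitivity <= 1.0 or not 0.0 <= specificity <= 1.0:
            raise ValueError("sensitivity and specificity must lie in [0, 1]")
        lr_pos_inf = specificity == 1.0
        lr_pos = np.inf if lr_pos_inf else sensitivity / (1.0 - specificity)
        if specificity == 0.0:
            lr_neg = np.inf
        else:
            lr_neg = (1.0 - sensitivity) / specificity
        return cls(
            tp=0, fp=0, tn=0, fn=0,
            sensitivity=sensitivity, specificity=specificity,
            lr_pos=float(lr_pos), lr_neg=float(lr_neg),
            youden_j=sensitivity + specificity - 1.0,
            lr_pos_infinite=lr_pos_inf,
            lr_neg_zero=sensitivity == 1.0,
        )


def dichotomize(values, spec: PredictorSpec) -> np.ndarray:
    """Binary calls for a predictor: 1 = positive (risk-indicating) call.

    Continuous: value > threshold (high_is_risk) or value <= threshold
    (low_is_risk).  Binary: the call is the value itself, which must be
    coded 0/1.
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError(
            f"predictor {spec.name!r}: missing values present; handle missingness upstream"
        )
    if spec.kind == "binary":
        if not np.isin(values, (0.0, 1.0)).all():
            raise ValueError(f"binary predictor {spec.name!r} has values outside {{0, 1}}")
        return values.astype(int)
    if spec.threshold is None:
        raise ValueError(f"continuous predictor {spec.name!r} has no threshold set")
    if spec.direction == "high_is_risk":
        return (values > spec.threshold).astype(int)
    return (values <= spec.threshold).astype(int)


def performance(calls, outcome, zero_cell_policy: str = "infinite") -> DiagnosticPerformance:
    """Confusion matrix and diagnostic quantities of binary calls.

    ``zero_cell_policy`` governs division by zero when specificity (or
    sensitivity) is exactly 1 or 0: ``infinite`` keeps the exact rates
    and flags the infinite ratio; ``haldane`` adds 0.5 to every cell.
    """
    calls = np.asarray(calls, dtype=int)
    outcome = np.asarray(outcome, dtype=int)
    if calls.shape != outcome.shape:
        raise ValueError("calls and outcome must have equal length")
    if not np.isin(calls, (0, 1)).all() or not np.isin(outcome, (0, 1)).all():
        raise ValueError("calls and outcome must be coded 0/1")
    tp = int(((calls == 1) & (outcome == 1)).sum())
    fp = int(((calls == 1) & (outcome == 0)).sum())
    tn = int(((calls == 0) & (outcome == 0)).sum())
    fn = int(((calls == 0) & (outcome == 1)).sum())
    return DiagnosticPerformance.from_counts(tp, fp, tn, fn, zero_cell_policy)
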