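"""Empirical ROC analysis: AUROC with DeLong variance, significance
against chance, Youden-optimal thresholds, and correlated-ROC
comparison.

AUROC here is the tie-corrected Mann–Whitney statistic: the probability
that a random case scores above a random control, with ties counting
one half.  Variances and covariances of correlated AUROCs use the
placement-value (structural component) estimator of DeLong, DeLong and
Clarke-Pearson.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "RocResult",
    "YoudenResult",
    "DelongComparison",
    "roc_curve",
    "auroc_test_vs_chance",
    "youden_optimal",
    "delong_compare",
]

_DIRECTIONS = ("high_is_risk", "low_is_risk")


class DelongComparison(NamedTuple):
    delta_auroc: float
    se: float
    z: float
    p: float


@dataclass
class YoudenResult:
    """Youden-optimal operating point: J = sensitivity + specificity − 1."""

    threshold: float
    j: float
    sensitivity: float
    specificity: float


@dataclass
class RocResult:
    """An empirical ROC curve with DeLong uncertainty.

    ``operating_points`` is ordered by increasing specificity (so
    sensitivity is nonincreasing along the list) and includes the two
    degenerate endpoints (sens 1/spec 0 and sens 0/spec 1).  Thresholds
    are on the original measurement scale; a positive call is
    value > threshold for ``high_is_risk`` and value <= threshold for
    ``low_is_risk``.
    """

    operating_points: list[tuple[float, float, float]]
    auroc: float
    auroc_se: float
    p_vs_chance: float
    direction: str
    n_cases: int
    n_controls: int
    zero_variance: bool = False
    # retained so paired DeLong comparison and bootstrap can reuse the data
    scores: np.ndarray = field(default=None, repr=False)
    outcome: np.ndarray = field(default=None, repr=False)

    def summary(self) -> dict:
        """AUROC with its standard error, normal 95% CI and p vs chance."""
        half = 1.959963984540054 * self.auroc_se
        return {
            "auroc": self.auroc,
            "se": self.auroc_se,
            "ci_lower": max(self.auroc - half, 0.0),
            "ci_upper": min(self.auroc + half, 1.0),
            "p_vs_chance": self.p_vs_chance,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "direction": self.direction,
        }

    def to_csv(self, path) -> None:
        """Operating points (threshold, sensitivity, specificity) as CSV."""
        import pandas as pd

        pd.DataFrame(
            self.operating_points, columns=["threshold", "sensitivity", "specificity"]
        ).to_csv(path, index=False)


def _validate(values, outcome):
    values = np.asarray(values, dtype=float)
    outcome = np.asarray(outcome)
    if values.ndim != 1 or outcome.ndim != 1 or len(values) != len(outcome):
        raise ValueError("values and outcome must be 1-D vectors of equal length")
    if np.isnan(values).any():
        raise ValueError("values contain missing entries; filter before ROC analysis")
    if not np.isin(outcome, (0, 1)).all():
        raise ValueError("outcome must be coded 0/1")
    outcome = outcome.astype(int)
    n_cases = int(outcome.sum())
    if n_cases == 0:
        raise ValueError("degenerate outcome: no cases (outcome == 1) present")
    if n_cases == len(outcome):
        raise ValueError("degenerate outcome: no controls (outcome == 0) present")
    return values, outcome


def _placements(scores: np.ndarray, outcome: np.ndarray):
    """DeLong placement values.

    Returns (auroc, V10, V01): V10[i] = average of ψ(case_i, control_j)
    over controls, V01[j] the dual, with ψ = 1 / ½ / 0 for
    greater / tied / smaller.  Mid-ranks give both in O(N log N).
    """
    cases = scores[outcome == 1]
    controls = scores[outcome == 0]
    m, n = len(cases), len(controls)
    all_ranks = rankdata(np.concatenate([cases, controls]))
    case_ranks = rankdata(cases)
    control_ranks = rankdata(controls)
    v10 = (all_ranks[:m] - case_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - control_ranks) / m
    # single division over the exact rank sum (midranks are multiples of
    # 1/2), so the result is bit-identical to exhaustive pair counting
    auroc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    return auroc, v10, v01


def _auroc_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_curve(values, outcome, direction: str = "high_is_risk") -> RocResult:
    """Empirical ROC of a predictor against a binary outcome.

    All distinct observed values serve as candidate cuts, plus the two
    infinite endpoints.  ``low_is_risk`` reverses the calling
    inequality (positive call when value <= cut).
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")
    values, outcome = _validate(values, outcome)

    # AUROC and DeLong variance on the risk-oriented score
    scores = values if direction == "high_is_risk" else -values
    auroc, v10, v01 = _placements(scores, outcome)
    var = _auroc_variance(v10, v01)
    se = float(np.sqrt(var))

    zero_variance = se == 0.0
    if zero_variance:
        p = 1.0 if auroc == 0.5 else 0.0
    else:
        z = (auroc - 0.5) / se
        p = float(2.0 * norm.sf(abs(z)))

    cases = np.sort(values[outcome == 1])
    controls = np.sort(values[outcome == 0])
    m, n = len(cases), len(controls)
    cuts = np.concatenate(([-np.inf], np.unique(values), [np.inf]))
    if direction == "high_is_risk":
        # positive call: value > t
        sens = 1.0 - np.searchsorted(cases, cuts, side="right") / m
        spec = np.searchsorted(controls, cuts, side="right") / n
    else:
        # positive call: value <= t
        sens = np.searchsorted(cases, cuts, side="right") / m
        spec = 1.0 - np.searchsorted(controls, cuts, side="right") / n
    order = np.lexsort((-sens, spec))
    points = [
        (float(cuts[k]), float(sens[k]), float(spec[k])) for k in order
    ]

    return RocResult(
        operating_points=points,
        auroc=float(auroc),
        auroc_se=se,
        p_vs_chance=p,
        direction=direction,
        n_cases=m,
        n_controls=n,
        zero_variance=zero_variance,
        scores=scores,
        outcome=outcome,
    )


def auroc_test_vs_chance(
    roc: RocResult,
    *,
    method: str = "delong",
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> float:
    """Two-sided p-value for AUROC != 0.5.

    The default is the DeLong normal approximation
    z = (AUROC − ½) / se.  ``method="permutation"`` runs a Monte-Carlo
    permutation test of the outcome labels instead — exactly valid at
    the tiny sample sizes typical of early-psychosis cohorts.
    """
    if roc.n_cases < 2 or roc.n_controls < 2:
        raise ValueError("need at least 2 cases and 2 controls to test against chance")
    if method == "delong":
        if roc.zero_variance:
            warnings.warn(
                "DeLong variance is zero (perfect or constant classifier); "
                "p-value reported as a limiting value",
                RuntimeWarning,
                stacklevel=2,
            )
        return roc.p_vs_chance
    if method == "permutation":
        rng = np.random.default_rng(seed)
        observed = abs(roc.auroc - 0.5)
        scores, outcome = roc.scores, roc.outcome.copy()
        hits = 0
        for _ in range(n_permutations):
            rng.shuffle(outcome)
            a, _, _ = _placements(scores, outcome)
            if abs(a - 0.5) >= observed - 1e-12:
                hits += 1
        return (hits + 1) / (n_permutations + 1)
    raise ValueError("method must be 'delong' or 'permutation'")


def youden_optimal(roc: RocResult) -> YoudenResult:
    """The cut maximizing J = sensitivity + specificity − 1.

    The two degenerate endpoints (infinite cuts) are excluded unless no
    interior point achieves J > 0.  Ties are broken in favour of higher
    sensitivity (a missed transition costs more than a false alarm),
    then in favour of the less extreme threshold.
    """
    pts = roc.operating_points
    interior = [p for p in pts if np.isfinite(p[0])]
    candidates = interior if interior and max(se + sp - 1.0 for _, se, sp in interior) > 0 else pts

    finite = [t for t, _, _ in pts if np.isfinite(t)]
    center = float(np.median(finite)) if finite else 0.0

    def key(point):
        t, se, sp = point
        extremity = abs(t - center) if np.isfinite(t) else np.inf
        return (se + sp - 1.0, se, -extremity)

    t, se, sp = max(candidates, key=key)
    return YoudenResult(threshold=t, j=se + sp - 1.0, sensitivity=se, specificity=sp)


def delong_compare(roc_a: RocResult, roc_b: RocResult) -> DelongComparison:
    """DeLong test for a difference between two correlated AUROCs.

    Both ROC curves must come from the same subjects (paired scores,
    identical outcome vector); the covariance of the two AUROCs is
    estimated from per-subject placement values.
    """
    if roc_a.scores is None or roc_b.scores is None:
        raise ValueError("RocResults must retain their score vectors for comparison")
    if len(roc_a.outcome) != len(roc_b.outcome) or not np.array_equal(
        roc_a.outcome, roc_b.outcome
    ):
        raise ValueError("paired comparison requires the same subjects and outcome vector")

    outcome = roc_a.outcome
    a1, v10_1, v01_1 = _placements(roc_a.scores, outcome)
    a2, v10_2, v01_2 = _placements(roc_b.scores, outcome)
    m, n = len(v10_1), len(v01_1)
    if m > 1:
        cov10 = np.cov(v10_1, v10_2, ddof=1)[0, 1]
    else:  # pragma: no cover
        cov10 = 0.0
    if n > 1:
        cov01 = np.cov(v01_1, v01_2, ddof=1)[0, 1]
    else:  # pragma: no cover
        cov01 = 0.0
    var1 = _auroc_variance(v10_1, v01_1)
    var2 = _auroc_variance(v10_2, v01_2)
    cov = cov10 / m + cov01 / n

    delta = float(a1 - a2)
    var_delta = var1 + var2 - 2.0 * cov
    se = float(np.sqrt(max(var_delta, 0.0)))
    if se == 0.0:
        z = 0.0 if delta == 0.0 else np.sign(delta) * np.inf
        p = 1.0 if delta == 0.0 else 0.0
    else:
        z = delta / se
        p = float(2.0 * norm.sf(abs(z)))
    return DelongComparison(delta_auroc=delta, se=se, z=float(z), p=p)
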