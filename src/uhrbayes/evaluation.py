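"""Combined-model evaluation: ROC over posterior probabilities,
predictive values at a prevalence, BCa bootstrap internal validation,
and paired model comparison.

PPV and NPV follow the standard identities

    PPV = sens * prev / (sens * prev + (1 - spec) * (1 - prev))
    NPV = spec * (1 - prev) / (spec * (1 - prev) + (1 - sens) * prev)

The internal-validation statistic is "sensitivity at fixed specificity":
per bootstrap replicate, the largest sensitivity among operating points
whose specificity is at least the fixed value (i.e. the point with the
smallest specificity >= the target — the conservative reading).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .roc import DelongComparison, RocResult, delong_compare, roc_curve, youden_optimal

__all__ = [
    "ModelEvaluation",
    "BootstrapCI",
    "evaluate_model",
    "sensitivity_at_specificity",
    "bootstrap_sens_at_spec",
    "compare_models",
    "predictive_values",
]


@dataclass
class ModelEvaluation:
    """Summary of a model's posterior scores against the outcome."""

    roc: RocResult
    threshold_probability: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    prevalence: float
    youden_j: float
    comparisons: list[tuple[str, float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        """Summary row mirroring the usual ROC-table columns."""
        return {
            "threshold_probability": self.threshold_probability,
            "auroc": self.roc.auroc,
            "sensitivity_pct": 100.0 * self.sensitivity,
            "specificity_pct": 100.0 * self.specificity,
            "se": self.roc.auroc_se,
            "p_auroc": self.roc.p_vs_chance,
            "ppv": self.ppv,
            "npv": self.npv,
            "prevalence": self.prevalence,
            "youden_j": self.youden_j,
        }


@dataclass
class BootstrapCI:
    statistic: str
    point: float
    lower: float
    upper: float
    n_iterations: int
    method: str
    seed: int | None
    level: float = 0.95
    n_redraws: int = 0
    degenerate: bool = False
    point_outside: bool = False


def predictive_values(sensitivity: float, specificity: float, prevalence: float):
    """(PPV, NPV) from sensitivity, specificity and prevalence."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    pos = sensitivity * prevalence + (1.0 - specificity) * (1.0 - prevalence)
    neg = specificity * (1.0 - prevalence) + (1.0 - sensitivity) * prevalence
    ppv = sensitivity * prevalence / pos if pos > 0 else 0.0
    npv = specificity * (1.0 - prevalence) / neg if neg > 0 else 1.0
    return float(ppv), float(npv)


def evaluate_model(posteriors, outcome, prevalence: float | None = None) -> ModelEvaluation:
    """Evaluate posterior transition probabilities against the outcome.

    The operating threshold on the posterior scale is Youden-optimal;
    predictive values are computed at ``prevalence`` (default: the
    sample outcome rate).
    """
    posteriors = np.asarray(posteriors, dtype=float)
    if np.nanmin(posteriors) < 0.0 or np.nanmax(posteriors) > 1.0:
        raise ValueError("posteriors must lie in [0, 1]")
    outcome = np.asarray(outcome, dtype=int)
    if len(np.unique(posteriors)) == 1:
        warnings.warn(
            "degenerate posteriors (all equal): AUROC is 0.5 and the model is uninformative",
            RuntimeWarning,
            stacklevel=2,
        )
    roc = roc_curve(posteriors, outcome, "high_is_risk")
    opt = youden_optimal(roc)
    prev = float(np.mean(outcome)) if prevalence is None else float(prevalence)
    ppv, npv = predictive_values(opt.sensitivity, opt.specificity, prev)
    return ModelEvaluation(
        roc=roc,
        threshold_probability=opt.threshold,
        sensitivity=opt.sensitivity,
        specificity=opt.specificity,
        ppv=ppv,
        npv=npv,
        prevalence=prev,
        youden_j=opt.j,
    )


def sensitivity_at_specificity(scores, outcome, fixed_specificity: float) -> float:
    """Largest sensitivity whose specificity is >= ``fixed_specificity``.

    Scores are risk-oriented (higher = riskier); a positive call is
    score > threshold.  The chosen cut is the smallest one attaining the
    required specificity.
    """
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    cases = scores[outcome == 1]
    controls = np.sort(scores[outcome == 0])
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both outcome classes are required")
    n0 = len(controls)
    k = int(np.ceil(fixed_specificity * n0))
    if k <= 0:
        return 1.0  # threshold -inf already satisfies the constraint
    t = controls[k - 1]
    return float(np.mean(cases > t))


def _bca_interval(point, reps, jack, level):
    """Efron's bias-corrected and accelerated interval from bootstrap
    replicates and jackknife leave-one-out values."""
    b = len(reps)
    # bias correction; ties with the point estimate count half
    frac = (np.sum(reps < point) + 0.5 * np.sum(reps == point)) / b
    frac = min(max(frac, 1.0 / (b + 1)), b / (b + 1.0))
    z0 = norm.ppf(frac)
    # acceleration from the jackknife
    d = jack.mean() - jack
    denom = (d ** 2).sum() ** 1.5
    a = (d ** 3).sum() / (6.0 * denom) if denom > 0 else 0.0
    alpha = (1.0 - level) / 2.0
    out = []
    for z_alpha in (norm.ppf(alpha), norm.ppf(1.0 - alpha)):
        adj = z0 + (z0 + z_alpha) / (1.0 - a * (z0 + z_alpha))
        out.append(float(np.quantile(reps, norm.cdf(adj))))
    return out[0], out[1]


def bootstrap_sens_at_spec(
    posteriors,
    outcome,
    fixed_specificity: float,
    n_iterations: int = 1000,
    seed: int | None = None,
    method: str = "bca",
    stratified: bool = False,
) -> BootstrapCI:
    """Bootstrap CI for model sensitivity at a fixed specificity.

    Subjects are resampled with replacement (whole case set by default,
    per-class when ``stratified``); replicates that draw a single
    outcome class are redrawn, up to 10 x ``n_iterations`` extra draws.
    ``method="bca"`` applies the bias-corrected and accelerated
    adjustment with jackknife acceleration; ``"percentile"`` takes plain
    quantiles.
    """
    if method not in ("bca", "percentile"):
        raise ValueError("method must be 'bca' or 'percentile'")
    scores = np.asarray(posteriors, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    n = len(scores)
    point = sensitivity_at_specificity(scores, outcome, fixed_specificity)

    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(outcome == 1)
    ctrl_idx = np.flatnonzero(outcome == 0)

    reps = np.empty(n_iterations)
    redraws = 0
    max_redraws = 10 * n_iterations
    for b in range(n_iterations):
        while True:
            if stratified:
                idx = np.concatenate(
                    [rng.choice(case_idx, len(case_idx)), rng.choice(ctrl_idx, len(ctrl_idx))]
                )
            else:
                idx = rng.integers(0, n, n)
            y = outcome[idx]
            if 0 < y.sum() < n:
                break
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("too many single-class bootstrap replicates")
        reps[b] = sensitivity_at_specificity(scores[idx], y, fixed_specificity)
    if redraws:
        warnings.warn(
            f"{redraws} single-class bootstrap replicate(s) redrawn",
            RuntimeWarning,
            stacklevel=2,
        )

    degenerate = bool(np.all(reps == reps[0]))
    if degenerate:
        lower = upper = float(reps[0])
    elif method == "percentile":
        lower, upper = (float(q) for q in np.quantile(reps, [0.025, 0.975]))
    else:
        jack = np.empty(n)
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[i] = False
            yi = outcome[mask]
            if 0 < yi.sum() < n - 1:
                jack[i] = sensitivity_at_specificity(scores[mask], yi, fixed_specificity)
            else:
                jack[i] = point
            mask[i] = True
        lower, upper = _bca_interval(point, reps, jack, 0.95)

    return BootstrapCI(
        statistic=f"sensitivity at specificity >= {fixed_specificity:g}",
        point=point,
        lower=lower,
        upper=upper,
        n_iterations=n_iterations,
        method=method,
        seed=seed,
        n_redraws=redraws,
        degenerate=degenerate,
        point_outside=not (lower <= point <= upper),
    )


def compare_models(eval_a: ModelEvaluation, eval_b: ModelEvaluation) -> DelongComparison:
    """DeLong comparison of two models evaluated on the same subjects."""
    return delong_compare(eval_a.roc, eval_b.roc)
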