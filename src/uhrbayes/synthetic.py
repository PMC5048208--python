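"""Synthetic ultra-high-risk (UHR) cohort generation.

Generates analysis-ready cohorts — one row per subject, a binary
transition outcome, and a mix of binary and continuous predictors —
with planted class-conditional structure, so that every downstream
stage (ROC screening, likelihood-ratio estimation, the sequential
odds-ratio chain, model evaluation) can be tested against known ground
truth.

Continuous predictors are drawn from class-conditional Gaussians with
equal (or per-class) standard deviation; the class means are solved
analytically so that dichotomizing at the planted threshold attains the
requested sensitivity and specificity exactly in the population.
Binary predictors are class-conditional Bernoulli draws with positivity
rate = sensitivity in cases and 1 − specificity in non-cases.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

__all__ = [
    "GROUPS",
    "PredictorGenSpec",
    "CohortSpec",
    "Cohort",
    "generate_cohort",
    "default_uhr_config",
]

GROUPS = ("historical", "clinical", "biomarker")
_KINDS = ("binary", "continuous")
_DIRECTIONS = ("high_is_risk", "low_is_risk")


@dataclass(frozen=True)
class PredictorGenSpec:
    """Generating parameters for one predictor.

    ``target_sensitivity`` and ``target_specificity`` are the operating
    characteristics that dichotomizing at ``threshold`` (with the stated
    ``direction``) must attain in the population.  For binary predictors
    the threshold is fixed at 1 and "value == 1" is a positive call.

    ``class_sd`` applies to continuous predictors; ``case_sd`` optionally
    overrides the case-class standard deviation (the two outcome groups
    need not share a variance).
    """

    name: str
    group: str
    kind: str
    direction: str
    target_sensitivity: float
    target_specificity: float
    threshold: float = 1.0
    class_sd: float = 1.0
    case_sd: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.direction not in _DIRECTIONS:
            raise ValueError(
                f"direction must be one of {_DIRECTIONS}, got {self.direction!r}"
            )
        for label in ("target_sensitivity", "target_specificity"):
            v = getattr(self, label)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{label} must lie strictly in (0, 1), got {v}")
        j = self.target_sensitivity + self.target_specificity - 1.0
        if j < 0.0:
            raise ValueError(
                f"predictor {self.name!r}: target sensitivity "
                f"{self.target_sensitivity} and specificity "
                f"{self.target_specificity} imply Youden J = {j:.4f} < 0; a "
                "positive call would be anti-informative in the stated "
                "direction, i.e. the targets require a non-monotone cut. "
                "Flip `direction` instead."
            )
        if self.kind == "continuous":
            if self.class_sd <= 0:
                raise ValueError("class_sd must be positive")
            if self.case_sd is not None and self.case_sd <= 0:
                raise ValueError("case_sd must be positive")
        if self.kind == "binary" and self.threshold != 1:
            raise ValueError("binary predictors use threshold 1 (value == 1 is a positive call)")

    # Analytic class-conditional means (continuous predictors) -------
    def class_means(self) -> tuple[float, float]:
        """Solve (case mean, control mean) so the targets hold at the cut.

        high_is_risk calls value > t positive; low_is_risk calls
        value <= t positive.
        """
        if self.kind != "continuous":
            raise ValueError("class means are defined for continuous predictors only")
        t = self.threshold
        sd1 = self.case_sd if self.case_sd is not None else self.class_sd
        sd0 = self.class_sd
        z_se = norm.ppf(self.target_sensitivity)
        z_sp = norm.ppf(self.target_specificity)
        if self.direction == "high_is_risk":
            # P(X > t | case) = sens ; P(X <= t | control) = spec
            return t + sd1 * z_se, t - sd0 * z_sp
        # P(X <= t | case) = sens ; P(X > t | control) = spec
        return t - sd1 * z_se, t + sd0 * z_sp

    def population_youden_threshold(self) -> float:
        """The cut maximizing J = sens + spec − 1 in the population.

        For the class-conditional Gaussian model this is where the two
        class densities cross (dJ/dt = ±(f0 − f1) = 0): the midpoint of
        the class means under equal SDs.  Note this coincides with the
        planted ``threshold`` only when the target sensitivity equals
        the target specificity — an emulation cannot make an asymmetric
        (sens, spec) pair hold at a cut *and* make that cut
        Youden-optimal under equal class variances.
        """
        if self.kind == "binary":
            return 1.0
        mu1, mu0 = self.class_means()
        sd1 = self.case_sd if self.case_sd is not None else self.class_sd
        sd0 = self.class_sd
        if sd1 == sd0:
            return (mu1 + mu0) / 2.0
        # unequal SDs: crossing point between the means (quadratic in t)
        a = 1.0 / sd0**2 - 1.0 / sd1**2
        b = 2.0 * (mu1 / sd1**2 - mu0 / sd0**2)
        c = mu0**2 / sd0**2 - mu1**2 / sd1**2 - 2.0 * np.log(sd1 / sd0)
        roots = np.roots([a, b, c])
        lo, hi = min(mu0, mu1), max(mu0, mu1)
        inside = [r.real for r in roots if abs(r.imag) < 1e-9 and lo <= r.real <= hi]
        return float(inside[0]) if inside else float(min(roots, key=lambda r: abs(r.real - (lo + hi) / 2)).real)


@dataclass(frozen=True)
class CohortSpec:
    """Full generating specification for a synthetic cohort."""

    n_subjects: int
    prevalence: float
    predictors: tuple[PredictorGenSpec, ...]
    dependence: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "predictors", tuple(self.predictors))
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie strictly in (0, 1)")
        if not self.predictors:
            raise ValueError("at least one predictor is required")
        if not 0.0 <= self.dependence < 1.0:
            raise ValueError("dependence must lie in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        names = [p.name for p in self.predictors]
        if len(set(names)) != len(names):
            raise ValueError("predictor names must be unique")

    @property
    def predictor_names(self) -> list[str]:
        return [p.name for p in self.predictors]

    # ---- config-file round trip ------------------------------------
    def to_yaml(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        payload["predictors"] = [dataclasses.asdict(p) for p in self.predictors]
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "CohortSpec":
        if hasattr(source, "read"):
            payload = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    payload = yaml.safe_load(fh)
            except (OSError, ValueError):
                payload = yaml.safe_load(io.StringIO(str(source)))
        preds = tuple(PredictorGenSpec(**p) for p in payload.pop("predictors"))
        return cls(predictors=preds, **payload)


@dataclass
class Cohort:
    """An analysis-ready subject × predictor table with binary outcome.

    ``values`` holds one column per predictor (binary coded 0/1 as
    floats); missing entries are NaN and are additionally exposed through
    the boolean ``missing`` mask.  Missing values are never imputed here.
    """

    subject_ids: list[str]
    outcome: np.ndarray
    values: pd.DataFrame
    spec: CohortSpec | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=int)
        if len(self.subject_ids) != len(self.outcome) or len(self.outcome) != len(self.values):
            raise ValueError("subject_ids, outcome and values must agree in length")
        if not np.isin(self.outcome, (0, 1)).all():
            raise ValueError("outcome must be coded 0/1")

    @property
    def n_subjects(self) -> int:
        return len(self.outcome)

    @property
    def missing(self) -> pd.DataFrame:
        return self.values.isna()

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out.insert(0, "transition", self.outcome)
        out.index = pd.Index(self.subject_ids, name="subject_id")
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        frame = pd.read_csv(path, index_col=0)
        if "transition" not in frame.columns:
            raise ValueError("cohort CSV must contain a 'transition' column coded 0/1")
        outcome = frame.pop("transition").to_numpy()
        return cls(
            subject_ids=[str(s) for s in frame.index],
            outcome=outcome,
            values=frame.reset_index(drop=True),
        )


def _equicorrelated_normal(rng: np.random.Generator, n: int, p: int, rho: float) -> np.ndarray:
    """n × p standard normal draws, equicorrelated at rho within each row."""
    eps = rng.standard_normal((n, p))
    if rho == 0.0:
        return eps
    shared = rng.standard_normal((n, 1))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps


def generate_cohort(spec: CohortSpec, *, allow_degenerate: bool = False) -> Cohort:
    """Draw a cohort from a :class:`CohortSpec`.

    The outcome is Bernoulli(prevalence) per subject; a draw in which one
    outcome class is empty is redrawn unless ``allow_degenerate`` is set
    (downstream ROC analysis needs both classes).  Within each outcome
    class, predictors share an equicorrelated Gaussian copula with
    correlation ``spec.dependence`` (0 = conditional independence, the
    assumption the likelihood-ratio chain makes).
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_subjects, len(spec.predictors)

    outcome = (rng.random(n) < spec.prevalence).astype(int)
    if not allow_degenerate:
        for _ in range(10_000):
            if 0 < outcome.sum() < n:
                break
            outcome = (rng.random(n) < spec.prevalence).astype(int)
        else:  # pragma: no cover - prevalence in (0,1) makes this unreachable in practice
            raise RuntimeError("could not draw a two-class outcome vector")

    values = np.empty((n, p))
    for cls_label in (1, 0):
        idx = np.flatnonzero(outcome == cls_label)
        z = _equicorrelated_normal(rng, len(idx), p, spec.dependence)
        for j, pred in enumerate(spec.predictors):
            if pred.kind == "continuous":
                mu1, mu0 = pred.class_means()
                sd = (
                    (pred.case_sd if pred.case_sd is not None else pred.class_sd)
                    if cls_label == 1
                    else pred.class_sd
                )
                mu = mu1 if cls_label == 1 else mu0
                values[idx, j] = mu + sd * z[:, j]
            else:
                rate = (
                    pred.target_sensitivity
                    if cls_label == 1
                    else 1.0 - pred.target_specificity
                )
                # threshold the latent normal so the copula carries dependence
                values[idx, j] = (z[:, j] < norm.ppf(rate)).astype(float)

    frame = pd.DataFrame(values, columns=spec.predictor_names)
    if spec.missing_rate > 0:
        mask = rng.random((n, p)) < spec.missing_rate
        frame = frame.mask(mask)

    ids = [f"S{i + 1:03d}" for i in range(n)]
    return Cohort(subject_ids=ids, outcome=outcome, values=frame, spec=spec)


def default_uhr_config(seed: int = 0) -> CohortSpec:
    """The study-scale cohort specification: n = 40, 28% one-year
    transition rate, and the seven retained predictors with their
    published sensitivity/specificity as generating targets.

    Groups: any history of drug use (historical); PANSS positive,
    negative and general subscale scores and GAF (clinical); erythrocyte
    nervonic acid and total omega-3 (biomarker).  Thresholds are the
    published Youden-optimal cuts; class SDs are set on field-typical
    scales for each instrument.
    """
    preds = (
        PredictorGenSpec(
            name="drug_use", group="historical", kind="binary",
            direction="high_is_risk", target_sensitivity=0.7273,
            target_specificity=0.7241, threshold=1,
        ),
        PredictorGenSpec(
            name="panss_positive", group="clinical", kind="continuous",
            direction="high_is_risk", target_sensitivity=0.8182,
            target_specificity=0.6552, threshold=14.0, class_sd=4.0,
        ),
        PredictorGenSpec(
            name="panss_negative", group="clinical", kind="continuous",
            direction="high_is_risk", target_sensitivity=0.7273,
            target_specificity=0.6897, threshold=12.0, class_sd=5.0,
        ),
        PredictorGenSpec(
            name="panss_general", group="clinical", kind="continuous",
            direction="high_is_risk", target_sensitivity=0.7273,
            target_specificity=0.7586, threshold=31.0, class_sd=8.0,
        ),
        PredictorGenSpec(
            name="gaf", group="clinical", kind="continuous",
            direction="low_is_risk", target_sensitivity=0.9091,
            target_specificity=0.5172, threshold=60.0, class_sd=10.0,
        ),
        PredictorGenSpec(
            name="nervonic_acid", group="biomarker", kind="continuous",
            direction="low_is_risk", target_sensitivity=0.9091,
            target_specificity=0.5357, threshold=0.2902, class_sd=0.08,
        ),
        PredictorGenSpec(
            name="total_omega3", group="biomarker", kind="continuous",
            direction="low_is_risk", target_sensitivity=0.8182,
            target_specificity=0.6786, threshold=5.0727, class_sd=1.2,
        ),
    )
    return CohortSpec(n_subjects=40, prevalence=0.28, predictors=preds, seed=seed)
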