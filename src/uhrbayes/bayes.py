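"""Sequential combination of grouped likelihood ratios — the odds-ratio
form of Bayes' rule.

The model starts from the pretest odds of transition,

    pretest odds = p / (1 − p),

multiplies in one likelihood ratio per predictor — LR+ for a positive
call, LR− for a negative call — group by group in the configured
assessment order (historical → clinical → biomarker by default), and
converts back,

    posterior probability = odds / (1 + odds).

Under the conditional-independence (naive Bayes) assumption this equals
the exact posterior P(transition | calls).  The stepwise trajectory of
probabilities after each assessment group is retained per case, which is
what makes the staged-assessment reading of the model possible.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .metrics import PredictorSpec

__all__ = [
    "probability_to_odds",
    "odds_to_probability",
    "BayesModel",
    "CaseTrajectory",
    "case_posterior",
    "fit_model",
]


def probability_to_odds(p: float) -> float:
    """odds = p / (1 − p); defined for 0 <= p < 1."""
    if not 0.0 <= p < 1.0:
        if p == 1.0:
            raise ValueError("p = 1 has infinite odds")
        raise ValueError(f"probability must lie in [0, 1), got {p}")
    return p / (1.0 - p)


def odds_to_probability(o: float) -> float:
    """p = o / (1 + o); inverse of :func:`probability_to_odds` on [0, 1)."""
    if o < 0.0:
        raise ValueError(f"odds must be nonnegative, got {o}")
    if math.isinf(o):
        return 1.0
    return o / (1.0 + o)


@dataclass
class CaseTrajectory:
    """Per-case stepwise evolution of transition probability.

    ``probabilities`` starts at ("pretest", pretest probability) and
    appends one entry per assessment group.  An excluded case (missing
    required predictor under the whole-case exclusion policy) carries
    ``final_probability = nan`` and the reason.
    """

    subject_id: str
    probabilities: list[tuple[str, float]]
    final_probability: float
    excluded: bool = False
    exclusion_reason: str | None = None


@dataclass
class BayesModel:
    """A fitted sequential likelihood-ratio model.

    ``lr_table`` maps predictor name → (LR+, LR−) at full precision;
    ``grouping`` is the ordered list of (group name, ordered predictor
    names) defining the assessment sequence; ``predictor_specs`` carry
    the thresholds and directions needed to dichotomize raw values.
    """

    pretest_probability: float
    lr_table: dict[str, tuple[float, float]]
    grouping: list[tuple[str, list[str]]]
    predictor_specs: list[PredictorSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.pretest_probability < 1.0:
            raise ValueError("pretest_probability must lie strictly in (0, 1)")
        grouped = [n for _, names in self.grouping for n in names]
        if len(set(grouped)) != len(grouped):
            raise ValueError("each predictor may appear in exactly one group")
        missing = [n for n in grouped if n not in self.lr_table]
        if missing:
            raise ValueError(f"predictors missing from lr_table: {missing}")
        if self.predictor_specs:
            spec_names = {s.name for s in self.predictor_specs}
            absent = [n for n in grouped if n not in spec_names]
            if absent:
                raise ValueError(f"predictors missing from predictor_specs: {absent}")

    @property
    def predictor_names(self) -> list[str]:
        return [n for _, names in self.grouping for n in names]

    def spec_for(self, name: str) -> PredictorSpec:
        for s in self.predictor_specs:
            if s.name == name:
                return s
        raise KeyError(name)

    # ---- the chain ---------------------------------------------------
    def trajectory(
        self,
        calls: dict,
        subject_id: str = "case",
        missing_policy: str = "exclude",
    ) -> CaseTrajectory:
        """Posterior trajectory for one case's binary calls.

        ``calls`` maps predictor name → 1 (positive), 0 (negative) or
        None/NaN (missing).  Under ``missing_policy="exclude"`` any
        missing required predictor excludes the whole case; under
        ``"skip"`` a missing predictor simply contributes no update.
        """
        if missing_policy not in ("exclude", "skip"):
            raise ValueError("missing_policy must be 'exclude' or 'skip'")
        unknown = [k for k in calls if k not in self.lr_table]
        if unknown:
            raise ValueError(f"unknown predictor name(s): {unknown}")

        def is_missing(v) -> bool:
            return v is None or (isinstance(v, float) and math.isnan(v))

        needed = self.predictor_names
        missing = [n for n in needed if is_missing(calls.get(n, None))]
        if missing and missing_policy == "exclude":
            return CaseTrajectory(
                subject_id=subject_id,
                probabilities=[("pretest", self.pretest_probability)],
                final_probability=float("nan"),
                excluded=True,
                exclusion_reason="missing data: " + ", ".join(missing),
            )

        odds = probability_to_odds(self.pretest_probability)
        steps = [("pretest", self.pretest_probability)]
        for group, names in self.grouping:
            for name in names:
                v = calls.get(name, None)
                if is_missing(v):
                    continue  # skip policy: no update
                if v not in (0, 1):
                    raise ValueError(f"call for {name!r} must be 0, 1 or missing, got {v!r}")
                lr_pos, lr_neg = self.lr_table[name]
                odds *= lr_pos if v == 1 else lr_neg
            steps.append((group, odds_to_probability(odds)))
        return CaseTrajectory(
            subject_id=subject_id,
            probabilities=steps,
            final_probability=steps[-1][1],
        )

    def posterior(self, calls: dict, missing_policy: str = "exclude") -> float:
        return self.trajectory(calls, missing_policy=missing_policy).final_probability

    # ---- serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "pretest_probability": self.pretest_probability,
            "lr_table": {k: list(v) for k, v in self.lr_table.items()},
            "grouping": [[g, list(names)] for g, names in self.grouping],
            "predictor_specs": [dataclasses.asdict(s) for s in self.predictor_specs],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, payload: dict) -> "BayesModel":
        return cls(
            pretest_probability=payload["pretest_probability"],
            lr_table={k: tuple(v) for k, v in payload["lr_table"].items()},
            grouping=[(g, list(names)) for g, names in payload["grouping"]],
            predictor_specs=[PredictorSpec(**s) for s in payload.get("predictor_specs", [])],
        )

    @classmethod
    def from_json(cls, source) -> "BayesModel":
        if hasattr(source, "read"):
            return cls.from_dict(json.load(source))
        text = str(source)
        if text.lstrip().startswith("{"):
            return cls.from_dict(json.loads(text))
        with open(text) as fh:
            return cls.from_dict(json.load(fh))


def case_posterior(
    calls: dict,
    model: BayesModel,
    subject_id: str = "case",
    missing_policy: str = "exclude",
) -> CaseTrajectory:
    """Stepwise posterior for one case (thin wrapper over
    :meth:`BayesModel.trajectory`)."""
    return model.trajectory(calls, subject_id=subject_id, missing_policy=missing_policy)


def fit_model(
    cohort,
    candidate_specs,
    grouping=None,
    alpha: float = 0.05,
    pretest_probability: float | None = None,
    zero_cell_policy: str = "infinite",
) -> BayesModel:
    """Fit the staged likelihood-ratio model on a cohort.

    Thin wrapper over :class:`uhrbayes.model.BayesChainClassifier`:
    (1) screen candidates by AUROC significantly different from 0.5 at
    ``alpha``; (2) set Youden-optimal thresholds for retained continuous
    predictors; (3) estimate LR+/LR− at those cuts; (4) assemble the
    grouped model with pretest probability defaulting to the cohort's
    outcome rate.
    """
    from .model import BayesChainClassifier

    clf = BayesChainClassifier(
        candidate_specs=candidate_specs,
        grouping=grouping,
        alpha=alpha,
        pretest_probability=pretest_probability,
        zero_cell_policy=zero_cell_policy,
    )
    clf.fit(cohort.values, np.asarray(cohort.outcome))
    return clf.model_
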