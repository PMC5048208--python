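"""Shared fixtures: the published operating characteristics of the
seven retained predictors, and the planted default model built from
them at full precision."""

from __future__ import annotations

import numpy as np
import pytest

from uhrbayes import BayesModel, PredictorSpec, default_uhr_config, dichotomize
from uhrbayes.metrics import DiagnosticPerformance

# Published sensitivity/specificity (percent / 100) of the seven
# retained predictors, and the 2-dp likelihood ratios they imply.
TABLE2 = {
    "drug_use": (0.7273, 0.7241, 2.64, 0.38),
    "panss_positive": (0.8182, 0.6552, 2.37, 0.28),
    "panss_negative": (0.7273, 0.6897, 2.34, 0.40),
    "panss_general": (0.7273, 0.7586, 3.01, 0.36),
    "gaf": (0.9091, 0.5172, 1.88, 0.18),
    "nervonic_acid": (0.9091, 0.5357, 1.96, 0.17),
    "total_omega3": (0.8182, 0.6786, 2.55, 0.27),
}

GROUPING = [
    ("historical", ["drug_use"]),
    ("clinical", ["panss_positive", "panss_negative", "panss_general", "gaf"]),
    ("biomarker", ["nervonic_acid", "total_omega3"]),
]


def planted_model(pretest: float = 0.28) -> BayesModel:
    """The default staged model with full-precision LRs derived from the
    published sensitivity/specificity pairs."""
    spec = default_uhr_config()
    lr_table = {}
    for name, (sens, spec_, _, _) in TABLE2.items():
        perf = DiagnosticPerformance.from_rates(sens, spec_)
        lr_table[name] = (perf.lr_pos, perf.lr_neg)
    predictor_specs = [
        PredictorSpec(p.name, p.group, p.kind, p.direction, p.threshold)
        for p in spec.predictors
    ]
    return BayesModel(
        pretest_probability=pretest,
        lr_table=lr_table,
        grouping=[(g, list(ns)) for g, ns in GROUPING],
        predictor_specs=predictor_specs,
    )


def subset_posteriors(model: BayesModel, cohort, groups) -> np.ndarray:
    """Chain posteriors using only the given assessment groups,
    dichotomizing the cohort's raw values at the model's thresholds."""
    grouping = [(g, ns) for g, ns in model.grouping if g in groups]
    names = [n for _, ns in grouping for n in ns]
    sub = BayesModel(
        pretest_probability=model.pretest_probability,
        lr_table={n: model.lr_table[n] for n in names},
        grouping=grouping,
        predictor_specs=[s for s in model.predictor_specs if s.name in names],
    )
    calls = {
        s.name: dichotomize(cohort.values[s.name].to_numpy(), s)
        for s in sub.predictor_specs
    }
    return np.array(
        [
            sub.posterior({n: int(calls[n][i]) for n in names})
            for i in range(cohort.n_subjects)
        ]
    )


@pytest.fixture(scope="session")
def uhr_spec():
    return default_uhr_config()


@pytest.fixture(scope="session")
def default_model():
    return planted_model()
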