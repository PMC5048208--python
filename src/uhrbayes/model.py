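"""scikit-learn-style estimator for the staged likelihood-ratio model.

``BayesChainClassifier`` wraps the full fitting pipeline — ROC screen of
candidate predictors against chance, Youden-optimal dichotomization of
continuous predictors, likelihood-ratio estimation, and assembly into
the grouped sequential odds-ratio chain — behind the familiar
fit / predict_proba / predict surface, so the model composes with
sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .bayes import BayesModel, CaseTrajectory
from .metrics import PredictorSpec, dichotomize, performance
from .roc import roc_curve, youden_optimal
from .synthetic import GROUPS

__all__ = ["BayesChainClassifier", "candidate_specs_from_cohort_spec"]


def candidate_specs_from_cohort_spec(cohort_spec) -> list[PredictorSpec]:
    """Candidate predictor specs (thresholds unset, to be learned) from a
    synthetic-cohort generating spec."""
    out = []
    for p in cohort_spec.predictors:
        out.append(
            PredictorSpec(
                name=p.name,
                group=p.group,
                kind=p.kind,
                direction=p.direction,
                threshold=1.0 if p.kind == "binary" else None,
            )
        )
    return out


class BayesChainClassifier(ClassifierMixin, BaseEstimator):
    """Staged probabilistic classifier chaining diagnostic likelihood
    ratios via the odds-ratio form of Bayes' rule.

    Parameters
    ----------
    candidate_specs : list of PredictorSpec, optional
        Candidate predictors.  Continuous candidates with
        ``threshold=None`` get a Youden-optimal cut during fitting.
        If omitted, every column of X becomes a candidate: columns whose
        non-missing values are all 0/1 are treated as binary, the rest as
        continuous, direction inferred from the data (the orientation
        with AUROC >= 0.5), and all assigned to the "clinical" group.
    grouping : list of (group name, list of predictor names), optional
        Assessment order.  Defaults to the candidates' groups in the
        order historical -> clinical -> biomarker, preserving candidate
        order within a group.
    alpha : float
        Significance level of the AUROC-versus-chance screen; candidates
        with DeLong p >= alpha are dropped.
    pretest_probability : float, optional
        Baseline transition probability.  Defaults to the training
        outcome rate.
    zero_cell_policy : {"infinite", "haldane"}
        How likelihood ratios behave when a confusion cell is empty.
    missing_policy : {"exclude", "skip"}
        Prediction-time handling of missing predictor values: exclude
        the whole case (posterior = NaN) or skip the predictor.

    Attributes
    ----------
    model_ : BayesModel
        The fitted chain (pretest probability, LR table, grouping).
    specs_ : list of PredictorSpec
        Retained predictors with learned thresholds.
    performance_ : dict
        name -> DiagnosticPerformance at the chosen cut.
    screen_ : pandas.DataFrame
        Per-candidate ROC screen (n, AUROC, SE, p, Youden J, threshold,
        retained flag).
    threshold_ : float
        Youden-optimal probability cut on the training posteriors, used
        by :meth:`predict`.
    """

    def __init__(
        self,
        candidate_specs=None,
        grouping=None,
        alpha: float = 0.05,
        pretest_probability: float | None = None,
        zero_cell_policy: str = "infinite",
        missing_policy: str = "exclude",
    ):
        self.candidate_specs = candidate_specs
        self.grouping = grouping
        self.alpha = alpha
        self.pretest_probability = pretest_probability
        self.zero_cell_policy = zero_cell_policy
        self.missing_policy = missing_policy

    # ---- helpers -----------------------------------------------------
    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X.reset_index(drop=True)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.candidate_specs is not None:
            if X.shape[1] != len(self.candidate_specs):
                raise ValueError(
                    "array X must have one column per candidate predictor "
                    f"({len(self.candidate_specs)}), got {X.shape[1]}"
                )
            cols = [s.name for s in self.candidate_specs]
        elif hasattr(self, "feature_names_in_"):
            cols = list(self.feature_names_in_)
        else:
            cols = [f"x{j}" for j in range(X.shape[1])]
        return pd.DataFrame(X, columns=cols)

    def _infer_candidates(self, frame: pd.DataFrame, y: np.ndarray) -> list[PredictorSpec]:
        specs = []
        for col in frame.columns:
            v = frame[col].to_numpy(dtype=float)
            ok = ~np.isnan(v)
            binary = np.isin(v[ok], (0.0, 1.0)).all()
            roc = roc_curve(v[ok], y[ok], "high_is_risk")
            direction = "high_is_risk" if roc.auroc >= 0.5 else "low_is_risk"
            specs.append(
                PredictorSpec(
                    name=str(col),
                    group="clinical",
                    kind="binary" if binary else "continuous",
                    direction=direction,
                    threshold=1.0 if binary else None,
                )
            )
        return specs

    # ---- estimator API -----------------------------------------------
    def fit(self, X, y):
        frame = self._as_frame(X)
        y = np.asarray(y, dtype=int)
        if y.ndim != 1 or len(y) != len(frame):
            raise ValueError("y must be a 1-D outcome vector matching X")
        classes = np.unique(y)
        if not np.isin(classes, (0, 1)).all() or len(classes) != 2:
            raise ValueError("y must contain both outcome classes, coded 0/1")

        candidates = (
            list(self.candidate_specs)
            if self.candidate_specs is not None
            else self._infer_candidates(frame, y)
        )
        missing_cols = [s.name for s in candidates if s.name not in frame.columns]
        if missing_cols:
            raise ValueError(f"X lacks candidate predictor column(s): {missing_cols}")

        screen_rows = []
        retained: list[PredictorSpec] = []
        perf = {}
        for spec in candidates:
            v = frame[spec.name].to_numpy(dtype=float)
            ok = ~np.isnan(v)  # pairwise deletion per predictor
            roc = roc_curve(v[ok], y[ok], spec.direction)
            keep = roc.p_vs_chance < self.alpha
            threshold = spec.threshold
            yj = np.nan
            if spec.kind == "continuous" and threshold is None:
                opt = youden_optimal(roc)
                threshold, yj = opt.threshold, opt.j
            if keep:
                fitted = PredictorSpec(
                    name=spec.name, group=spec.group, kind=spec.kind,
                    direction=spec.direction, threshold=threshold,
                )
                calls = dichotomize(v[ok], fitted)
                perf[spec.name] = performance(calls, y[ok], self.zero_cell_policy)
                yj = perf[spec.name].youden_j
                retained.append(fitted)
            screen_rows.append(
                {
                    "predictor": spec.name, "group": spec.group,
                    "n": int(ok.sum()), "auroc": roc.auroc,
                    "auroc_se": roc.auroc_se, "p_vs_chance": roc.p_vs_chance,
                    "youden_j": yj, "threshold": threshold,
                    "direction": spec.direction, "retained": bool(keep),
                }
            )
        self.screen_ = pd.DataFrame(screen_rows)
        if not retained:
            pvals = ", ".join(
                f"{r['predictor']}: p={r['p_vs_chance']:.4g}" for r in screen_rows
            )
            raise ValueError(
                f"no candidate predictor passed the AUROC screen at alpha={self.alpha} "
                f"({pvals})"
            )

        retained_names = {s.name for s in retained}
        if self.grouping is not None:
            grouping = [
                (g, [n for n in names if n in retained_names])
                for g, names in self.grouping
            ]
            grouping = [(g, names) for g, names in grouping if names]
        else:
            grouping = []
            for g in GROUPS:
                names = [s.name for s in retained if s.group == g]
                if names:
                    grouping.append((g, names))

        pretest = (
            float(np.mean(y))
            if self.pretest_probability is None
            else float(self.pretest_probability)
        )
        self.specs_ = retained
        self.performance_ = perf
        self.lr_table_ = {n: (perf[n].lr_pos, perf[n].lr_neg) for n in perf}
        self.pretest_ = pretest
        self.model_ = BayesModel(
            pretest_probability=pretest,
            lr_table={n: self.lr_table_[n] for n in (m for _, ns in grouping for m in ns)},
            grouping=grouping,
            predictor_specs=retained,
        )
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = frame.shape[1]
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)

        # Youden-optimal probability cut on the training posteriors
        post = self._posteriors(frame)
        ok = ~np.isnan(post)
        self.threshold_ = youden_optimal(roc_curve(post[ok], y[ok], "high_is_risk")).threshold
        return self

    def _calls_row(self, row: pd.Series) -> dict:
        calls = {}
        for spec in self.model_.predictor_specs:
            v = row[spec.name]
            if pd.isna(v):
                calls[spec.name] = None
            else:
                calls[spec.name] = int(dichotomize(np.array([v]), spec)[0])
        return calls

    def trajectories(self, X) -> list[CaseTrajectory]:
        """Per-case stepwise probability trajectories."""
        check_is_fitted(self, "model_")
        frame = self._as_frame(X)
        ids = (
            [str(i) for i in X.index]
            if isinstance(X, pd.DataFrame)
            else [f"case{i}" for i in range(len(frame))]
        )
        return [
            self.model_.trajectory(self._calls_row(row), subject_id=sid,
                                   missing_policy=self.missing_policy)
            for sid, (_, row) in zip(ids, frame.iterrows())
        ]

    def _posteriors(self, frame: pd.DataFrame) -> np.ndarray:
        return np.array(
            [
                self.model_.posterior(self._calls_row(row), missing_policy=self.missing_policy)
                for _, row in frame.iterrows()
            ]
        )

    def predict_proba(self, X) -> np.ndarray:
        """Posterior transition probabilities, column-stacked as
        [P(no transition), P(transition)].  Excluded cases are NaN."""
        check_is_fitted(self, "model_")
        p = self._posteriors(self._as_frame(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        """Binary call at the fitted Youden-optimal probability cut."""
        check_is_fitted(self, "model_")
        p = self.predict_proba(X)[:, 1]
        return (p > self.threshold_).astype(int)
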